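"""Direct estimation of age-specific and total fertility rates.

Birth histories are recorded DHS-style in century-month codes (CMC):
every date is an integer count of months since a fixed epoch, and all
age/exposure arithmetic is exact integer month arithmetic.  Rates are
computed over the retrospective window of ``window_months`` (default 36)
months ending at — and including — the interview month, restricted to
maternal ages 15-49, i.e. the seven five-year groups
[15,20), [20,25), ..., [45,50).

Conventions (documented because the source data convention is silent):

* the window is the right-closed month interval (doi - W, doi];
* age at calendar month m is ``m - dob`` months; group boundaries sit at
  exact multiples of 60 months from age 180, lower-inclusive;
* births to mothers younger than 15 or 50+ at delivery are excluded from
  the numerators and reported in a diagnostics tally;
* an age group with zero exposure has an undefined ASFR: it contributes 0
  to the TFR and sets a completeness flag instead of propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "AGE_GROUP_LABELS",
    "N_AGE_GROUPS",
    "WomanRecord",
    "AgeGroupRates",
    "exposure_by_age_group",
    "births_by_age_group",
    "weighted_rates",
    "tfr_from_asfr",
]

N_AGE_GROUPS = 7
AGE_GROUP_LABELS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]
_AGE_MIN_MONTHS = 15 * 12          # 180
_AGE_MAX_MONTHS = 50 * 12          # 600
_GROUP_WIDTH_MONTHS = 5 * 12       # 60


@dataclass
class WomanRecord:
    """One woman's birth history in months-since-epoch (CMC) form."""

    woman_id: str
    cluster_id: str
    dob_cmc: int
    doi_cmc: int
    weight: float
    child_dobs_cmc: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.doi_cmc <= self.dob_cmc:
            raise ValueError(
                f"woman {self.woman_id}: interview month {self.doi_cmc} "
                f"not after birth month {self.dob_cmc}"
            )
        if self.weight < 0:
            raise ValueError(f"woman {self.woman_id}: negative weight {self.weight}")
        for cd in self.child_dobs_cmc:
            if cd > self.doi_cmc:
                raise ValueError(
                    f"woman {self.woman_id}: child born month {cd} after "
                    f"interview month {self.doi_cmc}"
                )


@dataclass
class AgeGroupRates:
    """Weighted births, exposure and rates for the seven 15-49 age groups.

    ``asfr`` entries are births per woman-year; ``tfr = 5 * sum(asfr)``
    with undefined groups (zero exposure) contributing 0 and flagged in
    ``undefined_groups``.  ``births_out_of_age_range`` counts live births
    inside the window whose mother was outside [15, 50) at delivery.
    """

    births: np.ndarray
    exposure: np.ndarray
    asfr: np.ndarray
    tfr: float
    undefined_groups: np.ndarray        # boolean mask, True where exposure == 0
    births_out_of_age_range: float = 0.0

    @property
    def complete(self) -> bool:
        return not bool(self.undefined_groups.any())

    @property
    def summed_asfr(self) -> float:
        """Sum of the seven group ASFRs, i.e. TFR / 5."""
        return float(self.tfr / 5.0)


def _window_bounds(doi_cmc: int, window_months: int) -> Tuple[int, int]:
    if window_months <= 0:
        raise ValueError(f"window_months must be positive, got {window_months}")
    # right-closed interval of exactly window_months months ending at doi
    return doi_cmc - window_months + 1, doi_cmc


def exposure_by_age_group(woman: WomanRecord, window_months: int = 36) -> np.ndarray:
    """Woman-years of exposure per age group within the window.

    The exposure in group ``a`` is the number of calendar months in the
    window during which the woman's age in months lies in
    ``[180 + 60 a, 180 + 60 (a+1))``, divided by 12.
    """
    w_lo, w_hi = _window_bounds(woman.doi_cmc, window_months)
    out = np.zeros(N_AGE_GROUPS)
    for a in range(N_AGE_GROUPS):
        # months m with age m - dob in [g_lo, g_hi)
        g_lo = woman.dob_cmc + _AGE_MIN_MONTHS + a * _GROUP_WIDTH_MONTHS
        g_hi = g_lo + _GROUP_WIDTH_MONTHS
        months = min(w_hi, g_hi - 1) - max(w_lo, g_lo) + 1
        out[a] = max(months, 0) / 12.0
    return out


def births_by_age_group(woman: WomanRecord, window_months: int = 36) -> np.ndarray:
    """Live births in the window, tallied by the mother's age group at birth."""
    counts, _ = _births_detail(woman, window_months)
    return counts


def _births_detail(woman: WomanRecord, window_months: int) -> Tuple[np.ndarray, int]:
    w_lo, w_hi = _window_bounds(woman.doi_cmc, window_months)
    counts = np.zeros(N_AGE_GROUPS)
    dropped = 0
    for cd in woman.child_dobs_cmc:
        if cd > woman.doi_cmc:
            raise ValueError(
                f"woman {woman.woman_id}: child born month {cd} after interview"
            )
        if not (w_lo <= cd <= w_hi):
            continue
        age = cd - woman.dob_cmc
        if _AGE_MIN_MONTHS <= age < _AGE_MAX_MONTHS:
            counts[(age - _AGE_MIN_MONTHS) // _GROUP_WIDTH_MONTHS] += 1
        else:
            dropped += 1
    return counts, dropped


def weighted_rates(women: Iterable[WomanRecord],
                   window_months: int = 36) -> AgeGroupRates:
    """Weighted direct ASFR/TFR estimator over a collection of women.

    births[a] = sum_i w_i b_i[a], exposure[a] = sum_i w_i e_i[a],
    asfr = births / exposure, tfr = 5 * sum(asfr).
    """
    births = np.zeros(N_AGE_GROUPS)
    exposure = np.zeros(N_AGE_GROUPS)
    dropped = 0.0
    n = 0
    for woman in women:
        if woman.weight < 0:
            raise ValueError(f"woman {woman.woman_id}: negative weight")
        e = exposure_by_age_group(woman, window_months)
        b, d = _births_detail(woman, window_months)
        births += woman.weight * b
        exposure += woman.weight * e
        dropped += woman.weight * d
        n += 1
    if n == 0 or exposure.sum() <= 0:
        raise ValueError("no woman with positive exposure in the window")
    undefined = exposure <= 0
    asfr = np.zeros(N_AGE_GROUPS)
    np.divide(births, exposure, out=asfr, where=~undefined)
    return AgeGroupRates(
        births=births,
        exposure=exposure,
        asfr=asfr,
        tfr=tfr_from_asfr(asfr),
        undefined_groups=undefined,
        births_out_of_age_range=dropped,
    )


def tfr_from_asfr(asfr: Sequence[float]) -> float:
    """Total fertility rate implied by a 7-group ASFR schedule: 5 * sum."""
    asfr = np.asarray(asfr, dtype=float)
    if asfr.shape != (N_AGE_GROUPS,):
        raise ValueError(f"expected {N_AGE_GROUPS} rates, got shape {asfr.shape}")
    if np.any(asfr < 0):
        raise ValueError("ASFR entries must be nonnegative")
    return float(5.0 * asfr.sum())
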