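"""Published summary counts of the reference weaning cohort.

The difficult-to-wean ICU cohort the package's generator defaults are
calibrated to was published only as group-level summaries: 71 T-piece
trials in 51 patients, 32 failed trials, with per-group counts for the
categorical characteristics.  Those counts are reproduced here so that the
categorical group comparisons can be recomputed exactly without any
patient-level data (a 2x2 test depends on its table alone).
"""

from __future__ import annotations

from .stats import TwoByTwo

#: trials by outcome: (failed, successful)
GROUP_SIZES: tuple[int, int] = (32, 39)

#: per characteristic: count with the characteristic in (fail, success)
CATEGORICAL_COUNTS: dict[str, tuple[int, int]] = {
    "male": (17, 24),
    "chronic_respiratory_failure": (15, 10),
    "cardiac_failure": (15, 15),
    "stroke": (8, 3),
    "dementia_or_anoxic_encephalopathy": (6, 1),
    "icu_acquired_weakness": (15, 9),
    "cvvhd": (1, 1),
    "tracheostomy": (16, 1),
    "death": (13, 3),
}

#: age summaries per outcome group: (mean, sd)
AGE_SUMMARY: dict[str, tuple[float, float]] = {
    "fail": (74.5, 11.1),
    "success": (67.7, 15.3),
}

N_PATIENTS: int = 51
PATIENT_DEATHS: int = 11


def two_by_two(name: str) -> TwoByTwo:
    """The outcome-by-characteristic 2x2 table for a published count row."""
    yes_fail, yes_success = CATEGORICAL_COUNTS[name]
    n_fail, n_success = GROUP_SIZES
    return TwoByTwo(
        a=yes_fail,
        b=yes_success,
        c=n_fail - yes_fail,
        d=n_success - yes_success,
    )


def pooled_mean_age() -> float:
    """Whole-sample mean age implied by the group means and sizes."""
    n_fail, n_success = GROUP_SIZES
    return (
        n_fail * AGE_SUMMARY["fail"][0] + n_success * AGE_SUMMARY["success"][0]
    ) / (n_fail + n_success)
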