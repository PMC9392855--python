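"""Synthetic weaning-trial cohorts calibrated to the reference study summary.

No patient-level data exist for the difficult-to-wean cohort the package's
defaults describe (71 T-piece trials in 51 ICU patients, 32 failed trials);
only group-level summaries were published.  This module generates cohorts
with that statistical structure so every downstream stage — index
derivation, group comparisons, ROC analysis, stepwise regression — runs
end to end without external data.

Generative model, per trial:

* outcome ~ Bernoulli(failure_probability);
* covariates drawn per outcome group (normals for continuous covariates,
  the published prevalences for the binary flags);
* for each calibrated index, pre ~ truncated Normal(group pre mean, sd)
  and change% ~ Normal(group change mean, sd), post = pre * (1 + chg/100),
  with change draws resampled until the post value is physiologic;
* the underlying gas tensions are then back-solved so that
  :func:`modrer.bloodgas.derive_index_panel` reproduces the drawn pH,
  PaCO2, ScvO2, lactate and Mod-RER values exactly: PaO2 and PcvO2 come
  from plausible truncated normals (difference floored at 5 mmHg), PcvCO2
  is set to mod_rer * (PaO2 - PcvO2), SaO2 follows a fixed Hill-type
  dissociation curve of PaO2, and ScvO2 is the drawn index value itself.

Everything is driven by one :class:`numpy.random.Generator`; the same seed
and spec give a byte-identical cohort CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .bloodgas import (
    COMORBIDITY_FLAGS,
    BloodGasPanel,
    Outcome,
    Sex,
    TrialRecord,
)


class BacksolveError(RuntimeError):
    """Raised when no physiologic gas panel matches the drawn index values."""


@dataclass(frozen=True)
class GroupNormal:
    """Truncated-normal parameters for one covariate, per outcome group."""

    fail_mean: float
    fail_sd: float
    success_mean: float
    success_sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.fail_sd < 0 or self.success_sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must be ordered")


@dataclass(frozen=True)
class IndexCalibration:
    """Pre-value and percent-change distributions for one index, per group."""

    pre: GroupNormal
    change: GroupNormal  # percent scale; untruncated, post bounds apply instead
    post_lo: float
    post_hi: float


def _prev(k_fail: int, k_success: int) -> tuple[float, float]:
    return k_fail / 32.0, k_success / 39.0


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Defaults encode the published summary of the reference cohort: 71
    trials, 51 patients, failure fraction 32/71 = 0.451, Table-style group
    means/SDs for the covariates and for each index's pre value and
    percent change.  ScvO2 is parameterised on the percent scale (as
    printed) and converted to a fraction when panels are built.
    """

    n_trials: int = 71
    n_patients: int = 51
    failure_probability: float = 32.0 / 71.0
    male_prevalence: tuple[float, float] = _prev(17, 24)
    comorbidity_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "chronic_respiratory_failure": _prev(15, 10),
            "cardiac_failure": _prev(15, 15),
            "stroke": _prev(8, 3),
            "dementia_or_anoxic_encephalopathy": _prev(6, 1),
            "icu_acquired_weakness": _prev(15, 9),
            "cvvhd": _prev(1, 1),
            "tracheostomy": _prev(16, 1),
        }
    )
    age: GroupNormal = GroupNormal(74.5, 11.1, 67.7, 15.3, 18.0, 105.0)
    # medians/IQRs published for these two; normal stand-ins use the median
    # as mean and IQR/1.349 as sd
    days_intubated: GroupNormal = GroupNormal(21.5, 21.9, 5.0, 8.2, 0.5, 400.0)
    trial_duration: GroupNormal = GroupNormal(102.5, 159.4, 75.0, 70.4, 10.0, 1440.0)
    apache_ii: GroupNormal = GroupNormal(23.4, 8.4, 21.4, 8.2, 0.0, 71.0)
    indices: dict[str, IndexCalibration] = field(
        default_factory=lambda: {
            "ph": IndexCalibration(
                GroupNormal(7.42, 0.04, 7.44, 0.05, 6.90, 7.75),
                GroupNormal(-0.48, 0.63, -1.99, 11.41),
                6.60, 7.95,
            ),
            "paco2": IndexCalibration(
                GroupNormal(39.33, 7.06, 38.88, 6.33, 15.0, 90.0),
                GroupNormal(11.08, 11.28, 4.48, 10.59),
                10.0, 150.0,
            ),
            "scvo2": IndexCalibration(  # percent scale
                GroupNormal(67.08, 7.84, 68.28, 7.23, 25.0, 88.0),
                GroupNormal(-2.81, 8.59, 2.91, 10.79),
                15.0, 95.0,
            ),
            "lactate": IndexCalibration(
                GroupNormal(1.31, 0.46, 1.49, 0.84, 0.2, 8.0),
                GroupNormal(1.28, 22.8, 3.07, 16.66),
                0.05, 15.0,
            ),
            "mod_rer": IndexCalibration(
                GroupNormal(1.25, 0.73, 1.14, 0.58, 0.15, 4.5),
                GroupNormal(54.77, 59.57, 3.32, 63.69),
                0.10, 9.0,
            ),
        }
    )
    # gas back-solve parameters (mean, sd, lo, hi); the PaO2 level is chosen
    # so that mod_rer * (PaO2 - PcvO2) lands on a physiologic PcvCO2 (~45
    # mmHg) and the emergent cv-arterial CO2 gap near 6 mmHg
    pao2: tuple[float, float, float, float] = (78.0, 12.0, 55.0, 300.0)
    pcvo2: tuple[float, float, float, float] = (42.0, 6.0, 25.0, 60.0)
    min_po2_diff: float = 5.0
    hill_p50: float = 26.6
    hill_n: float = 2.7
    hemoglobin: tuple[float, float, float, float] = (10.5, 1.5, 7.0, 17.0)
    include_hemoglobin: bool = True
    # reserved for an optional bivariate-normal pre/post mode; the default
    # multiplicative change model does not use it
    pre_post_rho: float = 0.7
    max_resample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.failure_probability <= 1:
            raise ValueError("failure_probability must be in [0, 1]")
        if self.n_patients > self.n_trials:
            raise ValueError("n_patients cannot exceed n_trials")
        for name, (pf, ps) in {
            "male": self.male_prevalence,
            **self.comorbidity_prevalence,
        }.items():
            if not (0 <= pf <= 1 and 0 <= ps <= 1):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")

    def null(self) -> "CohortSpec":
        """A null-model spec: both groups share the success distributions,
        so every index's true AUC for outcome prediction is 0.5."""
        def flatten(gn: GroupNormal) -> GroupNormal:
            return dataclasses.replace(
                gn, fail_mean=gn.success_mean, fail_sd=gn.success_sd
            )

        return dataclasses.replace(
            self,
            male_prevalence=(self.male_prevalence[1], self.male_prevalence[1]),
            comorbidity_prevalence={
                k: (ps, ps) for k, (_, ps) in self.comorbidity_prevalence.items()
            },
            age=flatten(self.age),
            days_intubated=flatten(self.days_intubated),
            trial_duration=flatten(self.trial_duration),
            apache_ii=flatten(self.apache_ii),
            indices={
                k: dataclasses.replace(
                    c, pre=flatten(c.pre), change=flatten(c.change)
                )
                for k, c in self.indices.items()
            },
        )


class CohortTable:
    """An ordered collection of trial records; the unit the statistics run on."""

    def __init__(self, trials: list[TrialRecord]):
        self.trials = list(trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    @property
    def n_failures(self) -> int:
        return sum(t.failed for t in self.trials)

    def outcomes(self) -> np.ndarray:
        """Event indicator array: 1 for a failed trial."""
        return np.array([int(t.failed) for t in self.trials])

    def to_dataframe(self) -> pd.DataFrame:
        """Wide one-row-per-trial frame in the cohort CSV column layout."""
        rows = []
        for t in self.trials:
            row: dict[str, object] = {
                "trial_id": t.trial_id,
                "patient_id": t.patient_id,
                "outcome": t.outcome.value,
                "age": t.age,
                "sex": t.sex.value,
            }
            for flag in COMORBIDITY_FLAGS:
                row[flag] = int(getattr(t, flag))
            row["days_intubated"] = t.days_intubated
            row["trial_duration_min"] = t.trial_duration
            row["apache_ii"] = t.apache_ii
            for prefix, panel in (("pre", t.pre), ("post", t.post)):
                row[f"{prefix}_ph"] = panel.ph
                row[f"{prefix}_pao2"] = panel.pao2
                row[f"{prefix}_paco2"] = panel.paco2
                row[f"{prefix}_sao2"] = panel.sao2
                row[f"{prefix}_pcvo2"] = panel.pcvo2
                row[f"{prefix}_pcvco2"] = panel.pcvco2
                row[f"{prefix}_scvo2"] = panel.scvo2
                row[f"{prefix}_lac"] = panel.lactate
                row[f"{prefix}_hb"] = (
                    panel.hemoglobin if panel.hemoglobin is not None else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)


def hill_saturation(po2, p50: float = 26.6, n: float = 2.7):
    """Monotone Hill-type O2 dissociation curve mapping pO2 (mmHg) to
    saturation fraction: pO2^n / (pO2^n + p50^n)."""
    po2 = np.asarray(po2, dtype=float)
    r = (po2 / p50) ** n
    return r / (1.0 + r)


def _trunc_normal(rng, mean, sd, lo, hi, size, max_tries=1000):
    """Truncated normal by rejection; exact given the rng stream."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise BacksolveError(f"degenerate draw {mean} outside [{lo}, {hi}]")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_tries:
            raise BacksolveError(
                f"truncated normal N({mean}, {sd}) on [{lo}, {hi}]: "
                "acceptance region too improbable"
            )
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _group_draw(rng, gn: GroupNormal, fail_mask: np.ndarray) -> np.ndarray:
    n = len(fail_mask)
    out = np.empty(n)
    nf = int(fail_mask.sum())
    out[fail_mask] = _trunc_normal(rng, gn.fail_mean, gn.fail_sd, gn.lo, gn.hi, nf)
    out[~fail_mask] = _trunc_normal(
        rng, gn.success_mean, gn.success_sd, gn.lo, gn.hi, n - nf
    )
    return out


def _draw_index(rng, cal: IndexCalibration, fail_mask, max_resample):
    """Pre values and percent changes, with post kept physiologic.

    Change draws are truncated *symmetrically about the group mean*, at
    the tighter of the two distances from the mean to the feasible change
    interval implied by the post bounds.  One-sided resampling (redraw
    only when post leaves its window) would silently shift the realised
    group mean — e.g. a positive index has an implicit -100% floor — and
    break the calibration; the symmetric rule preserves the calibrated
    means exactly, at the cost of mildly shrinking the change SD when a
    bound is close.
    """
    pre = _group_draw(rng, cal.pre, fail_mask)
    mean = np.where(fail_mask, cal.change.fail_mean, cal.change.success_mean)
    lo = 100.0 * (cal.post_lo / pre - 1.0)
    hi = 100.0 * (cal.post_hi / pre - 1.0)
    half_width = np.minimum(mean - lo, hi - mean)
    if (half_width <= 0).any():
        raise BacksolveError(
            "mean change maps some pre values outside the physiologic post "
            "window; pre bounds and change means are inconsistent"
        )
    chg = _group_draw(rng, cal.change, fail_mask)
    bad = np.abs(chg - mean) > half_width
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_resample:
            raise BacksolveError("no physiologic post value after bounded retries")
        chg[bad] = _group_draw(rng, cal.change, fail_mask)[bad]
        bad = np.abs(chg - mean) > half_width
    post = pre * (1 + chg / 100.0)
    return pre, post, chg


def _draw_gases(rng, spec: CohortSpec, n: int, scvo2_frac: np.ndarray):
    """PaO2/PcvO2 pairs with diff >= min_po2_diff and SaO2 above ScvO2."""
    pm, psd, plo, phi = spec.pao2
    vm, vsd, vlo, vhi = spec.pcvo2
    pao2 = _trunc_normal(rng, pm, psd, plo, phi, n)
    pcvo2 = _trunc_normal(rng, vm, vsd, vlo, vhi, n)
    sao2 = hill_saturation(pao2, spec.hill_p50, spec.hill_n)
    bad = (pao2 - pcvo2 < spec.min_po2_diff) | (sao2 <= scvo2_frac + 0.005)
    tries = 0
    while bad.any():
        tries += 1
        if tries > spec.max_resample:
            raise BacksolveError(
                "no gas pair with PaO2 - PcvO2 >= floor and SaO2 > ScvO2 "
                "after bounded retries"
            )
        nb = int(bad.sum())
        pao2[bad] = _trunc_normal(rng, pm, psd, plo, phi, nb)
        pcvo2[bad] = _trunc_normal(rng, vm, vsd, vlo, vhi, nb)
        sao2 = hill_saturation(pao2, spec.hill_p50, spec.hill_n)
        bad = (pao2 - pcvo2 < spec.min_po2_diff) | (sao2 <= scvo2_frac + 0.005)
    return pao2, pcvo2, sao2


def generate_cohort(
    spec: CohortSpec | None = None, rng: np.random.Generator | int | None = None
) -> CohortTable:
    """Generate a synthetic cohort under ``spec`` (defaults to the reference
    calibration).  ``rng`` may be a Generator, a seed, or None (use
    ``spec.seed``); the result is deterministic given (spec, seed)."""
    spec = spec or CohortSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = spec.n_trials

    fail = rng.random(n) < spec.failure_probability
    age = _group_draw(rng, spec.age, fail)
    p_male = np.where(fail, *spec.male_prevalence)
    male = rng.random(n) < p_male
    flags = {}
    for flag in COMORBIDITY_FLAGS:
        pf, ps = spec.comorbidity_prevalence[flag]
        flags[flag] = rng.random(n) < np.where(fail, pf, ps)
    days = _group_draw(rng, spec.days_intubated, fail)
    duration = _group_draw(rng, spec.trial_duration, fail)
    apache = _group_draw(rng, spec.apache_ii, fail)

    drawn = {
        name: _draw_index(rng, cal, fail, spec.max_resample)
        for name, cal in spec.indices.items()
    }
    scvo2_pre = drawn["scvo2"][0] / 100.0  # percent -> fraction
    scvo2_post = drawn["scvo2"][1] / 100.0
    pao2_pre, pcvo2_pre, sao2_pre = _draw_gases(rng, spec, n, scvo2_pre)
    pao2_post, pcvo2_post, sao2_post = _draw_gases(rng, spec, n, scvo2_post)
    pcvco2_pre = drawn["mod_rer"][0] * (pao2_pre - pcvo2_pre)
    pcvco2_post = drawn["mod_rer"][1] * (pao2_post - pcvo2_post)
    if spec.include_hemoglobin:
        hm, hsd, hlo, hhi = spec.hemoglobin
        hb = _trunc_normal(rng, hm, hsd, hlo, hhi, n)
    else:
        hb = np.full(n, np.nan)

    # patient linkage: distinct patients first, then repeat trials in
    # difficult-to-wean (failing) patients
    patient_ids = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    assignment = list(range(min(spec.n_patients, n)))
    if n > spec.n_patients:
        fail_patients = [i for i in range(spec.n_patients) if fail[i]] or list(
            range(spec.n_patients)
        )
        extra = rng.choice(fail_patients, size=n - spec.n_patients, replace=True)
        assignment.extend(int(i) for i in extra)

    trials = []
    for i in range(n):
        hbi = float(hb[i]) if spec.include_hemoglobin else None
        pre = BloodGasPanel(
            ph=float(drawn["ph"][0][i]),
            pao2=float(pao2_pre[i]),
            paco2=float(drawn["paco2"][0][i]),
            sao2=float(sao2_pre[i]),
            pcvo2=float(pcvo2_pre[i]),
            pcvco2=float(pcvco2_pre[i]),
            scvo2=float(scvo2_pre[i]),
            lactate=float(drawn["lactate"][0][i]),
            hemoglobin=hbi,
        )
        post = BloodGasPanel(
            ph=float(drawn["ph"][1][i]),
            pao2=float(pao2_post[i]),
            paco2=float(drawn["paco2"][1][i]),
            sao2=float(sao2_post[i]),
            pcvo2=float(pcvo2_post[i]),
            pcvco2=float(pcvco2_post[i]),
            scvo2=float(scvo2_post[i]),
            lactate=float(drawn["lactate"][1][i]),
            hemoglobin=hbi,
        )
        trials.append(
            TrialRecord(
                trial_id=f"T{i + 1:03d}",
                patient_id=patient_ids[assignment[i]],
                outcome=Outcome.FAIL if fail[i] else Outcome.SUCCESS,
                age=float(age[i]),
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                **{flag: bool(flags[flag][i]) for flag in COMORBIDITY_FLAGS},
                days_intubated=float(days[i]),
                trial_duration=float(duration[i]),
                apache_ii=float(apache[i]),
                pre=pre,
                post=post,
            )
        )
    return CohortTable(trials)


def generate_null_cohort(
    spec: CohortSpec | None = None, rng: np.random.Generator | int | None = None
) -> CohortTable:
    """A cohort in which outcome labels carry no signal: both groups use the
    success-group distributions for every covariate and index, so any
    index's true AUC is 0.5 and any group contrast satisfies its null."""
    spec = spec or CohortSpec()
    return generate_cohort(spec.null(), rng)
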