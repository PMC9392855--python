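"""Blood-gas data model and derived cardiopulmonary-reserve indices.

A weaning trial is treated as an exercise analogue: a patient who cannot
sustain the work of spontaneous breathing crosses into anaerobic metabolism,
which shows up in paired arterial / central-venous blood gases drawn before
and at the end of a T-piece trial.  The central quantity here is the
modified respiratory exchange ratio

    Mod-RER = PcvCO2 / (PaO2 - PcvO2)

a bedside surrogate for VCO2/VO2: central-venous CO2 tension stands in for
CO2 production, and the arterial-to-central-venous O2 tension difference
for oxygen uptake.  Alongside it live the comparator indices computable
from the same two syringes: the central-venous-to-arterial CO2 gap, the
simplified oxygen extraction ratio (SaO2-ScvO2)/SaO2, the a-v O2 difference
(content or pressure form) and the Pcv-aCO2 / C(a-cv)O2 ratio.

Saturations are stored internally as fractions in (0, 1]; CSV input in
percent is normalised at the boundary (see :mod:`modrer.io`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional


class DegenerateDenominatorError(ValueError):
    """Raised when an index denominator is zero or has a non-physiologic sign."""


class MissingHemoglobinError(ValueError):
    """Raised when a content-based index is requested without hemoglobin."""


class Polarity(str, Enum):
    """Direction in which an index *change* predicts weaning failure."""

    HIGHER_PREDICTS_EVENT = "higher_predicts_event"
    LOWER_PREDICTS_EVENT = "lower_predicts_event"


#: Directionality of each percent-change score with respect to failure.
#: Mod-RER and PaCO2 rise in failing trials; ScvO2 falls.
INDEX_POLARITY: dict[str, Polarity] = {
    "mod_rer": Polarity.HIGHER_PREDICTS_EVENT,
    "paco2": Polarity.HIGHER_PREDICTS_EVENT,
    "scvo2": Polarity.LOWER_PREDICTS_EVENT,
    "ph": Polarity.LOWER_PREDICTS_EVENT,
    "lactate": Polarity.HIGHER_PREDICTS_EVENT,
    "pco2_gap": Polarity.HIGHER_PREDICTS_EVENT,
    "gap_mod_rer": Polarity.HIGHER_PREDICTS_EVENT,
    "o2_extraction": Polarity.HIGHER_PREDICTS_EVENT,
    "pv_a_co2_over_ca_v_o2": Polarity.HIGHER_PREDICTS_EVENT,
    "a_v_o2_diff": Polarity.HIGHER_PREDICTS_EVENT,
}

#: Names of the indices an IndexPanel carries (pass-throughs included).
INDEX_NAMES: tuple[str, ...] = (
    "mod_rer",
    "pco2_gap",
    "gap_mod_rer",
    "o2_extraction",
    "a_v_o2_diff",
    "pv_a_co2_over_ca_v_o2",
    "ph",
    "paco2",
    "scvo2",
    "lactate",
)


@dataclass(frozen=True)
class BloodGasPanel:
    """One paired arterial + central-venous blood draw at one time point.

    Parameters
    ----------
    ph : arterial pH (unitless)
    pao2, paco2 : arterial O2 / CO2 tensions, mmHg
    sao2 : arterial O2 saturation, fraction in (0, 1]
    pcvo2, pcvco2 : central-venous O2 / CO2 tensions, mmHg
    scvo2 : central-venous O2 saturation, fraction in (0, 1]
    lactate : mmol/L
    hemoglobin : g/dL; optional because many bedside panels omit it, in
        which case content-based indices are unavailable (not an error).
    """

    ph: float
    pao2: float
    paco2: float
    sao2: float
    pcvo2: float
    pcvco2: float
    scvo2: float
    lactate: float
    hemoglobin: Optional[float] = None

    def __post_init__(self) -> None:
        if not (6.5 < self.ph < 8.0):
            raise ValueError(f"arterial pH {self.ph} outside (6.5, 8.0)")
        for name in ("pao2", "paco2", "pcvo2", "pcvco2"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name}={v} must be a positive tension (mmHg)")
        for name in ("sao2", "scvo2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(
                    f"{name}={v} must be a fraction in (0, 1]; percent input "
                    "belongs at the CSV boundary"
                )
        if self.lactate < 0:
            raise ValueError(f"lactate={self.lactate} must be >= 0")
        if self.hemoglobin is not None and not self.hemoglobin > 0:
            raise ValueError(f"hemoglobin={self.hemoglobin} must be > 0 g/dL")
        # Venous saturation above arterial is pathological but representable
        # (e.g. mislabelled syringes, left-to-right shunt); warn, don't fail.
        if self.scvo2 > self.sao2:
            warnings.warn(
                f"ScvO2 ({self.scvo2:.3f}) exceeds SaO2 ({self.sao2:.3f}): "
                "pathological crossover or swapped samples",
                stacklevel=3,
            )


class Outcome(str, Enum):
    FAIL = "fail"
    SUCCESS = "success"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: Boolean comorbidity / status flags carried by every trial record.
COMORBIDITY_FLAGS: tuple[str, ...] = (
    "chronic_respiratory_failure",
    "cardiac_failure",
    "stroke",
    "dementia_or_anoxic_encephalopathy",
    "icu_acquired_weakness",
    "cvvhd",
    "tracheostomy",
)


@dataclass(frozen=True)
class TrialRecord:
    """One weaning trial: outcome, covariates and the pre/post gas panels."""

    trial_id: str
    patient_id: str
    outcome: Outcome
    age: float
    sex: Sex
    chronic_respiratory_failure: bool
    cardiac_failure: bool
    stroke: bool
    dementia_or_anoxic_encephalopathy: bool
    icu_acquired_weakness: bool
    cvvhd: bool
    tracheostomy: bool
    days_intubated: float
    trial_duration: float  # minutes
    apache_ii: float
    pre: BloodGasPanel
    post: BloodGasPanel

    def __post_init__(self) -> None:
        if not isinstance(self.outcome, Outcome):
            object.__setattr__(self, "outcome", Outcome(self.outcome))
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))
        if self.age < 18:
            raise ValueError(f"age={self.age}: eligibility requires age >= 18")
        if not self.trial_duration > 0:
            raise ValueError("trial_duration must be > 0 minutes")

    @property
    def failed(self) -> bool:
        return self.outcome is Outcome.FAIL


@dataclass(frozen=True)
class IndexPanel:
    """All derived indices at one time point; None marks 'not computable'."""

    mod_rer: Optional[float]
    pco2_gap: Optional[float]
    gap_mod_rer: Optional[float]
    o2_extraction: Optional[float]
    a_v_o2_diff: Optional[float]
    pv_a_co2_over_ca_v_o2: Optional[float]
    ph: float
    paco2: float
    scvo2: float
    lactate: float

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# index computations
# ---------------------------------------------------------------------------

def mod_rer(panel: BloodGasPanel) -> float:
    """Modified respiratory exchange ratio, PcvCO2 / (PaO2 - PcvO2).

    Requires PaO2 > PcvO2; an arterial tension at or below the venous one
    signals a non-physiologic or mislabelled pair and raises
    :class:`DegenerateDenominatorError`.
    """
    denom = panel.pao2 - panel.pcvo2
    if denom <= 0:
        raise DegenerateDenominatorError(
            f"PaO2 ({panel.pao2}) <= PcvO2 ({panel.pcvo2}): Mod-RER undefined"
        )
    return panel.pcvco2 / denom


def pco2_gap(panel: BloodGasPanel) -> float:
    """Central-venous-to-arterial CO2 gap, PcvCO2 - PaCO2, in mmHg.

    A perfusion-adequacy marker; may legitimately be negative.
    """
    return panel.pcvco2 - panel.paco2


def gap_mod_rer(panel: BloodGasPanel) -> float:
    """Gap-based Mod-RER variant, (PcvCO2 - PaCO2) / (PaO2 - PcvO2).

    Uses the cv-arterial CO2 gap rather than PcvCO2 itself in the
    numerator; same denominator precondition as :func:`mod_rer`.
    """
    denom = panel.pao2 - panel.pcvo2
    if denom <= 0:
        raise DegenerateDenominatorError(
            f"PaO2 ({panel.pao2}) <= PcvO2 ({panel.pcvo2}): gap Mod-RER undefined"
        )
    return (panel.pcvco2 - panel.paco2) / denom


def o2_extraction(panel: BloodGasPanel) -> float:
    """Simplified oxygen extraction ratio, (SaO2 - ScvO2) / SaO2."""
    return (panel.sao2 - panel.scvo2) / panel.sao2


def o2_content(saturation: float, po2: float, hemoglobin: float) -> float:
    """Blood O2 content in mL O2 / dL: 1.34 * Hb * Sat + 0.0031 * pO2.

    The standard form: hemoglobin-bound oxygen (1.34 mL O2 per gram of
    saturated Hb) plus dissolved oxygen (0.0031 mL/dL per mmHg).
    """
    if hemoglobin is None:
        raise MissingHemoglobinError("oxygen content requires hemoglobin (g/dL)")
    return 1.34 * hemoglobin * saturation + 0.0031 * po2


def pv_a_co2_over_ca_v_o2(panel: BloodGasPanel) -> float:
    """Pcv-aCO2 gap over the arterio-venous O2 content difference.

    (PcvCO2 - PaCO2) / (CaO2 - CcvO2), in mmHg per mL/dL; an anaerobic-
    metabolism marker.  Requires hemoglobin and a nonzero content
    difference.
    """
    if panel.hemoglobin is None:
        raise MissingHemoglobinError(
            "P(cv-a)CO2 / C(a-cv)O2 requires hemoglobin"
        )
    ca = o2_content(panel.sao2, panel.pao2, panel.hemoglobin)
    ccv = o2_content(panel.scvo2, panel.pcvo2, panel.hemoglobin)
    if ca == ccv:
        raise DegenerateDenominatorError("zero arterio-venous O2 content difference")
    return (panel.pcvco2 - panel.paco2) / (ca - ccv)


def a_v_o2_diff(panel: BloodGasPanel, mode: str = "content_mL_per_L") -> float:
    """Arterio-venous oxygen difference.

    ``content_mL_per_L`` (default): 10 * (CaO2 - CcvO2), mL O2 per litre
    (requires hemoglobin).  ``pressure_mmHg``: PaO2 - PcvO2, the partial-
    pressure form used in the Mod-RER denominator.
    """
    if mode == "pressure_mmHg":
        return panel.pao2 - panel.pcvo2
    if mode == "content_mL_per_L":
        if panel.hemoglobin is None:
            raise MissingHemoglobinError("content-mode a-vO2 difference requires hemoglobin")
        ca = o2_content(panel.sao2, panel.pao2, panel.hemoglobin)
        ccv = o2_content(panel.scvo2, panel.pcvo2, panel.hemoglobin)
        return 10.0 * (ca - ccv)
    raise ValueError(f"unknown a-vO2 difference mode: {mode!r}")


def percent_change(pre_value: float, post_value: float) -> float:
    """Per-trial percent change, 100 * (post - pre) / pre; increase positive."""
    if pre_value == 0:
        raise ZeroDivisionError("percent change undefined for a zero pre value")
    return 100.0 * (post_value - pre_value) / pre_value


def _index_panel(panel: BloodGasPanel, avo2_mode: str) -> IndexPanel:
    def attempt(fn, *args):
        try:
            return fn(*args)
        except (DegenerateDenominatorError, MissingHemoglobinError) as exc:
            warnings.warn(f"{fn.__name__} not computable: {exc}", stacklevel=4)
            return None

    return IndexPanel(
        mod_rer=attempt(mod_rer, panel),
        pco2_gap=pco2_gap(panel),
        gap_mod_rer=attempt(gap_mod_rer, panel),
        o2_extraction=o2_extraction(panel),
        a_v_o2_diff=attempt(a_v_o2_diff, panel, avo2_mode),
        pv_a_co2_over_ca_v_o2=attempt(pv_a_co2_over_ca_v_o2, panel),
        ph=panel.ph,
        paco2=panel.paco2,
        scvo2=panel.scvo2,
        lactate=panel.lactate,
    )


def derive_index_panel(
    trial: TrialRecord, avo2_mode: str = "content_mL_per_L"
) -> tuple[IndexPanel, IndexPanel, dict[str, Optional[float]]]:
    """Compute every index at both time points plus per-index percent changes.

    Indices that cannot be computed on a given panel (missing hemoglobin,
    degenerate denominator) come back as ``None`` with a warning; the rest
    of the record is still derived.  Deterministic and side-effect free.
    """
    pre = _index_panel(trial.pre, avo2_mode)
    post = _index_panel(trial.post, avo2_mode)
    changes: dict[str, Optional[float]] = {}
    for name in INDEX_NAMES:
        a, b = getattr(pre, name), getattr(post, name)
        if a is None or b is None or a == 0:
            changes[name] = None
        else:
            changes[name] = percent_change(a, b)
    return pre, post, changes
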