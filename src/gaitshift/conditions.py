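"""Goggle conditions and their simulated-impairment severities.

Six walking conditions are studied: no goggles, and five alcohol-impairment
simulation goggles whose strap colour encodes a manufacturer-declared
simulated blood-alcohol-concentration (BAC) range. Severity is a unitless
scalar in [0, 1] derived from the midpoint of that range, normalised so the
strongest goggles (orange, 0.26-0.35 % BAC) sit at 1 and the no-goggles
condition at 0. The synthetic cohort generator perturbs gait parameters as
deterministic monotone functions of this severity.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ConditionLabel",
    "ConditionProfile",
    "CLASS_ORDER",
    "CONDITIONS",
    "get_condition",
    "build_condition_profiles",
]

# Canonical class order used everywhere (confusion matrices, reports).
CLASS_ORDER: tuple[str, ...] = ("none", "green", "blue", "black", "red", "orange")

# Manufacturer-declared simulated BAC ranges (% BAC) per strap colour.
_BAC_RANGES: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "green": (0.04, 0.06),
    "blue": (0.06, 0.08),
    "black": (0.08, 0.15),
    "red": (0.15, 0.25),
    "orange": (0.26, 0.35),
}


@dataclass(frozen=True)
class ConditionLabel:
    """One of the six walking conditions.

    Attributes
    ----------
    name : str
        Strap colour, or ``"none"`` for the no-goggles condition.
    bac_range : tuple of float
        Manufacturer-declared simulated BAC range in % BAC.
    severity : float
        Normalised impairment level in [0, 1]: BAC-range midpoint divided
        by the largest midpoint over the six conditions.
    """

    name: str
    bac_range: tuple[float, float]
    severity: float

    @property
    def bac_midpoint(self) -> float:
        return 0.5 * (self.bac_range[0] + self.bac_range[1])


def _build_conditions() -> dict[str, ConditionLabel]:
    max_mid = max(0.5 * (lo + hi) for lo, hi in _BAC_RANGES.values())
    out = {}
    for name, (lo, hi) in _BAC_RANGES.items():
        mid = 0.5 * (lo + hi)
        out[name] = ConditionLabel(name=name, bac_range=(lo, hi), severity=mid / max_mid)
    return out


CONDITIONS: dict[str, ConditionLabel] = _build_conditions()


def get_condition(name: str) -> ConditionLabel:
    """Look up a condition by name; raise on anything outside the six."""
    try:
        return CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition label {name!r}; expected one of {CLASS_ORDER}"
        ) from None


@dataclass(frozen=True)
class ConditionProfile:
    """Gait-perturbation multipliers for one condition.

    All multipliers are deterministic monotone functions of the condition's
    severity and take their neutral value (1, or 0 for the additive
    irregularity term) at severity 0.

    Attributes
    ----------
    label : ConditionLabel
    step_time_cv_multiplier : float
        Multiplies the baseline coefficient of variation of step intervals
        (>= 1); impaired gait is less regular in time.
    sway_amplitude_multiplier : float
        Multiplies the mediolateral sway-noise amplitude (>= 1).
    cadence_multiplier : float
        Multiplies the participant's base step frequency (<= 1); impaired
        walkers slow down.
    harmonic_irregularity : float
        Standard deviation of per-step amplitude modulation (>= 0).
    """

    label: ConditionLabel
    step_time_cv_multiplier: float
    sway_amplitude_multiplier: float
    cadence_multiplier: float
    harmonic_irregularity: float


# Frozen effect-size slopes (per unit severity); see docs/methods.md for the
# calibration rationale.
_CV_SLOPE = 8.0
_SWAY_SLOPE = 3.2
_CADENCE_SLOPE = 0.22
_IRREGULARITY_SLOPE = 1.1


def condition_profile(label: ConditionLabel, effect_scale: float = 1.0) -> ConditionProfile:
    """Build the perturbation profile for one condition.

    ``effect_scale`` scales all departures from neutral; 0 disables every
    condition effect (the null generator used for control experiments).
    """
    s = label.severity * effect_scale
    return ConditionProfile(
        label=label,
        step_time_cv_multiplier=1.0 + _CV_SLOPE * s,
        sway_amplitude_multiplier=1.0 + _SWAY_SLOPE * s,
        cadence_multiplier=1.0 - _CADENCE_SLOPE * s,
        harmonic_irregularity=_IRREGULARITY_SLOPE * s,
    )


def build_condition_profiles(
    names: list[str] | tuple[str, ...] | None = None,
    effect_scale: float = 1.0,
) -> list[ConditionProfile]:
    """Profiles for a list of condition names (default: all six, canonical order)."""
    if names is None:
        names = CLASS_ORDER
    return [condition_profile(get_condition(n), effect_scale) for n in names]
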