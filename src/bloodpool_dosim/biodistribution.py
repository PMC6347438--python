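"""Well-mixed blood-pool biodistribution and time-integrated activity.

A blood-pool agent is assumed to distribute uniformly throughout the
blood volume within minutes of injection, so each organ's fraction of
the injected dose equals its fractional blood content. Blood residing
within an organ is assigned to that organ as the source region (the
*wall* for hollow organs — the agent sits in vasculature, never in a
lumen); blood not assigned to any named organ goes to the synthetic
region ``rest_of_body``.

Two excretion scenarios are supported:

* **full retention** — no biologic excretion; the entire injected dose
  undergoes physical decay in place, so each region's time-integrated
  activity coefficient is ``fraction * T_half / ln 2`` (hours).
* **partial urinary excretion** — a fixed fraction of the dose (free or
  released tracer) leaves the blood pool for the urinary bladder; the
  retained sub-pool decays in place while the excreted sub-pool passes
  through a dynamic voiding-bladder model (first-order entry into bladder
  contents, physical decay throughout, contents reset at every void).

Time-integrated activity coefficients ã are in hours (MBq·h per MBq
administered), the convention consumed by MIRD-schema dose software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .physics import LN2, Radionuclide

__all__ = [
    "REST_OF_BODY",
    "BLADDER_CONTENTS",
    "BloodVolumeTable",
    "ScenarioSpec",
    "FULL_RETENTION",
    "FREE_FDG_25PCT",
    "TiaVector",
    "blood_pool_fractions",
    "residence_time",
    "bladder_residence",
    "tia_vector",
]

REST_OF_BODY = "rest_of_body"
BLADDER_CONTENTS = "urinary_bladder_contents"


@dataclass(frozen=True)
class BloodVolumeTable:
    """Organ → fraction of total blood volume (dimensionless)."""

    fractions: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for organ, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"blood fraction for {organ!r} outside [0,1]: {f}")
        total = sum(self.fractions.values())
        if total > 1.0 + 1e-9:
            raise ValidationError(f"blood fractions sum to {total:.6g} > 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """Biodistribution assumptions for one dosimetry scenario.

    ``retained_fraction`` of the dose stays in the blood pool and decays
    in place; ``excreted_fraction`` is routed to the urinary bladder with
    first-order biologic entry half-time ``bladder_entry_halftime_min``
    and bladder voiding every ``voiding_interval_h`` hours. The two
    fractions must sum to 1.
    """

    name: str
    retained_fraction: float
    excreted_fraction: float
    bladder_entry_halftime_min: float = 12.0
    voiding_interval_h: float = 3.5

    def __post_init__(self) -> None:
        for f in (self.retained_fraction, self.excreted_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"scenario fractions must be in [0,1], got {f}")
        if abs(self.retained_fraction + self.excreted_fraction - 1.0) > 1e-9:
            raise ValidationError("retained_fraction + excreted_fraction must equal 1")
        if self.bladder_entry_halftime_min < 0:
            raise ValidationError("bladder entry half-time must be >= 0")
        if self.voiding_interval_h <= 0:
            raise ValidationError("voiding interval must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioSpec":
        excreted = float(raw.get("excreted_fraction", 0.0))
        return cls(
            name=str(raw.get("name", f"excretion_{excreted:g}")),
            retained_fraction=float(raw.get("retained_fraction", 1.0 - excreted)),
            excreted_fraction=excreted,
            bladder_entry_halftime_min=float(raw.get("bladder_entry_halftime_min", 12.0)),
            voiding_interval_h=float(raw.get("voiding_interval_h", 3.5)),
        )


#: No biologic excretion; 100% physical decay in the blood pool.
FULL_RETENTION = ScenarioSpec("full_retention", 1.0, 0.0)
#: Poor labeling: 25% of the dose excreted as free tracer via the bladder.
FREE_FDG_25PCT = ScenarioSpec("free_fdg_25pct", 0.75, 0.25)


@dataclass(frozen=True)
class TiaVector:
    """Per-source-region time-integrated activity coefficients ã (hours)."""

    entries: dict[str, float]
    nuclide: Radionuclide
    scenario: ScenarioSpec

    def __post_init__(self) -> None:
        for region, a in self.entries.items():
            if a < 0:
                raise ValidationError(f"negative ã for {region!r}: {a}")
        ceiling = self.nuclide.half_life_h / LN2
        total = sum(self.entries.values())
        if total > ceiling * (1.0 + 1e-9):
            raise ValidationError(
                f"Σã = {total:.6g} h exceeds the physical-decay ceiling "
                f"T_half/ln2 = {ceiling:.6g} h"
            )

    def total_hours(self) -> float:
        return sum(self.entries.values())

    def to_series(self):
        import pandas as pd

        return pd.Series(self.entries, name="tia_h")


def blood_pool_fractions(table: BloodVolumeTable) -> dict[str, float]:
    """Map blood-volume fractions to injected-dose fractions.

    Identity mapping under the well-mixed assumption, plus a
    ``rest_of_body`` remainder so the fractions sum to exactly 1.
    """
    named = {k: v for k, v in table.fractions.items() if k != REST_OF_BODY}
    rest = table.fractions.get(REST_OF_BODY, 0.0) + (1.0 - sum(table.fractions.values()))
    out = dict(named)
    out[REST_OF_BODY] = max(0.0, rest)
    return out


def residence_time(
    fraction: float, nuclide: Radionuclide, scenario: ScenarioSpec
) -> float:
    """ã (hours) for a blood-pool region holding ``fraction`` of the dose.

    Only the retained sub-pool decays in place:
    ``retained_fraction * fraction * T_half / ln2``. Linear in ``fraction``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"dose fraction must be in [0,1], got {fraction}")
    return scenario.retained_fraction * fraction * nuclide.half_life_h / LN2


def bladder_residence(
    excreted_fraction: float, nuclide: Radionuclide, scenario: ScenarioSpec
) -> float:
    """ã (hours) for bladder contents under the dynamic voiding model.

    The excreted sub-pool enters the bladder contents with first-order
    biologic half-time ``bladder_entry_halftime_min``; physical decay
    applies throughout; contents reset to zero at every void. Between
    voids at ``t_k`` the contents activity has the closed form

        B(t) = f * exp(-λ_p t) * (exp(-λ_b t_k) - exp(-λ_b t)),

    which is integrated interval by interval and summed to convergence.
    Monotone increasing in both the voiding interval and the half-life;
    reduces to ``f * T_half/ln2`` for instant entry and no voiding.
    """
    f = excreted_fraction
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"excreted fraction must be in [0,1], got {f}")
    if f == 0.0:
        return 0.0
    lam_p = nuclide.decay_constant_per_min
    tau = scenario.voiding_interval_h * 60.0  # minutes; may be inf

    if scenario.bladder_entry_halftime_min == 0.0:
        # Instant entry: everything is in the bladder at t=0 and the first
        # void removes it all.
        if math.isinf(tau):
            return f / lam_p / 60.0
        return f * -math.expm1(-lam_p * tau) / lam_p / 60.0

    lam_b = LN2 / scenario.bladder_entry_halftime_min
    if math.isinf(tau):
        return f * (1.0 / lam_p - 1.0 / (lam_p + lam_b)) / 60.0

    total = 0.0
    k = 0
    while True:
        t0, t1 = k * tau, (k + 1) * tau
        term = f * (
            math.exp(-lam_b * t0)
            * (math.exp(-lam_p * t0) - math.exp(-lam_p * t1))
            / lam_p
            - (math.exp(-(lam_p + lam_b) * t0) - math.exp(-(lam_p + lam_b) * t1))
            / (lam_p + lam_b)
        )
        total += term
        k += 1
        if term <= 1e-16 * max(total, 1e-300) or k > 100000:
            break
    return total / 60.0


def tia_vector(
    table: BloodVolumeTable, nuclide: Radionuclide, scenario: ScenarioSpec
) -> TiaVector:
    """Full per-region ã vector for one scenario.

    Blood-pool regions receive the retained-pool residence times; under
    partial excretion the bladder-contents region additionally receives
    the voiding-model ã of the excreted sub-pool.
    """
    fractions = blood_pool_fractions(table)
    entries = {
        region: residence_time(frac, nuclide, scenario)
        for region, frac in fractions.items()
    }
    if scenario.excreted_fraction > 0.0:
        entries[BLADDER_CONTENTS] = entries.get(BLADDER_CONTENTS, 0.0) + bladder_residence(
            scenario.excreted_fraction, nuclide, scenario
        )
    return TiaVector(entries=entries, nuclide=nuclide, scenario=scenario)
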