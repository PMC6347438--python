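"""MIRD-schema absorbed dose, effective dose and regulatory limit logic.

The MIRD schema computes the absorbed dose to each target organ as

    D(target) = Σ_sources ã(source) · S(target ← source)

with ã the time-integrated activity coefficient (hours per unit
administered activity) and S the phantom-specific dose per unit
time-integrated activity (mGy per MBq·h). S-values are *input* — from a
user-transcribed phantom table or the synthetic generator — never
computed here; classical stylized-phantom tables are proprietary.

On top of the MIRD sum this module provides:

* the hollow-organ wall correction — classical phantoms place hollow-organ
  activity in the lumen and give the wall *half* the contents-absorbed
  electron dose (surface convention); for a blood-pool agent the activity
  is in the wall itself and the electron self-dose must be the wall
  self-absorbed term;
* the ICRP-60 effective dose E = Σ_T w_T · H_T (equivalent dose numerically
  equal to absorbed dose; radiation weighting factor 1 for photons and
  electrons/positrons), with the 0.05 remainder handled as the mean dose of
  the remainder organs;
* 21 CFR 361.1 single-administration and annual dose-limit screening with
  dose-limiting organ and maximum annual administrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .biodistribution import TiaVector
from .errors import SchemaMismatchError, ValidationError

__all__ = [
    "SValueMatrix",
    "HollowOrganSpec",
    "TissueWeights",
    "RegulatoryLimits",
    "AdminLimitResult",
    "DoseReport",
    "absorbed_doses",
    "wall_correction",
    "effective_dose",
    "admin_limits",
    "total_effective_dose",
    "compare_agents",
]


@dataclass(frozen=True)
class SValueMatrix:
    """Target × source S-value matrix in mGy per MBq·h for one phantom."""

    values: pd.DataFrame  # index = targets, columns = sources
    phantom_name: str = ""

    def __post_init__(self) -> None:
        df = self.values
        if (df.to_numpy() < 0).any():
            raise ValidationError("S-values must be non-negative")
        # Self-dose dominance: for any region that is both source and
        # target, no other target receives more per decay than the region
        # itself (electron self-absorption guarantees this physically).
        shared = [r for r in df.columns if r in df.index]
        for src in shared:
            col = df[src]
            if (col.drop(src) > col[src] * (1 + 1e-12)).any():
                worst = col.drop(src).idxmax()
                raise ValidationError(
                    f"self-dose dominance violated for source {src!r}: "
                    f"S({worst}←{src}) > S({src}←{src})"
                )

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)

    @property
    def sources(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path, phantom_name: str = "") -> "SValueMatrix":
        """Read a CSV with first column = target organ, one column per source."""
        df = pd.read_csv(path, comment="#")
        df = df.set_index(df.columns[0]).astype(float)
        df.index.name = "target"
        return cls(values=df, phantom_name=phantom_name or str(path))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="target")


@dataclass(frozen=True)
class HollowOrganSpec:
    """Wall/contents geometry of one hollow organ for the wall correction.

    ``delta_electron`` is the mean electron (non-penetrating) energy per
    decay expressed as mGy·kg per MBq·h, so dividing by a mass in kg gives
    a self-absorbed electron dose per unit ã.
    """

    organ: str
    wall_mass_kg: float
    contents_mass_kg: float
    delta_electron: float
    wall_region: str | None = None  # ã source region of the wall; defaults to organ
    contents_region: str | None = None  # ã region of luminal contents, if any

    def __post_init__(self) -> None:
        if self.wall_mass_kg <= 0 or self.contents_mass_kg <= 0:
            raise ValidationError("wall and contents masses must be positive")
        if self.delta_electron < 0:
            raise ValidationError("delta_electron must be >= 0")


def absorbed_doses(tia: TiaVector, s: SValueMatrix) -> dict[str, float]:
    """MIRD sum: D(target) = Σ_sources ã(source)·S(target←source), mGy/MBq."""
    missing = sorted(set(tia.entries) - set(s.sources))
    if missing:
        raise SchemaMismatchError(
            f"ã regions missing from the S-matrix sources: {missing}"
        )
    vec = pd.Series(tia.entries, dtype=float).reindex(s.sources, fill_value=0.0)
    doses = s.values.to_numpy() @ vec.to_numpy()
    return dict(zip(s.targets, doses.astype(float)))


def wall_correction(
    doses: Mapping[str, float],
    tia: TiaVector,
    spec: HollowOrganSpec,
    s: SValueMatrix | None = None,
) -> dict[str, float]:
    """Replace the luminal electron self-dose convention with wall self-absorption.

    Classical stylized phantoms credit the hollow-organ wall with *half*
    the contents-absorbed electron dose (``½ · ã_contents · Δ_e /
    m_contents``, the surface convention). For a blood-pool agent the
    activity sits in the wall, so that term is removed and the wall
    self-absorbed electron term ``ã_wall · Δ_e / m_wall`` is added. Photon
    terms are untouched; only ``spec.organ``'s dose changes and the result
    is clamped at zero. If the organ has no ã, the input is returned
    unchanged with a warning.
    """
    out = dict(doses)
    wall_region = spec.wall_region or spec.organ
    a_wall = tia.entries.get(wall_region, 0.0)
    contents_region = spec.contents_region
    a_contents = tia.entries.get(contents_region, a_wall) if contents_region else a_wall
    if spec.organ not in out or (a_wall == 0.0 and a_contents == 0.0):
        warnings.warn(
            f"wall correction skipped: no dose/ã for organ {spec.organ!r}",
            stacklevel=2,
        )
        return out
    surface_term = 0.5 * a_contents * spec.delta_electron / spec.contents_mass_kg
    wall_term = a_wall * spec.delta_electron / spec.wall_mass_kg
    out[spec.organ] = max(0.0, out[spec.organ] - surface_term + wall_term)
    return out


@dataclass(frozen=True)
class TissueWeights:
    """ICRP tissue weighting factors w_T plus remainder handling."""

    weights: dict[str, float]
    remainder_weight: float
    remainder_organs: tuple[str, ...]
    surrogates: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()) or self.remainder_weight < 0:
            raise ValidationError("tissue weights must be >= 0")
        total = sum(self.weights.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"tissue weights sum to {total:.12g}, expected 1")


def effective_dose(
    doses: Mapping[str, float],
    w: TissueWeights,
    mass_weighted_remainder: Mapping[str, float] | None = None,
) -> float:
    """ICRP effective dose E = Σ w_T·H_T in mSv per MBq.

    Equivalent dose H_T equals absorbed dose numerically (w_R = 1 for
    photons and electrons/positrons). A weighted tissue absent from
    ``doses`` is taken from its surrogate organ (e.g. oesophagus ← thymus)
    if one is configured; otherwise an error names the tissue. The
    remainder contribution is the unweighted mean dose of the remainder
    organs present, or a mass-weighted mean if organ masses are supplied.
    """
    e = 0.0
    for tissue, wt in w.weights.items():
        organ = tissue if tissue in doses else w.surrogates.get(tissue)
        if organ is None or organ not in doses:
            raise SchemaMismatchError(
                f"no dose (or surrogate) available for weighted tissue {tissue!r}"
            )
        e += wt * float(doses[organ])
    rem = [o for o in w.remainder_organs if o in doses]
    if not rem:
        raise SchemaMismatchError("no remainder organs present in the dose table")
    if mass_weighted_remainder:
        masses = np.array([mass_weighted_remainder.get(o, 0.0) for o in rem])
        if masses.sum() <= 0:
            raise ValidationError("remainder organ masses must be positive")
        rem_dose = float(np.average([doses[o] for o in rem], weights=masses))
    else:
        rem_dose = float(np.mean([doses[o] for o in rem]))
    return e + w.remainder_weight * rem_dose


@dataclass(frozen=True)
class RegulatoryLimits:
    """21 CFR 361.1 dose limits (mSv) with the restricted-organ category."""

    single_restricted_mSv: float = 30.0
    single_other_mSv: float = 50.0
    annual_restricted_mSv: float = 50.0
    annual_other_mSv: float = 150.0
    restricted_organs: frozenset[str] = frozenset(
        {"whole_body", "gonads", "testes", "ovaries", "red_marrow",
         "blood_forming_organs", "lens_of_eye"}
    )

    def limits_for(self, organ: str) -> tuple[float, float]:
        """(single-administration, annual) limits in mSv for one organ."""
        if organ in self.restricted_organs:
            return self.single_restricted_mSv, self.annual_restricted_mSv
        return self.single_other_mSv, self.annual_other_mSv


@dataclass(frozen=True)
class AdminLimitResult:
    """Outcome of the regulatory screening for one administration plan."""

    limiting_organ: str | None
    max_annual_admins: int | None
    max_single_admin_mbq: float
    per_admin_mSv: dict[str, float]

    @property
    def binding(self) -> bool:
        return self.limiting_organ is not None


_REL_TOL = 1e-9  # treat doses exactly at a limit as compliant


def admin_limits(
    doses: Mapping[str, float],
    effective_mSv_per_mbq: float,
    activity_per_admin_mbq: float,
    limits: RegulatoryLimits,
) -> AdminLimitResult:
    """Dose-limiting organ and maximum annual administrations under 21 CFR 361.1.

    Per organ, the per-administration equivalent dose is
    ``dose_per_MBq × activity``; an organ at or under its
    single-administration limit allows ``floor(annual_limit / per-admin
    dose)`` administrations per year, and one over it allows none. The
    limiting organ attains the minimum. The restricted whole-body limit is
    screened only when a ``whole_body`` absorbed dose is present in
    ``doses`` (the effective dose is reported but is not a 361.1
    quantity). All-zero doses yield the "no binding constraint" sentinel
    (``limiting_organ=None``, unbounded administrations).
    """
    if activity_per_admin_mbq <= 0:
        raise ValidationError("activity per administration must be positive")
    per_admin = {
        organ: float(d) * activity_per_admin_mbq for organ, d in doses.items() if d > 0
    }
    if not per_admin:
        return AdminLimitResult(None, None, math.inf, {})
    max_single = math.inf
    best_organ, best_n = None, None
    for organ, dose in per_admin.items():
        single_lim, annual_lim = limits.limits_for(organ)
        max_single = min(max_single, single_lim / (dose / activity_per_admin_mbq))
        if dose > single_lim * (1 + _REL_TOL):
            n = 0
        else:
            n = int(math.floor(annual_lim / dose * (1 + _REL_TOL)))
        if best_n is None or n < best_n or (n == best_n and dose > per_admin[best_organ]):
            best_organ, best_n = organ, n
    return AdminLimitResult(
        limiting_organ=best_organ,
        max_annual_admins=best_n,
        max_single_admin_mbq=max_single,
        per_admin_mSv=per_admin,
    )


def total_effective_dose(
    coefficient_mSv_per_mbq: float, activity_mbq: float, ndigits: int | None = 1
) -> float:
    """Total effective dose ``coefficient × activity`` in mSv.

    Reported rounded (one decimal by default; ``ndigits=None`` for the
    raw product).
    """
    if coefficient_mSv_per_mbq < 0 or activity_mbq < 0:
        raise ValidationError("coefficient and activity must be >= 0")
    total = coefficient_mSv_per_mbq * activity_mbq
    return total if ndigits is None else round(total, ndigits)


def compare_agents(
    doses_by_agent: Mapping[str, Mapping[str, float]], baseline: str | None = None
) -> pd.DataFrame:
    """Per-organ dose comparison across agents or scenarios.

    Returns a table over the organs common to all reports, with one dose
    column per agent, a ``ratio_<agent>`` column (agent / baseline) for
    every non-baseline agent, and rows ranked by the largest absolute
    dose difference from the baseline. Purely presentational: it computes
    nothing the reports do not already contain.
    """
    if len(doses_by_agent) < 2:
        raise ValidationError("need at least two dose reports to compare")
    labels = list(doses_by_agent)
    baseline = baseline or labels[0]
    if baseline not in doses_by_agent:
        raise KeyError(f"baseline {baseline!r} not among agents {labels}")
    common = set.intersection(*(set(d) for d in doses_by_agent.values()))
    if not common:
        raise ValidationError("dose reports share no organs")
    df = pd.DataFrame(
        {label: {o: doses_by_agent[label][o] for o in sorted(common)} for label in labels}
    )
    rank = pd.Series(0.0, index=df.index)
    for label in labels:
        if label == baseline:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            df[f"ratio_{label}"] = df[label] / df[baseline]
        rank = np.maximum(rank, (df[label] - df[baseline]).abs())
    return df.assign(_rank=rank).sort_values("_rank", ascending=False).drop(columns="_rank")


@dataclass(frozen=True)
class DoseReport:
    """Per-organ doses plus the headline summary for one scenario.

    Footer convention: equivalent dose equals absorbed dose numerically
    (radiation weighting factor 1 for photons and positrons/electrons).
    """

    scenario: str
    organ_doses_mgy_per_mbq: dict[str, float]
    effective_dose_msv_per_mbq: float
    limiting_organ: str | None
    max_single_admin_mbq: float
    max_annual_admins: int | None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.organ_doses_mgy_per_mbq.values()):
            raise ValidationError("organ doses must be >= 0")
        if self.max_annual_admins is not None and self.max_annual_admins < 0:
            raise ValidationError("max annual administrations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"absorbed_dose_mGy_per_MBq": pd.Series(self.organ_doses_mgy_per_mbq)}
        ).rename_axis("organ")
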