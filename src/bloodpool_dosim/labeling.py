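"""Mass-balance and kinetic analysis of erythrocyte radiolabeling runs.

A labeling run is an ordered series of dose-calibrator readings taken on
the compartments of one labeling experiment: the washed cell pellet, the
original incubation supernatant, and up to three wash supernatants. All
arithmetic is done on activities decay-corrected to the run start (tracer
addition), so percent incorporation is comparable across runs regardless
of when each aliquot reached the calibrator.

Kinetic models
--------------
* Uptake: single-exponential saturation ``F(t) = f_inf * (1 - exp(-k t))``
  — first-order transporter-mediated uptake, the simplest form consistent
  with near-complete saturation between 30 min and 2 h of incubation.
* Leakage: a straight line in percent leaked vs minutes of plasma
  incubation (the default), with a first-order release variant available.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .errors import ExtrapolationWarning, FitError, UndefinedRatioError, ValidationError
from .physics import Radionuclide, decay_correct, decay_factor

__all__ = [
    "Compartment",
    "ActivityMeasurement",
    "LabelingRun",
    "UptakeModel",
    "LeakageModel",
    "FirstOrderRelease",
    "percent_incorporation",
    "wash_fractions",
    "recovery_fraction",
    "fit_uptake",
    "fit_leakage",
    "fit_leakage_first_order",
    "predict_leakage_at",
    "predict_yield",
    "load_labeling_run",
]


class Compartment(str, enum.Enum):
    """Where an aliquot came from within the labeling procedure."""

    CELLS = "cells"
    SUPERNATANT = "supernatant"
    WASH_1 = "wash_1"
    WASH_2 = "wash_2"
    WASH_3 = "wash_3"
    PLASMA = "plasma"


_WASHES = {Compartment.WASH_1, Compartment.WASH_2, Compartment.WASH_3}


@dataclass(frozen=True)
class ActivityMeasurement:
    """One dose-calibrator reading: compartment, activity (MBq), minutes from run start."""

    compartment: Compartment
    activity_mbq: float
    t_min: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        if self.activity_mbq < 0:
            raise ValidationError(f"activity must be >= 0, got {self.activity_mbq}")
        if self.t_min < 0:
            raise ValidationError(f"measurement time must be >= 0, got {self.t_min}")


@dataclass(frozen=True)
class LabelingRun:
    """An ordered series of activity measurements for one labeling experiment.

    ``initial_activity_mbq`` is the activity added at t=0; the
    decay-corrected compartment sum may not exceed it by more than
    ``balance_tolerance`` (calibrator noise allowance, default 5%).
    """

    nuclide: Radionuclide
    measurements: tuple[ActivityMeasurement, ...]
    initial_activity_mbq: float
    balance_tolerance: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        comps = [m.compartment for m in self.measurements]
        if comps.count(Compartment.CELLS) != 1:
            raise ValidationError("a labeling run needs exactly one cells measurement")
        if comps.count(Compartment.SUPERNATANT) > 1:
            raise ValidationError("at most one supernatant measurement allowed")
        if sum(c in _WASHES for c in comps) > 3 or len(set(comps)) != len(comps):
            raise ValidationError("at most one measurement per wash compartment")
        if self.initial_activity_mbq < 0:
            raise ValidationError("initial activity must be >= 0")
        corrected = sum(self.corrected_activities().values())
        limit = self.initial_activity_mbq * (1.0 + self.balance_tolerance)
        if self.initial_activity_mbq > 0 and corrected > limit:
            raise ValidationError(
                f"decay-corrected compartment sum {corrected:.4g} MBq exceeds "
                f"initial {self.initial_activity_mbq:.4g} MBq by more than "
                f"{self.balance_tolerance:.0%}"
            )

    def corrected_activities(self) -> dict[Compartment, float]:
        """Activities decay-corrected to run start, in measurement order."""
        return {
            m.compartment: decay_correct(m.activity_mbq, m.t_min, 0.0, self.nuclide)
            for m in self.measurements
        }


def percent_incorporation(run: LabelingRun) -> float:
    """Fraction of recovered activity residing in the cell pellet.

    All activities are decay-corrected to run start; the denominator is
    the sum of measured compartments (relative percent of recovered
    activity), so the result is invariant to a common measurement time.
    """
    corrected = run.corrected_activities()
    if len(corrected) < 2:
        raise ValidationError("need cells plus at least one other compartment")
    total = sum(corrected.values())
    if total == 0:
        raise UndefinedRatioError("all compartment activities are zero")
    return corrected[Compartment.CELLS] / total


def wash_fractions(run: LabelingRun) -> dict[Compartment, float]:
    """Per-compartment fractions of decay-corrected recovered activity.

    Normalized so the fractions sum to exactly 1 (the published per-step
    percentages were rounded independently and total 101%).
    """
    corrected = run.corrected_activities()
    total = sum(corrected.values())
    if total == 0:
        raise UndefinedRatioError("all compartment activities are zero")
    return {c: a / total for c, a in corrected.items()}


def recovery_fraction(run: LabelingRun) -> float:
    """Decay-corrected recovered activity over nominal initial activity.

    Diagnostic for unrecovered residue (tube walls, aspiration losses);
    requires a positive ``initial_activity_mbq``.
    """
    if run.initial_activity_mbq <= 0:
        raise ValidationError("recovery diagnostic needs a positive initial activity")
    return sum(run.corrected_activities().values()) / run.initial_activity_mbq


@dataclass(frozen=True)
class UptakeModel:
    """Saturating uptake curve ``F(t) = f_inf * (1 - exp(-k t))``."""

    f_inf: float
    k_per_min: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_inf <= 1.0:
            raise ValidationError(f"f_inf must be in [0, 1], got {self.f_inf}")
        if not self.k_per_min > 0:
            raise ValidationError(f"k must be > 0, got {self.k_per_min}")

    def predict(self, t_min):
        """Incorporated fraction after ``t_min`` minutes of incubation."""
        return self.f_inf * -np.expm1(-self.k_per_min * np.asarray(t_min, dtype=float))

    def ratio(self, t1_min: float, t2_min: float) -> float:
        """Incorporation ratio ``F(t1)/F(t2)`` between two incubation times."""
        return float(self.predict(t1_min) / self.predict(t2_min))


def _two_point_uptake(t1: float, f1: float, t2: float, f2: float) -> UptakeModel:
    # Exact interpolant: solve (1-e^{-k t1})/(1-e^{-k t2}) = f1/f2 for k.
    r = f1 / f2
    if not t1 / t2 < r < 1.0:
        raise FitError(
            f"ratio {r:.4g} outside the identifiable range "
            f"({t1 / t2:.4g}, 1) for a saturating uptake curve"
        )

    def g(k: float) -> float:
        return -np.expm1(-k * t1) / -np.expm1(-k * t2) - r

    lo, hi = 1e-9, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - r < 1 guarantees a bracket
            raise FitError("failed to bracket the uptake rate constant")
    k = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=1e-14)
    return UptakeModel(f_inf=min(1.0, f1 / -np.expm1(-k * t1)), k_per_min=k)


def fit_uptake(timepoints: Sequence[tuple[float, float]]) -> UptakeModel:
    """Least-squares fit of the saturating uptake curve.

    With exactly two distinct timepoints the fit is the exact interpolant
    (closed form via root finding); with more, a bounded nonlinear least
    squares. The fitted curve is nondecreasing by construction.
    """
    pts = sorted((float(t), float(f)) for t, f in timepoints)
    if len(pts) < 2 or len({t for t, _ in pts}) < 2:
        raise FitError("need at least two distinct incubation times")
    for t, f in pts:
        if t < 0 or not 0.0 <= f <= 1.0:
            raise ValidationError(f"invalid uptake point (t={t}, fraction={f})")
    t = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if len(pts) == 2:
        return _two_point_uptake(t[0], f[0], t[1], f[1])

    # initial guess places ~95% saturation at the last timepoint
    p0 = [min(1.0, max(f) * 1.01), 3.0 / max(t)]
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, finf, k: finf * -np.expm1(-k * tt),
            t,
            f,
            p0=p0,
            bounds=([0.0, 1e-12], [1.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"uptake fit did not converge: {exc}") from exc
    return UptakeModel(f_inf=float(popt[0]), k_per_min=float(popt[1]))


@dataclass(frozen=True)
class LeakageModel:
    """Straight-line leakage: percent leaked = intercept + slope * t(min)."""

    intercept_pct: float
    slope_pct_per_min: float
    r_squared: float
    t_range_min: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValidationError(f"r_squared must be in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class FirstOrderRelease:
    """First-order release variant: percent leaked = L_inf * (1 - exp(-k t))."""

    l_inf_pct: float
    k_per_min: float
    r_squared: float

    def predict(self, t_min):
        return self.l_inf_pct * -np.expm1(-self.k_per_min * np.asarray(t_min, float))


def _check_leak_points(points) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(t) < 2 or len(np.unique(t)) < 2:
        raise FitError("need at least two distinct incubation times")
    return t, y


def fit_leakage(points: Sequence[tuple[float, float]]) -> LeakageModel:
    """Ordinary least squares line through (minutes, percent leaked) points."""
    t, y = _check_leak_points(points)
    res = stats.linregress(t, y)
    r2 = 1.0 if np.allclose(y, y.mean()) else float(res.rvalue) ** 2
    return LeakageModel(
        intercept_pct=float(res.intercept),
        slope_pct_per_min=float(res.slope),
        r_squared=min(1.0, r2),
        t_range_min=(float(t.min()), float(t.max())),
    )


def fit_leakage_first_order(points: Sequence[tuple[float, float]]) -> FirstOrderRelease:
    """First-order release fit (config-flag alternative to the linear default)."""
    t, y = _check_leak_points(points)
    popt, _ = optimize.curve_fit(
        lambda tt, linf, k: linf * -np.expm1(-k * tt),
        t,
        y,
        p0=[max(y.max(), 1.0), 1.0 / max(t.max(), 1.0)],
        bounds=([0.0, 1e-12], [100.0, np.inf]),
        maxfev=10000,
    )
    pred = popt[0] * -np.expm1(-popt[1] * t)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sstot == 0 else 1.0 - float(((y - pred) ** 2).sum()) / sstot
    return FirstOrderRelease(float(popt[0]), float(popt[1]), max(0.0, min(1.0, r2)))


def predict_leakage_at(model: LeakageModel, t_min: float) -> float:
    """Fitted percent leaked at ``t_min``, clamped to [0, 100].

    Warns when evaluated more than 30 min outside the fitted time range.
    """
    rng = model.t_range_min
    if rng is not None and not rng[0] - 30.0 <= t_min <= rng[1] + 30.0:
        warnings.warn(
            f"t={t_min} min is far outside the fitted range {rng}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    value = model.intercept_pct + model.slope_pct_per_min * t_min
    return float(min(100.0, max(0.0, value)))


def predict_yield(
    initial_mbq: float,
    incorporated_fraction: float,
    prep_time_min: float,
    nuclide: Radionuclide,
) -> float:
    """Activity (MBq) incorporated in the finished batch.

    ``initial * fraction * decay_factor(prep_time)``: the starting activity
    scaled by the incorporation fraction and by physical decay over the
    total preparation time (default planning value 65 min, the midpoint of
    a 60-70 min incubate-and-wash protocol).
    """
    if initial_mbq < 0 or prep_time_min < 0:
        raise ValidationError("initial activity and prep time must be >= 0")
    if not 0.0 <= incorporated_fraction <= 1.0:
        raise ValidationError("incorporated fraction must be in [0, 1]")
    return initial_mbq * incorporated_fraction * decay_factor(prep_time_min, nuclide)


def load_labeling_run(
    csv_path,
    nuclide: Radionuclide | None = None,
    initial_activity_mbq: float | None = None,
    sidecar_yaml=None,
) -> LabelingRun:
    """Read a run from a ``compartment,activity_mbq,t_min`` CSV.

    Nuclide and initial activity come either from the keyword arguments or
    from a sidecar YAML with keys ``nuclide`` and ``initial_activity_mbq``.
    """
    import pandas as pd

    from .config import load_nuclide

    if sidecar_yaml is not None:
        with open(sidecar_yaml) as fh:
            meta = yaml.safe_load(fh)
        nuclide = nuclide or load_nuclide(meta["nuclide"])
        if initial_activity_mbq is None:
            initial_activity_mbq = float(meta["initial_activity_mbq"])
    if nuclide is None or initial_activity_mbq is None:
        raise ValidationError("nuclide and initial activity are required")
    df = pd.read_csv(csv_path, comment="#")
    measurements = tuple(
        ActivityMeasurement(
            Compartment(row["compartment"]),
            float(row["activity_mbq"]),
            float(row.get("t_min", 0.0)),
        )
        for _, row in df.iterrows()
    )
    return LabelingRun(nuclide, measurements, float(initial_activity_mbq))
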