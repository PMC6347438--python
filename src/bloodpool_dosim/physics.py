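"""Radioactive decay arithmetic shared by every downstream stage.

Conventions
-----------
* Time is carried as **minutes on a common clock** — minutes from injection
  for biodistribution, minutes from tracer addition for labeling runs.
  Parsing of wall-clock timestamps belongs in I/O code, never here.
* Activities are in MBq.

The half-lives of the packaged radionuclides live in ``data/nuclides.yaml``
(with literature provenance), not in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LN2", "Radionuclide", "decay_factor", "decay_correct"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Radionuclide:
    """Physical identity of a tracer isotope.

    Parameters
    ----------
    name:
        Text label, e.g. ``"F-18"``.
    half_life_min:
        Physical half-life :math:`T_{1/2}` in minutes. Must be positive.
    """

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not self.half_life_min > 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_min}")

    @property
    def decay_constant_per_min(self) -> float:
        """Decay constant :math:`\\lambda = \\ln 2 / T_{1/2}` (per minute)."""
        return LN2 / self.half_life_min

    @property
    def half_life_h(self) -> float:
        """Half-life in hours."""
        return self.half_life_min / 60.0


def decay_factor(elapsed_min, nuclide: Radionuclide):
    """Fraction of activity surviving after ``elapsed_min`` minutes.

    Returns :math:`2^{-t/T_{1/2}}`; strictly decreasing in ``elapsed_min``
    and equal to 1 at ``elapsed_min = 0``. Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any elapsed time is negative.
    """
    elapsed = np.asarray(elapsed_min, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed time must be non-negative")
    out = np.exp2(-elapsed / nuclide.half_life_min)
    return float(out) if out.ndim == 0 else out


def decay_correct(measured, t_measured_min, t_reference_min, nuclide: Radionuclide):
    """Rescale a measured activity to an earlier reference time.

    ``measured / decay_factor(t_measured - t_reference)``: the activity the
    sample had at the reference time, assuming pure physical decay in
    between. Round-trips exactly with decay: correcting an activity that
    was decayed from ``t_reference`` to ``t_measured`` recovers the original.

    Raises
    ------
    ValueError
        If ``measured`` is negative, or ``t_measured < t_reference``.
    """
    if np.any(np.asarray(measured, dtype=float) < 0):
        raise ValueError("measured activity must be non-negative")
    return measured / decay_factor(
        np.asarray(t_measured_min, dtype=float) - t_reference_min, nuclide
    )
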