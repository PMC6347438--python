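"""Loaders for the packaged configuration tables.

Every numeric constant the pipeline needs — half-lives, ICRP blood-volume
fractions, ICRP-60 tissue weights, 21 CFR 361.1 limits, reference
effective-dose coefficients and the published organ-dose fixture — lives
in ``bloodpool_dosim/data`` with a provenance comment, never in code.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .physics import Radionuclide

__all__ = [
    "data_path",
    "load_nuclide",
    "load_blood_volume_csv",
    "load_icrp89_blood_volumes",
    "load_tissue_weights",
    "load_regulatory_limits",
    "load_reference_organ_doses",
    "load_reference_coefficients",
]

_ALIASES = {
    "18F": "F-18",
    "F18": "F-18",
    "F-18": "F-18",
    "99MTC": "Tc-99m",
    "TC99M": "Tc-99m",
    "TC-99M": "Tc-99m",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("bloodpool_dosim") / "data" / name))


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_nuclide(name: str) -> Radionuclide:
    """Look up a packaged radionuclide by name (aliases like ``18F`` accepted)."""
    canonical = _ALIASES.get(name.upper().replace(" ", ""), name)
    with open(data_path("nuclides.yaml")) as fh:
        table = yaml.safe_load(fh)["nuclides"]
    if canonical not in table:
        raise KeyError(f"unknown nuclide {name!r}; packaged: {sorted(table)}")
    return Radionuclide(canonical, float(table[canonical]["half_life_minutes"]))


def load_blood_volume_csv(path, provenance: str = ""):
    """Read an ``organ,fraction`` CSV into a :class:`BloodVolumeTable`."""
    from .biodistribution import BloodVolumeTable

    df = _read_csv(path)
    if not {"organ", "fraction"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns organ,fraction")
    fractions = dict(zip(df["organ"].astype(str), df["fraction"].astype(float)))
    return BloodVolumeTable(fractions=fractions, provenance=provenance or str(path))


def load_icrp89_blood_volumes():
    """The packaged ICRP Publication 89 blood-volume table."""
    return load_blood_volume_csv(
        data_path("icrp89_blood_volumes.csv"),
        provenance="ICRP Publication 89 (2002), Table 2.14",
    )


def load_tissue_weights(path=None):
    """ICRP-60 tissue weighting factors (packaged file unless a path is given)."""
    from .mird import TissueWeights

    with open(path or data_path("icrp60_tissue_weights.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return TissueWeights(
        weights={k: float(v) for k, v in raw["weights"].items()},
        remainder_weight=float(raw["remainder_weight"]),
        remainder_organs=tuple(raw["remainder_organs"]),
        surrogates=dict(raw.get("surrogates", {})),
        provenance=raw.get("provenance", str(path or "")),
    )


def load_regulatory_limits(path=None):
    """21 CFR 361.1 single-administration and annual dose limits."""
    from .mird import RegulatoryLimits

    with open(path or data_path("cfr361_limits.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return RegulatoryLimits(
        single_restricted_mSv=float(raw["single_admin_mSv"]["restricted"]),
        single_other_mSv=float(raw["single_admin_mSv"]["other"]),
        annual_restricted_mSv=float(raw["annual_mSv"]["restricted"]),
        annual_other_mSv=float(raw["annual_mSv"]["other"]),
        restricted_organs=frozenset(raw["restricted_organs"]),
    )


def load_reference_organ_doses(path=None) -> pd.DataFrame:
    """Published FDG-erythrocyte organ-dose coefficients (mGy/MBq).

    Columns are the two biodistribution scenarios (``full_retention``,
    ``free_fdg_25pct``); the index is the target organ.
    """
    df = _read_csv(path or data_path("fdg_rbc_organ_doses.csv"))
    return df.set_index("organ").astype(float)


def load_reference_coefficients() -> dict:
    """Headline effective-dose coefficients and planned activity ranges."""
    with open(data_path("reference_coefficients.yaml")) as fh:
        return yaml.safe_load(fh)
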