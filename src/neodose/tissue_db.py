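"""Per-tissue dielectric and thermal properties.

Dielectric properties (relative permittivity ``eps_r`` and conductivity
``sigma`` in S/m) are stored per tissue *and* per frequency; thermal
properties (conductivity ``k``, specific heat ``c``, perfusion ``w``,
metabolic rate ``q_met``) and mass density ``rho`` are frequency
independent but carried on every row for convenience.

Units at the interface:

=================  =======================================
eps_r              dimensionless (>= 1 for tissues)
sigma_S_per_m      S/m
rho_kg_m3          kg/m^3
k_W_mK             W/(m K)
c_J_kgK            J/(kg K)
perfusion_ml_min_kg  mL blood per minute per kg of tissue
qmet_W_kg          W per kg of tissue
=================  =======================================

Perfusion is converted internally to a volumetric blood mass exchange
rate ``W_b`` in kg blood m^-3 s^-1 (see :func:`volumetric_perfusion`),
which multiplies the blood specific heat in the bioheat perfusion term.

Neonatal tissues hold more water than adult tissues, which raises both
permittivity and conductivity.  The package applies multiplicative
newborn/adult ratios to an adult property table; the shipped ratio table
is a clearly labeled synthetic default and should be replaced with
authoritative values for publication-grade use.  Thermal properties are
never scaled (adult values are retained, which is conservative since
higher water content would increase conductivity and heat capacity and
therefore lower temperatures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TissueTable",
    "ScalingTable",
    "load_adult_table",
    "load_neonate_scaling",
    "identity_scaling",
    "apply_age_scaling",
    "simplify_segmentation",
    "lookup",
    "volumetric_perfusion",
]

#: relative tolerance for matching a requested frequency to a stored one
FREQ_RTOL = 0.10

_COLUMNS = [
    "tissue",
    "freq_MHz",
    "eps_r",
    "sigma_S_per_m",
    "rho_kg_m3",
    "k_W_mK",
    "c_J_kgK",
    "perfusion_ml_min_kg",
    "qmet_W_kg",
    "source",
]


@dataclass
class TissueTable:
    """Wrapper around a per-tissue property DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"tissue table missing columns: {missing}")
        num = self.df[_COLUMNS[1:-1]].to_numpy(dtype=float)
        if not np.all(np.isfinite(num)):
            raise ValueError("tissue table contains non-finite values")
        if (num < 0).any():
            raise ValueError("tissue table contains negative physical values")
        if (self.df["eps_r"] < 1).any():
            raise ValueError("relative permittivity must be >= 1")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.df["tissue"].unique())

    def subset(self, tissues: Iterable[str]) -> "TissueTable":
        keep = set(tissues)
        return TissueTable(self.df[self.df["tissue"].isin(keep)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TissueTable":
        return cls(pd.read_csv(path))

    def density(self, tissue: str) -> float:
        rows = self.df[self.df["tissue"] == tissue]
        if rows.empty:
            raise KeyError(f"unknown tissue {tissue!r}")
        return float(rows["rho_kg_m3"].iloc[0])


@dataclass
class ScalingTable:
    """Newborn/adult dielectric property ratios at a stated frequency."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("tissue", "freq_MHz", "ratio_eps", "ratio_sigma"):
            if c not in self.df.columns:
                raise ValueError(f"scaling table missing column {c!r}")
        if (self.df[["ratio_eps", "ratio_sigma"]] <= 0).any().any():
            raise ValueError("scaling ratios must be > 0")

    def ratios(self, tissue: str) -> tuple[float, float]:
        rows = self.df[self.df["tissue"] == tissue]
        if rows.empty:
            raise KeyError(tissue)
        return float(rows["ratio_eps"].iloc[0]), float(rows["ratio_sigma"].iloc[0])

    def reciprocal(self) -> "ScalingTable":
        out = self.df.copy()
        out["ratio_eps"] = 1.0 / out["ratio_eps"]
        out["ratio_sigma"] = 1.0 / out["ratio_sigma"]
        return ScalingTable(out)


def _data_path(name: str):
    return resources.files("neodose.data") / name


def load_adult_table() -> TissueTable:
    """Packaged adult dielectric + thermal property table (editable CSV)."""
    with resources.as_file(_data_path("tissues_adult.csv")) as p:
        return TissueTable.from_csv(p)


def load_neonate_scaling() -> ScalingTable:
    """Packaged default newborn/adult dielectric ratio table.

    These are synthetic, water-content-motivated defaults (ratios >= 1
    for high-water tissues); supply an authoritative table for
    publication-grade work.
    """
    with resources.as_file(_data_path("scaling_neonate.csv")) as p:
        return ScalingTable(pd.read_csv(p))


def identity_scaling(tissues: Iterable[str], freq_MHz: float = 297.0) -> ScalingTable:
    rows = [
        {"tissue": t, "freq_MHz": freq_MHz, "ratio_eps": 1.0, "ratio_sigma": 1.0,
         "source": "identity"}
        for t in tissues
    ]
    return ScalingTable(pd.DataFrame(rows))


def apply_age_scaling(adult: TissueTable, ratios: ScalingTable) -> TissueTable:
    """Scale adult dielectric properties by newborn/adult ratios.

    eps_r' = eps_r * ratio_eps, sigma' = sigma * ratio_sigma.  Thermal
    fields and density are left unchanged.  Tissues without an explicit
    ratio get 1.0 with a warning.
    """
    df = adult.df.copy()
    known = set(ratios.df["tissue"])
    re = np.ones(len(df))
    rs = np.ones(len(df))
    missing = []
    for i, t in enumerate(df["tissue"]):
        if t in known:
            re[i], rs[i] = ratios.ratios(t)
        else:
            missing.append(t)
    if missing:
        warnings.warn(
            f"no scaling ratio for tissues {sorted(set(missing))}; using 1.0",
            stacklevel=2,
        )
    df["eps_r"] = df["eps_r"] * re
    df["sigma_S_per_m"] = df["sigma_S_per_m"] * rs
    df["source"] = df["source"].astype(str) + " [age-scaled]"
    return TissueTable(df)


def simplify_segmentation(model, keep: Iterable[str], fallback: str):
    """Remap tissue labels not in ``keep`` to the ``fallback`` tissue.

    Emulates a coarse segmentation: every voxel keeps its geometry but
    unsegmented tissues are pooled into one generic class (typically
    connective tissue).  Masks are recomputed; the voxel count is
    conserved.
    """
    from .phantoms import VoxelModel  # local import to avoid cycle

    keep = set(keep)
    if not keep:
        raise ValueError("keep set must not be empty")
    name_to_label = {v: k for k, v in model.tissue_names.items()}
    if fallback not in name_to_label:
        raise KeyError(f"fallback tissue {fallback!r} not present in model")
    fb = name_to_label[fallback]

    labels = model.labels.copy()
    new_names = {}
    new_density = {}
    for lab, name in model.tissue_names.items():
        if name in keep or name == fallback or name == "blanket":
            new_names[lab] = name
            new_density[lab] = model.density[lab]
        else:
            labels[model.labels == lab] = fb
            new_names.setdefault(fb, fallback)
            new_density.setdefault(fb, model.density[fb])
    new_names[fb] = fallback
    new_density[fb] = model.density[fb]

    out = VoxelModel(
        labels=labels,
        voxel_size=model.voxel_size,
        tissue_names=new_names,
        density=new_density,
        masks={},
        reference_slice=model.reference_slice,
    )
    out.masks = {k: v.copy() for k, v in model.masks.items()}
    out.recompute_basic_masks()
    if "core" in out.masks:
        from .phantoms import define_core_mask

        try:
            out.masks["core"] = define_core_mask(out)
        except KeyError:
            del out.masks["core"]  # core tissues were remapped away
    return out


def lookup(table: TissueTable, tissue: str, freq_MHz: float) -> pd.Series:
    """Return the stored property row for ``tissue`` near ``freq_MHz``.

    The requested frequency must lie within 10% of a stored frequency for
    that tissue; no interpolation across frequencies is performed.
    """
    rows = table.df[table.df["tissue"] == tissue]
    if rows.empty:
        raise KeyError(f"unknown tissue {tissue!r}")
    rel = np.abs(rows["freq_MHz"] - freq_MHz) / freq_MHz
    ok = rows[rel <= FREQ_RTOL]
    if ok.empty:
        stored = sorted(rows["freq_MHz"].unique())
        raise ValueError(
            f"no stored frequency within {FREQ_RTOL:.0%} of {freq_MHz} MHz for "
            f"{tissue!r} (stored: {stored})"
        )
    return ok.iloc[0]


def volumetric_perfusion(
    rho_tissue: float, w_ml_min_kg: float, rho_blood: float = 1050.0
) -> float:
    """Convert perfusion to a volumetric blood mass exchange rate.

    ``w`` mL blood min^-1 (kg tissue)^-1 in a voxel of tissue density
    ``rho_tissue`` corresponds to

        W_b = rho_tissue * w * rho_blood * 1e-6 / 60   [kg blood m^-3 s^-1]

    (1e-6 converts mL to m^3, /60 converts minutes to seconds).  The
    Pennes perfusion heat term is then ``W_b * c_b * (T_blood - T)`` in
    W m^-3.
    """
    return rho_tissue * w_ml_min_kg * rho_blood * 1e-6 / 60.0
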