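"""Specific absorption rate (SAR) dosimetry on voxel models.

Conventions
-----------
* ``|E|`` is the **RMS** electric-field magnitude, so the pointwise SAR
  is ``SAR = sigma * |E|^2 / rho`` with no factor 1/2.
* All SAR values are 100% duty cycle; time-averaging over a pulse
  sequence is the caller's concern.
* The peak spatial 10 g SAR (psSAR10g) uses a centered-cube growth with
  a fractionally weighted outermost shell so the enclosed tissue mass is
  exactly 10 g — an IEC 62704-1-style simplification.  Air (and
  blanket) voxels inside the cube contribute zero mass and zero SAR.
  Voxels whose cube would have to extend past the grid before reaching
  10 g are marked invalid and excluded from the peak.
* The mean B1+ used for per-B1+^2 normalization is the mean of |B1+|
  over *tissue* voxels in the model's central axial (reference) slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .phantoms import BLANKET_LABEL, VoxelModel, shift_model
from .tissue_db import TissueTable, lookup

logger = logging.getLogger(__name__)

__all__ = [
    "PowerBudget",
    "ExposureField",
    "SARResult",
    "surrogate_field",
    "pointwise_sar",
    "region_average_sar",
    "mass_averaged_sar_10g",
    "compute_sar",
    "normalize",
    "shift_experiment",
    "read_field",
    "write_field",
]

BUDGET_RTOL = 0.01  # closure tolerance: forward = reflected + radiated + absorbed


@dataclass
class PowerBudget:
    forward_W: float
    reflected_W: float
    radiated_W: float
    absorbed_W: float

    def validate(self) -> None:
        total = self.reflected_W + self.radiated_W + self.absorbed_W
        if self.forward_W <= 0:
            raise ValueError("forward power must be > 0")
        if min(self.reflected_W, self.radiated_W, self.absorbed_W) < -1e-12:
            raise ValueError("power budget terms must be >= 0")
        if abs(total - self.forward_W) > BUDGET_RTOL * self.forward_W:
            raise ValueError(
                f"power budget does not close: forward={self.forward_W:.4g} W vs "
                f"reflected+radiated+absorbed={total:.4g} W (>1%)"
            )

    def scaled(self, factor: float) -> "PowerBudget":
        return PowerBudget(*(getattr(self, f) * factor for f in
                             ("forward_W", "reflected_W", "radiated_W", "absorbed_W")))


@dataclass
class ExposureField:
    """RMS |E| and complex B1+ grids in the (fixed) coil frame."""

    E_rms: np.ndarray            # V/m
    B1_plus: np.ndarray          # complex, microtesla
    budget: PowerBudget
    central_slice: int
    freq_MHz: float = 297.0

    @property
    def P_in(self) -> float:
        return self.budget.forward_W

    def validate(self) -> None:
        if self.E_rms.shape != self.B1_plus.shape:
            raise ValueError("E and B1+ grids must share a geometry")
        self.budget.validate()

    def scaled(self, power_factor: float) -> "ExposureField":
        """Same field pattern at ``power_factor`` times the drive power
        (fields scale with the square root)."""
        a = np.sqrt(power_factor)
        return ExposureField(self.E_rms * a, self.B1_plus * a,
                             self.budget.scaled(power_factor),
                             self.central_slice, self.freq_MHz)


@dataclass
class SARResult:
    sar: np.ndarray                    # W/kg pointwise
    head_avg: float
    whole_body_avg: float
    psSAR10g: float
    ps_location: tuple[int, int, int]
    ps_valid: np.ndarray
    sar10_grid: np.ndarray
    mean_B1_slice: float               # microtesla at the drive of `budget`
    budget: PowerBudget
    normalizations: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for mode, vals in self.normalizations.items():
            for region, v in vals.items():
                rows.append({"normalization": mode, "region": region, "value": v})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-voxel property grids
# ---------------------------------------------------------------------------

def _property_grids(model: VoxelModel, table: TissueTable, freq_MHz: float):
    sigma = np.zeros(model.labels.shape)
    rho = np.zeros(model.labels.shape)
    for lab, name in model.tissue_names.items():
        sel = model.labels == lab
        if not sel.any():
            continue
        row = lookup(table, name, freq_MHz)
        sigma[sel] = row["sigma_S_per_m"]
        rho[sel] = row["rho_kg_m3"]
    return sigma, rho


def pointwise_sar(field: ExposureField, model: VoxelModel,
                  table: TissueTable) -> np.ndarray:
    """SAR(v) = sigma(v) |E_rms(v)|^2 / rho(v); zero in air and blanket."""
    field.validate()
    sigma, rho = _property_grids(model, table, field.freq_MHz)
    tissue = model.masks["whole_body"]
    if np.any(rho[tissue] == 0):
        bad = np.unique(model.labels[tissue & (rho == 0)])
        raise ValueError(f"zero density in tissue labels {bad.tolist()}")
    sar = np.zeros(model.labels.shape)
    sar[tissue] = sigma[tissue] * field.E_rms[tissue] ** 2 / rho[tissue]
    return sar


def region_average_sar(sar: np.ndarray, model: VoxelModel,
                       mask: np.ndarray) -> float:
    """Mass-weighted mean SAR over ``mask``."""
    if not mask.any():
        raise ValueError("empty region mask")
    rho = model.density_grid()
    w = rho[mask]
    return float(np.sum(sar[mask] * w) / np.sum(w))


# ---------------------------------------------------------------------------
# psSAR10g: centered-cube growth via 3D summed-area tables
# ---------------------------------------------------------------------------

def _padded_cumsum(grid: np.ndarray) -> np.ndarray:
    c = np.zeros(tuple(s + 1 for s in grid.shape))
    c[1:, 1:, 1:] = grid.cumsum(0).cumsum(1).cumsum(2)
    return c


def _cube_sum(c: np.ndarray, n: int, shape) -> np.ndarray:
    """Sums over cubes of half-width ``n`` at all fully interior centers."""
    nx, ny, nz = shape
    i1, i2 = slice(0, nx - 2 * n), slice(2 * n + 1, nx + 1)
    j1, j2 = slice(0, ny - 2 * n), slice(2 * n + 1, ny + 1)
    k1, k2 = slice(0, nz - 2 * n), slice(2 * n + 1, nz + 1)
    return (c[i2, j2, k2] - c[i1, j2, k2] - c[i2, j1, k2] - c[i2, j2, k1]
            + c[i1, j1, k2] + c[i1, j2, k1] + c[i2, j1, k1] - c[i1, j1, k1])


def mass_averaged_sar_10g(sar: np.ndarray, model: VoxelModel,
                          target_mass_kg: float = 0.010):
    """Peak spatial mass-averaged SAR by centered-cube growth.

    For every tissue voxel a cube centered on it grows until the
    enclosed tissue mass reaches ``target_mass_kg``; the outermost shell
    is fractionally weighted so the enclosed mass is exact.  Returns
    ``(psSAR10g, location, sar10_grid, valid_mask)``; the peak is the
    maximum over valid voxels with ties broken by lowest linear index.
    """
    tissue = model.masks["whole_body"]
    rho = model.density_grid()
    rho = np.where(tissue, rho, 0.0)
    dV = model.voxel_volume_m3
    mass = rho * dV
    total = mass.sum()
    if total < target_mass_kg:
        raise ValueError(
            f"total tissue mass {total * 1e3:.1f} g below target "
            f"{target_mass_kg * 1e3:.0f} g"
        )
    power = sar * mass  # W deposited per voxel

    cm = _padded_cumsum(mass)
    cp = _padded_cumsum(power)
    shape = sar.shape

    sar10 = np.full(shape, np.nan)
    found = np.zeros(shape, dtype=bool)
    m_prev = np.zeros(shape)
    p_prev = np.zeros(shape)

    n_max = (min(shape) - 1) // 2
    for n in range(n_max + 1):
        interior = tuple(slice(n, s - n) for s in shape)
        m_n = _cube_sum(cm, n, shape)
        p_n = _cube_sum(cp, n, shape)
        t_i = tissue[interior]
        newly = t_i & ~found[interior] & (m_n >= target_mass_kg)
        if newly.any():
            dm = m_n - m_prev[interior]
            dp = p_n - p_prev[interior]
            f = (target_mass_kg - m_prev[interior]) / np.where(dm > 0, dm, 1.0)
            val = (p_prev[interior] + f * dp) / target_mass_kg
            block = sar10[interior]
            block[newly] = val[newly]
            sar10[interior] = block
            fblock = found[interior]
            fblock[newly] = True
            found[interior] = fblock
        m_prev[interior] = m_n
        p_prev[interior] = p_n
        if found[tissue].all():
            break

    valid = found & tissue
    if not valid.any():
        raise ValueError("no voxel can reach the target mass within the grid")
    flat = np.where(valid.ravel(), np.nan_to_num(sar10.ravel(), nan=-np.inf), -np.inf)
    idx = int(np.argmax(flat))  # argmax returns the lowest linear index on ties
    loc = np.unravel_index(idx, shape)
    return float(sar10[loc]), tuple(int(v) for v in loc), sar10, valid


# ---------------------------------------------------------------------------
# full SAR evaluation and normalization
# ---------------------------------------------------------------------------

def _mean_b1_slice(field: ExposureField, model: VoxelModel,
                   reference_slice: int | None = None) -> float:
    z = reference_slice if reference_slice is not None else model.reference_slice
    if z is None:
        z = model.labels.shape[2] // 2
    tissue = model.masks["whole_body"][:, :, z]
    if not tissue.any():
        raise ValueError(f"no tissue voxels in reference slice {z}")
    return float(np.abs(field.B1_plus[:, :, z][tissue]).mean())


def compute_sar(field: ExposureField, model: VoxelModel, table: TissueTable,
                head_mask: np.ndarray | None = None,
                target_mass_kg: float = 0.010) -> SARResult:
    """Pointwise SAR, region averages, psSAR10g and all normalizations."""
    sar = pointwise_sar(field, model, table)
    head = head_mask if head_mask is not None else model.masks["head"]
    head_avg = region_average_sar(sar, model, head)
    wb_avg = region_average_sar(sar, model, model.masks["whole_body"])
    ps, loc, sar10, valid = mass_averaged_sar_10g(sar, model, target_mass_kg)
    res = SARResult(
        sar=sar, head_avg=head_avg, whole_body_avg=wb_avg,
        psSAR10g=ps, ps_location=loc, ps_valid=valid, sar10_grid=sar10,
        mean_B1_slice=_mean_b1_slice(field, model), budget=field.budget,
    )
    for mode in ("input_power", "net_forward", "absorbed", "b1_slice"):
        res.normalizations[mode] = normalize(res, mode)
    return res


def normalize(res: SARResult, mode: str) -> dict[str, float]:
    """Region SAR values divided by the requested reference quantity.

    * ``input_power``: per W of total input (forward) power;
    * ``net_forward``: per W of forward - reflected power;
    * ``absorbed``: per W of tissue-absorbed power;
    * ``b1_slice``: per (mean |B1+| over the central axial slice)^2 at
      the same drive, in W/kg/uT^2.
    """
    b = res.budget
    if mode == "input_power":
        denom = b.forward_W
    elif mode == "net_forward":
        denom = b.forward_W - b.reflected_W
    elif mode == "absorbed":
        denom = b.absorbed_W
    elif mode == "b1_slice":
        denom = res.mean_B1_slice ** 2
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise ZeroDivisionError(f"normalization denominator for {mode!r} is {denom}")
    return {
        "head_avg": res.head_avg / denom,
        "whole_body_avg": res.whole_body_avg / denom,
        "psSAR10g": res.psSAR10g / denom,
    }


# ---------------------------------------------------------------------------
# surrogate exposure fields
# ---------------------------------------------------------------------------

def surrogate_field(
    model: VoxelModel,
    table: TissueTable,
    kind: str = "radial_gradient",
    P_in: float = 1.0,
    reflected_fraction: float = 0.11,
    absorbed_fraction: float = 0.59,
    b1_efficiency_uT_per_sqrtW: float = 0.53,
    freq_MHz: float = 297.0,
    params: dict | None = None,
) -> ExposureField:
    """Deterministic parametric stand-in for a full-wave EM solve.

    The |E| pattern is an invented shape (uniform, radial gradient about
    the coil axis, or a superficial hotspot) scaled so the integrated
    absorbed power equals ``absorbed_fraction * P_in``; B1+ is a smooth
    center-weighted profile scaled so the mean |B1+| over tissue voxels
    in the central axial slice equals ``b1_efficiency * sqrt(P_in)``.
    The remaining power is booked as radiated, which closes the budget
    by construction.  ``kind='imported'`` takes explicit grids and a
    budget from ``params`` and validates closure.
    """
    params = dict(params or {})
    shape = model.labels.shape
    vox = np.asarray(model.voxel_size)
    tissue = model.masks["whole_body"]

    if kind == "imported":
        E = np.asarray(params["E_rms"], dtype=float)
        B1 = np.asarray(params["B1_plus"], dtype=complex)
        budget = PowerBudget(*(float(params[k]) for k in
                               ("forward_W", "reflected_W", "radiated_W", "absorbed_W")))
        if E.shape != shape:
            raise ValueError("imported grids do not match the model geometry")
        budget.validate()
        return ExposureField(E, B1, budget, _default_slice(model), freq_MHz)

    axes = [(np.arange(n) + 0.5) * d for n, d in zip(shape, vox)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    cx, cy = shape[0] * vox[0] / 2, shape[1] * vox[1] / 2
    r_cyl = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    r_ref = max(cx, cy)
    # head-coil axial envelope: exposure falls off away from the coil
    # center, which sits at the model's reference (head) slice
    z0 = _default_slice(model) * vox[2]
    sigma_z = float(params.get("axial_sigma_mm", 100.0))
    envelope = np.exp(-((Z - z0) / sigma_z) ** 2) + np.zeros(shape)

    if kind == "uniform":
        e = np.ones(shape)
    elif kind == "radial_gradient":
        # birdcage-like: E grows with distance from the coil axis
        e = (r_cyl / r_ref) * envelope
    elif kind == "superficial_hotspot":
        base = (r_cyl / r_ref) * envelope
        center = np.asarray(params.get("hotspot_center_mm",
                                       _default_hotspot(model)))
        s = float(params.get("hotspot_sigma_mm", 20.0))
        amp = float(params.get("hotspot_amplitude", 0.6))
        d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        e = base + amp * np.exp(-d2 / (2 * s ** 2))
    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")

    sigma, _rho = _property_grids(model, table, freq_MHz)
    dV = model.voxel_volume_m3
    absorbed_unit = float(np.sum(sigma[tissue] * e[tissue] ** 2) * dV)
    if absorbed_unit <= 0:
        raise ValueError("surrogate pattern deposits no power in tissue")
    target_abs = absorbed_fraction * P_in
    if absorbed_fraction + reflected_fraction > 1.0 + BUDGET_RTOL:
        raise ValueError("absorbed + reflected fractions exceed 1")
    E = e * np.sqrt(target_abs / absorbed_unit)

    b1_shape = 1.0 - 0.15 * (r_cyl / r_ref) ** 2 + np.zeros(shape)
    z = _default_slice(model)
    t_slice = tissue[:, :, z]
    mean_shape = float(b1_shape[:, :, z][t_slice].mean())
    B1 = (b1_shape / mean_shape) * b1_efficiency_uT_per_sqrtW * np.sqrt(P_in)
    B1 = B1.astype(complex)

    budget = PowerBudget(
        forward_W=P_in,
        reflected_W=reflected_fraction * P_in,
        radiated_W=(1.0 - reflected_fraction - absorbed_fraction) * P_in,
        absorbed_W=target_abs,
    )
    field = ExposureField(E, B1, budget, z, freq_MHz)
    field.validate()
    return field


def _default_slice(model: VoxelModel) -> int:
    if model.reference_slice is not None:
        return model.reference_slice
    return model.labels.shape[2] // 2


def _default_hotspot(model: VoxelModel):
    hc = model.meta.get("head_center_mm")
    if hc:
        # posterior neck: behind and below the head center
        return (hc[0], hc[1] + 50.0, hc[2] - 55.0)
    shape = np.asarray(model.labels.shape) * np.asarray(model.voxel_size)
    return tuple(shape / 2)


# ---------------------------------------------------------------------------
# position-shift experiment
# ---------------------------------------------------------------------------

def shift_experiment(
    model: VoxelModel,
    field: ExposureField,
    table: TissueTable,
    shifts_mm,
    clip_warn_fraction: float = 0.20,
) -> pd.DataFrame:
    """SAR vs model position inside a fixed field.

    The field stays in the coil frame; the model (with its reference
    slice) is translated.  Per-B1+^2 values use the mean |B1+| in the
    *translated* anatomic slice, i.e. the slice shifts with the model.
    Rows where the shift clips more than ``clip_warn_fraction`` of the
    tissue voxels are flagged.
    """
    n0 = int(model.masks["whole_body"].sum())
    rows = []
    for shift in shifts_mm:
        shifted = shift_model(model, shift)
        clipped = 1.0 - shifted.masks["whole_body"].sum() / n0
        flagged = clipped > clip_warn_fraction
        if flagged:
            logger.warning("shift %s clips %.0f%% of tissue voxels",
                           list(shift), 100 * clipped)
        res = compute_sar(field, shifted, table)
        b1sq = res.normalizations["b1_slice"]
        rows.append({
            "shift_x_mm": shift[0], "shift_y_mm": shift[1], "shift_z_mm": shift[2],
            "mean_B1_slice_uT": res.mean_B1_slice,
            "head_avg_per_B1sq": b1sq["head_avg"],
            "whole_body_avg_per_B1sq": b1sq["whole_body_avg"],
            "psSAR10g_per_B1sq": b1sq["psSAR10g"],
            "clipped_fraction": clipped,
            "flagged": flagged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HDF5 field I/O
# ---------------------------------------------------------------------------

def write_field(field: ExposureField, path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("E_rms", data=field.E_rms)
        f.create_dataset("B1_plus_real", data=field.B1_plus.real)
        f.create_dataset("B1_plus_imag", data=field.B1_plus.imag)
        f.attrs["forward_W"] = field.budget.forward_W
        f.attrs["reflected_W"] = field.budget.reflected_W
        f.attrs["radiated_W"] = field.budget.radiated_W
        f.attrs["absorbed_W"] = field.budget.absorbed_W
        f.attrs["central_slice"] = field.central_slice
        f.attrs["freq_MHz"] = field.freq_MHz


def read_field(path) -> ExposureField:
    with h5py.File(Path(path), "r") as f:
        E = f["E_rms"][()]
        B1 = f["B1_plus_real"][()] + 1j * f["B1_plus_imag"][()]
        budget = PowerBudget(*(float(f.attrs[k]) for k in
                               ("forward_W", "reflected_W", "radiated_W", "absorbed_W")))
        field = ExposureField(E, B1, budget, int(f.attrs["central_slice"]),
                              float(f.attrs["freq_MHz"]))
    field.validate()
    return field
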