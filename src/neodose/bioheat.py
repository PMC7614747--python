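"""Pennes bioheat solver on voxel models.

The solver integrates, per tissue (and blanket) voxel,

    rho c dT/dt = div(k grad T) + rho SAR + rho q_met
                  + W_b c_b (T_blood - T)

with an explicit forward-Euler scheme on the voxel grid.  Face
conductances between adjacent voxels use the harmonic mean of the two
conductivities; faces against air (or the grid boundary) carry a Robin
convective flux ``h (T - T_ambient)`` per face area — a single ``h``
for the whole exterior, whether exposed skin or blanket surface.  Air
itself carries no temperature.

``W_b`` is the volumetric blood mass exchange rate (kg blood m^-3
s^-1) derived from the tissue perfusion (mL min^-1 kg^-1); see
:func:`neodose.tissue_db.volumetric_perfusion`.

The blood pool can be a dynamic lumped compartment ("variable core
temperature"): a finite blood volume (default 324 mL, typical of a
3.6 kg term neonate) whose temperature evolves with the net
tissue-blood heat exchange,

    V_b rho_b c_b dT_blood/dt = sum_v W_b(v) c_b (T(v) - T_blood) dV.

It is integrated with the same time step as the grid, with the
exchange evaluated at the current temperatures (operator splitting).

Protocols: every simulation starts from a uniform 37 C state and is
first *equilibrated* for 60 min with h = 8 W m^-2 K^-1, a 22 C
background and the core held fixed, because activating the dynamic
blood pool from an unphysical uniform state gives unreliable results.
Exposure runs then continue from that state, by default with
h = 11 W m^-2 K^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantoms import BLANKET_LABEL, VoxelModel
from .tissue_db import TissueTable, lookup, volumetric_perfusion

logger = logging.getLogger(__name__)

__all__ = [
    "ThermalConfig",
    "ThermalState",
    "ThermalSystem",
    "build_system",
    "step",
    "equilibrate",
    "run_exposure",
    "perfusion_multiplier",
    "total_thermal_energy",
    "DEFAULT_PERFUSION_RAMP",
]

#: per-tissue maximum perfusion multipliers for the temperature-dependent
#: vasodilation ramp (reached at 45 C).  Configurable defaults; the ramp
#: applies only when `temp_dependent_perfusion` is enabled (adult mode).
DEFAULT_PERFUSION_RAMP = {"skin": 10.0, "muscle": 10.0, "fat": 5.0, "brain": 2.0}

RAMP_T_LOW = 39.0   # C: multiplier is 1 below this
RAMP_T_HIGH = 45.0  # C: multiplier saturates here


@dataclass
class ThermalConfig:
    h_W_m2K: float = 11.0
    T_ambient_C: float = 22.0
    dt_s: float | str = "auto"
    duration_s: float = 3600.0
    variable_core: bool = False
    temp_dependent_perfusion: bool = False
    blood_volume_ml: float = 324.0
    rho_blood: float = 1050.0
    c_blood: float = 3617.0
    T_blood_C: float = 37.0
    record_interval_s: float = 60.0
    freq_MHz: float = 297.0
    perfusion_ramp: dict = field(default_factory=lambda: dict(DEFAULT_PERFUSION_RAMP))
    core_average: str = "mass"  # or "arithmetic"
    #: axes whose exterior faces are insulated instead of Robin; used for
    #: reduced-dimension analytic verification (e.g. a true 1D slab)
    adiabatic_axes: tuple = ()

    def validate(self) -> None:
        if self.h_W_m2K < 0:
            raise ValueError("h must be >= 0")
        if self.variable_core and self.blood_volume_ml <= 0:
            raise ValueError("blood_volume_ml must be > 0 with variable core")


@dataclass
class ThermalState:
    T: np.ndarray          # C, defined on tissue+blanket voxels
    T_blood: float
    t: float = 0.0

    def copy(self) -> "ThermalState":
        return ThermalState(self.T.copy(), self.T_blood, self.t)


class ThermalSystem:
    """Precomputed discrete operator for one model + config."""

    def __init__(self, model: VoxelModel, table: TissueTable, config: ThermalConfig):
        config.validate()
        self.model = model
        self.config = config
        shape = model.labels.shape
        dx = np.asarray(model.voxel_size, dtype=float) * 1e-3  # m
        dV = float(np.prod(dx))
        areas = [dV / d for d in dx]  # face area normal to each axis

        domain = model.labels > 0  # tissue + blanket
        self.domain = domain
        self.tissue = model.masks["whole_body"]

        k = np.zeros(shape)
        rho = np.zeros(shape)
        c = np.zeros(shape)
        wb = np.zeros(shape)   # kg blood m^-3 s^-1
        qm = np.zeros(shape)   # W/kg
        for lab, name in model.tissue_names.items():
            sel = model.labels == lab
            if not sel.any():
                continue
            row = lookup(table, name, config.freq_MHz)
            for fld in ("k_W_mK", "c_J_kgK", "rho_kg_m3"):
                if not np.isfinite(row[fld]) or row[fld] <= 0:
                    raise ValueError(f"tissue {name!r}: invalid thermal property {fld}")
            k[sel] = row["k_W_mK"]
            rho[sel] = row["rho_kg_m3"]
            c[sel] = row["c_J_kgK"]
            if name != "blanket":
                wb[sel] = volumetric_perfusion(
                    row["rho_kg_m3"], row["perfusion_ml_min_kg"], config.rho_blood)
                qm[sel] = row["qmet_W_kg"]

        self.C = rho * c * dV                      # J/K per voxel
        with np.errstate(divide="ignore"):
            self.invC = np.where(domain, 1.0 / np.where(self.C > 0, self.C, 1.0), 0.0)

        # harmonic-mean face conductances (W/K), zero unless both sides in domain
        self.G = []
        for a in range(3):
            k0 = np.take(k, range(shape[a] - 1), axis=a)
            k1 = np.take(k, range(1, shape[a]), axis=a)
            both = (np.take(domain, range(shape[a] - 1), axis=a)
                    & np.take(domain, range(1, shape[a]), axis=a))
            with np.errstate(divide="ignore", invalid="ignore"):
                kh = np.where(k0 + k1 > 0, 2.0 * k0 * k1 / (k0 + k1), 0.0)
            self.G.append(np.where(both, kh * areas[a] / dx[a], 0.0))

        # Robin conductance per voxel (W/K): h in series with the
        # half-voxel conduction dx/(2k), so the convective flux applies at
        # the face (surface) temperature rather than the cell center
        R = np.zeros(shape)
        h = config.h_W_m2K
        with np.errstate(divide="ignore", invalid="ignore"):
            if h > 0:
                U = [np.where(k > 0, 1.0 / (1.0 / h + (dx[a] / 2.0) / np.where(k > 0, k, 1.0)), 0.0)
                     for a in range(3)]
            else:
                U = [np.zeros(shape)] * 3
        for a in range(3):
            if a in config.adiabatic_axes:
                continue
            lo = np.take(domain, range(shape[a] - 1), axis=a)
            hi = np.take(domain, range(1, shape[a]), axis=a)
            exposed_lo = lo & ~hi  # voxel at i exposed on its +a face
            exposed_hi = hi & ~lo  # voxel at i+1 exposed on its -a face
            pad_lo = [(0, 0)] * 3
            pad_lo[a] = (0, 1)
            pad_hi = [(0, 0)] * 3
            pad_hi[a] = (1, 0)
            exposed = (np.pad(exposed_lo, pad_lo).astype(float)
                       + np.pad(exposed_hi, pad_hi).astype(float))
            # grid-boundary faces count as exposed to ambient
            idx0 = [slice(None)] * 3
            idx0[a] = slice(0, 1)
            idx1 = [slice(None)] * 3
            idx1[a] = slice(shape[a] - 1, shape[a])
            edge = np.zeros(shape)
            edge[tuple(idx0)] += np.take(domain, [0], axis=a)
            edge[tuple(idx1)] += np.take(domain, [shape[a] - 1], axis=a)
            R += U[a] * areas[a] * (exposed + edge)
        self.R = R                                 # W/K per voxel

        self.Wcb = wb * config.c_blood * dV        # W/K per voxel
        self.Qmet = qm * rho * dV                  # W per voxel
        self.S_rf = np.zeros(shape)                # W per voxel (set via set_sar)
        self._rho_dV = rho * dV

        # perfusion-ramp bookkeeping
        self.ramp_masks = {}
        if config.temp_dependent_perfusion:
            for tname, mmax in config.perfusion_ramp.items():
                labs = [l for l, n in model.tissue_names.items() if n == tname]
                if labs:
                    self.ramp_masks[tname] = (np.isin(model.labels, labs), float(mmax))

        # stability bound: C / (sum of conductances + Robin + max perfusion)
        gsum = np.zeros(shape)
        for a in range(3):
            pad_lo = [(0, 0)] * 3
            pad_lo[a] = (0, 1)
            pad_hi = [(0, 0)] * 3
            pad_hi[a] = (1, 0)
            gsum += np.pad(self.G[a], pad_lo) + np.pad(self.G[a], pad_hi)
        wmax = self.Wcb.copy()
        for mask, mmax in self.ramp_masks.values():
            wmax[mask] *= mmax
        denom = gsum + self.R + wmax
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(denom > 0, self.C / np.where(denom > 0, denom, 1.0), np.inf)
        self.dt_stable = 0.9 * float(tau[domain].min()) if domain.any() else np.inf

        self.blood_heat_capacity = (config.blood_volume_ml * 1e-6
                                    * config.rho_blood * config.c_blood)  # J/K

    # ------------------------------------------------------------------
    def set_sar(self, sar: np.ndarray | None, scale: float = 1.0) -> None:
        """Install the RF source term (SAR in W/kg, times a drive scale)."""
        if sar is None:
            self.S_rf = np.zeros(self.C.shape)
        else:
            self.S_rf = sar * self._rho_dV * scale

    def resolve_dt(self) -> float:
        dt = self.config.dt_s
        if dt == "auto":
            return self.dt_stable
        dt = float(dt)
        if dt > self.dt_stable:
            raise ValueError(
                f"dt={dt} s exceeds the stability bound {self.dt_stable:.3g} s")
        return dt

    def initial_state(self, T0: float = 37.0) -> ThermalState:
        T = np.full(self.C.shape, self.config.T_ambient_C)
        T[self.domain] = T0
        return ThermalState(T, self.config.T_blood_C, 0.0)


def build_system(model: VoxelModel, table: TissueTable,
                 config: ThermalConfig) -> ThermalSystem:
    return ThermalSystem(model, table, config)


def perfusion_multiplier(T_local, tissue: str,
                         ramp: dict | None = None,
                         enabled: bool = True):
    """Vasodilation factor: 1 below 39 C, linear to the per-tissue
    maximum at 45 C, constant above.  Identity when disabled (neonate
    mode assumes temperature-independent perfusion) or for tissues
    without a ramp entry."""
    if not enabled:
        return np.ones_like(np.asarray(T_local, dtype=float))
    ramp = ramp if ramp is not None else DEFAULT_PERFUSION_RAMP
    mmax = ramp.get(tissue, 1.0)
    T = np.asarray(T_local, dtype=float)
    frac = np.clip((T - RAMP_T_LOW) / (RAMP_T_HIGH - RAMP_T_LOW), 0.0, 1.0)
    return 1.0 + frac * (mmax - 1.0)


def step(state: ThermalState, system: ThermalSystem, dt: float) -> ThermalState:
    """One explicit forward-Euler update of the grid and blood pool."""
    cfg = system.config
    T = state.T
    net = system.R * (cfg.T_ambient_C - T)
    net += system.Qmet + system.S_rf

    for a in range(3):
        G = system.G[a]
        hi = [slice(None)] * 3
        hi[a] = slice(1, None)
        lo = [slice(None)] * 3
        lo[a] = slice(None, -1)
        d = G * (T[tuple(hi)] - T[tuple(lo)])
        net[tuple(lo)] += d
        net[tuple(hi)] -= d

    wcb = system.Wcb
    if system.ramp_masks:
        wcb = wcb.copy()
        for tname, (mask, mmax) in system.ramp_masks.items():
            frac = np.clip((T[mask] - RAMP_T_LOW) / (RAMP_T_HIGH - RAMP_T_LOW), 0.0, 1.0)
            wcb[mask] *= 1.0 + frac * (mmax - 1.0)
    net += wcb * (state.T_blood - T)

    T_new = T + dt * net * system.invC

    Tb_new = state.T_blood
    if cfg.variable_core:
        exchange = float(np.sum(wcb * (T - state.T_blood)))  # W into the pool
        Tb_new = state.T_blood + dt * exchange / system.blood_heat_capacity

    if not np.isfinite(T_new[system.domain]).all() or np.abs(
            T_new[system.domain]).max() > 100.0:
        raise RuntimeError(
            f"thermal instability at t={state.t + dt:.1f} s "
            f"(dt={dt:.3g} s, stability bound {system.dt_stable:.3g} s)")
    return ThermalState(T_new, Tb_new, state.t + dt)


# ---------------------------------------------------------------------------
# summaries and protocols
# ---------------------------------------------------------------------------

def _summaries(state: ThermalState, system: ThermalSystem) -> dict:
    model = system.model
    T = state.T
    out = {"t_s": state.t, "T_blood_C": state.T_blood,
           "T_max_C": float(T[system.tissue].max())}
    core = model.masks.get("core")
    if core is not None and core.any():
        if system.config.core_average == "mass":
            w = system.C[core]  # rho*c*dV weighting ~ heat-capacity weighted
            wm = system._rho_dV[core]
            out["T_core_C"] = float(np.sum(T[core] * wm) / np.sum(wm))
        else:
            out["T_core_C"] = float(T[core].mean())
    else:
        out["T_core_C"] = np.nan
    skin = model.masks.get("skin")
    if skin is not None and skin.any():
        out["T_skin_mean_C"] = float(T[skin].mean())
    return out


def _run(state: ThermalState, system: ThermalSystem, duration: float,
         record_interval: float) -> tuple[pd.DataFrame, ThermalState]:
    dt = system.resolve_dt()
    n_steps = max(1, int(np.ceil(duration / dt)))
    dt = duration / n_steps  # land exactly on the end time
    if dt > system.dt_stable:
        n_steps += 1
        dt = duration / n_steps
    rec_every = max(1, int(round(record_interval / dt)))
    rows = [_summaries(state, system)]
    for i in range(1, n_steps + 1):
        state = step(state, system, dt)
        if i % rec_every == 0 or i == n_steps:
            rows.append(_summaries(state, system))
    return pd.DataFrame(rows), state


def equilibrate(model: VoxelModel, table: TissueTable,
                config: ThermalConfig | None = None,
                duration_s: float = 3600.0,
                h_W_m2K: float = 8.0) -> ThermalState:
    """Pre-exposure conditioning run.

    Starts from uniform 37 C tissue in a 22 C background with
    h = 8 W m^-2 K^-1, the core held at 37 C and no RF, and integrates
    for 60 min so the surface layers relax to a physical profile.
    """
    base = config or ThermalConfig()
    cfg = replace(base, h_W_m2K=h_W_m2K, variable_core=False,
                  T_blood_C=37.0, duration_s=duration_s,
                  temp_dependent_perfusion=False)
    system = build_system(model, table, cfg)
    system.set_sar(None)
    state = system.initial_state(37.0)
    if duration_s == 0:
        return state
    series, state = _run(state, system, duration_s, max(60.0, duration_s / 10))
    last = series.iloc[-1]
    logger.info("equilibration done: T_max=%.2f C, mean skin T=%.2f C",
                last["T_max_C"], last.get("T_skin_mean_C", np.nan))
    return state


def run_exposure(
    state0: ThermalState,
    model: VoxelModel,
    table: TissueTable,
    config: ThermalConfig,
    sar: np.ndarray | None = None,
    sar_scale: float = 1.0,
) -> tuple[pd.DataFrame, ThermalState]:
    """Continue from ``state0`` with the configured boundary/blood-pool
    settings and an optional RF source, emitting a summary time series
    (t, core, max, blood, mean skin temperature) at the configured
    cadence plus the final state."""
    system = build_system(model, table, config)
    system.set_sar(sar, sar_scale)
    state = ThermalState(state0.T.copy(), config.T_blood_C if not config.variable_core
                         else state0.T_blood, 0.0)
    if config.variable_core:
        state.T_blood = state0.T_blood
    return _run(state, system, config.duration_s, config.record_interval_s)


def total_thermal_energy(state: ThermalState, system: ThermalSystem,
                         include_blood: bool = True) -> float:
    """sum(rho c T dV) over the domain, plus the blood pool term; used by
    the conservation checks."""
    e = float(np.sum(system.C[system.domain] * state.T[system.domain]))
    if include_blood and system.config.variable_core:
        e += system.blood_heat_capacity * state.T_blood
    return e
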