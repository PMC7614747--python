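"""IEC limit logic: allowed drive power, thermal limit crossings, h sweeps.

Limits default to the operative values for head-coil exposure: head
average SAR 3.2 W/kg, psSAR10g 10 W/kg, core-temperature rise 0.5 C and
absolute local temperature 39 C.  They are plain configurable numbers;
no operating-mode taxonomy is encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioheat import ThermalConfig, equilibrate, run_exposure

__all__ = ["LimitSet", "ComplianceReport", "power_for_limit", "check_thermal",
           "h_sensitivity"]


@dataclass
class LimitSet:
    head_avg_W_kg: float = 3.2
    psSAR10g_W_kg: float = 10.0
    whole_body_W_kg: float | None = None
    core_rise_C: float = 0.5
    absolute_T_C: float = 39.0

    def validate(self) -> None:
        for name in ("head_avg_W_kg", "psSAR10g_W_kg", "core_rise_C", "absolute_T_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def scaled(self, factor: float) -> "LimitSet":
        return LimitSet(
            self.head_avg_W_kg * factor, self.psSAR10g_W_kg * factor,
            None if self.whole_body_W_kg is None else self.whole_body_W_kg * factor,
            self.core_rise_C, self.absolute_T_C)


@dataclass
class ComplianceReport:
    allowed_power_W: float
    binding_limit: str
    margins: dict[str, float]
    crossings: dict[str, float | None] = field(default_factory=dict)
    sweep: pd.DataFrame | None = None


def power_for_limit(sar_per_watt: dict[str, float],
                    limits: LimitSet | None = None) -> tuple[float, str]:
    """Largest drive power under every SAR limit.

    ``sar_per_watt`` holds region SAR normalized to input power
    (W/kg/W), keys ``head_avg``, ``psSAR10g`` and optionally
    ``whole_body_avg``.  Returns ``(P_allowed, binding limit name)``
    with ``P_allowed = min(limit / normalized SAR)`` over the limits.
    """
    limits = limits or LimitSet()
    limits.validate()
    pairs = {"head_avg": limits.head_avg_W_kg, "psSAR10g": limits.psSAR10g_W_kg}
    if limits.whole_body_W_kg is not None:
        pairs["whole_body_avg"] = limits.whole_body_W_kg
    allowed = {}
    for name, lim in pairs.items():
        if name not in sar_per_watt:
            continue
        s = sar_per_watt[name]
        if s <= 0:
            raise ZeroDivisionError(f"normalized SAR for {name!r} is {s}")
        allowed[name] = lim / s
    if not allowed:
        raise ValueError("no usable normalized SAR values supplied")
    binding = min(allowed, key=allowed.get)
    return allowed[binding], binding


def check_thermal(series: pd.DataFrame, limits: LimitSet | None = None,
                  T_core_baseline: float | None = None) -> dict[str, float | None]:
    """First crossing times of the thermal limits in a summary series.

    ``series`` needs columns ``t_s``, ``T_core_C`` and ``T_max_C``.
    The core-rise baseline defaults to the core temperature at RF onset
    (the first row).  Crossings are located by linear interpolation
    between samples; ``None`` when a limit is never exceeded.
    """
    limits = limits or LimitSet()
    if series.empty:
        raise ValueError("empty thermal series")
    t = series["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("series must be strictly increasing in time")
    baseline = (T_core_baseline if T_core_baseline is not None
                else float(series["T_core_C"].iloc[0]))

    def first_crossing(values: np.ndarray, threshold: float) -> float | None:
        above = values > threshold
        if not above.any():
            return None
        i = int(np.argmax(above))
        if i == 0:
            return float(t[0])
        # linear interpolation between samples i-1 and i
        v0, v1 = values[i - 1], values[i]
        frac = (threshold - v0) / (v1 - v0)
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    rise = series["T_core_C"].to_numpy(dtype=float) - baseline
    return {
        "core_rise_s": first_crossing(rise, limits.core_rise_C),
        "absolute_T_s": first_crossing(series["T_max_C"].to_numpy(dtype=float),
                                       limits.absolute_T_C),
    }


def h_sensitivity(
    model,
    table,
    config: ThermalConfig,
    sar: np.ndarray,
    sar_scale: float = 1.0,
    deltas: tuple[float, ...] = (-0.20, -0.10, 0.0, 0.10, 0.20),
    limits: LimitSet | None = None,
    state0=None,
) -> pd.DataFrame:
    """Repeat the exposure run over perturbed heat-transfer coefficients.

    Each row reports the h used, the limit-crossing times and the final
    core/max temperatures.  The equilibration state is shared across h
    values (the conditioning protocol fixes its own h), so the sweep
    isolates the exposure-phase sensitivity.
    """
    limits = limits or LimitSet()
    if state0 is None:
        state0 = equilibrate(model, table, config)
    rows = []
    for d in deltas:
        cfg = replace(config, h_W_m2K=config.h_W_m2K * (1.0 + d))
        series, final = run_exposure(state0, model, table, cfg, sar, sar_scale)
        crossings = check_thermal(series, limits)
        rows.append({
            "delta": d,
            "h_W_m2K": cfg.h_W_m2K,
            "core_rise_crossing_s": crossings["core_rise_s"],
            "absolute_T_crossing_s": crossings["absolute_T_s"],
            "final_T_core_C": series["T_core_C"].iloc[-1],
            "final_T_max_C": series["T_max_C"].iloc[-1],
            "final_T_blood_C": series["T_blood_C"].iloc[-1],
        })
    return pd.DataFrame(rows)
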