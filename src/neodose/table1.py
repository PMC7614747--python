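"""Published EM-simulation summary fixture for worked-example arithmetic.

Full-wave EM simulation of the birdcage coil on the MRI-derived models
is out of scope here, but the published per-model summary numbers (power
budget fractions, B1+ efficiency, SAR normalized per input power and per
mean squared B1+ in the central axial slice) support a set of derived
compliance quantities — allowed drive power, SAR at the head-average
limit, neonate/adult exposure ratios — that this package recomputes
through its normalization and compliance operations.

Models: ``neonate_a`` (term neonate, 13-tissue segmentation),
``neonate_b`` (scaled 8-week model, 31 tissues, plus a simplified
13-class variant) and ``duke`` (adult male).  Property sets: ``adult``
dielectric properties, ``neonatal`` age-adjusted properties, and for
neonate B ``adult_simplified``.

For neonate A with neonatal properties the global psSAR10g sits outside
the head (in the hand near the face); ``psSAR10g_head`` carries the
in-head maximum for that case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["table1_fixture", "table1_dataframe", "MODELS", "PROPERTY_SETS"]

MODELS = ("neonate_a", "neonate_b", "duke")
PROPERTY_SETS = {
    "neonate_a": ("adult", "neonatal"),
    "neonate_b": ("adult", "adult_simplified", "neonatal"),
    "duke": ("adult",),
}

_COLUMNS = (
    "reflected_pct", "absorbed_pct", "b1_efficiency_uT_per_sqrtW", "b1_cov",
    "head_avg_per_W", "whole_body_avg_per_W", "psSAR10g_per_W",
    "head_avg_per_B1sq", "whole_body_avg_per_B1sq", "psSAR10g_per_B1sq",
)

_DATA = {
    ("neonate_a", "adult"): dict(
        reflected_pct=13, absorbed_pct=58,
        b1_efficiency_uT_per_sqrtW=0.61, b1_cov=0.23,
        head_avg_per_W=0.41, whole_body_avg_per_W=0.17, psSAR10g_per_W=0.95,
        head_avg_per_B1sq=1.12, whole_body_avg_per_B1sq=0.45,
        psSAR10g_per_B1sq=2.58,
    ),
    ("neonate_a", "neonatal"): dict(
        reflected_pct=11, absorbed_pct=59,
        b1_efficiency_uT_per_sqrtW=0.53, b1_cov=0.17,
        head_avg_per_W=0.40, whole_body_avg_per_W=0.16, psSAR10g_per_W=1.10,
        psSAR10g_head_per_W=0.92,
        head_avg_per_B1sq=1.39, whole_body_avg_per_B1sq=0.57,
        psSAR10g_per_B1sq=3.84, psSAR10g_head_per_B1sq=3.21,
    ),
    ("neonate_b", "adult"): dict(
        reflected_pct=17, absorbed_pct=47,
        b1_efficiency_uT_per_sqrtW=0.62, b1_cov=0.22,
        head_avg_per_W=0.32, whole_body_avg_per_W=0.13, psSAR10g_per_W=0.94,
        head_avg_per_B1sq=0.81, whole_body_avg_per_B1sq=0.35,
        psSAR10g_per_B1sq=2.41,
    ),
    ("neonate_b", "adult_simplified"): dict(
        reflected_pct=17, absorbed_pct=47,
        b1_efficiency_uT_per_sqrtW=0.61, b1_cov=0.22,
        head_avg_per_W=0.31, whole_body_avg_per_W=0.13, psSAR10g_per_W=0.91,
        head_avg_per_B1sq=0.83, whole_body_avg_per_B1sq=0.35,
        psSAR10g_per_B1sq=2.41,
    ),
    ("neonate_b", "neonatal"): dict(
        reflected_pct=16, absorbed_pct=52,
        b1_efficiency_uT_per_sqrtW=0.53, b1_cov=0.16,
        head_avg_per_W=0.35, whole_body_avg_per_W=0.15, psSAR10g_per_W=1.08,
        head_avg_per_B1sq=1.21, whole_body_avg_per_B1sq=0.51,
        psSAR10g_per_B1sq=3.78,
    ),
    ("duke", "adult"): dict(
        reflected_pct=0.4, absorbed_pct=88,
        b1_efficiency_uT_per_sqrtW=0.47, b1_cov=0.19,
        head_avg_per_W=0.15, whole_body_avg_per_W=0.01, psSAR10g_per_W=0.45,
        head_avg_per_B1sq=0.69, whole_body_avg_per_B1sq=0.05,
        psSAR10g_per_B1sq=2.05,
    ),
}


def table1_fixture() -> dict:
    """Nested ``{model: {property_set: {column: value}}}`` fixture."""
    out: dict = {m: {} for m in MODELS}
    for (model, props), vals in _DATA.items():
        out[model][props] = dict(vals)
    return out


def table1_dataframe() -> pd.DataFrame:
    rows = []
    for (model, props), vals in _DATA.items():
        rows.append({"model": model, "properties": props, **vals})
    return pd.DataFrame(rows)


def check_complete() -> list[str]:
    """Names of any missing (model, property set, column) entries."""
    missing = []
    fx = table1_fixture()
    for model, psets in PROPERTY_SETS.items():
        for ps in psets:
            entry = fx.get(model, {}).get(ps)
            if entry is None:
                missing.append(f"{model}/{ps}")
                continue
            for col in _COLUMNS:
                if col not in entry or not np.isfinite(entry[col]):
                    missing.append(f"{model}/{ps}/{col}")
    return missing
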