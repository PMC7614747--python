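"""Synthetic neonate-like voxel phantoms.

The analysis operates on labeled voxel grids.  Real segmented neonate
models are MRI-derived and cannot be reconstructed from published
numbers, so this module generates *synthetic* stand-ins from nested
ellipsoids: a spherical head (skin / fat / skull / CSF / brain shells),
an ellipsoidal torso with interior organs (heart wall with a blood
core, lungs, liver, stomach, a bony spine in a connective-tissue
sheath, sternum cartilage), four limb ellipsoids, and optionally a
small "hand near the face" feature.  Body-part sizes are rescaled by a
single factor so the phantom hits a target mass (default 3.50 kg, a
term birth weight) while the head keeps a prescribed volume (default
1030 mL).

Coordinate convention (used everywhere in the package): 0-based voxel
indices with axis order (x = left-right, y = anterior-posterior,
z = inferior-superior); world coordinates in mm are ``index *
voxel_size`` measured from the grid corner, and voxel centers sit at
``(index + 0.5) * voxel_size``.  The face points toward -y.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .tissue_db import TissueTable, load_adult_table

logger = logging.getLogger(__name__)

__all__ = [
    "Ellipsoid",
    "BodyPart",
    "Organ",
    "PhantomSpec",
    "VoxelModel",
    "GeometryError",
    "default_neonate_spec",
    "sphere_spec",
    "slab_spec",
    "generate_phantom",
    "add_blanket",
    "define_core_mask",
    "shift_model",
    "read_model",
    "write_model",
]

#: reserved label for the insulating blanket shell (not body tissue)
BLANKET_LABEL = 99

#: canonical tissue order used for label assignment (1-based)
TISSUE_ORDER = [
    "skin", "fat", "muscle", "bone", "csf", "brain", "blood", "heart",
    "lung", "liver", "stomach", "cartilage", "connective",
]


class GeometryError(ValueError):
    """A requested shape does not fit the voxel grid (or is degenerate)."""


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def scaled(self, s: float) -> "Ellipsoid":
        return Ellipsoid(self.center_mm, tuple(a * s for a in self.semiaxes_mm))


@dataclass(frozen=True)
class BodyPart:
    """Ellipsoid with concentric tissue layers.

    ``layers`` lists (tissue, inner_fraction) pairs from the outside in;
    a layer occupies normalized radii (inner_fraction, previous_inner].
    The innermost layer should end at 0.
    """

    name: str
    shape: Ellipsoid
    layers: tuple[tuple[str, float], ...]
    scalable: bool = True
    #: False allows shapes that deliberately overfill the grid (slabs)
    check_fit: bool = True


@dataclass(frozen=True)
class Organ:
    tissue: str
    shape: Ellipsoid


@dataclass
class PhantomSpec:
    """Everything needed to rasterize a phantom deterministically."""

    #: None disables mass calibration (analytic shapes)
    target_mass_kg: float | None = 3.50
    grid_shape: tuple[int, int, int] = (96, 96, 144)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    parts: tuple[BodyPart, ...] = ()
    organs: tuple[Organ, ...] = ()
    head_part: str = "head"
    face_center_mm: tuple[float, float, float] | None = None
    face_radius_mm: float = 45.0
    seed: int = 0
    organ_jitter_mm: float = 0.5
    mass_rtol: float = 0.002
    #: relabel exterior-surface voxels as skin (off for single-tissue
    #: analytic phantoms, where it would perturb the physics)
    force_skin_shell: bool = True

    def validate(self) -> None:
        if self.target_mass_kg is not None and self.target_mass_kg <= 0:
            raise ValueError("target_mass_kg must be > 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be > 0")
        if not self.parts:
            raise GeometryError("spec has no body parts")
        for p in self.parts:
            if min(p.shape.semiaxes_mm) <= 0:
                raise GeometryError(f"part {p.name!r} has a zero-size ellipsoid")


@dataclass
class VoxelModel:
    """Labeled 3D tissue grid plus the masks the analysis needs."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    tissue_names: dict[int, str]
    density: dict[int, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    reference_slice: int | None = None
    meta: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------
    @property
    def voxel_volume_m3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz * 1e-9

    def label_for(self, tissue: str) -> int:
        for lab, name in self.tissue_names.items():
            if name == tissue:
                return lab
        raise KeyError(f"tissue {tissue!r} not present in model")

    def density_grid(self) -> np.ndarray:
        """Per-voxel density in kg/m^3 (0 in air)."""
        out = np.zeros(self.labels.shape, dtype=float)
        for lab in np.unique(self.labels):
            if lab == 0:
                continue
            out[self.labels == lab] = self.density[int(lab)]
        return out

    def total_mass_kg(self, include_blanket: bool = False) -> float:
        mask = self.labels > 0
        if not include_blanket:
            mask &= self.labels != BLANKET_LABEL
        rho = self.density_grid()
        return float(rho[mask].sum() * self.voxel_volume_m3)

    def recompute_basic_masks(self) -> None:
        self.masks["whole_body"] = (self.labels > 0) & (self.labels != BLANKET_LABEL)
        self.masks["blanket"] = self.labels == BLANKET_LABEL
        skin_labels = [l for l, n in self.tissue_names.items() if n == "skin"]
        self.masks["skin"] = np.isin(self.labels, skin_labels)

    def validate(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        for lab in present:
            lab = int(lab)
            if lab not in self.tissue_names:
                raise ValueError(f"label {lab} present in grid but not in tissue map")
            if lab not in self.density:
                raise ValueError(f"label {lab} has no density entry")
        for name, m in self.masks.items():
            if m.shape != self.labels.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
        if "whole_body" in self.masks and "blanket" in self.masks:
            if np.any(self.masks["whole_body"] & self.masks["blanket"]):
                raise ValueError("blanket mask overlaps body tissue")
        m = self.total_mass_kg()
        if not np.isfinite(m) or m <= 0:
            raise ValueError("total tissue mass must be finite and > 0")

    def copy(self) -> "VoxelModel":
        return VoxelModel(
            labels=self.labels.copy(),
            voxel_size=tuple(self.voxel_size),
            tissue_names=dict(self.tissue_names),
            density=dict(self.density),
            masks={k: v.copy() for k, v in self.masks.items()},
            reference_slice=self.reference_slice,
            meta=json.loads(json.dumps(self.meta)),
        )


# ---------------------------------------------------------------------------
# spec factories
# ---------------------------------------------------------------------------

def default_neonate_spec(
    target_mass_kg: float = 3.50,
    head_volume_ml: float = 1030.0,
    seed: int = 0,
    hand_near_face: bool = True,
) -> PhantomSpec:
    """Term-neonate layout: head volume and body mass are the calibrated
    quantities; everything else is plausible-but-invented geometry."""
    r_head = (3.0 * head_volume_ml * 1e3 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    cx, cy = 96.0, 96.0
    z_head = 225.0
    head = BodyPart(
        "head",
        Ellipsoid((cx, cy, z_head), (r_head, r_head, r_head)),
        (("skin", 0.965), ("fat", 0.93), ("bone", 0.87), ("csf", 0.80), ("brain", 0.0)),
        scalable=False,
    )
    torso = BodyPart(
        "torso",
        Ellipsoid((cx, cy, 114.0), (72.0, 62.0, 104.0)),
        (("skin", 0.96), ("fat", 0.88), ("muscle", 0.0)),
    )
    arm_l = BodyPart(
        "arm_l", Ellipsoid((30.0, cy, 132.0), (20.0, 20.0, 70.0)),
        (("skin", 0.90), ("fat", 0.75), ("muscle", 0.30), ("bone", 0.0)),
    )
    arm_r = BodyPart(
        "arm_r", Ellipsoid((162.0, cy, 132.0), (20.0, 20.0, 70.0)),
        (("skin", 0.90), ("fat", 0.75), ("muscle", 0.30), ("bone", 0.0)),
    )
    leg_l = BodyPart(
        "leg_l", Ellipsoid((62.0, cy, 46.0), (27.0, 27.0, 40.0)),
        (("skin", 0.92), ("fat", 0.78), ("muscle", 0.30), ("bone", 0.0)),
    )
    leg_r = BodyPart(
        "leg_r", Ellipsoid((130.0, cy, 46.0), (27.0, 27.0, 40.0)),
        (("skin", 0.92), ("fat", 0.78), ("muscle", 0.30), ("bone", 0.0)),
    )
    parts = [torso, arm_l, arm_r, leg_l, leg_r, head]
    if hand_near_face:
        parts.append(
            BodyPart(
                "hand",
                Ellipsoid((cx, 28.0, 210.0), (14.0, 10.0, 18.0)),
                (("skin", 0.80), ("muscle", 0.35), ("bone", 0.0)),
                scalable=False,
            )
        )
    organs = (
        Organ("connective", Ellipsoid((cx, 120.0, 112.0), (12.0, 12.0, 95.0))),
        Organ("bone", Ellipsoid((cx, 120.0, 112.0), (7.0, 7.0, 95.0))),
        Organ("lung", Ellipsoid((72.0, 92.0, 152.0), (18.0, 16.0, 28.0))),
        Organ("lung", Ellipsoid((120.0, 92.0, 152.0), (18.0, 16.0, 28.0))),
        Organ("heart", Ellipsoid((cx, 90.0, 150.0), (22.0, 20.0, 24.0))),
        Organ("blood", Ellipsoid((cx, 90.0, 150.0), (13.0, 12.0, 14.5))),
        Organ("liver", Ellipsoid((cx, 100.0, 118.0), (34.0, 26.0, 20.0))),
        Organ("stomach", Ellipsoid((80.0, 100.0, 96.0), (16.0, 14.0, 16.0))),
        Organ("cartilage", Ellipsoid((cx, 76.0, 150.0), (6.0, 6.0, 28.0))),
    )
    face_center = (cx, cy - r_head, z_head)
    return PhantomSpec(
        target_mass_kg=target_mass_kg,
        parts=tuple(parts),
        organs=organs,
        face_center_mm=face_center,
        seed=seed,
    )


def sphere_spec(
    radius_mm: float = 50.0,
    voxel_size_mm: float = 1.0,
    tissue: str = "muscle",
    margin_mm: float = 6.0,
    target_mass_kg: float | None = None,
) -> PhantomSpec:
    """Single homogeneous sphere — the workhorse for analytic checks."""
    n = int(np.ceil(2 * (radius_mm + margin_mm) / voxel_size_mm))
    c = n * voxel_size_mm / 2.0
    part = BodyPart(
        "sphere", Ellipsoid((c, c, c), (radius_mm,) * 3), ((tissue, 0.0),),
        scalable=target_mass_kg is not None,
    )
    return PhantomSpec(
        target_mass_kg=target_mass_kg,
        grid_shape=(n, n, n),
        voxel_size_mm=(voxel_size_mm,) * 3,
        parts=(part,),
        head_part="sphere",
        face_center_mm=(c, c - radius_mm, c),
        organ_jitter_mm=0.0,
        force_skin_shell=False,
    )


def slab_spec(
    nx: int, ny: int = 5, nz: int = 5, voxel_size_mm: float = 2.0,
    tissue: str = "muscle",
) -> PhantomSpec:
    """Full-grid slab (no air inside the grid along y/z): used for 1D
    conduction tests.  Rasterized as an oversized ellipsoid covering the
    whole grid."""
    dx = voxel_size_mm
    big = 1e6
    part = BodyPart(
        "slab",
        Ellipsoid((nx * dx / 2, ny * dx / 2, nz * dx / 2), (nx * dx / 2, big, big)),
        ((tissue, 0.0),),
        scalable=False,
        check_fit=False,
    )
    spec = PhantomSpec(
        target_mass_kg=None,
        grid_shape=(nx, ny, nz),
        voxel_size_mm=(dx,) * 3,
        parts=(part,),
        head_part="slab",
        organ_jitter_mm=0.0,
        force_skin_shell=False,
    )
    return spec


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _voxel_centers(shape, voxel_size):
    axes = [
        (np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _norm_radius_sq(coords, ell: Ellipsoid):
    x, y, z = coords
    cx, cy, cz = ell.center_mm
    ax, ay, az = ell.semiaxes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


def _check_fits(ell: Ellipsoid, shape, voxel_size, name: str, slack_mm: float = 0.0):
    for a in range(3):
        lo = ell.center_mm[a] - ell.semiaxes_mm[a]
        hi = ell.center_mm[a] + ell.semiaxes_mm[a]
        if lo < -slack_mm or hi > shape[a] * voxel_size[a] + slack_mm:
            raise GeometryError(
                f"{name!r} extends outside the grid along axis {a} "
                f"([{lo:.1f}, {hi:.1f}] mm vs [0, {shape[a] * voxel_size[a]:.1f}])"
            )


def _rasterize(spec: PhantomSpec, scale: float, densities: dict[str, float],
               jitter: dict[int, np.ndarray], check: bool) -> np.ndarray:
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    coords = _voxel_centers(spec.grid_shape, spec.voxel_size_mm)
    name_to_label = {t: i + 1 for i, t in enumerate(TISSUE_ORDER)}

    for part in spec.parts:
        ell = part.shape.scaled(scale) if part.scalable else part.shape
        if check and part.check_fit:
            _check_fits(ell, spec.grid_shape, spec.voxel_size_mm, part.name,
                        slack_mm=max(spec.voxel_size_mm))
        r2 = _norm_radius_sq(coords, ell)
        outer = 1.0
        for tissue, inner in part.layers:
            band = (r2 <= outer ** 2) & (r2 > inner ** 2) if inner > 0 else (r2 <= outer ** 2)
            labels[band] = name_to_label[tissue]
            outer = inner

    body = labels > 0
    for i, organ in enumerate(spec.organs):
        ell = organ.shape
        if i in jitter:
            ell = Ellipsoid(tuple(np.asarray(ell.center_mm) + jitter[i]),
                            ell.semiaxes_mm)
        r2 = _norm_radius_sq(coords, ell)
        inside = (r2 <= 1.0) & body  # organs never extend past the body surface
        labels[inside] = name_to_label[organ.tissue]

    if spec.force_skin_shell:
        # contiguous exterior skin shell: any body voxel on the surface -> skin
        body = labels > 0
        exterior = body & ~ndimage.binary_erosion(body)
        labels[exterior] = name_to_label["skin"]
    return labels


def generate_phantom(spec: PhantomSpec, table: TissueTable | None = None) -> VoxelModel:
    """Rasterize a :class:`PhantomSpec` into a :class:`VoxelModel`.

    If ``spec.target_mass_kg`` > 0, the scalable body parts are rescaled
    (single factor, bisection) until the total tissue mass matches the
    target; the head part is never rescaled so its volume stays at the
    specified value.
    """
    spec.validate()
    if table is None:
        table = load_adult_table()
    densities = {t: table.density(t) for t in TISSUE_ORDER}
    name_to_label = {t: i + 1 for i, t in enumerate(TISSUE_ORDER)}
    dens_by_label = {name_to_label[t]: densities[t] for t in TISSUE_ORDER}
    vox_m3 = float(np.prod(spec.voxel_size_mm)) * 1e-9

    rng = np.random.default_rng(spec.seed)
    jitter = {}
    if spec.organ_jitter_mm > 0:
        for i in range(len(spec.organs)):
            jitter[i] = rng.uniform(-spec.organ_jitter_mm, spec.organ_jitter_mm, 3)

    def mass_of(labels):
        rho = np.zeros(labels.shape)
        for lab, d in dens_by_label.items():
            rho[labels == lab] = d
        return float(rho.sum() * vox_m3)

    if spec.target_mass_kg is not None and any(p.scalable for p in spec.parts):
        # feasible upper scale from bounding boxes of scalable parts
        s_hi = np.inf
        for p in spec.parts:
            if not p.scalable:
                continue
            for a in range(3):
                c, ax = p.shape.center_mm[a], p.shape.semiaxes_mm[a]
                lim = spec.grid_shape[a] * spec.voxel_size_mm[a]
                s_hi = min(s_hi, c / ax if ax else np.inf, (lim - c) / ax if ax else np.inf)
        s_lo = 0.5
        s_hi = min(s_hi, 1.6)
        if s_hi <= s_lo:
            raise GeometryError("grid too small for the requested body parts")
        m_hi = mass_of(_rasterize(spec, s_hi, densities, jitter, check=False))
        if m_hi < spec.target_mass_kg * (1 - 0.05):
            raise GeometryError(
                f"target mass {spec.target_mass_kg} kg unreachable within the grid "
                f"(max {m_hi:.2f} kg)"
            )
        scale = 1.0
        for _ in range(40):
            labels = _rasterize(spec, scale, densities, jitter, check=False)
            m = mass_of(labels)
            if abs(m - spec.target_mass_kg) <= spec.mass_rtol * spec.target_mass_kg:
                break
            if m < spec.target_mass_kg:
                s_lo = scale
            else:
                s_hi = scale
            scale = 0.5 * (s_lo + s_hi)
        labels = _rasterize(spec, scale, densities, jitter, check=True)
    else:
        scale = 1.0
        labels = _rasterize(spec, scale, densities, jitter, check=True)

    present = set(int(v) for v in np.unique(labels)) - {0}
    tissue_names = {lab: t for t, lab in name_to_label.items() if lab in present}
    density = {lab: dens_by_label[lab] for lab in present}

    model = VoxelModel(
        labels=labels,
        voxel_size=tuple(spec.voxel_size_mm),
        tissue_names=tissue_names,
        density=density,
        meta={
            "body_scale": float(scale),
            "face_center_mm": list(spec.face_center_mm) if spec.face_center_mm else None,
            "face_radius_mm": float(spec.face_radius_mm),
            "seed": int(spec.seed),
        },
    )
    model.recompute_basic_masks()

    # head mask: voxels of the head part's ellipsoid that contain tissue
    head_parts = [p for p in spec.parts if p.name == spec.head_part]
    if head_parts:
        ell = head_parts[0].shape if not head_parts[0].scalable else head_parts[0].shape.scaled(scale)
        coords = _voxel_centers(spec.grid_shape, spec.voxel_size_mm)
        model.masks["head"] = (_norm_radius_sq(coords, ell) <= 1.0) & model.masks["whole_body"]
        model.meta["head_center_mm"] = list(ell.center_mm)
        # central axial slice through the head center
        model.reference_slice = int(ell.center_mm[2] / spec.voxel_size_mm[2])
        model.reference_slice = min(model.reference_slice, spec.grid_shape[2] - 1)
    try:
        model.masks["core"] = define_core_mask(model)
    except KeyError:
        pass  # analytic phantoms without heart/brain labels
    model.validate()
    if spec.target_mass_kg is not None:
        m = model.total_mass_kg()
        if abs(m - spec.target_mass_kg) > 0.05 * spec.target_mass_kg:
            raise GeometryError(
                f"calibrated mass {m:.3f} kg misses target {spec.target_mass_kg} kg by >5%"
            )
    return model


# ---------------------------------------------------------------------------
# blanket / core / shift
# ---------------------------------------------------------------------------

def add_blanket(
    model: VoxelModel,
    thickness_mm: float,
    face_aperture: tuple[tuple[float, float, float], float] | None | str = "auto",
) -> VoxelModel:
    """Wrap the body in an insulating shell, leaving the face uncovered.

    The shell is every air voxel within ``thickness_mm`` (Euclidean
    distance, anisotropic voxels respected) of the body surface, so it
    follows the skin at the given thickness.  ``face_aperture`` is
    ``(center_mm, radius_mm)``; voxels of the would-be blanket within
    that sphere are left open.  ``"auto"`` uses the face center recorded
    by the generator; ``None`` covers everything.
    """
    if thickness_mm == 0:
        return model.copy()
    n = int(round(thickness_mm / min(model.voxel_size)))
    if n < 1:
        raise ValueError(
            f"blanket thickness {thickness_mm} mm is below one voxel "
            f"({min(model.voxel_size)} mm)"
        )
    if face_aperture == "auto":
        fc = model.meta.get("face_center_mm")
        face_aperture = (tuple(fc), model.meta.get("face_radius_mm", 45.0)) if fc else None

    out = model.copy()
    body = out.labels > 0
    dist = ndimage.distance_transform_edt(~body, sampling=out.voxel_size)
    shell = (dist <= thickness_mm + 1e-9) & ~body
    if face_aperture is not None:
        (cx, cy, cz), radius = face_aperture
        coords = _voxel_centers(out.labels.shape, out.voxel_size)
        d2 = ((coords[0] - cx) ** 2 + (coords[1] - cy) ** 2 + (coords[2] - cz) ** 2)
        shell &= ~(d2 <= radius ** 2)
    out.labels[shell] = BLANKET_LABEL
    out.tissue_names[BLANKET_LABEL] = "blanket"
    out.density[BLANKET_LABEL] = 150.0  # wool; excluded from body mass
    out.recompute_basic_masks()
    out.meta["blanket_thickness_mm"] = float(thickness_mm)
    out.validate()
    return out


def define_core_mask(model: VoxelModel) -> np.ndarray:
    """Interior (1-voxel eroded) heart+blood and brain voxels.

    Erosion removes boundary voxels so the core average is not biased by
    partial-volume surfaces; a compartment that erodes to nothing (e.g.
    a single-voxel heart) falls back to its un-eroded voxels.
    """
    groups = {"heart": ("heart", "blood"), "brain": ("brain",)}
    missing = [
        "/".join(tissues) for tissues in groups.values()
        if not any(n in tissues for n in model.tissue_names.values())
    ]
    if missing:
        raise KeyError(
            f"model has no {', '.join(missing)} labels (needed for the core mask)")
    core = np.zeros(model.labels.shape, dtype=bool)
    for gname, tissues in groups.items():
        labs = [l for l, n in model.tissue_names.items() if n in tissues]
        m = np.isin(model.labels, labs)
        eroded = ndimage.binary_erosion(m)
        core |= eroded if eroded.any() else m
    return core


def shift_model(model: VoxelModel, shift_mm) -> VoxelModel:
    """Translate the model (labels, masks, reference slice) on the grid.

    Shifts are quantized to whole voxels; the sub-voxel residual is
    recorded in ``meta['shift_residual_mm']`` and logged.  Voxels
    translated outside the grid are dropped with a warning.
    """
    shift_mm = np.asarray(shift_mm, dtype=float)
    vox = np.asarray(model.voxel_size, dtype=float)
    shift_vox = np.round(shift_mm / vox).astype(int)
    residual = shift_mm - shift_vox * vox
    if np.any(np.abs(shift_vox) >= np.asarray(model.labels.shape)):
        raise ValueError(f"shift {shift_mm} mm exceeds the grid extent")
    if np.any(np.abs(residual) > 1e-9):
        logger.warning("shift quantized to %s voxels; residual %s mm",
                       shift_vox.tolist(), np.round(residual, 3).tolist())

    def translate(arr):
        out = np.zeros_like(arr)
        src = [slice(max(0, -s), arr.shape[a] - max(0, s)) for a, s in enumerate(shift_vox)]
        dst = [slice(max(0, s), arr.shape[a] - max(0, -s)) for a, s in enumerate(shift_vox)]
        out[tuple(dst)] = arr[tuple(src)]
        return out

    out = model.copy()
    n_before = int((model.labels > 0).sum())
    out.labels = translate(model.labels)
    n_after = int((out.labels > 0).sum())
    if n_after < n_before:
        logger.warning("shift clipped %d voxels at the grid boundary", n_before - n_after)
    out.masks = {k: translate(v) for k, v in model.masks.items()}
    if model.reference_slice is not None:
        out.reference_slice = int(model.reference_slice + shift_vox[2])
        if not (0 <= out.reference_slice < model.labels.shape[2]):
            raise ValueError("reference slice shifted outside the grid")
    out.meta["shift_residual_mm"] = residual.tolist()
    for key in ("face_center_mm", "head_center_mm"):
        if out.meta.get(key):
            out.meta[key] = (np.asarray(out.meta[key]) + shift_vox * vox).tolist()
    return out


# ---------------------------------------------------------------------------
# I/O: NIfTI label volume + JSON sidecar (+ one NIfTI per mask)
# ---------------------------------------------------------------------------

def write_model(model: VoxelModel, path) -> None:
    """Write ``labels.nii.gz``, per-mask NIfTIs and ``model.json`` to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(model.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(model.labels.astype(np.int16), affine),
             path / "labels.nii.gz")
    for name, m in model.masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                 path / f"mask_{name}.nii.gz")
    sidecar = {
        "voxel_size_mm": list(model.voxel_size),
        "tissue_names": {str(k): v for k, v in model.tissue_names.items()},
        "density_kg_m3": {str(k): v for k, v in model.density.items()},
        "masks": sorted(model.masks),
        "reference_slice": model.reference_slice,
        "meta": model.meta,
        "axes": "x=left-right, y=anterior-posterior, z=inferior-superior; "
                "world = index * voxel_size from grid corner",
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2))


def read_model(path) -> VoxelModel:
    """Inverse of :func:`write_model`; recomputes missing basic masks.

    Raises a validation error when the grid contains a label absent from
    the sidecar tissue/density maps.
    """
    path = Path(path)
    sidecar = json.loads((path / "model.json").read_text())
    img = nib.load(path / "labels.nii.gz")
    labels = np.asarray(img.dataobj).astype(np.int16)
    tissue_names = {int(k): v for k, v in sidecar["tissue_names"].items()}
    density = {int(k): float(v) for k, v in sidecar["density_kg_m3"].items()}
    masks = {}
    for name in sidecar.get("masks", []):
        p = path / f"mask_{name}.nii.gz"
        if p.exists():
            masks[name] = np.asarray(nib.load(p).dataobj).astype(bool)
    model = VoxelModel(
        labels=labels,
        voxel_size=tuple(float(v) for v in sidecar["voxel_size_mm"]),
        tissue_names=tissue_names,
        density=density,
        masks=masks,
        reference_slice=sidecar.get("reference_slice"),
        meta=sidecar.get("meta", {}),
    )
    if not {"whole_body", "blanket", "skin"} <= set(masks):
        model.recompute_basic_masks()
    if "core" not in model.masks:
        try:
            model.masks["core"] = define_core_mask(model)
        except KeyError:
            pass
    model.validate()
    return model
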