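"""Slice→atlas registration: AP search, rigid fit, elastic refinement.

Coordinate conventions
----------------------
Slice pixels are addressed ``(x, y)`` with ``x`` the column (ML-like axis)
and ``y`` the row (DV-like axis); the physical position of pixel ``(x, y)``
is its center, ``((x + 0.5) * pixel_size_um, (y + 0.5) * pixel_size_um)``.
The atlas section plane is addressed in physical µm ``(dv_um, ml_um)``.

The full transform of a slice point into the atlas, applied in this fixed
order, is::

    hflip  →  center  →  rotate(θ)  →  scale(s)  →  translate(+t, +plane center)
           →  elastic displacement  →  embed at ap_um

Rotation is about the slice center; translation is expressed in atlas-plane
µm relative to the plane center, so a zero transform maps the slice center
onto the section center.  Region lookup is nearest-voxel:
``floor(coord / spacing)`` per axis, background (0) outside the volume.

Tie-breaking in all searches is toward the smaller parameter value (and
``hflip=False``); all estimators are deterministic given their inputs and
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import RBFInterpolator
from skimage.filters import gaussian, threshold_otsu
from skimage.metrics import normalized_mutual_information
from skimage.transform import resize

from .atlas import Atlas, ap_index, atlas_section

logger = logging.getLogger(__name__)

__all__ = [
    "SliceImage",
    "RigidParams",
    "Deformation",
    "SliceRegistration",
    "similarity",
    "estimate_ap",
    "fit_rigid",
    "refine_elastic",
    "register_slice",
    "transform_points",
    "transform_point",
    "inverse_transform_points",
    "read_slice_tiff",
    "write_slice_tiff",
]


@dataclass
class SliceImage:
    """One multi-channel coronal slice image with its metadata."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    subject_id: str = ""
    condition: str = ""
    slice_id: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ValueError("SliceImage needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str | None = None) -> np.ndarray:
        if name is None:
            name = next(iter(self.channels))
        return self.channels[name]


@dataclass
class RigidParams:
    """In-plane rigid/similarity parameters plus the AP position."""

    ap_um: float
    rotation_deg: float = 0.0
    scale: float = 1.0
    tx_um: float = 0.0
    ty_um: float = 0.0
    hflip: bool = False

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation_deg must lie in (-180, 180]")


@dataclass
class Deformation:
    """Thin-plate-spline displacement field over the atlas section plane.

    Control points lie on a regular ``grid_shape`` grid spanning
    ``[0, plane_extent_um]`` per axis; ``displacements_um`` holds one
    ``(d_dv, d_ml)`` vector per control point.  Zero displacements encode
    the identity map exactly; displacement magnitudes are bounded by
    ``cap_um``.
    """

    grid_shape: tuple[int, int]
    plane_extent_um: tuple[float, float]
    displacements_um: np.ndarray | None = None
    cap_um: float = 500.0

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ValueError("deformation grid must be at least 2x2")
        if self.displacements_um is None:
            self.displacements_um = np.zeros((rows, cols, 2))
        self.displacements_um = np.asarray(self.displacements_um, dtype=float)
        if self.displacements_um.shape != (rows, cols, 2):
            raise ValueError(
                f"displacements must have shape {(rows, cols, 2)}, "
                f"got {self.displacements_um.shape}"
            )
        mags = np.linalg.norm(self.displacements_um, axis=-1)
        if np.any(mags > self.cap_um + 1e-9):
            raise ValueError(
                f"control-point displacement {mags.max():.1f} µm exceeds cap {self.cap_um} µm"
            )

    @property
    def is_identity(self) -> bool:
        return not np.any(self.displacements_um)

    def control_points(self) -> np.ndarray:
        rows, cols = self.grid_shape
        dv = np.linspace(0.0, self.plane_extent_um[0], rows)
        ml = np.linspace(0.0, self.plane_extent_um[1], cols)
        g = np.stack(np.meshgrid(dv, ml, indexing="ij"), axis=-1)
        return g.reshape(-1, 2)

    def displace(self, points_um: np.ndarray) -> np.ndarray:
        """TPS-interpolated displacement at ``(dv_um, ml_um)`` points."""
        points_um = np.atleast_2d(points_um)
        if self.is_identity:
            return np.zeros_like(points_um, dtype=float)
        interp = RBFInterpolator(
            self.control_points(),
            self.displacements_um.reshape(-1, 2),
            kernel="thin_plate_spline",
        )
        return interp(points_um)


@dataclass
class SliceRegistration:
    """The complete transform of one slice into the atlas."""

    rigid: RigidParams
    deformation: Deformation
    atlas_name: str = ""
    provenance: dict = field(default_factory=lambda: {"method": "manual", "score": None})

    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "atlas_name": self.atlas_name,
            "rigid": asdict(self.rigid),
            "deformation": {
                "grid_shape": list(self.deformation.grid_shape),
                "plane_extent_um": list(self.deformation.plane_extent_um),
                "displacements_um": self.deformation.displacements_um.tolist(),
                "cap_um": self.deformation.cap_um,
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SliceRegistration":
        rigid = RigidParams(**d["rigid"])
        dd = d["deformation"]
        deformation = Deformation(
            grid_shape=tuple(dd["grid_shape"]),
            plane_extent_um=tuple(dd["plane_extent_um"]),
            displacements_um=np.asarray(dd["displacements_um"]),
            cap_um=dd.get("cap_um", 500.0),
        )
        return cls(rigid=rigid, deformation=deformation,
                   atlas_name=d.get("atlas_name", ""),
                   provenance=dict(d.get("provenance", {})))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "SliceRegistration":
        return cls.from_dict(json.loads(Path(path).read_text()))


def identity_registration(atlas: Atlas, ap_um: float) -> SliceRegistration:
    """The voxel-center embedding at a given AP position (no warp)."""
    extent = (atlas.shape[1] * atlas.spacing_um[1], atlas.shape[2] * atlas.spacing_um[2])
    return SliceRegistration(
        rigid=RigidParams(ap_um=ap_um),
        deformation=Deformation(grid_shape=(2, 2), plane_extent_um=extent),
        atlas_name=atlas.name,
    )


# ---------------------------------------------------------------------------
# geometry

def _plane_extent_um(atlas: Atlas) -> tuple[float, float]:
    return (atlas.shape[1] * atlas.spacing_um[1], atlas.shape[2] * atlas.spacing_um[2])


def rigid_forward_plane(
    xy_px: np.ndarray,
    rigid: RigidParams,
    pixel_size_um: float,
    slice_shape: tuple[int, int],
    atlas: Atlas,
) -> np.ndarray:
    """Map slice pixels ``(x, y)`` to atlas-plane points ``(dv_um, ml_um)``."""
    xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
    H, W = slice_shape
    x, y = xy[:, 0].copy(), xy[:, 1].copy()
    if rigid.hflip:
        x = (W - 1) - x
    u = (x + 0.5) * pixel_size_um - W * pixel_size_um / 2.0
    v = (y + 0.5) * pixel_size_um - H * pixel_size_um / 2.0
    th = np.deg2rad(rigid.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    u2 = rigid.scale * (c * u - s * v)
    v2 = rigid.scale * (s * u + c * v)
    dv_ext, ml_ext = _plane_extent_um(atlas)
    ml = u2 + ml_ext / 2.0 + rigid.tx_um
    dv = v2 + dv_ext / 2.0 + rigid.ty_um
    return np.stack([dv, ml], axis=1)


def rigid_inverse_plane(
    plane_um: np.ndarray,
    rigid: RigidParams,
    pixel_size_um: float,
    slice_shape: tuple[int, int],
    atlas: Atlas,
) -> np.ndarray:
    """Map atlas-plane points ``(dv_um, ml_um)`` back to slice pixels ``(x, y)``."""
    p = np.atleast_2d(np.asarray(plane_um, dtype=float))
    H, W = slice_shape
    dv_ext, ml_ext = _plane_extent_um(atlas)
    u2 = p[:, 1] - ml_ext / 2.0 - rigid.tx_um
    v2 = p[:, 0] - dv_ext / 2.0 - rigid.ty_um
    th = np.deg2rad(rigid.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    u = (c * u2 + s * v2) / rigid.scale
    v = (-s * u2 + c * v2) / rigid.scale
    x = (u + W * pixel_size_um / 2.0) / pixel_size_um - 0.5
    y = (v + H * pixel_size_um / 2.0) / pixel_size_um - 0.5
    if rigid.hflip:
        x = (W - 1) - x
    return np.stack([x, y], axis=1)


def transform_points(
    reg: SliceRegistration,
    atlas: Atlas,
    xy_px: np.ndarray,
    pixel_size_um: float,
    slice_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Transform slice pixels into atlas µm coordinates and region labels.

    Returns
    -------
    coords_um : (N, 3) array of ``(ap, dv, ml)`` in µm
    region_ids : (N,) integer labels (0 where the point leaves the volume)
    """
    plane = rigid_forward_plane(xy_px, reg.rigid, pixel_size_um, slice_shape, atlas)
    if not reg.deformation.is_identity:
        plane = plane + reg.deformation.displace(plane)
    n = plane.shape[0]
    coords = np.column_stack([np.full(n, reg.rigid.ap_um), plane])
    idx = np.floor(coords / np.asarray(atlas.spacing_um)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(atlas.shape)), axis=1)
    region = np.zeros(n, dtype=np.int64)
    region[inside] = atlas.annotation[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return coords, region


def transform_point(
    reg: SliceRegistration,
    atlas: Atlas,
    xy_px: Sequence[float],
    pixel_size_um: float,
    slice_shape: tuple[int, int],
) -> tuple[np.ndarray, int]:
    """Single-point version of :func:`transform_points` (bounds-checked)."""
    x, y = float(xy_px[0]), float(xy_px[1])
    H, W = slice_shape
    if not (0 <= x < W and 0 <= y < H):
        raise ValueError(f"pixel ({x}, {y}) outside slice bounds {W}x{H}")
    coords, region = transform_points(reg, atlas, [(x, y)], pixel_size_um, slice_shape)
    return coords[0], int(region[0])


def inverse_transform_points(
    reg: SliceRegistration,
    atlas: Atlas,
    coords_um: np.ndarray,
    pixel_size_um: float,
    slice_shape: tuple[int, int],
    n_iter: int = 25,
) -> np.ndarray:
    """Map atlas coordinates back to slice pixels.

    The rigid part inverts analytically.  The elastic part is inverted by
    fixed-point iteration ``r ← a − D(r)`` (a contraction for capped,
    smooth displacement fields).
    """
    coords_um = np.atleast_2d(np.asarray(coords_um, dtype=float))
    plane = coords_um[:, 1:].copy()
    if not reg.deformation.is_identity:
        r = plane.copy()
        for _ in range(n_iter):
            r = plane - reg.deformation.displace(r)
        plane = r
    return rigid_inverse_plane(plane, reg.rigid, pixel_size_um, slice_shape, atlas)


# ---------------------------------------------------------------------------
# similarity metric

def _correlation_ratio(img01: np.ndarray, section: np.ndarray) -> float:
    """1 − Σ_label within-label intensity variance / total variance."""
    total_var = img01.var()
    if total_var == 0:
        return 0.0
    _, inv = np.unique(section, return_inverse=True)
    inv = inv.ravel()
    flat = img01.ravel()
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=flat)
    sq = np.bincount(inv, weights=flat**2)
    within = sq - sums**2 / counts
    return float(1.0 - within.sum() / (total_var * flat.size))


def similarity(
    image: np.ndarray,
    section: np.ndarray,
    w_nmi: float = 0.35,
    w_cr: float = 0.35,
    w_overlap: float = 0.30,
    smooth_sigma: float = 1.0,
    bins: int = 64,
) -> float:
    """Score agreement between a slice intensity image and a label section.

    Three bounded terms, each in [0, 1], combined with configurable
    weights:

    * normalized mutual information between the smoothed, min–max
      normalized intensities and the region labels;
    * the correlation ratio (1 − within-label variance / total variance),
      which peaks when each atlas region maps to homogeneous intensity;
    * foreground overlap — Dice between the thresholded slice mask and the
      nonzero-label mask.  The threshold is half the Otsu value, so dim
      tissue regions stay inside the mask of a zero-background image.

    Higher is better; the score is invariant to affine rescaling of the
    slice intensities.  Degenerate (constant) inputs score 0.
    """
    image = np.asarray(image, dtype=float)
    section = np.asarray(section)
    if image.shape != section.shape:
        raise ValueError(f"shape mismatch {image.shape} vs {section.shape}")
    if image.max() == image.min() or section.max() == section.min():
        return 0.0
    smoothed = gaussian(image, sigma=smooth_sigma, preserve_range=True)
    lo, hi = smoothed.min(), smoothed.max()
    if hi == lo:
        return 0.0
    img01 = (smoothed - lo) / (hi - lo)
    nmi = normalized_mutual_information(img01, section.astype(float), bins=bins)
    cr = _correlation_ratio(img01, section)
    fg_img = img01 > 0.5 * threshold_otsu(img01)
    fg_sec = section > 0
    denom = fg_img.sum() + fg_sec.sum()
    dice = 2.0 * np.logical_and(fg_img, fg_sec).sum() / denom if denom else 0.0
    return float(w_nmi * (nmi - 1.0) + w_cr * cr + w_overlap * dice)


# ---------------------------------------------------------------------------
# estimation

def estimate_ap(
    slice_image: SliceImage,
    atlas: Atlas,
    step_um: float | None = None,
    try_flip: bool = True,
    channel: str | None = None,
) -> tuple[float, bool, float]:
    """Locate a slice along the AP axis by exhaustive similarity search.

    Every candidate AP voxel (stride ``round(step_um / spacing)``) is
    scored against the slice resampled to the section grid, optionally for
    both flip states.  Ties break toward smaller AP and ``hflip=False``.

    Returns ``(ap_um, hflip, score)`` with ``ap_um`` at the voxel center.
    """
    image = slice_image.channel(channel)
    if image.max() == image.min():
        raise ValueError("empty foreground: slice image is constant")
    sp_ap = atlas.spacing_um[0]
    if step_um is None:
        step_um = sp_ap
    if step_um < sp_ap:
        raise ValueError(f"step_um must be >= atlas AP spacing ({sp_ap} µm)")
    stride = max(1, int(round(step_um / sp_ap)))
    n_dv, n_ml = atlas.shape[1], atlas.shape[2]
    resized = resize(image, (n_dv, n_ml), anti_aliasing=True, preserve_range=True)
    best = (-np.inf, 0.0, False)
    for flip in (False, True) if try_flip else (False,):
        img = np.fliplr(resized) if flip else resized
        for i in range(0, atlas.shape[0], stride):
            score = similarity(img, atlas.annotation[i])
            if score > best[0]:
                best = (score, (i + 0.5) * sp_ap, flip)
    score, ap_um, hflip = best
    return float(ap_um), bool(hflip), float(score)


def _render_to_plane(
    image: np.ndarray,
    rigid: RigidParams,
    pixel_size_um: float,
    atlas: Atlas,
    upsample: int = 2,
) -> np.ndarray:
    """Resample the slice onto the atlas section grid under the rigid map."""
    n_dv, n_ml = atlas.shape[1], atlas.shape[2]
    sp_dv, sp_ml = atlas.spacing_um[1], atlas.spacing_um[2]
    dv = (np.arange(n_dv * upsample) + 0.5) * sp_dv / upsample
    ml = (np.arange(n_ml * upsample) + 0.5) * sp_ml / upsample
    grid = np.stack(np.meshgrid(dv, ml, indexing="ij"), axis=-1).reshape(-1, 2)
    xy = rigid_inverse_plane(grid, rigid, pixel_size_um, image.shape, atlas)
    sampled = ndimage.map_coordinates(
        image, [xy[:, 1], xy[:, 0]], order=1, mode="constant", cval=0.0
    )
    return sampled.reshape(n_dv * upsample, n_ml * upsample)


_RIGID_BOUNDS = {"rotation_deg": 15.0, "scale": (0.7, 1.3), "translation_frac": 0.25}


def fit_rigid(
    slice_image: SliceImage,
    atlas: Atlas,
    ap_um: float,
    hflip: bool = False,
    channel: str | None = None,
    upsample: int = 2,
) -> RigidParams:
    """Fit in-plane rotation, scale and translation at a fixed AP position.

    A coarse grid search (rotation ±15° step 5°, scale 0.7–1.3 step 0.1,
    then translation over ±25% of the plane extent) seeds a derivative-free
    Powell refinement of the similarity score.  Parameters that leave the
    search box are clipped with a logged warning.  Deterministic.
    """
    image = slice_image.channel(channel)
    px = slice_image.pixel_size_um
    section = atlas_section(atlas, ap_um)
    section_up = np.repeat(np.repeat(section, upsample, axis=0), upsample, axis=1)
    dv_ext, ml_ext = _plane_extent_um(atlas)
    t_max = _RIGID_BOUNDS["translation_frac"] * max(dv_ext, ml_ext)
    s_lo, s_hi = _RIGID_BOUNDS["scale"]
    r_max = _RIGID_BOUNDS["rotation_deg"]

    def score_of(rot, scale, tx, ty):
        rigid = RigidParams(ap_um=ap_um, rotation_deg=rot, scale=scale,
                            tx_um=tx, ty_um=ty, hflip=hflip)
        rendered = _render_to_plane(image, rigid, px, atlas, upsample)
        return similarity(rendered, section_up)

    # stage 1: rotation x scale at zero translation
    best, best_rs = -np.inf, (0.0, 1.0)
    for rot in np.arange(-r_max, r_max + 1e-9, 5.0):
        for scale in np.arange(s_lo, s_hi + 1e-9, 0.1):
            sc = score_of(rot, scale, 0.0, 0.0)
            if sc > best:
                best, best_rs = sc, (rot, scale)
    # stage 2: translation grid at the best rotation/scale
    best_t = (0.0, 0.0)
    for tx in np.linspace(-t_max, t_max, 7):
        for ty in np.linspace(-t_max, t_max, 7):
            sc = score_of(best_rs[0], best_rs[1], tx, ty)
            if sc > best:
                best, best_t = sc, (tx, ty)

    def objective(theta):
        rot = float(np.clip(theta[0], -r_max, r_max))
        scale = float(np.clip(theta[1], s_lo, s_hi))
        tx = float(np.clip(theta[2], -t_max, t_max))
        ty = float(np.clip(theta[3], -t_max, t_max))
        return -score_of(rot, scale, tx, ty)

    x0 = np.array([best_rs[0], best_rs[1], best_t[0], best_t[1]])
    res = optimize.minimize(
        objective, x0, method="Powell",
        bounds=[(-r_max, r_max), (s_lo, s_hi), (-t_max, t_max), (-t_max, t_max)],
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 200},
    )
    rot, scale, tx, ty = res.x
    clipped = (
        not (-r_max <= rot <= r_max)
        or not (s_lo <= scale <= s_hi)
        or not (-t_max <= tx <= t_max)
        or not (-t_max <= ty <= t_max)
    )
    if clipped:
        logger.warning("rigid fit left the search box; parameters clipped")
    return RigidParams(
        ap_um=float(ap_um),
        rotation_deg=float(np.clip(rot, -r_max, r_max)),
        scale=float(np.clip(scale, s_lo, s_hi)),
        tx_um=float(np.clip(tx, -t_max, t_max)),
        ty_um=float(np.clip(ty, -t_max, t_max)),
        hflip=bool(hflip),
    )


def refine_elastic(
    slice_image: SliceImage,
    atlas: Atlas,
    rigid: RigidParams,
    grid_shape: tuple[int, int] = (4, 4),
    cap_um: float = 300.0,
    n_sweeps: int = 2,
    channel: str | None = None,
    upsample: int = 2,
    enabled: bool = True,
) -> Deformation:
    """Optimize control-point displacements by coordinate-wise search.

    Displacements are bounded by ``cap_um``.  With ``enabled=False`` (the
    pipeline default) the identity deformation is returned untouched —
    elastic correction is meant to be reviewed, or supplied, manually via
    the registration JSON.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("deformation grid must be at least 2x2")
    extent = _plane_extent_um(atlas)
    deformation = Deformation(grid_shape=grid_shape, plane_extent_um=extent, cap_um=cap_um)
    if not enabled:
        return deformation

    image = slice_image.channel(channel)
    px = slice_image.pixel_size_um
    section = atlas_section(atlas, rigid.ap_um)
    section_up = np.repeat(np.repeat(section, upsample, axis=0), upsample, axis=1)
    n_dv, n_ml = atlas.shape[1], atlas.shape[2]
    sp_dv, sp_ml = atlas.spacing_um[1], atlas.spacing_um[2]
    dv = (np.arange(n_dv * upsample) + 0.5) * sp_dv / upsample
    ml = (np.arange(n_ml * upsample) + 0.5) * sp_ml / upsample
    grid = np.stack(np.meshgrid(dv, ml, indexing="ij"), axis=-1).reshape(-1, 2)

    def score_with(disp):
        d = Deformation(grid_shape=grid_shape, plane_extent_um=extent,
                        displacements_um=disp, cap_um=cap_um)
        # first-order elastic inverse: slice sample point for plane point p
        # approximates elastic^{-1}(p) ≈ p − D(p)
        plane = grid - d.displace(grid) if not d.is_identity else grid
        xy = rigid_inverse_plane(plane, rigid, px, image.shape, atlas)
        rendered = ndimage.map_coordinates(
            image, [xy[:, 1], xy[:, 0]], order=1, mode="constant", cval=0.0
        ).reshape(section_up.shape)
        return similarity(rendered, section_up)

    disp = deformation.displacements_um.copy()
    current = score_with(disp)
    deltas = [c for c in (-cap_um / 2, -cap_um / 4, cap_um / 4, cap_um / 2)]
    for _ in range(n_sweeps):
        for r in range(rows):
            for c in range(cols):
                for axis in (0, 1):
                    base = disp[r, c, axis]
                    best_val, best_score = base, current
                    for delta in deltas:
                        cand = float(np.clip(base + delta, -cap_um, cap_um))
                        disp[r, c, axis] = cand
                        if np.linalg.norm(disp[r, c]) > cap_um:
                            continue
                        sc = score_with(disp)
                        if sc > best_score:
                            best_val, best_score = cand, sc
                    disp[r, c, axis] = best_val
                    current = best_score
    return Deformation(grid_shape=grid_shape, plane_extent_um=extent,
                       displacements_um=disp, cap_um=cap_um)


def register_slice(
    slice_image: SliceImage,
    atlas: Atlas,
    channel: str | None = None,
    step_um: float | None = None,
    elastic: bool = False,
    elastic_grid: tuple[int, int] = (4, 4),
    max_ap_iter: int = 3,
) -> SliceRegistration:
    """Full automatic registration: AP search → rigid fit → AP refinement.

    The initial AP search compares the unwarped slice to every section, so
    its estimate can be off when the mounting warp is large.  The rigid
    fit and the AP estimate are then alternated: all sections are
    re-scored against the rigidly resampled slice, and if the best AP
    moves, the rigid parameters are refit there — up to ``max_ap_iter``
    rounds or until stable.  Elastic refinement is opt-in, mirroring a
    review-first workflow.
    """
    if channel is None and "tissue" in slice_image.channels:
        channel = "tissue"
    ap_um, hflip, _ = estimate_ap(slice_image, atlas, step_um=step_um, channel=channel)
    rigid = fit_rigid(slice_image, atlas, ap_um, hflip, channel=channel)
    image = slice_image.channel(channel)
    sp_ap = atlas.spacing_um[0]
    best_score = -np.inf
    for _ in range(max_ap_iter):
        rendered = _render_to_plane(image, rigid, slice_image.pixel_size_um, atlas, upsample=1)
        i0 = ap_index(atlas, rigid.ap_um)
        best_i = i0
        for i in range(atlas.shape[0]):
            sc = similarity(rendered, atlas.annotation[i])
            if sc > best_score:
                best_i, best_score = i, sc
        if best_i == i0:
            break
        rigid = fit_rigid(slice_image, atlas, (best_i + 0.5) * sp_ap, hflip, channel=channel)
    deformation = refine_elastic(
        slice_image, atlas, rigid, grid_shape=elastic_grid,
        channel=channel, enabled=elastic,
    )
    return SliceRegistration(
        rigid=rigid,
        deformation=deformation,
        atlas_name=atlas.name,
        provenance={"method": "auto", "score": float(best_score)},
    )


# ---------------------------------------------------------------------------
# slice TIFF I/O

def write_slice_tiff(slice_image: SliceImage, path) -> None:
    """Write channels as pages of a multi-page float32 TIFF."""
    import tifffile

    stack = np.stack([slice_image.channels[k] for k in slice_image.channels]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={
        "channel_names": list(slice_image.channels),
        "pixel_size_um": slice_image.pixel_size_um,
    })


def read_slice_tiff(
    path,
    pixel_size_um: float,
    channel_names: Sequence[str] | None = None,
    subject_id: str = "",
    condition: str = "",
    slice_id: str = "",
) -> SliceImage:
    """Read a single- or multi-page TIFF into a :class:`SliceImage`."""
    import tifffile

    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    if len(channel_names) != data.shape[0]:
        raise ValueError(
            f"{len(channel_names)} channel names for {data.shape[0]} pages"
        )
    return SliceImage(
        channels={n: data[i] for i, n in enumerate(channel_names)},
        pixel_size_um=pixel_size_um,
        subject_id=subject_id,
        condition=condition,
        slice_id=slice_id or Path(path).stem,
    )
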