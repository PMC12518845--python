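"""Synthetic experiments with known ground truth.

Generates everything the pipeline consumes — an atlas bundle, per-subject
coronal slice images under known rigid (+ optional elastic) warps, planted
cells with per-region / per-condition / per-channel Poisson rates, and
ready-made detection tables — so registration, detection, quantification
and the statistics layer can each be validated against construction-time
truth without downloading data.

The default configuration mirrors a multi-condition immediate-early-gene
mapping study: three conditions (one carrying a planted rate effect),
several subjects per condition, ~19 slices per brain for the single-channel
activity-marker preset and ~6 slices with three channels for the multiplex
in-situ preset.  Slices are cut at atlas voxel-center AP planes.

Everything is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas, make_synthetic_atlas, save_atlas
from .detection import CellDetection, export_detections
from .registration import (
    Deformation,
    RigidParams,
    SliceImage,
    SliceRegistration,
    transform_points,
    write_slice_tiff,
)

__all__ = [
    "WarpConfig",
    "NoiseConfig",
    "EffectConfig",
    "ExperimentConfig",
    "Experiment",
    "sample_warp",
    "plant_cells",
    "generate_slice",
    "generate_experiment",
    "simulate_counts_table",
    "simulate_correlated_table",
    "make_spot_image",
    "rnascope_preset",
]


@dataclass
class WarpConfig:
    """Ranges for the per-slice mounting warp (uniform sampling)."""

    rotation_deg: float = 8.0          # |rotation| bound
    scale_range: tuple[float, float] = (0.95, 1.08)
    translation_um: float = 200.0      # |tx|, |ty| bound
    elastic_amplitude_um: float = 0.0  # 0 disables elastic warping
    elastic_grid: tuple[int, int] = (3, 3)
    allow_hflip: bool = False


@dataclass
class NoiseConfig:
    background_sd: float = 0.02        # Gaussian pixel noise on unit-range images
    spot_snr: float = 8.0              # spot amplitude / background_sd
    spot_diameter_um: float = 50.0
    tissue_bleed: float = 0.05         # fraction of tissue contrast in signal channels


@dataclass
class EffectConfig:
    """A multiplicative rate effect planted in a subset of regions."""

    condition: str = "ingroup"
    n_regions: int = 5
    factor: float = 2.0
    regions: tuple[int, ...] | None = None  # explicit leaf ids; else drawn

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("effect factor must be > 0")


@dataclass
class ExperimentConfig:
    # atlas
    n_leaf_regions: int = 12
    atlas_shape: tuple[int, int, int] = (64, 48, 48)
    spacing_um: tuple[float, float, float] = (100.0, 100.0, 100.0)
    # design
    conditions: tuple[str, ...] = ("baseline", "ingroup", "outgroup")
    n_subjects_per_condition: int = 6
    n_slices_per_subject: int = 19
    channels: tuple[str, ...] = ("cFos",)
    marker_probs: dict = field(default_factory=dict)  # extra-marker prob per cell
    # rates (cells per mm², per region; drawn once from the range)
    base_rate_range: tuple[float, float] = (20.0, 60.0)
    base_rates: dict | None = None     # leaf id -> rate; overrides the range
    effect: EffectConfig = field(default_factory=EffectConfig)
    # imaging
    pixel_size_um: float = 10.0
    warp: WarpConfig = field(default_factory=WarpConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.warp, Mapping):
            self.warp = WarpConfig(**self.warp)
        if isinstance(self.noise, Mapping):
            self.noise = NoiseConfig(**self.noise)
        if isinstance(self.effect, Mapping):
            self.effect = EffectConfig(**self.effect)
        # normalize sequences so YAML round-trips compare equal
        self.atlas_shape = tuple(self.atlas_shape)
        self.spacing_um = tuple(self.spacing_um)
        self.conditions = tuple(self.conditions)
        self.channels = tuple(self.channels)
        self.base_rate_range = tuple(self.base_rate_range)
        self.warp.scale_range = tuple(self.warp.scale_range)
        self.warp.elastic_grid = tuple(self.warp.elastic_grid)
        if self.effect.regions is not None:
            self.effect.regions = tuple(self.effect.regions)
        if self.base_rates is not None:
            if any(v < 0 for v in self.base_rates.values()):
                raise ValueError("rates must be >= 0")
        if self.base_rate_range[0] < 0:
            raise ValueError("rates must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def rnascope_preset(**overrides) -> ExperimentConfig:
    """Multiplex in-situ style preset: 3 channels, ~6 slices per brain."""
    kw = dict(
        n_slices_per_subject=6,
        channels=("cFos", "Drd1", "Drd2"),
        marker_probs={"Drd1": 0.3, "Drd2": 0.3},
    )
    kw.update(overrides)
    return ExperimentConfig(**kw)


# ---------------------------------------------------------------------------
# warps and cells

def sample_warp(
    config: ExperimentConfig, ap_um: float, rng: np.random.Generator,
    atlas: Atlas,
) -> tuple[RigidParams, Deformation]:
    """Draw a rigid + elastic warp uniformly over the configured ranges.

    Zero-width ranges yield the identity transform exactly.
    """
    w = config.warp
    rigid = RigidParams(
        ap_um=ap_um,
        rotation_deg=float(rng.uniform(-w.rotation_deg, w.rotation_deg)),
        scale=float(rng.uniform(*w.scale_range)),
        tx_um=float(rng.uniform(-w.translation_um, w.translation_um)),
        ty_um=float(rng.uniform(-w.translation_um, w.translation_um)),
        hflip=bool(rng.integers(0, 2)) if w.allow_hflip else False,
    )
    extent = (atlas.shape[1] * atlas.spacing_um[1], atlas.shape[2] * atlas.spacing_um[2])
    rows, cols = w.elastic_grid
    if w.elastic_amplitude_um > 0:
        disp = rng.uniform(-w.elastic_amplitude_um, w.elastic_amplitude_um,
                           size=(rows, cols, 2))
        cap = w.elastic_amplitude_um * np.sqrt(2.0)
    else:
        disp, cap = np.zeros((max(rows, 2), max(cols, 2), 2)), 500.0
        rows, cols = disp.shape[:2]
    return rigid, Deformation(grid_shape=(rows, cols), plane_extent_um=extent,
                              displacements_um=disp, cap_um=cap)


def plant_cells(
    region_map: np.ndarray,
    pixel_size_um: float,
    rates: Mapping[int, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plant cells by Poisson(rate × footprint area) per region.

    ``region_map`` is the slice-resolution leaf-label image; positions are
    uniform over each region's footprint pixels with sub-pixel jitter.
    Returns a frame with x_px, y_px, region_id.
    """
    px_mm2 = (pixel_size_um / 1000.0) ** 2
    rows = []
    for rid in sorted(rates):
        lam = rates[rid]
        if lam < 0:
            raise ValueError("rates must be >= 0")
        ys, xs = np.nonzero(region_map == rid)
        if xs.size == 0:
            continue  # region absent at this AP plane
        n = int(rng.poisson(lam * xs.size * px_mm2))
        if n == 0:
            continue
        take = rng.integers(0, xs.size, size=n)
        jx = rng.uniform(-0.5, 0.5, size=n)
        jy = rng.uniform(-0.5, 0.5, size=n)
        for k in range(n):
            rows.append({
                "x_px": float(xs[take[k]] + jx[k]),
                "y_px": float(ys[take[k]] + jy[k]),
                "region_id": int(rid),
            })
    return pd.DataFrame(rows, columns=["x_px", "y_px", "region_id"])


def _render_spots(image: np.ndarray, cells: pd.DataFrame, amplitude: float,
                  sigma_px: float) -> None:
    """Add Gaussian spots in place."""
    if cells.empty:
        return
    H, W = image.shape
    half = max(2, int(np.ceil(3 * sigma_px)))
    for _, c in cells.iterrows():
        cx, cy = c["x_px"], c["y_px"]
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        xs = np.arange(max(x0, 0), min(x1, W))
        ys = np.arange(max(y0, 0), min(y1, H))
        if xs.size == 0 or ys.size == 0:
            continue
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma_px**2))
        image[np.ix_(ys, xs)] += amplitude * np.outer(gy, gx)


def _region_base_intensity(rid: int) -> float:
    """Deterministic tissue-contrast value per region (0 = background)."""
    if rid == 0:
        return 0.0
    return 0.25 + 0.5 * ((rid * 0.381966) % 1.0)


@dataclass
class SliceRecord:
    subject_id: str
    condition: str
    slice_id: str
    image: SliceImage
    true_registration: SliceRegistration
    cells: pd.DataFrame                      # x_px, y_px, region_id, channels
    detections: dict[str, list[CellDetection]]


@dataclass
class Experiment:
    config: ExperimentConfig
    atlas: Atlas
    slices: list[SliceRecord]
    rates: pd.DataFrame          # region_id, channel, condition, rate
    effect_regions: tuple[int, ...]

    def write(self, root) -> Path:
        """Emit the on-disk dialects every pipeline stage reads."""
        root = Path(root)
        save_atlas(self.atlas, root / "atlas")
        (root / "images").mkdir(parents=True, exist_ok=True)
        (root / "detections").mkdir(exist_ok=True)
        subjects = {}
        for rec in self.slices:
            subjects[rec.subject_id] = rec.condition
            sdir = root / "images" / rec.subject_id
            sdir.mkdir(exist_ok=True)
            write_slice_tiff(rec.image, sdir / f"{rec.slice_id}.tif")
            for ch, dets in rec.detections.items():
                export_detections(
                    dets, root / "detections" / f"{rec.slice_id}_{ch}.csv",
                    slice_id=rec.slice_id,
                )
        meta = {
            "pixel_size_um": self.config.pixel_size_um,
            "channels": list(self.config.channels),
            "subjects": subjects,
        }
        (root / "experiment.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        self.rates.to_csv(root / "true_rates.csv", index=False)
        return root


def generate_slice(
    atlas: Atlas,
    ap_um: float,
    rates_by_channel: Mapping[str, Mapping[int, float]],
    config: ExperimentConfig,
    rng: np.random.Generator,
    subject_id: str = "",
    condition: str = "",
    slice_id: str = "",
) -> SliceRecord:
    """Render one warped slice with planted cells.

    The slice grid covers the atlas section plane at ``pixel_size_um``; the
    per-pixel region map comes from pushing every pixel through the sampled
    true transform, so the emitted ground truth is consistent with the
    images by construction.
    """
    rigid, deformation = sample_warp(config, ap_um, rng, atlas)
    reg = SliceRegistration(rigid=rigid, deformation=deformation,
                            atlas_name=atlas.name,
                            provenance={"method": "synthetic", "score": None})
    H = int(round(atlas.shape[1] * atlas.spacing_um[1] / config.pixel_size_um))
    W = int(round(atlas.shape[2] * atlas.spacing_um[2] / config.pixel_size_um))
    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    xy = np.column_stack([xs.ravel(), ys.ravel()])
    _, region_ids = transform_points(reg, atlas, xy, config.pixel_size_um, (H, W))
    region_map = region_ids.reshape(H, W)

    # master cells from the first channel's rates; extra markers are
    # per-cell Bernoulli draws so centroids coincide across channels
    first = config.channels[0]
    cells = plant_cells(region_map, config.pixel_size_um, rates_by_channel[first], rng)
    for ch in config.channels[1:]:
        prob = config.marker_probs.get(ch, 0.0)
        cells[ch] = rng.random(len(cells)) < prob if len(cells) else pd.Series(dtype=bool)
    cells[first] = True
    if len(cells):
        cells = cells[[c for c in ("x_px", "y_px", "region_id")] + list(config.channels)]

    noise = config.noise
    sigma_px = noise.spot_diameter_um / config.pixel_size_um / 4.0
    amplitude = noise.spot_snr * noise.background_sd
    channels_img: dict[str, np.ndarray] = {}
    detections: dict[str, list[CellDetection]] = {}
    base = np.vectorize(_region_base_intensity)(region_map).astype(float) if region_map.size else np.zeros((H, W))
    # structural channel (DAPI/autofluorescence-like): full tissue contrast,
    # no spots — this is what registration keys on
    channels_img["tissue"] = base + rng.normal(0.0, noise.background_sd, size=base.shape)
    for ch in config.channels:
        img = noise.tissue_bleed * base
        ch_cells = cells[cells[ch]] if len(cells) else cells
        _render_spots(img, ch_cells, amplitude, sigma_px)
        img += rng.normal(0.0, noise.background_sd, size=img.shape)
        channels_img[ch] = img
        detections[ch] = [
            CellDetection(x_px=c["x_px"], y_px=c["y_px"], channel=ch,
                          intensity=amplitude, area_px=np.pi * (2 * sigma_px) ** 2)
            for _, c in ch_cells.iterrows()
        ]
    image = SliceImage(channels=channels_img, pixel_size_um=config.pixel_size_um,
                       subject_id=subject_id, condition=condition, slice_id=slice_id)
    return SliceRecord(subject_id=subject_id, condition=condition,
                       slice_id=slice_id, image=image, true_registration=reg,
                       cells=cells, detections=detections)


def _draw_rates(config: ExperimentConfig, atlas: Atlas) -> dict[int, float]:
    if config.base_rates is not None:
        return {int(k): float(v) for k, v in config.base_rates.items()}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    leaves = atlas.hierarchy.leaf_ids()
    lo, hi = config.base_rate_range
    return {rid: float(rng.uniform(lo, hi)) for rid in leaves}


def _effect_regions(config: ExperimentConfig, atlas: Atlas) -> tuple[int, ...]:
    if config.effect.regions is not None:
        return tuple(int(r) for r in config.effect.regions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 417]))
    leaves = atlas.hierarchy.leaf_ids()
    n = min(config.effect.n_regions, len(leaves))
    return tuple(sorted(rng.choice(leaves, size=n, replace=False).tolist()))


def generate_experiment(config: ExperimentConfig) -> Experiment:
    """Generate the full experiment: atlas, warped slices, cells, truth."""
    atlas = make_synthetic_atlas(
        n_leaf_regions=config.n_leaf_regions,
        shape=config.atlas_shape,
        spacing_um=config.spacing_um,
        seed=config.seed,
    )
    base = _draw_rates(config, atlas)
    effect_regions = _effect_regions(config, atlas)
    rate_rows = []
    per_condition: dict[str, dict[str, dict[int, float]]] = {}
    for cond in config.conditions:
        ch_rates: dict[str, dict[int, float]] = {}
        mult = {rid: (config.effect.factor
                      if cond == config.effect.condition and rid in effect_regions
                      else 1.0)
                for rid in base}
        ch_rates[config.channels[0]] = {rid: base[rid] * mult[rid] for rid in base}
        per_condition[cond] = ch_rates
        for rid in base:
            for ch in config.channels:
                eff_rate = base[rid] * mult[rid]
                if ch != config.channels[0]:
                    eff_rate *= config.marker_probs.get(ch, 0.0)
                rate_rows.append({"region_id": rid, "channel": ch,
                                  "condition": cond, "rate": eff_rate})

    # slices cut at voxel-center AP planes spanning the central brain
    n_ap = config.atlas_shape[0]
    sp_ap = config.spacing_um[0]
    lo, hi = int(0.2 * n_ap), int(0.8 * n_ap)
    ap_indices = np.unique(
        np.linspace(lo, hi, config.n_slices_per_subject).round().astype(int)
    )
    slices: list[SliceRecord] = []
    for ci, cond in enumerate(config.conditions):
        for si in range(config.n_subjects_per_condition):
            subject = f"{cond}-{si + 1:02d}"
            for ki, ap_i in enumerate(ap_indices):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, ci, si, ki])
                )
                slices.append(
                    generate_slice(
                        atlas,
                        ap_um=(ap_i + 0.5) * sp_ap,
                        rates_by_channel=per_condition[cond],
                        config=config,
                        rng=rng,
                        subject_id=subject,
                        condition=cond,
                        slice_id=f"{subject}-s{ki + 1:02d}",
                    )
                )
    return Experiment(
        config=config,
        atlas=atlas,
        slices=slices,
        rates=pd.DataFrame(rate_rows),
        effect_regions=effect_regions,
    )


# ---------------------------------------------------------------------------
# direct table simulators (decoupled from imaging, for the statistics layer)

def simulate_counts_table(
    n_regions: int = 50,
    conditions: Sequence[str] = ("baseline", "ingroup", "outgroup"),
    n_per_condition: int = 8,
    base_rate_range: tuple[float, float] = (20.0, 60.0),
    area_mm2: float = 2.0,
    effect_regions: Sequence[int] = (),
    effect_condition: str = "ingroup",
    effect_factor: float = 1.0,
    label_class: str = "cFos",
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson counts table straight from per-region rates (no imaging).

    Region ids are 1..n_regions; every subject samples every region with a
    fixed area, so the statistics layer sees a complete design.  With
    ``effect_factor=1`` all conditions share one distribution (a global
    null).
    """
    rng = np.random.default_rng(seed)
    rates = rng.uniform(*base_rate_range, size=n_regions)
    effect_regions = set(int(r) for r in effect_regions)
    rows = []
    for cond in conditions:
        for s in range(n_per_condition):
            subject = f"{cond}-{s + 1:02d}"
            for ridx in range(n_regions):
                rid = ridx + 1
                lam = rates[ridx] * (effect_factor if cond == effect_condition
                                     and rid in effect_regions else 1.0)
                cells = int(rng.poisson(lam * area_mm2))
                rows.append({
                    "subject": subject, "condition": cond,
                    "region_id": rid, "acronym": f"R{rid:03d}",
                    "label_class": label_class, "cells": cells,
                    "area_mm2": area_mm2, "density": cells / area_mm2,
                })
    return pd.DataFrame(rows)


def simulate_correlated_table(
    n_regions: int = 30,
    conditions: Sequence[str] = ("baseline", "ingroup"),
    n_per_condition: int = 8,
    unique_edge: tuple[int, int] | None = None,
    unique_condition: str = "ingroup",
    unique_r: float = 0.9,
    mean: float = 40.0,
    sd: float = 8.0,
    label_class: str = "cFos",
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian density table for correlation-network tests.

    Regions are independent except, optionally, one pair (1-based ids)
    given correlation ``unique_r`` in ``unique_condition``; the remaining
    conditions share a compensating negative correlation so the *pooled*
    (condition-ignoring) correlation of that pair is ≈ 0 — an edge truly
    unique to the condition rather than a property of the whole cohort.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_other = max(len(conditions) - 1, 1)
    counter_r = min(unique_r / n_other, 0.95) if unique_edge is not None else 0.0
    for cond in conditions:
        Z = rng.normal(size=(n_per_condition, n_regions))
        if unique_edge is not None:
            i, j = (unique_edge[0] - 1, unique_edge[1] - 1)
            shared = rng.normal(size=n_per_condition)
            r_here = unique_r if cond == unique_condition else -counter_r
            a = np.sqrt(abs(r_here))
            b = np.sqrt(1 - abs(r_here))
            Z[:, i] = a * shared + b * Z[:, i]
            Z[:, j] = np.sign(r_here) * a * shared + b * Z[:, j]
        X = mean + sd * Z
        for s in range(n_per_condition):
            subject = f"{cond}-{s + 1:02d}"
            for ridx in range(n_regions):
                dens = float(X[s, ridx])
                rows.append({
                    "subject": subject, "condition": cond,
                    "region_id": ridx + 1, "acronym": f"R{ridx + 1:03d}",
                    "label_class": label_class, "cells": max(0, round(dens * 2)),
                    "area_mm2": 2.0, "density": dens,
                })
    return pd.DataFrame(rows)


def make_spot_image(
    shape: tuple[int, int] = (512, 512),
    n_spots: int = 50,
    pixel_size_um: float = 10.0,
    diameter_range_um: tuple[float, float] = (20.0, 50.0),
    snr: float = 8.0,
    background_sd: float = 0.02,
    min_separation_um: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A flat-background image with well-separated planted Gaussian spots.

    Returns ``(image, centroids)`` with centroids as an (n, 2) array of
    ``(x_px, y_px)``.  Spots are rejection-sampled to keep a minimum
    separation and a border margin.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    margin = min_separation_um / pixel_size_um
    min_sep_px = min_separation_um / pixel_size_um
    centroids: list[tuple[float, float]] = []
    tries = 0
    while len(centroids) < n_spots and tries < 50000:
        tries += 1
        x = rng.uniform(margin, W - margin)
        y = rng.uniform(margin, H - margin)
        if all(np.hypot(x - cx, y - cy) >= min_sep_px for cx, cy in centroids):
            centroids.append((x, y))
    if len(centroids) < n_spots:
        raise ValueError("could not place the requested number of spots")
    image = np.zeros(shape, dtype=float)
    cents = np.asarray(centroids)
    diam = rng.uniform(*diameter_range_um, size=n_spots)
    df = pd.DataFrame({"x_px": cents[:, 0], "y_px": cents[:, 1]})
    for k in range(n_spots):
        sigma_px = diam[k] / pixel_size_um / 4.0
        _render_spots(image, df.iloc[[k]], snr * background_sd, sigma_px)
    image += rng.normal(0.0, background_sd, size=shape)
    return image, cents
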