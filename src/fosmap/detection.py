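"""Cell detection, external-detection import, and multi-channel co-labeling.

The built-in detector is a deterministic multi-scale Laplacian-of-Gaussian
blob detector tuned by a physical diameter band; learned segmenters (or any
third-party pipeline) enter through :func:`import_detections` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.feature import blob_log

__all__ = [
    "CellDetection",
    "DetectionParams",
    "detect_cells",
    "import_detections",
    "export_detections",
    "colabel",
]

#: canonical detection-CSV columns (import and export)
DETECTION_COLUMNS = ["slice_id", "channel", "x", "y", "units", "intensity", "area"]


@dataclass
class CellDetection:
    """One detected cell (or one merged multi-channel cell after co-labeling)."""

    x_px: float
    y_px: float
    channel: str
    intensity: float = 0.0
    area_px: float = 1.0
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.area_px <= 0:
            raise ValueError("area_px must be > 0")
        if not self.labels:
            self.labels = frozenset({self.channel})
        else:
            self.labels = frozenset(self.labels)

    @property
    def label_class(self) -> str:
        """Composite marker class, e.g. ``"Drd1+cFos"`` for a co-labeled cell."""
        return "+".join(sorted(self.labels))


@dataclass
class DetectionParams:
    min_diameter_um: float = 15.0
    max_diameter_um: float = 60.0
    threshold: float = 0.2  # relative prominence against the image dynamic range
    channel: str = "cFos"

    def __post_init__(self):
        if not (0 < self.min_diameter_um < self.max_diameter_um):
            raise ValueError("need 0 < min_diameter_um < max_diameter_um")


def detect_cells(
    image: np.ndarray,
    pixel_size_um: float,
    params: DetectionParams,
) -> list[CellDetection]:
    """Detect cell-like spots with a multi-scale LoG detector.

    Scales cover the configured diameter band (σ = d / (2√2)); maxima are
    kept when their normalized-LoG response exceeds ``params.threshold``
    relative to the strongest response.  A final non-maximum suppression
    removes any detection whose centroid lies closer than
    ``min_diameter_um`` to a stronger one.  Deterministic; an empty list is
    a valid outcome.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return []
    img01 = (image - lo) / (hi - lo)
    sigma_min = params.min_diameter_um / pixel_size_um / (2.0 * np.sqrt(2.0))
    sigma_max = params.max_diameter_um / pixel_size_um / (2.0 * np.sqrt(2.0))
    # pre-smoothing suppresses pixel noise before the scale search; the
    # scale band is widened to account for the extra blur
    pre_sigma = max(1.0, 0.5 * sigma_min)
    from skimage.filters import gaussian

    smoothed = gaussian(img01, sigma=pre_sigma, preserve_range=True)
    s_lo = np.hypot(max(sigma_min, 0.5), pre_sigma)
    s_hi = np.hypot(max(sigma_max, sigma_min + 0.5), pre_sigma)
    blobs = blob_log(
        smoothed,
        min_sigma=s_lo,
        max_sigma=max(s_hi, s_lo + 0.25),
        num_sigma=7,
        threshold=None,
        threshold_rel=params.threshold,
        overlap=0.5,
    )
    if blobs.size == 0:
        return []
    # strength proxy for NMS ordering: smoothed intensity at the centroid
    strengths = smoothed[blobs[:, 0].astype(int).clip(0, image.shape[0] - 1),
                         blobs[:, 1].astype(int).clip(0, image.shape[1] - 1)]
    order = np.lexsort((blobs[:, 1], blobs[:, 0], -strengths))
    min_dist_px = params.min_diameter_um / pixel_size_um
    from scipy.spatial import cKDTree

    tree = cKDTree(blobs[:, :2])
    neighbors = tree.query_ball_point(blobs[:, :2], r=min_dist_px * (1 - 1e-12))
    suppressed = np.zeros(len(blobs), dtype=bool)
    kept: list[int] = []
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in neighbors[i]:
            if j != i:
                suppressed[j] = True
    out = []
    for i in sorted(kept, key=lambda i: (blobs[i, 0], blobs[i, 1])):
        y, x, sigma = blobs[i]
        sigma_intrinsic = np.sqrt(max(sigma**2 - pre_sigma**2, 0.25))
        r = sigma_intrinsic * np.sqrt(2.0)
        yy, xx = int(round(y)), int(round(x))
        out.append(
            CellDetection(
                x_px=float(x),
                y_px=float(y),
                channel=params.channel,
                intensity=float(image[np.clip(yy, 0, image.shape[0] - 1),
                                      np.clip(xx, 0, image.shape[1] - 1)]),
                area_px=float(np.pi * r * r),
            )
        )
    return out


def import_detections(
    path,
    pixel_size_um: float,
    column_map: Mapping[str, str] | None = None,
    default_units: str = "px",
    channel: str | None = None,
) -> list[CellDetection]:
    """Load a detections CSV (QuPath/ImageJ-style exports) in slice pixels.

    ``column_map`` renames third-party headers onto the canonical dialect
    (``slice_id, channel, x, y, units, intensity, area``).  Coordinates in
    µm are converted by ``pixel_size_um``; a per-row ``units`` column
    overrides ``default_units``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"detections CSV is missing required column '{col}'")
        if not pd.api.types.is_numeric_dtype(pd.to_numeric(df[col], errors="coerce")):
            raise ValueError(f"column '{col}' is not numeric")
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(f"column '{col}' contains non-numeric values")
    units = df["units"] if "units" in df.columns else pd.Series(default_units, index=df.index)
    scale = np.where(units.astype(str).str.lower().isin(("um", "µm", "micron", "microns")),
                     1.0 / pixel_size_um, 1.0)
    out = []
    for i, row in df.reset_index(drop=True).iterrows():
        out.append(
            CellDetection(
                x_px=float(row["x"]) * scale[i],
                y_px=float(row["y"]) * scale[i],
                channel=str(row["channel"]) if "channel" in df.columns else (channel or "ch0"),
                intensity=float(row.get("intensity", 0.0) or 0.0),
                area_px=float(row.get("area", 1.0) or 1.0),
            )
        )
    return out


def export_detections(detections: Sequence[CellDetection], path, slice_id: str = "") -> None:
    df = pd.DataFrame(
        [
            {
                "slice_id": slice_id,
                "channel": d.channel,
                "x": d.x_px,
                "y": d.y_px,
                "units": "px",
                "intensity": d.intensity,
                "area": d.area_px,
            }
            for d in detections
        ],
        columns=DETECTION_COLUMNS,
    )
    df.to_csv(path, index=False)


def colabel(
    detections_by_channel: Mapping[str, Sequence[CellDetection]],
    match_radius_um: float,
    pixel_size_um: float = 1.0,
) -> list[CellDetection]:
    """Resolve multi-channel detections into distinct co-labeled cells.

    Greedy mutual-nearest matching: the globally closest pair of cells
    whose channel sets are disjoint and whose centroids lie within
    ``match_radius_um`` is merged, repeatedly, with each partner also being
    the other's nearest eligible neighbor.  Distance ties break toward the
    lowest (channel-name-sorted) input index, making the result invariant
    to the order channels are supplied in.

    Channel-level detections are conserved: the sum of ``len(labels)``
    over output cells equals the total number of input detections.
    """
    if match_radius_um < 0:
        raise ValueError("match_radius_um must be non-negative")
    if not detections_by_channel:
        return []
    radius_px = match_radius_um / pixel_size_um

    clusters: list[dict] = []
    for ch in sorted(detections_by_channel):
        for det in detections_by_channel[ch]:
            clusters.append({
                "members": [det],
                "channels": {det.channel},
                "pos": np.array([det.x_px, det.y_px], dtype=float),
            })

    def eligible(a, b):
        return not (clusters[a]["channels"] & clusters[b]["channels"])

    alive = set(range(len(clusters)))
    while True:
        # pairwise distances among eligible pairs
        pairs = []
        alive_list = sorted(alive)
        for ii, a in enumerate(alive_list):
            for b in alive_list[ii + 1:]:
                if eligible(a, b):
                    dist = float(np.linalg.norm(clusters[a]["pos"] - clusters[b]["pos"]))
                    if dist <= radius_px:
                        pairs.append((dist, a, b))
        if not pairs:
            break
        pairs.sort()
        # mutual-nearest: both endpoints have no closer eligible partner
        nearest: dict[int, tuple[float, int]] = {}
        for dist, a, b in pairs:
            for u, v in ((a, b), (b, a)):
                if u not in nearest or dist < nearest[u][0]:
                    nearest[u] = (dist, v)
        merged = None
        for dist, a, b in pairs:
            if nearest[a][1] == b and nearest[b][1] == a:
                merged = (a, b)
                break
        if merged is None:  # no mutual pair left within radius
            break
        a, b = merged
        ca, cb = clusters[a], clusters[b]
        ca["members"].extend(cb["members"])
        ca["channels"] |= cb["channels"]
        ca["pos"] = np.mean([[m.x_px, m.y_px] for m in ca["members"]], axis=0)
        alive.discard(b)

    out = []
    for i in sorted(alive):
        cl = clusters[i]
        members = cl["members"]
        out.append(
            CellDetection(
                x_px=float(cl["pos"][0]),
                y_px=float(cl["pos"][1]),
                channel=sorted(cl["channels"])[0],
                intensity=float(np.mean([m.intensity for m in members])),
                area_px=float(np.mean([m.area_px for m in members])),
                labels=frozenset(cl["channels"]),
            )
        )
    out.sort(key=lambda d: (d.y_px, d.x_px, d.label_class))
    return out
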