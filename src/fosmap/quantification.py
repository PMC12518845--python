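"""Per-region cell counts, sampled areas, and the experiment counts table.

Densities are cells per mm² of the region area actually sampled by a
subject's registered slices (not the atlas volume of the region); a region
a subject never sampled is emitted with missing density rather than zero,
so the statistics layer can distinguish "not sampled" from "no cells".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, aggregate_to_level
from .detection import CellDetection
from .registration import SliceRegistration, transform_points

__all__ = [
    "TABLE_COLUMNS",
    "SliceQuant",
    "assign_regions",
    "region_areas",
    "quantify_slice",
    "build_table",
    "aggregate_table",
    "percent_expression",
]

#: bit-fixed counts-CSV header
TABLE_COLUMNS = [
    "subject", "condition", "region_id", "acronym",
    "label_class", "cells", "area_mm2", "density",
]


def assign_regions(
    cells: Sequence[CellDetection],
    registration: SliceRegistration,
    atlas: Atlas,
    pixel_size_um: float,
    slice_shape: tuple[int, int],
) -> tuple[pd.DataFrame, dict]:
    """Tag each cell with the leaf region at its transformed coordinate.

    Returns a DataFrame (x_px, y_px, label_class, region_id, in_mask) and a
    QC tally with the number of cells landing in background.
    """
    if not cells:
        return (
            pd.DataFrame(columns=["x_px", "y_px", "label_class", "region_id", "in_mask"]),
            {"n_cells": 0, "n_out_of_mask": 0},
        )
    xy = np.array([[c.x_px, c.y_px] for c in cells])
    _, region_ids = transform_points(registration, atlas, xy, pixel_size_um, slice_shape)
    df = pd.DataFrame({
        "x_px": xy[:, 0],
        "y_px": xy[:, 1],
        "label_class": [c.label_class for c in cells],
        "region_id": region_ids,
        "in_mask": region_ids != 0,
    })
    qc = {"n_cells": len(df), "n_out_of_mask": int((~df["in_mask"]).sum())}
    return df, qc


def region_areas(
    registration: SliceRegistration,
    atlas: Atlas,
    slice_shape: tuple[int, int],
    pixel_size_um: float,
) -> dict[int, float]:
    """Sampled area (mm²) per region: transformed-pixel counts × pixel area.

    Region 0 collects pixels landing in background / outside the volume;
    the values sum exactly to the total slice area.
    """
    H, W = slice_shape
    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    xy = np.column_stack([xs.ravel(), ys.ravel()])
    _, region_ids = transform_points(registration, atlas, xy, pixel_size_um, slice_shape)
    px_mm2 = (pixel_size_um / 1000.0) ** 2
    ids, counts = np.unique(region_ids, return_counts=True)
    return {int(i): float(c) * px_mm2 for i, c in zip(ids, counts)}


@dataclass
class SliceQuant:
    """Counts and areas for one quantified slice (intermediate record)."""

    subject_id: str
    condition: str
    slice_id: str
    counts: dict[tuple[int, str], int]   # (region_id, label_class) -> cells
    areas: dict[int, float]              # region_id -> mm² (0 = background)
    qc: dict = field(default_factory=dict)


def quantify_slice(
    cells: Sequence[CellDetection],
    registration: SliceRegistration,
    atlas: Atlas,
    slice_shape: tuple[int, int],
    pixel_size_um: float,
    subject_id: str = "",
    condition: str = "",
    slice_id: str = "",
) -> SliceQuant:
    """Assign cells to regions and measure sampled areas for one slice."""
    assigned, qc = assign_regions(cells, registration, atlas, pixel_size_um, slice_shape)
    in_mask = assigned[assigned["in_mask"]]
    counts = (
        in_mask.groupby(["region_id", "label_class"]).size().to_dict()
        if len(in_mask)
        else {}
    )
    areas = region_areas(registration, atlas, slice_shape, pixel_size_um)
    return SliceQuant(
        subject_id=subject_id, condition=condition, slice_id=slice_id,
        counts={(int(r), str(c)): int(n) for (r, c), n in counts.items()},
        areas=areas, qc=qc,
    )


def build_table(slice_quants: Sequence[SliceQuant], atlas: Atlas) -> pd.DataFrame:
    """Pool slice-level counts/areas into the subject × region × class table.

    Cells and areas are summed over each subject's slices before the
    density is taken (pooled density, not a mean of per-slice densities).
    Rows are emitted for every (sampled region) × (observed label class)
    pair, ordered by (subject, region_id, label_class); density is NaN
    where the sampled area is zero.
    """
    if not slice_quants:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    subjects: dict[str, dict] = {}
    label_classes: set[str] = set()
    for sq in slice_quants:
        sub = subjects.setdefault(
            sq.subject_id, {"condition": sq.condition, "counts": {}, "areas": {}}
        )
        if sub["condition"] != sq.condition:
            raise ValueError(f"subject {sq.subject_id} has inconsistent conditions")
        for key, n in sq.counts.items():
            sub["counts"][key] = sub["counts"].get(key, 0) + n
            label_classes.add(key[1])
        for rid, a in sq.areas.items():
            if rid != 0:
                sub["areas"][rid] = sub["areas"].get(rid, 0.0) + a
    label_classes = sorted(label_classes) or ["cells"]
    rows = []
    for subject in sorted(subjects):
        sub = subjects[subject]
        for rid in sorted(sub["areas"]):
            area = sub["areas"][rid]
            for cls in label_classes:
                cells = sub["counts"].get((rid, cls), 0)
                rows.append({
                    "subject": subject,
                    "condition": sub["condition"],
                    "region_id": rid,
                    "acronym": atlas.hierarchy.acronym(rid) if rid in atlas.hierarchy else str(rid),
                    "label_class": cls,
                    "cells": cells,
                    "area_mm2": area,
                    "density": cells / area if area > 0 else np.nan,
                })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def aggregate_table(table: pd.DataFrame, atlas: Atlas, level: int) -> pd.DataFrame:
    """Re-express a leaf-level table at a coarser hierarchy depth.

    Counts and areas are summed over leaves sharing the ancestor at tree
    depth ``level``; totals are conserved.
    """
    rows = []
    for (subject, condition, cls), grp in table.groupby(
        ["subject", "condition", "label_class"], sort=True
    ):
        counts = aggregate_to_level(
            dict(zip(grp["region_id"], grp["cells"])), atlas.hierarchy, level
        )
        areas = aggregate_to_level(
            dict(zip(grp["region_id"], grp["area_mm2"])), atlas.hierarchy, level
        )
        for rid in sorted(counts):
            area = areas[rid]
            rows.append({
                "subject": subject,
                "condition": condition,
                "region_id": rid,
                "acronym": atlas.hierarchy.acronym(rid),
                "label_class": cls,
                "cells": counts[rid],
                "area_mm2": area,
                "density": counts[rid] / area if area > 0 else np.nan,
            })
    out = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return out.sort_values(["subject", "region_id", "label_class"], ignore_index=True)


def percent_expression(
    table: pd.DataFrame, marker_class: str, denominator_class: str
) -> pd.DataFrame:
    """Per-subject, per-region percentage of marker cells over denominator cells.

    A marker class matches any composite label class containing the marker
    (``"Drd1"`` counts both ``"Drd1"`` and ``"Drd1+cFos"`` cells); percent
    is missing where the denominator count is zero.
    """
    for cls in (marker_class, denominator_class):
        present = table["label_class"].str.split("+").map(lambda ls: any(
            m in ls for m in cls.split("+"))).any()
        if not present:
            raise ValueError(f"label class {cls!r} not present in table")

    def count_matching(grp, cls):
        markers = set(cls.split("+"))
        sel = grp["label_class"].str.split("+").map(lambda ls: markers <= set(ls))
        return grp.loc[sel, "cells"].sum()

    rows = []
    for (subject, condition, rid, acr), grp in table.groupby(
        ["subject", "condition", "region_id", "acronym"], sort=True
    ):
        num = count_matching(grp, marker_class)
        den = count_matching(grp, denominator_class)
        rows.append({
            "subject": subject,
            "condition": condition,
            "region_id": rid,
            "acronym": acr,
            "percent": 100.0 * num / den if den > 0 else np.nan,
        })
    return pd.DataFrame(rows)
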