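"""3D annotation atlases: loading, synthesis, hierarchy and section queries.

An atlas couples a 3D integer label volume, indexed ``(ap, dv, ml)`` with
voxel index 0 at the anterior pole, to a rooted region hierarchy.  The
physical coordinate of voxel ``i`` along an axis is the voxel *center*,
``(i + 0.5) * spacing_um``; nearest-voxel lookup is therefore
``floor(coord / spacing)``.

Atlas bundles on disk follow a brainglobe-like layout: a directory holding
``annotation.tif`` (or ``annotation.nrrd``), ``structures.json`` (flat list
of region records with explicit parent ids) and ``meta.json`` (name and
per-axis voxel spacing in µm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

from ._nrrd import read_nrrd, write_nrrd

__all__ = [
    "RegionNode",
    "RegionHierarchy",
    "Atlas",
    "load_atlas",
    "save_atlas",
    "make_synthetic_atlas",
    "atlas_section",
    "section_edge_map",
    "region_ancestors",
    "aggregate_to_level",
]


@dataclass(frozen=True)
class RegionNode:
    """One region in the hierarchy tree."""

    id: int
    acronym: str
    name: str
    parent_id: int | None
    children_ids: tuple[int, ...] = ()
    color: tuple[int, int, int] = (128, 128, 128)


class RegionHierarchy:
    """A single rooted tree of :class:`RegionNode`, keyed by integer id."""

    def __init__(self, nodes: Iterable[RegionNode]):
        self.nodes: dict[int, RegionNode] = {}
        roots = []
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate region id {node.id}")
            if node.id <= 0:
                raise ValueError(f"region id must be a positive integer, got {node.id}")
            self.nodes[node.id] = node
            if node.parent_id is None:
                roots.append(node.id)
        if len(roots) != 1:
            raise ValueError(f"hierarchy must have exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise ValueError(f"region {node.id} references unknown parent {node.parent_id}")
        # rebuild children lists from parent pointers so both views agree
        children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                children[node.parent_id].append(node.id)
        for rid, kids in children.items():
            object.__setattr__(self.nodes[rid], "children_ids", tuple(sorted(kids)))
        if len(self._reachable_from_root()) != len(self.nodes):
            raise ValueError("parent/child graph is not a single rooted tree")

    def _reachable_from_root(self) -> set[int]:
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            rid = stack.pop()
            if rid in seen:
                raise ValueError("cycle detected in region hierarchy")
            seen.add(rid)
            stack.extend(self.nodes[rid].children_ids)
        return seen

    def __contains__(self, rid: int) -> bool:
        return rid in self.nodes

    def __getitem__(self, rid: int) -> RegionNode:
        return self.nodes[rid]

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionHierarchy) and self.nodes == other.nodes

    def is_leaf(self, rid: int) -> bool:
        return not self.nodes[rid].children_ids

    def leaf_ids(self) -> list[int]:
        return sorted(i for i in self.nodes if self.is_leaf(i))

    def depth(self, rid: int) -> int:
        """Number of edges from the root (root has depth 0)."""
        return len(region_ancestors(self, rid)) - 1

    def ancestor_at_level(self, rid: int, level: int) -> int:
        """The ancestor of ``rid`` at the given depth (``rid`` itself if shallower)."""
        chain = region_ancestors(self, rid)
        return chain[min(level, len(chain) - 1)]

    def acronym(self, rid: int) -> str:
        return self.nodes[rid].acronym

    def leaves_under(self, rid: int) -> list[int]:
        out = []
        stack = [rid]
        while stack:
            cur = stack.pop()
            kids = self.nodes[cur].children_ids
            if kids:
                stack.extend(kids)
            else:
                out.append(cur)
        return sorted(out)


@dataclass
class Atlas:
    """A 3D annotation volume plus its region hierarchy.

    Attributes
    ----------
    annotation : ndarray of int, shape (n_ap, n_dv, n_ml)
        Region label per voxel; 0 is background.
    spacing_um : tuple of 3 floats
        Voxel size per axis (AP, DV, ML) in µm.
    hierarchy : RegionHierarchy
    name : str
    """

    annotation: np.ndarray
    spacing_um: tuple[float, float, float]
    hierarchy: RegionHierarchy
    name: str = "atlas"

    def __post_init__(self):
        self.annotation = np.asarray(self.annotation)
        if self.annotation.ndim != 3:
            raise ValueError("annotation must be a 3D array")
        if not np.issubdtype(self.annotation.dtype, np.integer):
            raise ValueError("annotation must be an integer label volume")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three strictly positive values")
        labels = set(np.unique(self.annotation).tolist()) - {0}
        missing = sorted(l for l in labels if l not in self.hierarchy)
        if missing:
            raise ValueError(
                f"annotation labels absent from hierarchy: {missing}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.annotation.shape

    @property
    def ap_extent_um(self) -> float:
        return self.annotation.shape[0] * self.spacing_um[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Atlas)
            and self.name == other.name
            and np.array_equal(self.annotation, other.annotation)
            and np.allclose(self.spacing_um, other.spacing_um)
            and self.hierarchy == other.hierarchy
        )


# ---------------------------------------------------------------------------
# bundle I/O

def save_atlas(atlas: Atlas, path, volume_format: str = "tif") -> Path:
    """Write an atlas bundle directory (annotation volume + JSON metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if volume_format == "tif":
        tifffile.imwrite(path / "annotation.tif", atlas.annotation.astype(np.uint32))
    elif volume_format == "nrrd":
        write_nrrd(path / "annotation.nrrd", atlas.annotation.astype(np.uint32))
    else:
        raise ValueError(f"unknown volume_format {volume_format!r}")
    records = [
        {
            "id": n.id,
            "acronym": n.acronym,
            "name": n.name,
            "parent_structure_id": n.parent_id,
            "rgb_triplet": list(n.color),
        }
        for n in sorted(atlas.hierarchy.nodes.values(), key=lambda n: n.id)
    ]
    (path / "structures.json").write_text(json.dumps(records, indent=1))
    (path / "meta.json").write_text(
        json.dumps({"name": atlas.name, "spacing_um": list(atlas.spacing_um)})
    )
    return path


def load_atlas(path) -> Atlas:
    """Load an atlas bundle directory written by :func:`save_atlas`.

    Raises
    ------
    FileNotFoundError
        If a required bundle file is missing.
    ValueError
        If the volume is non-integer or contains labels absent from
        ``structures.json`` (the offending labels are named).
    """
    path = Path(path)
    vol_tif, vol_nrrd = path / "annotation.tif", path / "annotation.nrrd"
    if vol_tif.exists():
        annotation = np.asarray(tifffile.imread(vol_tif))
    elif vol_nrrd.exists():
        annotation = read_nrrd(vol_nrrd)
    else:
        raise FileNotFoundError(f"{path}: no annotation.tif or annotation.nrrd")
    if not np.issubdtype(annotation.dtype, np.integer):
        raise ValueError(f"{path}: annotation volume is not integer-typed")
    for required in ("structures.json", "meta.json"):
        if not (path / required).exists():
            raise FileNotFoundError(f"{path}: missing {required}")
    records = json.loads((path / "structures.json").read_text())
    nodes = [
        RegionNode(
            id=int(r["id"]),
            acronym=str(r["acronym"]),
            name=str(r.get("name", r["acronym"])),
            parent_id=None if r.get("parent_structure_id") is None else int(r["parent_structure_id"]),
            color=tuple(r.get("rgb_triplet", (128, 128, 128))),
        )
        for r in records
    ]
    meta = json.loads((path / "meta.json").read_text())
    return Atlas(
        annotation=annotation.astype(np.int64),
        spacing_um=tuple(meta["spacing_um"]),
        hierarchy=RegionHierarchy(nodes),
        name=meta.get("name", path.name),
    )


# ---------------------------------------------------------------------------
# synthesis

def make_synthetic_atlas(
    n_leaf_regions: int = 12,
    shape: tuple[int, int, int] = (64, 48, 48),
    spacing_um: tuple[float, float, float] = (100.0, 100.0, 100.0),
    seed: int = 0,
    n_lobes: int | None = None,
) -> Atlas:
    """Build a deterministic ellipsoidal test atlas.

    The brain mask is an ellipsoid inset from the volume border.  Leaf
    regions are nearest-seed (Voronoi) cells of points sampled inside one
    hemisphere and mirrored across the ML midplane, so the label volume has
    exact left/right mirror symmetry.  Leaves are grouped by AP position
    into parent "lobes" under a single root.

    Pure function of its arguments: the same call always returns a
    bit-identical atlas.
    """
    if n_leaf_regions < 2:
        raise ValueError("n_leaf_regions must be >= 2")
    if any(s < 16 for s in shape):
        raise ValueError("each volume axis must be >= 16 voxels")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing_um, dtype=float)

    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) / 2.0 - 2.0  # inset keeps a background border
    idx = np.indices(shape).astype(float)
    norm2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = norm2 <= 1.0

    # sample leaf seeds in the left half (ml < midplane), then mirror
    seeds = []
    max_tries = 20000
    for _ in range(max_tries):
        if len(seeds) == n_leaf_regions:
            break
        cand = rng.uniform(low=[0, 0, 0], high=[shape[0], shape[1], shape[2] / 2.0])
        v = sum(((cand[a] - center[a]) / semi[a]) ** 2 for a in range(3))
        if v <= 0.8:  # keep seeds comfortably inside the ellipsoid
            seeds.append(cand)
    if len(seeds) < n_leaf_regions:
        raise ValueError(
            f"could not place {n_leaf_regions} leaf seeds inside the ellipsoid"
        )
    seeds = np.asarray(seeds)
    mirrored = seeds.copy()
    mirrored[:, 2] = (shape[2] - 1) - mirrored[:, 2]
    all_seeds = np.concatenate([seeds, mirrored])  # 2n points, n labels
    seed_label = np.concatenate([np.arange(n_leaf_regions)] * 2)

    # nearest seed in physical (µm) coordinates, vectorized over voxels
    voxels = np.stack([idx[a][mask] for a in range(3)], axis=1) * spacing
    d2 = ((voxels[:, None, :] - all_seeds[None, :, :] * spacing) ** 2).sum(axis=2)
    nearest = seed_label[np.argmin(d2, axis=1)]

    if n_lobes is None:
        n_lobes = max(2, n_leaf_regions // 4)
    n_lobes = min(n_lobes, n_leaf_regions)
    # group leaves into lobes by seed AP order
    ap_order = np.argsort(seeds[:, 0], kind="stable")
    lobe_of_leaf = np.empty(n_leaf_regions, dtype=int)
    bounds = np.linspace(0, n_leaf_regions, n_lobes + 1).astype(int)
    for lobe, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        lobe_of_leaf[ap_order[lo:hi]] = lobe

    root_id = 1
    lobe_ids = [root_id + 1 + i for i in range(n_lobes)]
    leaf_ids = [root_id + 1 + n_lobes + i for i in range(n_leaf_regions)]

    annotation = np.zeros(shape, dtype=np.int64)
    annotation[mask] = np.asarray(leaf_ids)[nearest]

    colors = rng.integers(0, 256, size=(n_lobes + n_leaf_regions + 1, 3))
    nodes = [RegionNode(root_id, "root", "root", None, color=tuple(int(c) for c in colors[0]))]
    for i, lid in enumerate(lobe_ids):
        nodes.append(
            RegionNode(lid, f"LB{i + 1}", f"lobe {i + 1}", root_id,
                       color=tuple(int(c) for c in colors[1 + i]))
        )
    for i, fid in enumerate(leaf_ids):
        nodes.append(
            RegionNode(fid, f"R{i + 1:03d}", f"region {i + 1}",
                       lobe_ids[lobe_of_leaf[i]],
                       color=tuple(int(c) for c in colors[1 + n_lobes + i]))
        )
    return Atlas(
        annotation=annotation,
        spacing_um=tuple(spacing),
        hierarchy=RegionHierarchy(nodes),
        name=f"synthetic-{n_leaf_regions}r-{seed}",
    )


# ---------------------------------------------------------------------------
# section and hierarchy queries

def ap_index(atlas: Atlas, ap_um: float) -> int:
    """Nearest AP voxel index for a physical coordinate (µm)."""
    if not (0 <= ap_um < atlas.ap_extent_um):
        raise ValueError(
            f"ap_um={ap_um} outside [0, {atlas.ap_extent_um}) µm"
        )
    return min(int(ap_um / atlas.spacing_um[0]), atlas.shape[0] - 1)


def atlas_section(atlas: Atlas, ap_um: float) -> np.ndarray:
    """The (dv, ml) annotation plane at the nearest AP voxel."""
    return atlas.annotation[ap_index(atlas, ap_um)]


def section_edge_map(section: np.ndarray) -> np.ndarray:
    """Binary map of label boundaries (pixel differs from a 4-neighbor)."""
    edges = np.zeros(section.shape, dtype=bool)
    edges[:-1, :] |= section[:-1, :] != section[1:, :]
    edges[1:, :] |= section[1:, :] != section[:-1, :]
    edges[:, :-1] |= section[:, :-1] != section[:, 1:]
    edges[:, 1:] |= section[:, 1:] != section[:, :-1]
    return edges


def region_ancestors(hierarchy: RegionHierarchy, rid: int) -> list[int]:
    """Ancestor chain ordered root → ``rid`` (inclusive)."""
    if rid not in hierarchy:
        raise KeyError(f"unknown region id {rid}")
    chain = [rid]
    while hierarchy[chain[-1]].parent_id is not None:
        chain.append(hierarchy[chain[-1]].parent_id)
    return chain[::-1]


def aggregate_to_level(
    counts: Mapping[int, float], hierarchy: RegionHierarchy, level: int
) -> dict[int, float]:
    """Sum per-leaf counts up to ancestors at tree depth ``level``.

    A node shallower than ``level`` keeps its own id, so aggregating at a
    depth at or below the leaves returns the input unchanged and level 0
    collapses everything onto the root.  Totals are conserved at every
    level.
    """
    out: dict[int, float] = {}
    for rid, value in counts.items():
        anc = hierarchy.ancestor_at_level(rid, level)
        out[anc] = out.get(anc, 0) + value
    return out
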