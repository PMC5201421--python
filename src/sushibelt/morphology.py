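"""Compartment trees: the spatial scaffold for transport simulations.

A neuron is discretized into compartments connected parent-to-child, with the
soma as the root. Compartments carry a physical length (µm) so that rate
constants can be scaled to geometry. Trees come from three places: SWC
reconstruction files, synthetic unbranched cables, or explicit parent arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentTree",
    "SWCFormatError",
    "SWCStructureError",
    "read_swc",
    "build_cable",
    "build_tree",
    "resample",
]

NO_PARENT = -1


class SWCFormatError(ValueError):
    """Malformed SWC content (bad columns, unknown parent reference)."""


class SWCStructureError(ValueError):
    """SWC content that parses but does not describe a single rooted tree."""


@dataclass(frozen=True)
class CompartmentTree:
    """Rooted tree of compartments, indexed 0..N-1 with parent before child.

    Parameters
    ----------
    parent:
        Integer array of length N; ``parent[i]`` is the index of compartment
        i's parent, or ``-1`` for the root. Parents always precede children,
        so index order is a topological (depth-first compatible) order.
    length_um:
        Strictly positive compartment lengths in µm.
    xyz:
        Optional (N, 3) midpoint coordinates in µm.
    radius_um:
        Optional per-compartment radius in µm.
    """

    parent: np.ndarray
    length_um: np.ndarray
    xyz: np.ndarray | None = None
    radius_um: np.ndarray | None = None
    swc_type: np.ndarray | None = None

    _children: list[list[int]] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=int)
        length = np.asarray(self.length_um, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "length_um", length)
        n = parent.size
        if length.size != n:
            raise ValueError("parent and length_um must have equal length")
        roots = np.flatnonzero(parent == NO_PARENT)
        if roots.size != 1:
            raise SWCStructureError(f"tree must have exactly one root, found {roots.size}")
        if roots[0] != 0:
            raise ValueError("root must be compartment 0")
        if np.any(parent[1:] >= np.arange(1, n)):
            raise ValueError("parents must precede children in index order")
        if np.any(length <= 0):
            raise ValueError("all compartment lengths must be strictly positive")
        children: list[list[int]] = [[] for _ in range(n)]
        for child in range(1, n):
            children[parent[child]].append(child)
        object.__setattr__(self, "_children", children)
        # N compartments, N-1 edges, one root: guaranteed by the checks above.

    @property
    def n(self) -> int:
        return self.parent.size

    @property
    def n_edges(self) -> int:
        return self.n - 1

    @property
    def root(self) -> int:
        return 0

    def children(self, i: int) -> list[int]:
        return list(self._children[i])

    @property
    def edges(self) -> np.ndarray:
        """(N-1, 2) array of (parent, child) pairs, ordered by child index."""
        child = np.arange(1, self.n)
        return np.column_stack([self.parent[child], child])

    @property
    def path_distance_um(self) -> np.ndarray:
        """Path distance from the root to each compartment's distal end (µm)."""
        dist = np.zeros(self.n)
        for i in range(1, self.n):
            dist[i] = dist[self.parent[i]] + self.length_um[i]
        return dist

    @property
    def total_length_um(self) -> float:
        """Total cable length: sum of all compartment lengths."""
        return float(self.length_um.sum())

    def edge_midpoint_distance_um(self) -> np.ndarray:
        """Distance between compartment midpoints along each edge (µm)."""
        p, c = self.edges.T
        return 0.5 * (self.length_um[p] + self.length_um[c])

    def is_tip(self, i: int) -> bool:
        return not self._children[i]

    @property
    def tips(self) -> np.ndarray:
        return np.array([i for i in range(self.n) if not self._children[i]], dtype=int)

    def to_edge_dataframe(self) -> pd.DataFrame:
        path = self.path_distance_um
        child = np.arange(1, self.n)
        return pd.DataFrame(
            {
                "child_id": child,
                "parent_id": self.parent[child],
                "length_um": self.length_um[child],
                "path_dist_um": path[child],
            }
        )

    def to_edge_csv(self, path) -> None:
        self.to_edge_dataframe().to_csv(path, index=False)


def build_tree(parent, length_um, **kwargs) -> CompartmentTree:
    """Construct a tree from an explicit parent array (root first, -1 parent)."""
    return CompartmentTree(np.asarray(parent), np.asarray(length_um), **kwargs)


def build_cable(n_compartments: int, total_length_um: float) -> CompartmentTree:
    """Unbranched cable rooted at one end (the soma).

    Each compartment has length ``total_length_um / n_compartments``; the sum
    of compartment lengths equals the requested total exactly.
    """
    n = int(n_compartments)
    if n < 2:
        raise ValueError("a cable needs at least 2 compartments")
    if total_length_um <= 0:
        raise ValueError("total_length_um must be positive")
    delta = total_length_um / n
    parent = np.arange(-1, n - 1)
    length = np.full(n, delta)
    x = (np.arange(n) + 0.5) * delta
    xyz = np.column_stack([x, np.zeros(n), np.zeros(n)])
    return CompartmentTree(parent, length, xyz=xyz)


def read_swc(path, include_types=None) -> CompartmentTree:
    """Read an SWC reconstruction into a compartment tree.

    SWC is the standard 7-column whitespace format: id, type, x, y, z,
    radius, parent. Inter-sample Euclidean distances become compartment
    lengths. All soma samples (type 1) collapse into a single root
    compartment at the soma centroid.

    Parameters
    ----------
    include_types:
        Optional collection of SWC type codes to keep (soma is always kept).
        By default every type is retained.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(f"line {lineno}: expected 7 columns, got {len(fields)}")
            try:
                sid = int(fields[0])
                stype = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCFormatError(f"line {lineno}: {exc}") from exc
            rows.append((sid, stype, x, y, z, r, parent, lineno))
    if not rows:
        raise SWCFormatError("empty SWC file")

    soma_ids = {sid for sid, stype, *_ in rows if stype == 1}
    if include_types is not None:
        keep = set(include_types) | {1}
        rows = [r for r in rows if r[1] in keep]

    if any(r[5] <= 0 for r in rows):
        warnings.warn("SWC file contains non-positive radii", stacklevel=2)

    # Collapse the soma to a single root at the centroid of type-1 samples.
    if soma_ids:
        soma_rows = [r for r in rows if r[1] == 1]
        centroid = np.mean([[r[2], r[3], r[4]] for r in soma_rows], axis=0)
        soma_radius = float(np.mean([r[5] for r in soma_rows]))
    else:
        first = rows[0]
        if first[6] != -1:
            raise SWCFormatError("first sample must be a root (parent -1)")
        soma_ids = {first[0]}
        centroid = np.array(first[2:5], dtype=float)
        soma_radius = first[5]

    index_of: dict[int, int] = {sid: 0 for sid in soma_ids}
    parents = [NO_PARENT]
    lengths = [max(soma_radius, 1.0)]  # root length is nominal, kept positive
    coords = [centroid]
    radii = [soma_radius]
    types = [1]

    for sid, stype, x, y, z, r, pid, lineno in rows:
        if sid in soma_ids and stype == 1:
            continue
        if pid == -1:
            raise SWCStructureError(f"line {lineno}: multiple roots (sample {sid} has no parent)")
        if pid not in index_of:
            raise SWCFormatError(f"line {lineno}: parent id {pid} not previously defined")
        if sid in index_of:
            raise SWCFormatError(f"line {lineno}: duplicate sample id {sid}")
        pidx = index_of[pid]
        pos = np.array([x, y, z])
        seg = float(np.linalg.norm(pos - coords[pidx]))
        if seg <= 0:
            seg = 1e-3  # coincident samples: keep lengths strictly positive
        index_of[sid] = len(parents)
        parents.append(pidx)
        lengths.append(seg)
        coords.append(pos)
        radii.append(r)
        types.append(stype)

    return CompartmentTree(
        np.array(parents),
        np.array(lengths),
        xyz=np.array(coords),
        radius_um=np.array(radii),
        swc_type=np.array(types),
    )


def _sections(tree: CompartmentTree) -> list[list[int]]:
    """Decompose a tree into maximal unbranched sections of compartments.

    A section is a chain of compartments ending at a branch point or a tip;
    the root compartment opens the first section. Branch points terminate the
    section they belong to, so branch locations survive resampling.
    """
    sections = []
    stack = [tree.root]
    while stack:
        start = stack.pop()
        sec = [start]
        node = start
        while len(tree._children[node]) == 1:
            node = tree._children[node][0]
            sec.append(node)
        sections.append(sec)
        stack.extend(reversed(tree._children[node]))
    return sections


def resample(tree: CompartmentTree, target_spacing_um: float) -> CompartmentTree:
    """Re-divide each unbranched section into ~``target_spacing_um`` pieces.

    Section total length is conserved exactly (each section of length S is
    split into ``round(S / spacing)`` equal compartments, at least one), and
    branch points are preserved. Resampling twice at the same spacing is a
    fixed point of the compartment count. A section shorter than the spacing
    collapses to a single compartment with a warning.
    """
    if target_spacing_um <= 0:
        raise ValueError("target_spacing_um must be positive")
    sections = _sections(tree)

    new_parent: list[int] = []
    new_length: list[float] = []
    # last new index of each *old* section-terminal compartment
    terminal_new: dict[int, int] = {}
    sec_of_start = {}

    for sec in sections:
        sec_len = float(tree.length_um[sec].sum())
        m = max(1, int(round(sec_len / target_spacing_um)))
        if sec_len < target_spacing_um:
            warnings.warn(
                f"section of length {sec_len:.3g} µm shorter than spacing "
                f"{target_spacing_um:.3g} µm; kept as a single compartment",
                stacklevel=2,
            )
        piece = sec_len / m
        old_parent = tree.parent[sec[0]]
        attach = NO_PARENT if old_parent == NO_PARENT else terminal_new[old_parent]
        for j in range(m):
            idx = len(new_parent)
            new_parent.append(attach if j == 0 else idx - 1)
            new_length.append(piece)
        terminal_new[sec[-1]] = len(new_parent) - 1
        sec_of_start[sec[0]] = True

    return CompartmentTree(np.array(new_parent), np.array(new_length))
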