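"""Abstract source spaces: coordinates, adjacency, hemispheres, pairing.

A "source" here is a virtual current dipole reduced to an abstract channel
with a spatial position, graph adjacency, a hemisphere label, and (when
defined) a left-right pairing used for hemispheric comparisons.  Group
data are per-subject scalar maps or kernels over a shared space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SourceSpace", "SourceMap", "GroupDataset", "make_grid_space"]


@dataclass(frozen=True)
class SourceSpace:
    coords: np.ndarray  # (S, d) positions
    edges: np.ndarray  # (m, 2) undirected adjacency
    hemisphere: np.ndarray  # (S,) 'L'/'R'
    pairs: np.ndarray | None = None  # (S/2, 2) [left, right] index pairs

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.atleast_2d(np.asarray(self.coords, float).T).T)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere))
        if self.pairs is not None:
            pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
            left, right = pairs[:, 0], pairs[:, 1]
            if len(set(left.tolist())) != len(left) or len(set(right.tolist())) != len(right):
                raise ValueError("pairing must be a bijection between hemispheres")
            object.__setattr__(self, "pairs", pairs)

    @property
    def n_sources(self) -> int:
        return len(self.hemisphere)

    def hemi_index(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def subspace(self, index: np.ndarray) -> "SourceSpace":
        """Restriction to a source subset, re-indexing edges."""
        index = np.asarray(index)
        lookup = -np.ones(self.n_sources, dtype=np.int64)
        lookup[index] = np.arange(len(index))
        keep = (lookup[self.edges[:, 0]] >= 0) & (lookup[self.edges[:, 1]] >= 0)
        edges = lookup[self.edges[keep]]
        return SourceSpace(
            coords=self.coords[index],
            edges=edges,
            hemisphere=self.hemisphere[index],
            pairs=None,
        )


@dataclass
class SourceMap:
    """Per-source scalar values on a space."""

    values: np.ndarray
    space: SourceSpace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.space.n_sources:
            raise ValueError("value count does not match the source space")


@dataclass
class GroupDataset:
    """Per-subject maps (or kernels) with group labels on a shared space.

    ``values`` is ``(n_subjects, S)`` for scalar maps or
    ``(n_subjects, S, T)`` for per-source kernels.
    """

    values: np.ndarray
    labels: list[str]
    space: SourceSpace
    roi: np.ndarray | None = None  # boolean mask over sources

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per subject required")
        if self.values.shape[1] != self.space.n_sources:
            raise ValueError("subject maps do not match the source space")
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if len(self.roi) != self.space.n_sources:
                raise ValueError("ROI mask does not match the source space")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def group(self, label: str) -> np.ndarray:
        idx = [i for i, l in enumerate(self.labels) if l == label]
        return self.values[idx]


def make_grid_space(
    n_per_hemi: int = 10, n_rows: int = 1, spacing: float = 1.0
) -> SourceSpace:
    """Two mirrored rectangular grids of sources, one per hemisphere.

    Each hemisphere is an ``n_rows x (n_per_hemi / n_rows)`` grid with
    4-neighbour adjacency; hemispheres are spatially separated and not
    connected in the graph.  Source ``i`` of the left grid pairs with
    source ``i`` of the right grid.
    """
    if n_per_hemi % n_rows:
        raise ValueError("n_per_hemi must be divisible by n_rows")
    n_cols = n_per_hemi // n_rows
    ys, xs = np.divmod(np.arange(n_per_hemi), n_cols)
    base = np.column_stack([xs * spacing, ys * spacing]).astype(float)
    gap = (n_cols + 10) * spacing  # keep hemispheres well separated
    coords = np.vstack([base + [-gap, 0.0], base + [gap, 0.0]])
    edges = []
    for hemi_off in (0, n_per_hemi):
        for i in range(n_per_hemi):
            r, c = divmod(i, n_cols)
            if c + 1 < n_cols:
                edges.append((hemi_off + i, hemi_off + i + 1))
            if r + 1 < n_rows:
                edges.append((hemi_off + i, hemi_off + i + n_cols))
    hemisphere = np.array(["L"] * n_per_hemi + ["R"] * n_per_hemi)
    pairs = np.column_stack(
        [np.arange(n_per_hemi), np.arange(n_per_hemi) + n_per_hemi]
    )
    return SourceSpace(coords, np.array(edges), hemisphere, pairs)
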