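"""Quadrant-weight (QW) enrichment scoring of 2-D chemical spaces.

Each embedding is partitioned into a 3x3 grid of regions spanning the
bounding box of the DILI-positive compounds (equal thirds per axis; the
outer rows and columns extend to infinity so every compound falls in
exactly one cell). Each cell receives an enrichment score

    QW = ((A - NA) * 100 / n) / 2

where A and NA are the counts of DILI-positive and DILI-negative compounds
in the cell and n is the total dataset size. QW > 0 marks a region enriched
with DILI-positive compounds, QW < 0 one enriched with negatives, and
|QW| <= 50 always. Both coordinates of every compound are then multiplied
by its cell's QW, stretching enriched regions away from the origin and
collapsing balanced (QW = 0) regions onto it.

An alternative ``literal`` formula, -(A*100)/n + (NA*100/n)/2, is exposed
for comparison; its sign behavior differs from the enrichment
interpretation above and it is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import Embedding2D
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

QW_FORMULAS = ("prose", "literal")


def quadrant_weight(A: int, NA: int, n: int, formula: str = "prose") -> float:
    """Enrichment score of one region.

    Parameters
    ----------
    A, NA
        Counts of DILI-positive / DILI-negative compounds in the region.
    n
        Total number of compounds in the dataset (not in the region).
    formula
        ``prose`` (default): QW = ((A - NA) * 100 / n) / 2, positive iff the
        region holds more positives than negatives, bounded in [-50, 50].
        ``literal``: -(A*100)/n + (NA*100/n)/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if A < 0 or NA < 0 or A + NA > n:
        raise ValueError(f"invalid counts A={A}, NA={NA}, n={n}")
    if formula == "prose":
        return ((A - NA) * 100.0 / n) / 2.0
    if formula == "literal":
        return -(A * 100.0) / n + (NA * 100.0 / n) / 2.0
    raise ConfigurationError(f"unknown QW formula {formula!r}; expected one of {QW_FORMULAS}")


@dataclass
class QuadrantGrid:
    """k x k region boundaries with per-cell counts and QW values.

    ``x_edges``/``y_edges`` hold k+1 ascending edge positions. Cell (i, j)
    = row i (y), column j (x); membership uses half-open intervals
    [lo, hi) except the last bin of each axis, which is closed, and the
    outer cells extend to +/- infinity so assignment is total.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_A: np.ndarray  # k x k positive counts
    cell_NA: np.ndarray  # k x k negative counts
    cell_qw: np.ndarray  # k x k QW values
    n_total: int
    formula: str = "prose"

    @property
    def k(self) -> int:
        return len(self.x_edges) - 1

    def assign(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices (row, col) for each coordinate pair."""
        coords = np.asarray(coords, dtype=float)
        col = np.clip(np.searchsorted(self.x_edges, coords[:, 0], side="right") - 1, 0, self.k - 1)
        row = np.clip(np.searchsorted(self.y_edges, coords[:, 1], side="right") - 1, 0, self.k - 1)
        return row, col

    def qw_of(self, coords: np.ndarray) -> np.ndarray:
        row, col = self.assign(coords)
        return self.cell_qw[row, col]

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: edges, A, NA, QW."""
        rows = []
        for i in range(self.k):
            for j in range(self.k):
                rows.append(
                    {
                        "row": i,
                        "col": j,
                        "x_lo": self.x_edges[j],
                        "x_hi": self.x_edges[j + 1],
                        "y_lo": self.y_edges[i],
                        "y_hi": self.y_edges[i + 1],
                        "A": int(self.cell_A[i, j]),
                        "NA": int(self.cell_NA[i, j]),
                        "QW": self.cell_qw[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class WeightedEmbedding:
    """QW-weighted (and later normalized) coordinates of one space."""

    representation: str
    coords: np.ndarray
    source_grid: QuadrantGrid | None = None
    compound_ids: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("weighted coordinates must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("weighted embedding contains non-finite coordinates")

    @property
    def space_name(self) -> str:
        return self.representation

    @property
    def axis_names(self) -> tuple[str, str]:
        prefix = "NWtSNE" if self.normalized else "WtSNE"
        return (f"{prefix} 1", f"{prefix} 2")

    @property
    def n_compounds(self) -> int:
        return self.coords.shape[0]


def _axis_edges(lo: float, hi: float, fallback: tuple[float, float], k: int, axis: str):
    if hi > lo:
        return np.linspace(lo, hi, k + 1)
    logger.warning(
        "positive compounds are coincident on the %s axis; "
        "falling back to the full-dataset range",
        axis,
    )
    flo, fhi = fallback
    if fhi <= flo:  # entire dataset coincident too
        flo, fhi = flo - 0.5, fhi + 0.5
    return np.linspace(flo, fhi, k + 1)


def build_quadrant_grid(
    embedding: Embedding2D,
    labels: np.ndarray,
    k: int = 3,
    formula: str = "prose",
) -> QuadrantGrid:
    """Partition *embedding* into k x k regions and score each with QW.

    The grid spans the bounding box of the DILI-positive compounds, split
    into equal thirds per axis (k=3 default); compounds outside the box are
    clamped into the nearest outer cell. A degenerate positive box on an
    axis falls back to the full-dataset range on that axis, with a warning.
    """
    labels = np.asarray(labels, dtype=bool)
    coords = embedding.coords
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels length does not match embedding size")
    if not labels.any():
        raise ValueError("quadrant grid requires at least one DILI-positive compound")
    if k < 1:
        raise ConfigurationError("grid size must be >= 1")

    pos = coords[labels]
    x_edges = _axis_edges(
        pos[:, 0].min(), pos[:, 0].max(), (coords[:, 0].min(), coords[:, 0].max()), k, "x"
    )
    y_edges = _axis_edges(
        pos[:, 1].min(), pos[:, 1].max(), (coords[:, 1].min(), coords[:, 1].max()), k, "y"
    )
    n = coords.shape[0]
    grid = QuadrantGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        cell_A=np.zeros((k, k), dtype=int),
        cell_NA=np.zeros((k, k), dtype=int),
        cell_qw=np.zeros((k, k), dtype=float),
        n_total=n,
        formula=formula,
    )
    row, col = grid.assign(coords)
    for i in range(k):
        for j in range(k):
            in_cell = (row == i) & (col == j)
            grid.cell_A[i, j] = int((in_cell & labels).sum())
            grid.cell_NA[i, j] = int((in_cell & ~labels).sum())
            grid.cell_qw[i, j] = quadrant_weight(
                grid.cell_A[i, j], grid.cell_NA[i, j], n, formula=formula
            )
    return grid


def apply_weights(
    embedding: Embedding2D, grid: QuadrantGrid, qw_offset: float = 0.0
) -> WeightedEmbedding:
    """Multiply both coordinates of each compound by its cell's QW.

    A zero-QW cell collapses its compounds onto the origin; this is the
    method's behavior, not an artifact. ``qw_offset`` adds a constant to
    every cell's QW before multiplying, for users who need an injective
    map (default 0 = faithful).
    """
    qw = grid.qw_of(embedding.coords) + qw_offset
    coords = embedding.coords * qw[:, None]
    return WeightedEmbedding(
        representation=embedding.representation,
        coords=coords,
        source_grid=grid,
        compound_ids=list(embedding.compound_ids),
    )
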