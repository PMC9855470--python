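"""Min-max normalization and summation into the consensus chemical space.

After quadrant weighting, each space's coordinates are normalized per axis,

    NWtSNE = (WtSNE - MIN(WtSNE)) / (MAX(WtSNE) - MIN(WtSNE)),

so every axis spans [0, 1], and the consensus coordinates are the
element-wise sum of the normalized coordinates across the fused spaces.
With k fused spaces every consensus coordinate lies in [0, k].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import descriptors, embedding as embedding_mod, weighting
from .errors import AlignmentError, ConfigurationError, StageError, TooFewCompoundsError
from .io_data import LabeledDataset

logger = logging.getLogger(__name__)

#: Named representation subsets for the consensus pipeline.
PRESETS: dict[str, tuple[str, ...]] = {
    "all5": ("maccs", "rdkit_fp", "ecfp4", "properties", "invitro"),
    "rdkit+invitro": ("rdkit_fp", "invitro"),
}


@dataclass
class ConsensusEmbedding:
    """Fused 2-D coordinates plus the list of source representations."""

    coords: np.ndarray
    sources: list[str]
    compound_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("consensus coordinates must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("consensus embedding contains non-finite coordinates")

    @property
    def space_name(self) -> str:
        return "consensus(" + "+".join(self.sources) + ")"

    @property
    def axis_names(self) -> tuple[str, str]:
        return ("consensus tSNE 1", "consensus tSNE 2")

    @property
    def n_compounds(self) -> int:
        return self.coords.shape[0]


def normalize(weighted: weighting.WeightedEmbedding) -> weighting.WeightedEmbedding:
    """Min-max normalize each axis onto [0, 1].

    A constant axis (max == min) maps to all-zeros, with a warning.
    """
    if weighted.n_compounds < 2:
        raise TooFewCompoundsError("normalization requires at least 2 compounds")
    coords = weighted.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    out = np.zeros_like(coords)
    for ax in range(2):
        if span[ax] > 0:
            out[:, ax] = (coords[:, ax] - lo[ax]) / span[ax]
        else:
            logger.warning(
                "axis %d of space %s is constant; normalized to all-zeros",
                ax,
                weighted.representation,
            )
    return weighting.WeightedEmbedding(
        representation=weighted.representation,
        coords=out,
        source_grid=weighted.source_grid,
        compound_ids=list(weighted.compound_ids),
        normalized=True,
    )


def fuse(
    spaces: Sequence[weighting.WeightedEmbedding],
    multipliers: Sequence[float] | None = None,
) -> ConsensusEmbedding:
    """Sum normalized spaces element-wise into the consensus space.

    All spaces must be normalized and share one compound order. The
    optional per-space ``multipliers`` default to 1 (the method sums
    without coefficients).
    """
    spaces = list(spaces)
    if len(spaces) < 2:
        raise ConfigurationError("fusion requires at least 2 spaces")
    ref_ids = list(spaces[0].compound_ids)
    for sp in spaces:
        if not sp.normalized:
            raise ConfigurationError(f"space {sp.representation!r} is not normalized")
        if list(sp.compound_ids) != ref_ids:
            raise AlignmentError(
                f"compound order of space {sp.representation!r} does not match "
                f"{spaces[0].representation!r}"
            )
    if multipliers is None:
        multipliers = [1.0] * len(spaces)
    if len(multipliers) != len(spaces):
        raise ConfigurationError("one multiplier per space required")
    # sum addends in sorted order per coordinate so the result is exactly
    # invariant to the order the spaces are given in (fp addition is not
    # associative)
    stacked = np.stack([m * sp.coords for sp, m in zip(spaces, multipliers)])
    stacked.sort(axis=0)
    coords = stacked.sum(axis=0)
    return ConsensusEmbedding(
        coords=coords,
        sources=[sp.representation for sp in spaces],
        compound_ids=ref_ids,
    )


def run_consensus(
    dataset: LabeledDataset,
    representations: Sequence[str] | str = "all5",
    reducer: str = "tsne",
    params: Mapping | None = None,
    seed: int = embedding_mod.DEFAULT_SEED,
    grid_size: int = 3,
    qw_formula: str = "prose",
    weighted: bool = True,
    return_intermediates: bool = False,
):
    """Full pipeline: featurize, embed, grid, weight, normalize, fuse.

    ``representations`` is a preset name (``all5``, ``rdkit+invitro``) or an
    explicit list of at least two representation names. With
    ``weighted=False`` the quadrant-weight stage is skipped (coordinates
    are normalized and summed directly), which quantifies the weighting's
    contribution. Each t-SNE uses a distinct deterministic seed derived
    from ``seed``.

    Returns the :class:`ConsensusEmbedding`, or a dict of intermediates
    (feature matrices, embeddings, grids, weighted/normalized spaces,
    consensus) when ``return_intermediates`` is set.
    """
    if isinstance(representations, str):
        try:
            reps = PRESETS[representations]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {representations!r}; expected one of {sorted(PRESETS)}"
            ) from None
    else:
        reps = tuple(representations)
    for r in reps:
        if r not in descriptors.REPRESENTATIONS:
            raise ConfigurationError(f"unknown representation {r!r}")
    if len(reps) < 2:
        raise ConfigurationError("consensus requires at least 2 representations")

    labels = dataset.labels
    out: dict = {"features": {}, "embeddings": {}, "grids": {}, "normalized": {}}
    normalized_spaces: list[weighting.WeightedEmbedding] = []
    for i, rep in enumerate(reps):
        try:
            feats = descriptors.featurize(dataset, rep)
        except Exception as exc:
            raise StageError(f"featurize[{rep}]: {exc}") from exc
        try:
            emb = embedding_mod.embed(
                feats, reducer=reducer, params=dict(params) if params else None,
                seed=seed + i,
            )
        except Exception as exc:
            raise StageError(f"embed[{rep}]: {exc}") from exc
        try:
            if weighted:
                grid = weighting.build_quadrant_grid(
                    emb, labels, k=grid_size, formula=qw_formula
                )
                wemb = weighting.apply_weights(emb, grid)
                out["grids"][rep] = grid
            else:
                wemb = weighting.WeightedEmbedding(
                    representation=rep,
                    coords=emb.coords,
                    compound_ids=list(emb.compound_ids),
                )
        except Exception as exc:
            raise StageError(f"weight[{rep}]: {exc}") from exc
        try:
            norm = normalize(wemb)
        except Exception as exc:
            raise StageError(f"normalize[{rep}]: {exc}") from exc
        out["features"][rep] = feats
        out["embeddings"][rep] = emb
        out["normalized"][rep] = norm
        normalized_spaces.append(norm)

    try:
        consensus = fuse(normalized_spaces)
    except Exception as exc:
        raise StageError(f"fuse: {exc}") from exc
    out["consensus"] = consensus
    return out if return_intermediates else consensus


def plot_space(space, labels, path, title: str | None = None):
    """Scatter plot of one space, red = DILI-positive, blue = negative."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels, dtype=bool)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        space.coords[~labels, 0], space.coords[~labels, 1],
        s=12, c="tab:blue", label="DILI-negative", alpha=0.7,
    )
    ax.scatter(
        space.coords[labels, 0], space.coords[labels, 1],
        s=12, c="tab:red", label="DILI-positive", alpha=0.7,
    )
    ax.set_xlabel(space.axis_names[0])
    ax.set_ylabel(space.axis_names[1])
    ax.set_title(title or space.space_name)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
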