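"""Dimensionality reduction of feature matrices to 2-D chemical spaces.

Each feature matrix is reduced independently, yielding the "multiverse" of
alternative 2-D chemical-space representations of one dataset. The default
reducer is Barnes-Hut t-SNE with perplexity 30, 1000 iterations and
theta 0.5; PCA (top-2 scores of the column-centered matrix) is the linear
alternative. Euclidean distance is used on every representation, including
bit vectors, where it is monotone in Hamming distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE

from .descriptors import FeatureMatrix
from .errors import ConfigurationError, TooFewCompoundsError

logger = logging.getLogger(__name__)

#: t-SNE defaults
TSNE_DEFAULTS: dict = {"perplexity": 30.0, "iterations": 1000, "theta": 0.5}
DEFAULT_SEED = 42


@dataclass
class Embedding2D:
    """2-D coordinates of one representation, rows in dataset order."""

    representation: str
    coords: np.ndarray
    reducer: str
    params: dict = field(default_factory=dict)
    compound_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding coordinates must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")

    @property
    def space_name(self) -> str:
        return self.representation

    @property
    def axis_names(self) -> tuple[str, str]:
        if self.reducer == "pca":
            return ("PC 1", "PC 2")
        return ("tSNE 1", "tSNE 2")

    @property
    def n_compounds(self) -> int:
        return self.coords.shape[0]


def _pca_2d(values: np.ndarray) -> np.ndarray:
    """Top-2 principal-component scores of the column-centered matrix.

    Sign convention: the largest-magnitude loading of each component is
    forced positive, so axes are reproducible across row orders.
    """
    centered = values - values.mean(axis=0)
    # SVD is deterministic and handles n_features >> n_samples
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:2]
    scores = centered @ comps.T
    out = np.zeros((values.shape[0], 2))
    for k in range(min(2, comps.shape[0])):
        lead = comps[k, np.argmax(np.abs(comps[k]))]
        sign = 1.0 if lead >= 0 else -1.0
        out[:, k] = sign * scores[:, k]
    return out


def embed(
    matrix: FeatureMatrix,
    reducer: str = "tsne",
    params: dict | None = None,
    seed: int = DEFAULT_SEED,
) -> Embedding2D:
    """Reduce *matrix* to two dimensions.

    For ``tsne``, ``params`` may set ``perplexity`` (default 30),
    ``iterations`` (default 1000) and ``theta`` (default 0.5); the
    perplexity is shrunk with a warning when it reaches the (n-1)/3
    feasibility limit. Deterministic for fixed inputs and seed.
    """
    n = matrix.n_compounds
    if n < 4:
        raise TooFewCompoundsError(f"embedding requires at least 4 compounds, got {n}")
    if reducer == "pca":
        coords = _pca_2d(matrix.values)
        return Embedding2D(matrix.representation, coords, "pca", {}, list(matrix.compound_ids))
    if reducer != "tsne":
        raise ConfigurationError(f"unknown reducer {reducer!r}; expected 'tsne' or 'pca'")

    p = dict(TSNE_DEFAULTS)
    if params:
        p.update(params)
    perplexity = float(p["perplexity"])
    limit = (n - 1) / 3
    if perplexity >= limit:
        # keep strictly below the feasibility limit
        new_perp = max(1.0, np.floor(limit * 10) / 10 - 0.1)
        logger.warning(
            "perplexity %.1f infeasible for n=%d; shrunk to %.1f", perplexity, n, new_perp
        )
        perplexity = new_perp
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=int(p["iterations"]),
        angle=float(p["theta"]),
        method="barnes_hut",
        metric="euclidean",
        init="pca" if matrix.values.std(axis=0).any() else "random",
        random_state=seed,
    )
    coords = np.asarray(tsne.fit_transform(matrix.values), dtype=float)
    used = {"perplexity": perplexity, "iterations": int(p["iterations"]),
            "theta": float(p["theta"]), "seed": seed}
    return Embedding2D(matrix.representation, coords, "tsne", used, list(matrix.compound_ids))
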