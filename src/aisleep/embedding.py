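"""2-D manifold embedding of per-epoch PSD rows (0.2-30 Hz).

The embedder is consumed as a dependency with a fixed contract: given the
same input, seed and hyperparameters it returns the same coordinates, and
downstream staging code reads nothing from it except ``coords``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from aisleep.spectral import PSDMatrix

MIN_EPOCHS = 20


@dataclass
class Embedding2D:
    coords: np.ndarray  # (n_epochs, 2)
    seed: int


def embed_psd(
    psd: PSDMatrix,
    fmin: float = 0.2,
    fmax: float = 30.0,
    n_components: int = 2,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    standardize: bool = False,
) -> Embedding2D:
    """Project PSD rows restricted to [fmin, fmax] into two dimensions.

    Deterministic for a fixed seed. Raises if there are fewer epochs than the
    neighborhood size, advising parameter reduction.
    """
    import umap  # deferred: numba compilation makes this import expensive

    mask = psd.grid.band_mask(fmin, fmax, strict=False)
    if not mask.any():
        raise ValueError(f"frequency range [{fmin}, {fmax}] not covered by the grid")
    X = psd.values[:, mask]
    n = X.shape[0]
    if n < MIN_EPOCHS:
        raise ValueError(f"need at least {MIN_EPOCHS} epochs, got {n}")
    if n <= n_neighbors:
        raise ValueError(
            f"n_epochs={n} <= n_neighbors={n_neighbors}; reduce n_neighbors"
        )
    if standardize:
        std = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(std > 0, std, 1.0)
    reducer = umap.UMAP(
        n_components=n_components,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(X), dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return Embedding2D(coords=coords, seed=seed)
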