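"""PCA on latent mean vectors, per-cell PC coordinates, and decoder traversal.

Principal component analysis of the per-cell posterior means exposes the
dominant directions of behavioral variation learned by the VAE. Decoding
points moved along one component (holding the rest at zero) visualises the
cellular profile that component encodes; spatial maps of the per-cell
coordinates localise those behaviors in the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .vae import VAE


@dataclass
class PCDecomposition:
    """Centered PCA of latent means: orthonormal axes ordered by variance."""

    mean_latent: np.ndarray  # (d,)
    components: np.ndarray  # (k, d), rows orthonormal
    explained_variance: np.ndarray  # (k,) eigenvalues
    explained_variance_ratio: np.ndarray  # (k,), sums to 1

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(latent_means: np.ndarray) -> PCDecomposition:
    """Centered PCA retaining all components (up to min(cells − 1, d))."""
    X = np.asarray(latent_means, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("latent_means must be a 2-D array with at least 2 cells")
    pca = PCA(n_components=min(X.shape[0], X.shape[1])).fit(X)
    return PCDecomposition(
        mean_latent=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def project(pca: PCDecomposition, latent_means: np.ndarray) -> np.ndarray:
    """Per-cell coefficients alpha_i = (mu_z − mean) · e_i, shape (n, k)."""
    X = np.atleast_2d(np.asarray(latent_means, dtype=float))
    if X.shape[1] != pca.components.shape[1]:
        raise ValueError("latent dimension mismatch")
    return (X - pca.mean_latent) @ pca.components.T


def traverse_pc(
    vae: VAE,
    pca: PCDecomposition,
    component: int,
    alphas: np.ndarray | list[float],
    scale_mode: str = "sd",
) -> np.ndarray:
    """Decode latent points moved along one principal component.

    For each alpha the decoded point is ``mean_latent + alpha · s · e_i``
    with ``s`` the standard deviation of the component's coordinate across
    cells (``scale_mode='sd'``, so alpha is in standardized units matching
    the conventional ±3 range) or ``s = 1`` (``scale_mode='raw'``). The PCA
    mean is added back before decoding so traversal stays on the data
    manifold. Returns an array of shape (len(alphas), channels, T).
    """
    if not 0 <= component < pca.n_components:
        raise ValueError(f"component index {component} out of range")
    if scale_mode not in ("sd", "raw"):
        raise ValueError("scale_mode must be 'sd' or 'raw'")
    s = np.sqrt(pca.explained_variance[component]) if scale_mode == "sd" else 1.0
    alphas = np.asarray(alphas, dtype=float)
    Z = pca.mean_latent[None, :] + alphas[:, None] * s * pca.components[component][None, :]
    return vae.decode(Z)


def spatial_values(positions: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    """Tidy (x, y, value) table for spatial maps."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    values = np.asarray(values)
    if len(positions) != len(values):
        raise ValueError("positions and values must be aligned")
    return pd.DataFrame(
        {"x_um": positions[:, 0], "y_um": positions[:, 1], "value": values}
    )
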