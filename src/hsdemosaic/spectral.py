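"""Spectral response functions and Wasserstein band-pair weights.

Each band of a snapshot mosaic sensor has a spectral response curve over
wavelength. Bands whose responses overlap strongly image nearly the same
physical quantity, so their spatial structure is expected to correlate;
bands far apart in the spectrum correlate less. The gradient-consistency
regulariser therefore weights every band pair (c1, c2) by

    weight(c1, c2) = exp(-W(c1, c2) / tau)

where W(c1, c2) is the 1-Wasserstein (earth mover's) distance between
the two response curves, each normalised to a unit-mass distribution
over the wavelength grid, and tau is a temperature controlling how fast
the weight decays with spectral distance.

Units note: with wavelengths kept in nanometres the distances for a
VNIR sensor are O(100), and exp(-W/0.1) underflows for every off-
diagonal pair. By default the wavelength grid is rescaled to [0, 1]
over its span before computing distances, which makes the default
tau = 0.1 meaningful; pass ``normalise_wavelengths=False`` to keep
distances in nm (and choose tau accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

__all__ = [
    "SpectralResponseSet",
    "PairWeightMatrix",
    "wasserstein_distance_matrix",
    "pair_weights",
    "build_pair_weight_matrix",
    "save_weight_heatmap",
]


@dataclass(frozen=True)
class SpectralResponseSet:
    """Per-band spectral response curves on a common wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid (nm), length M.
    responses
        C×M non-negative array; row c is the response of band c. Every
        row must carry positive total mass.
    """

    wavelengths: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        r = np.asarray(self.responses, dtype=np.float64)
        if wl.ndim != 1 or len(wl) < 1:
            raise ValueError("wavelengths must be a 1-D grid")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if r.ndim != 2 or r.shape[1] != len(wl):
            raise ValueError(
                f"responses must be C×M with M={len(wl)}; got shape {r.shape}"
            )
        if np.any(r < 0):
            raise ValueError("responses must be non-negative")
        if np.any(r.sum(axis=1) <= 0):
            bad = np.where(r.sum(axis=1) <= 0)[0]
            raise ValueError(f"bands {bad.tolist()} have zero total response")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "responses", r)

    @property
    def n_bands(self) -> int:
        return self.responses.shape[0]

    # -- serialisation --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"wavelength": self.wavelengths}
        for c in range(self.n_bands):
            cols[f"band_{c}"] = self.responses[c]
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralResponseSet":
        df = pd.read_csv(path)
        bands = [c for c in df.columns if c.startswith("band_")]
        bands.sort(key=lambda s: int(s.split("_")[1]))
        return cls(
            wavelengths=df["wavelength"].to_numpy(),
            responses=df[bands].to_numpy().T,
        )


def wasserstein_distance_matrix(
    responses: SpectralResponseSet, normalise_wavelengths: bool = True
) -> np.ndarray:
    """Pairwise 1-Wasserstein distances between unit-mass response curves.

    Each response row is treated as a discrete distribution on the
    wavelength grid (weights proportional to the response values). The
    result is a symmetric C×C matrix with zero diagonal.
    """
    wl = responses.wavelengths
    if normalise_wavelengths and len(wl) > 1:
        wl = (wl - wl[0]) / (wl[-1] - wl[0])
    C = responses.n_bands
    W = np.zeros((C, C), dtype=np.float64)
    for i in range(C):
        for j in range(i + 1, C):
            d = wasserstein_distance(
                wl, wl, responses.responses[i], responses.responses[j]
            )
            W[i, j] = W[j, i] = d
    return W


def pair_weights(W: np.ndarray, tau: float) -> np.ndarray:
    """Exponential similarity weights exp(-W/tau) with exact unit diagonal."""
    if tau <= 0:
        raise ValueError(f"temperature tau must be positive; got {tau}")
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    out = np.exp(-W / float(tau))
    np.fill_diagonal(out, 1.0)
    return out


@dataclass(frozen=True)
class PairWeightMatrix:
    """Cached Wasserstein distances and their exponential weights.

    ``weights[c1, c2] = exp(-W[c1, c2]/tau)``: symmetric, unit diagonal,
    entries in (0, 1]. These are constants of the loss, computed once per
    response set, never learned.
    """

    W: np.ndarray
    weights: np.ndarray
    tau: float

    @property
    def n_bands(self) -> int:
        return self.W.shape[0]

    def save_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights).to_csv(path, index=False)


def build_pair_weight_matrix(
    responses: SpectralResponseSet,
    tau: float = 0.1,
    normalise_wavelengths: bool = True,
) -> PairWeightMatrix:
    """Compute and cache the band-pair weight matrix for a response set."""
    W = wasserstein_distance_matrix(responses, normalise_wavelengths=normalise_wavelengths)
    return PairWeightMatrix(W=W, weights=pair_weights(W, tau), tau=float(tau))


def save_weight_heatmap(pwm: PairWeightMatrix, path: str | Path) -> None:
    """Render the pair-weight matrix as a heatmap (lighter = closer bands)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pwm.weights, cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xlabel("band")
    ax.set_ylabel("band")
    ax.set_title(f"exp(-W/tau), tau={pwm.tau:g}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
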