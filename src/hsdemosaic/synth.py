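"""Synthetic hyperspectral scenes, sensor responses and snapshot mosaics.

The generator emulates the statistical structure that the
gradient-consistency prior exploits in real VNIR (400–1000 nm) scenes
of natural and biological materials:

* scenes are piecewise-constant material maps (random ellipses at
  mixed scales over a background, as in natural imagery where
  structure spans scales), so all spectral bands share the same edge
  set;
* each material has a smooth random reflectance spectrum (low-order
  cosine series, clipped positive) — spectra of natural objects and
  tissue vary slowly with wavelength;
* band images are the material spectra projected through overlapping
  Gaussian-profile sensor response curves, so adjacent bands are
  strongly correlated — the inter-band redundancy the method's premise
  requires and that real overlapping-filter sensors exhibit;
* an optical point-spread blur (Gaussian, sub-pixel sigma) applied per
  band, since real optics never deliver mathematically sharp steps;
* additive Gaussian sensor noise applied to the MEASUREMENT (the
  snapshot), not to the scene: truth cubes stay clean, matching how
  read/shot noise arises physically and how demosaicking benchmarks
  score reconstructions. The noise stream is seeded independently of
  the geometry stream so a noise ladder holds the scenes fixed.

Snapshots are produced from the generated truth cubes by the exact
mosaic degradation operator, which makes every pipeline stage testable
without any external dataset. Default sizes (16 bands, 4×4 mosaic,
64×64 scenes) keep a full simulate→train→evaluate cycle desk-scale.

What this generator does NOT emulate: specular highlights, motion
blur, smoke, sensor cross-talk, or the spectral statistics of any
specific tissue type — conclusions from these fixtures are about the
algorithmic pipeline, not about clinical image quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msfa import MSFAPattern, canonical_pattern, degrade
from .spectral import SpectralResponseSet

__all__ = ["SceneSpec", "make_response_set", "make_scene", "make_dataset", "Dataset"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene family.

    Wavelengths span ``wl_min``–``wl_max`` nm with ``n_wavelengths``
    samples; ``smoothness`` is the number of cosine harmonics in the
    material spectra (fewer = smoother); ``psf_sigma`` is the optical
    point-spread blur in pixels (0 disables it); ``noise_sd`` is the sd
    of the additive Gaussian sensor noise applied to snapshot
    measurements, on the [0, 1] intensity scale (truth cubes are
    noise-free).
    """

    X: int = 64
    Y: int = 64
    C: int = 16
    n_materials: int = 25
    wl_min: float = 400.0
    wl_max: float = 1000.0
    n_wavelengths: int = 121
    smoothness: int = 3
    bandwidth: float = 45.0
    psf_sigma: float = 0.6
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if min(self.X, self.Y, self.C, self.n_materials, self.n_wavelengths) < 1:
            raise ValueError("all dimensions must be positive")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be non-negative")
        if self.wl_max <= self.wl_min:
            raise ValueError("wavelength range must be increasing")


def make_response_set(
    C: int = 16,
    wavelengths: np.ndarray | None = None,
    peak_jitter: float = 5.0,
    bandwidth: float = 30.0,
    seed: int = 0,
) -> SpectralResponseSet:
    """Gaussian-profile band responses with evenly spaced, jittered peaks.

    Peaks are spread uniformly across the interior of the grid with
    seeded jitter (sd ``peak_jitter`` nm); ``bandwidth`` is the Gaussian
    sigma in nm, chosen so adjacent bands overlap substantially — the
    premise of the Wasserstein pair weighting.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if wavelengths is None:
        wavelengths = np.linspace(400.0, 1000.0, 121)
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    rng = np.random.default_rng(seed)
    lo, hi = wavelengths[0], wavelengths[-1]
    margin = 0.05 * (hi - lo)
    peaks = np.linspace(lo + margin, hi - margin, C)
    peaks = peaks + rng.normal(0.0, peak_jitter, size=C)
    responses = np.exp(-0.5 * ((wavelengths[None, :] - peaks[:, None]) / bandwidth) ** 2)
    return SpectralResponseSet(wavelengths=wavelengths, responses=responses)


def _material_spectra(
    n_materials: int, wavelengths: np.ndarray, smoothness: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random reflectance spectra in (0, 1]: low-order cosine series."""
    M = len(wavelengths)
    t = np.linspace(0.0, 1.0, M)
    spectra = np.empty((n_materials, M))
    for m in range(n_materials):
        coeffs = rng.normal(0.0, 1.0, size=smoothness) / (1.0 + np.arange(smoothness))
        s = np.zeros(M)
        for k, a in enumerate(coeffs):
            s += a * np.cos(np.pi * (k + 1) * t + rng.uniform(0, 2 * np.pi))
        # map to a positive reflectance-like range, keep away from 0
        s = 0.55 + 0.4 * s / (np.abs(s).max() + 1e-12)
        spectra[m] = np.clip(s, 0.05, 1.0)
    return spectra


def _material_map(X: int, Y: int, n_materials: int, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant label map: random ellipses at mixed scales
    painted over a background, later ellipses overwriting earlier ones.
    Semi-axes span 3–25 % of the image side so edges occur at both
    coarse and fine scales."""
    labels = np.zeros((X, Y), dtype=np.int64)
    xs, ys = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    for m in range(1, n_materials):
        cx, cy = rng.uniform(0, X), rng.uniform(0, Y)
        ax = rng.uniform(0.03, 0.25) * X
        ay = rng.uniform(0.03, 0.25) * Y
        theta = rng.uniform(0, np.pi)
        u = (xs - cx) * np.cos(theta) + (ys - cy) * np.sin(theta)
        v = -(xs - cx) * np.sin(theta) + (ys - cy) * np.cos(theta)
        labels[(u / ax) ** 2 + (v / ay) ** 2 <= 1.0] = m
    return labels


def make_scene(
    spec: SceneSpec,
    responses: SpectralResponseSet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one noise-free scene; returns (cube, material label map).

    The cube is the material spectra integrated against the band
    response curves (unit-normalised), yielding X×Y×C band intensities
    in (0, 1], optionally blurred by the optical PSF. Sensor noise
    belongs to the measurement, not the scene: it is added to
    snapshots by :func:`make_dataset`.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if responses is None:
        responses = make_response_set(
            spec.C,
            np.linspace(spec.wl_min, spec.wl_max, spec.n_wavelengths),
            bandwidth=spec.bandwidth,
            seed=spec.seed,
        )
    if responses.n_bands != spec.C:
        raise ValueError("response set band count does not match spec.C")
    labels = _material_map(spec.X, spec.Y, spec.n_materials, rng)
    spectra = _material_spectra(spec.n_materials, responses.wavelengths, spec.smoothness, rng)
    # project each material spectrum through the unit-mass response curves
    r = responses.responses / responses.responses.sum(axis=1, keepdims=True)
    band_values = spectra @ r.T  # (n_materials, C)
    cube = band_values[labels]  # (X, Y, C)
    if spec.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter

        cube = np.stack(
            [
                gaussian_filter(cube[:, :, c], spec.psf_sigma, mode="nearest")
                for c in range(spec.C)
            ],
            axis=-1,
        )
    return cube, labels


@dataclass(frozen=True)
class Dataset:
    """A simulated study: training snapshots and held-out test pairs.

    ``train_truths`` holds the clean cubes behind the training
    snapshots; unsupervised training never touches them, supervised
    baselines pair them with ``train_snapshots``.
    """

    train_snapshots: tuple[np.ndarray, ...]
    test_pairs: tuple[tuple[np.ndarray, np.ndarray], ...]  # (snapshot, truth)
    responses: SpectralResponseSet
    pattern: MSFAPattern
    train_truths: tuple[np.ndarray, ...] = ()

    @property
    def train_pairs(self) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
        return tuple(zip(self.train_snapshots, self.train_truths))


def make_dataset(
    spec: SceneSpec | None = None,
    pattern: MSFAPattern | None = None,
    n_train: int = 8,
    n_test: int = 4,
    seed: int = 0,
) -> Dataset:
    """Simulate a full dataset: truths, snapshots and sensor responses.

    Snapshots are the exact degradation of the (clean) truth cubes plus
    additive Gaussian measurement noise of sd ``spec.noise_sd``, clipped
    to [0, 1]. Scene geometry and measurement noise come from
    independent seed streams (a noise ladder holds the scenes fixed),
    and train and test scenes are disjoint by stream.
    """
    if n_train < 0 or n_test < 0:
        raise ValueError("n_train and n_test must be >= 0")
    spec = spec or SceneSpec()
    pattern = pattern or canonical_pattern(4)
    if pattern.n_bands != spec.C:
        raise ValueError("pattern band count does not match spec.C")
    root = np.random.SeedSequence([seed, spec.seed])
    resp_ss, train_ss, test_ss, noise_ss = root.spawn(4)
    responses = make_response_set(
        spec.C,
        np.linspace(spec.wl_min, spec.wl_max, spec.n_wavelengths),
        bandwidth=spec.bandwidth,
        seed=int(resp_ss.generate_state(1)[0] % (2**31)),
    )
    noise_rng = np.random.default_rng(noise_ss)

    def scenes(ss: np.random.SeedSequence, count: int):
        return [
            make_scene(spec, responses=responses, rng=np.random.default_rng(child))[0]
            for child in ss.spawn(count)
        ]

    def measure(cube: np.ndarray) -> np.ndarray:
        snap = degrade(cube, pattern)
        if spec.noise_sd > 0:
            snap = np.clip(
                snap + noise_rng.normal(0.0, spec.noise_sd, size=snap.shape), 0.0, 1.0
            )
        return snap

    train_truths = tuple(scenes(train_ss, n_train))
    train = tuple(measure(c) for c in train_truths)
    test = tuple((measure(c), c) for c in scenes(test_ss, n_test))
    return Dataset(
        train_snapshots=train,
        test_pairs=test,
        responses=responses,
        pattern=pattern,
        train_truths=train_truths,
    )
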