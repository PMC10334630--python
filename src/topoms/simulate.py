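"""Synthetic MALDI mass spectrometry images and labeled spectra.

The simulator emulates the structure of ground-truth MS images used for
noise studies: a rectangular pixel grid carrying one spectrum per pixel on a
shared m/z axis (default range 500-2000), with two morphological regions — a
circle in the top-left quadrant and a square in the bottom-right quadrant —
plus background.  True peaks (default 50) are placed uniformly without
replacement on the m/z grid and assigned to the circle only, the square
only, or both (shared); a pixel's spectrum is a constant baseline plus the
Gaussian profiles of the peaks active in its region.  Images are then
contaminated with additive Gaussian noise (clamped at zero to keep
intensities nonnegative) or additive Poisson noise, whose single rate
parameter at high values produces noise peaks rivalling the signal.

Rendering follows the mean-spectrum convention: a pixel's displayed value is
the arithmetic mean of its spectrum, and the persistence-denoised image is
the mean of the sparse vector of retained k%-persistence values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix import IntensityMatrix
from .persistence import reduced_persistence_transformation, top_k_percent

__all__ = [
    "ImageSpec",
    "NoiseSpec",
    "MSImage",
    "LabeledSpectra",
    "simulate_image",
    "add_noise",
    "mean_spectrum_image",
    "denoise_image",
    "simulate_labeled_spectra",
    "evaluate_peak_recovery",
]

TRUTH_DTYPE = np.dtype(
    [("bin", np.int64), ("region", "U6"), ("amplitude", np.float64)]
)


@dataclass(frozen=True)
class ImageSpec:
    """Configuration of a synthetic ground-truth MS image.

    ``peak_width`` is the Gaussian profile standard deviation in m/z units;
    the default keeps the 50 default peaks on the 500-2000 range mostly
    non-overlapping.  ``shared_fraction`` controls how many peaks are active
    in both regions.  Amplitudes are log-normal around ``amplitude_mean``.
    """

    width: int = 30
    height: int = 30
    mz_min: float = 500.0
    mz_max: float = 2000.0
    n_bins: int = 1000
    n_peaks: int = 50
    baseline: float = 0.0
    peak_width: float = 2.0
    min_separation: float = 12.0
    shared_fraction: float = 0.4
    amplitude_mean: float = 100.0
    amplitude_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be below mz_max")
        if self.n_peaks < 1:
            raise ValueError("need at least one peak")
        if self.n_peaks > self.n_bins:
            raise ValueError("cannot place more peaks than m/z bins")
        if self.baseline < 0:
            raise ValueError("baseline must be nonnegative")
        if self.width * self.height < 1:
            raise ValueError("image must contain at least one pixel")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: ``gaussian`` (sd) or ``poisson`` (lambda)."""

    kind: str = "gaussian"
    parameter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson"):
            raise ValueError("noise kind must be 'gaussian' or 'poisson'")
        if self.parameter < 0:
            raise ValueError("noise parameter must be nonnegative")


@dataclass(frozen=True)
class MSImage:
    """Pixel grid of spectra plus ground truth.

    ``data`` has shape ``(height, width, n_bins)``; ``truth_peaks`` lists
    (m/z bin, region, amplitude) for every true peak; ``region_masks`` maps
    'circle', 'square' and 'background' to boolean pixel masks.
    """

    mz_axis: np.ndarray
    data: np.ndarray
    truth_peaks: np.ndarray
    region_masks: dict
    baseline: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def active_bins(self, region: str) -> np.ndarray:
        """m/z bins of true peaks active in a region ('circle'/'square')."""
        mask = (self.truth_peaks["region"] == region) | (
            self.truth_peaks["region"] == "both"
        )
        return self.truth_peaks["bin"][mask]


def _region_masks(height: int, width: int) -> dict:
    rows, cols = np.mgrid[0:height, 0:width]
    cy, cx = height / 4.0, width / 4.0
    radius = min(height, width) / 5.0
    circle = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
    side = min(height, width) * 0.4
    r0, c0 = int(round(height * 0.55)), int(round(width * 0.55))
    square = (
        (rows >= r0) & (rows < r0 + side) & (cols >= c0) & (cols < c0 + side)
    )
    square &= ~circle
    background = ~(circle | square)
    return {"circle": circle, "square": square, "background": background}


def _place_peaks(rng, mz, n_peaks, min_separation):
    """Uniform peak placement with a minimum m/z separation.

    Distinct molecular species occupy distinct masses; enforcing a minimum
    gap keeps default peak profiles resolvable as separate local maxima.
    Greedy acceptance over a random permutation of the grid stays uniform
    over admissible configurations for practical densities.
    """
    accepted = []
    for b in rng.permutation(mz.size):
        if all(abs(mz[b] - mz[a]) >= min_separation for a in accepted):
            accepted.append(int(b))
            if len(accepted) == n_peaks:
                return np.sort(np.asarray(accepted))
    raise ValueError(
        f"cannot place {n_peaks} peaks with separation {min_separation} "
        f"on the m/z grid"
    )


def simulate_image(spec: ImageSpec) -> MSImage:
    """Simulate a noiseless ground-truth MS image, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    mz = np.linspace(spec.mz_min, spec.mz_max, spec.n_bins)
    bins = _place_peaks(rng, mz, spec.n_peaks, spec.min_separation)
    amplitudes = spec.amplitude_mean * np.exp(
        rng.normal(0.0, spec.amplitude_sigma, spec.n_peaks)
    )
    n_shared = int(round(spec.shared_fraction * spec.n_peaks))
    n_circle = (spec.n_peaks - n_shared + 1) // 2
    regions = np.array(
        ["both"] * n_shared
        + ["circle"] * n_circle
        + ["square"] * (spec.n_peaks - n_shared - n_circle),
        dtype="U6",
    )
    rng.shuffle(regions)

    truth = np.empty(spec.n_peaks, dtype=TRUTH_DTYPE)
    truth["bin"] = bins
    truth["region"] = regions
    truth["amplitude"] = amplitudes

    # Gaussian profile of every peak on the shared axis.
    profiles = amplitudes[:, None] * np.exp(
        -((mz[None, :] - mz[bins][:, None]) ** 2) / (2.0 * spec.peak_width**2)
    )
    circle_spec = spec.baseline + profiles[(regions == "circle") | (regions == "both")].sum(axis=0)
    square_spec = spec.baseline + profiles[(regions == "square") | (regions == "both")].sum(axis=0)
    background_spec = np.full(spec.n_bins, spec.baseline)

    masks = _region_masks(spec.height, spec.width)
    data = np.empty((spec.height, spec.width, spec.n_bins))
    data[masks["background"]] = background_spec
    data[masks["circle"]] = circle_spec
    data[masks["square"]] = square_spec
    return MSImage(
        mz_axis=mz, data=data, truth_peaks=truth, region_masks=masks,
        baseline=spec.baseline,
    )


def add_noise(image: MSImage, noise: NoiseSpec) -> MSImage:
    """Contaminate every (pixel, bin) intensity; ground truth is carried through."""
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian":
        if noise.parameter == 0:
            data = image.data.copy()
        else:
            data = np.clip(
                image.data + rng.normal(0.0, noise.parameter, image.data.shape), 0.0, None
            )
    else:  # poisson
        if noise.parameter == 0:
            data = image.data.copy()
        else:
            data = image.data + rng.poisson(noise.parameter, image.data.shape)
    return replace(image, data=data)


def mean_spectrum_image(image: MSImage) -> np.ndarray:
    """Pixel value = arithmetic mean of the pixel's spectrum."""
    return image.data.mean(axis=2)


def denoise_image(image: MSImage, k: float) -> np.ndarray:
    """Persistence-denoised rendering.

    Per pixel: reduced persistence transformation, retention of the k% most
    persistent features, scatter to the dense m/z grid, then the mean of
    that sparse vector.  For suitable k under low noise the region contrast
    of the ground truth reappears.
    """
    if not 0 < k <= 100:
        raise ValueError(f"k must be in (0, 100], got {k}")
    height, width, n_bins = image.data.shape
    out = np.empty((height, width))
    for r in range(height):
        for c in range(width):
            feats = reduced_persistence_transformation(image.data[r, c])
            kept = top_k_percent(feats, k)
            out[r, c] = kept["persistence"].sum() / n_bins
    return out


def evaluate_peak_recovery(noisy: MSImage, tolerance_bins: int = 1) -> np.ndarray:
    """Per-pixel precision of k%-persistence peak retention.

    For every pixel with at least one active true peak, k is set to the
    oracle fraction (active true peaks over detected peaks) so that exactly
    the true number of features is retained, and the precision is the share
    of retained positions within ``tolerance_bins`` of an active true peak.
    Returns the precision array over the evaluated pixels.
    """
    height, width = noisy.shape
    precisions = []
    for region in ("circle", "square"):
        bins = np.sort(noisy.active_bins(region))
        if bins.size == 0:
            continue
        for r, c in zip(*np.nonzero(noisy.region_masks[region])):
            feats = reduced_persistence_transformation(noisy.data[r, c])
            m = feats.size
            k = min(100.0, 100.0 * bins.size / m)
            kept = top_k_percent(feats, k)
            idx = np.searchsorted(bins, kept["index"])
            idx = np.clip(idx, 0, bins.size - 1)
            left = bins[np.maximum(idx - 1, 0)]
            near = np.minimum(
                np.abs(bins[idx] - kept["index"]), np.abs(left - kept["index"])
            )
            precisions.append(np.mean(near <= tolerance_bins))
    return np.asarray(precisions)


@dataclass(frozen=True)
class LabeledSpectra:
    """Two-class spectrum set with group ids, ready for the CV pipeline."""

    X: IntensityMatrix
    labels: np.ndarray
    groups: np.ndarray
    class_bins: tuple


def simulate_labeled_spectra(
    n_per_class: int = 100,
    n_shared: int = 10,
    n_exclusive: int = 5,
    groups: int = 4,
    noise_sd: float = 10.0,
    seed: int = 1234,
    n_bins: int = 300,
    mz_min: float = 500.0,
    mz_max: float = 2000.0,
    peak_width: float = 6.0,
    min_separation: float = 24.0,
    amplitude_mean: float = 100.0,
    amplitude_sigma: float = 0.2,
    scale_sigma: float = 0.1,
) -> LabeledSpectra:
    """Simulate two classes of spectra sharing some peaks and owning others.

    The two classes share ``n_shared`` peak positions and each own
    ``n_exclusive`` exclusive ones; every spectrum is its class template
    times a log-normal per-spectrum scale, plus additive Gaussian noise
    clamped at zero.  Group ids are assigned round-robin.  Deterministic
    given the seed.
    """
    if min(n_per_class, n_shared, n_exclusive, groups) < 1:
        raise ValueError("all counts must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    mz = np.linspace(mz_min, mz_max, n_bins)
    total_peaks = n_shared + 2 * n_exclusive
    if total_peaks > n_bins:
        raise ValueError("cannot place more peaks than m/z bins")
    bins = rng.permutation(_place_peaks(rng, mz, total_peaks, min_separation))
    shared = bins[:n_shared]
    excl0 = bins[n_shared : n_shared + n_exclusive]
    excl1 = bins[n_shared + n_exclusive :]
    amplitudes = amplitude_mean * np.exp(rng.normal(0.0, amplitude_sigma, total_peaks))

    profiles = amplitudes[:, None] * np.exp(
        -((mz[None, :] - mz[bins][:, None]) ** 2) / (2.0 * peak_width**2)
    )
    base0 = profiles[: n_shared + n_exclusive].sum(axis=0)
    base1 = np.concatenate([profiles[:n_shared], profiles[n_shared + n_exclusive :]]).sum(
        axis=0
    )

    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    scales = np.exp(rng.normal(0.0, scale_sigma, n))
    base = np.where(labels[:, None] == 0, base0[None, :], base1[None, :])
    X = base * scales[:, None]
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
    X = np.clip(X, 0.0, None)
    ids = np.array([f"s{i:05d}" for i in range(n)])
    matrix = IntensityMatrix(mz_axis=mz, values=X, spectrum_ids=ids)
    group_ids = np.arange(n) % groups + 1
    return LabeledSpectra(
        X=matrix,
        labels=labels,
        groups=group_ids,
        class_bins=(np.sort(np.concatenate([shared, excl0])),
                    np.sort(np.concatenate([shared, excl1]))),
    )
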