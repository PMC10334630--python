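"""Persistence transformation of a mass spectrum.

The persistence transformation maps a spectrum to one feature triple
``t(x) = (x, a*, a+)`` per peak, where ``a* = f(x)`` is the birth of the
topological feature created by the peak in the upper-level-set filtration and
``a+`` is its death — the highest threshold at which the peak's component
becomes path-connected to a component led by a taller (or elder equal-height)
peak.  The persistence ``p = a* - a+`` is the relative height of the peak and
serves as its importance score.  The global maximum never merges; its death
is the global minimum of the spectrum by convention.

Merging follows the elder rule: at a merge the component whose leading peak
has the higher birth survives.  Ties in birth are broken deterministically by
the order induced by the m/z axis — the peak at the smaller index is elder.

The reduced transformation keeps only ``(x, p)``, i.e. two stored values per
peak, which is the payload used for denoising and classification.

Implementation: indices are processed in descending order of intensity
(ties left to right) while active components are maintained as index
intervals with O(1) endpoint bookkeeping — an iterative sweep, so the
recursion limit never bounds the spectrum length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectrum import Spectrum, as_spectrum, condense_plateaus

__all__ = [
    "PEAK_DTYPE",
    "FEATURE_DTYPE",
    "REDUCED_DTYPE",
    "MergeTree",
    "find_peaks",
    "persistence_transformation",
    "reduced_persistence_transformation",
    "to_persistence_diagram",
    "build_merge_tree",
    "top_k_percent",
]

PEAK_DTYPE = np.dtype([("index", np.int64), ("apex", np.float64)])

FEATURE_DTYPE = np.dtype(
    [
        ("index", np.int64),
        ("position", np.float64),
        ("birth", np.float64),
        ("death", np.float64),
        ("persistence", np.float64),
    ]
)

REDUCED_DTYPE = np.dtype(
    [("index", np.int64), ("position", np.float64), ("persistence", np.float64)]
)


def find_peaks(spectrum) -> np.ndarray:
    """Plateau-collapsed local maxima of a spectrum, in ascending index order.

    An interior plateau is a peak iff both flanking values are strictly
    lower; a boundary plateau is a peak iff its single flanking value is
    strictly lower.  A constant spectrum yields one peak at index 0.  Each
    plateau is represented by its leftmost index.

    Returns a structured array with fields ``index`` and ``apex``.
    """
    spectrum = as_spectrum(spectrum)
    vals, starts = condense_plateaus(spectrum.intensities)
    mask = _condensed_peak_mask(vals)
    out = np.empty(int(mask.sum()), dtype=PEAK_DTYPE)
    out["index"] = starts[mask]
    out["apex"] = vals[mask]
    return out


def _condensed_peak_mask(vals: np.ndarray) -> np.ndarray:
    """Local-maximum mask on a condensed (no equal neighbours) sequence."""
    n = vals.size
    mask = np.ones(n, dtype=bool)
    if n > 1:
        mask[1:] = vals[1:] > vals[:-1]
        mask[:-1] &= vals[:-1] > vals[1:]
    return mask


def _sweep(vals: np.ndarray):
    """Single descending sweep over a condensed sequence.

    Returns ``(peaks, deaths, parents)`` in condensed coordinates, where
    ``peaks`` are the condensed indices of local maxima in ascending order,
    ``deaths[i]`` is the death value of the feature led by ``peaks[i]`` and
    ``parents[i]`` is the position (within ``peaks``) of the feature whose
    component absorbs it, or ``-1`` for the root.
    """
    n = vals.size
    # Descending by value; stable sort on the negated values keeps equal
    # values in ascending index order, i.e. the induced order.
    order = np.argsort(-vals, kind="stable")

    active = np.zeros(n, dtype=bool)
    lo = np.empty(n, dtype=np.int64)  # lo[r] = left endpoint of interval ending at r
    hi = np.empty(n, dtype=np.int64)  # hi[l] = right endpoint of interval starting at l
    elder = {}  # left endpoint -> condensed index of the component's elder peak
    death = {}  # condensed peak index -> death value
    parent = {}  # condensed peak index -> condensed index of absorbing elder

    for i in order:
        a = vals[i]
        left = i > 0 and active[i - 1]
        right = i + 1 < n and active[i + 1]
        active[i] = True
        if not left and not right:
            lo[i] = i
            hi[i] = i
            elder[i] = i
        elif left and not right:
            l = lo[i - 1]
            hi[l] = i
            lo[i] = l
        elif right and not left:
            r = hi[i + 1]
            elder[i] = elder.pop(i + 1)
            hi[i] = r
            lo[r] = i
        else:
            l = lo[i - 1]
            r = hi[i + 1]
            e_left = elder[l]
            e_right = elder.pop(i + 1)
            # Elder rule: higher birth survives; equal births resolved by
            # the induced order (e_left < i < e_right always holds).
            if vals[e_left] >= vals[e_right]:
                survivor, loser = e_left, e_right
            else:
                survivor, loser = e_right, e_left
            death[loser] = a
            parent[loser] = survivor
            elder[l] = survivor
            hi[l] = r
            lo[r] = l

    (root,) = elder.values()
    death[root] = float(vals.min())
    parent[root] = -1

    peaks = np.flatnonzero(_condensed_peak_mask(vals))
    pos_of = {c: k for k, c in enumerate(peaks)}
    deaths = np.array([death[c] for c in peaks])
    parents = np.array(
        [parent[c] if parent[c] < 0 else pos_of[parent[c]] for c in peaks],
        dtype=np.int64,
    )
    return peaks, deaths, parents


def persistence_transformation(spectrum) -> np.ndarray:
    """Compute the feature triples ``(x, a*, a+)`` of a spectrum.

    One triple per plateau-collapsed peak; trivial (non-peak) points are
    omitted.  Returns a structured array with fields ``index``, ``position``,
    ``birth``, ``death`` and ``persistence``, ordered by index.
    """
    spectrum = as_spectrum(spectrum)
    vals, starts = condense_plateaus(spectrum.intensities)
    peaks, deaths, _ = _sweep(vals)
    out = np.empty(peaks.size, dtype=FEATURE_DTYPE)
    out["index"] = starts[peaks]
    out["position"] = spectrum.positions[starts[peaks]]
    out["birth"] = vals[peaks]
    out["death"] = deaths
    out["persistence"] = out["birth"] - out["death"]
    return out


def reduced_persistence_transformation(spectrum) -> np.ndarray:
    """Reduced transformation: keep only ``(x, p)`` per peak.

    Stores two payload values per feature, ordered by index.
    """
    full = persistence_transformation(spectrum)
    out = np.empty(full.size, dtype=REDUCED_DTYPE)
    out["index"] = full["index"]
    out["position"] = full["position"]
    out["persistence"] = full["persistence"]
    return out


def to_persistence_diagram(features: np.ndarray) -> np.ndarray:
    """Project feature triples to the classical persistence diagram.

    Discards positions: ``(x, a*, a+) -> (a*, a+)``.  Returns an ``(m, 2)``
    array of (birth, death) pairs; compare as a multiset.
    """
    features = np.asarray(features)
    return np.column_stack([features["birth"], features["death"]])


@dataclass(frozen=True)
class MergeTree:
    """Merge tree of the upper-level-set filtration of one spectrum.

    ``features`` are the feature triples ordered by index; ``parent[i]`` is
    the position within ``features`` of the feature whose component absorbs
    feature ``i`` at its death threshold (``-1`` for the root).  The root is
    the global-maximum feature.
    """

    features: np.ndarray
    parent: np.ndarray
    root: int

    def __post_init__(self) -> None:
        if int(np.sum(self.parent < 0)) != 1:
            raise ValueError("merge tree must have exactly one root")


def build_merge_tree(spectrum) -> MergeTree:
    """Build the merge tree of a spectrum.

    When the two merging components tie in elder birth, the surviving
    (parent) feature is the smaller-index candidate.
    """
    spectrum = as_spectrum(spectrum)
    vals, starts = condense_plateaus(spectrum.intensities)
    peaks, deaths, parents = _sweep(vals)
    features = np.empty(peaks.size, dtype=FEATURE_DTYPE)
    features["index"] = starts[peaks]
    features["position"] = spectrum.positions[starts[peaks]]
    features["birth"] = vals[peaks]
    features["death"] = deaths
    features["persistence"] = features["birth"] - features["death"]
    root = int(np.flatnonzero(parents < 0)[0])
    return MergeTree(features=features, parent=parents, root=root)


def top_k_percent(features: np.ndarray, k: float) -> np.ndarray:
    """Retain the ``k%`` most persistent features of one spectrum.

    Keeps ``ceil(k/100 * m)`` features (at least one for any valid ``k``),
    so the global feature — which attains the maximal persistence and, among
    equally persistent features, the smallest index — is always retained.
    Ties at the cutoff are broken in favour of the smaller index.  The
    result is ordered by index.
    """
    if not 0 < k <= 100:
        raise ValueError(f"k must be in (0, 100], got {k}")
    features = np.asarray(features)
    m = features.size
    if m == 0:
        return features
    m_keep = math.ceil(k / 100.0 * m)
    # Sort by persistence descending, index ascending for ties.
    order = np.lexsort((features["index"], -features["persistence"]))
    kept = np.sort(order[:m_keep])
    return features[kept]
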