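"""Spectrum-matrix to persistence-matrix transform.

An intensity matrix ``X`` holds ``n`` spectra on a shared ascending m/z axis
of length ``q``.  ``transform_matrix`` maps each row independently through
the reduced persistence transformation and k% extraction and scatters the
retained persistences back onto the dense grid, producing the nonnegative
persistence matrix ``Z`` whose entry ``z_ij`` is the persistence of spectrum
``i`` at m/z index ``j`` (zero off retained peaks).  The dense layout keeps
``Z`` drop-in compatible with classifiers expecting a fixed ``q`` columns.

The extraction is applied per spectrum: each row keeps the
``ceil(k/100 * m_i)`` most persistent of its own ``m_i`` peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .persistence import reduced_persistence_transformation, top_k_percent
from .spectrum import as_spectrum

__all__ = ["IntensityMatrix", "PersistenceMatrix", "transform_matrix"]


@dataclass(frozen=True)
class IntensityMatrix:
    """``n x q`` nonnegative intensity matrix on a shared ascending m/z axis."""

    mz_axis: np.ndarray
    values: np.ndarray
    spectrum_ids: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_axis, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        ids = np.asarray(self.spectrum_ids)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if vals.shape[0] < 1:
            raise ValueError("matrix must contain at least one spectrum")
        if mz.ndim != 1 or mz.size != vals.shape[1]:
            raise ValueError("m/z axis length must equal the number of columns")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z axis must be strictly ascending")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite and nonnegative")
        if ids.shape != (vals.shape[0],):
            raise ValueError("one spectrum id per row required")
        object.__setattr__(self, "mz_axis", mz)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spectrum_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PersistenceMatrix:
    """``n x q`` matrix of persistences, zero off retained peaks."""

    mz_axis: np.ndarray
    values: np.ndarray
    spectrum_ids: np.ndarray
    k_used: float

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def transform_matrix(X: IntensityMatrix, k: float = 100.0) -> PersistenceMatrix:
    """Transform an intensity matrix into the persistence matrix ``Z``.

    Each row is processed independently: reduced persistence transformation,
    retention of the ``k%`` most persistent features, and scattering of the
    retained persistences to their m/z indices on the dense grid.
    """
    if not 0 < k <= 100:
        raise ValueError(f"k must be in (0, 100], got {k}")
    Z = np.zeros_like(X.values)
    for i in range(X.n):
        feats = reduced_persistence_transformation(
            as_spectrum(X.values[i], positions=X.mz_axis)
        )
        kept = top_k_percent(feats, k)
        Z[i, kept["index"]] = kept["persistence"]
    return PersistenceMatrix(
        mz_axis=X.mz_axis, values=Z, spectrum_ids=X.spectrum_ids, k_used=float(k)
    )
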