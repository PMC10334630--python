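"""A single mass spectrum: an ascending m/z grid with nonnegative intensities.

A spectrum is the basic unit of every computation in this package.  It is the
discrete realization of a nonnegative function ``f`` on an ordered set of m/z
positions: ``f(x_j) = s_j`` for the ``j``-th grid point.  Path-connectivity on
an upper-level set corresponds to contiguity of grid indices whose intensity
clears the threshold, which is the unique faithful discretization for sampled
one-dimensional curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "as_spectrum"]


@dataclass(frozen=True)
class Spectrum:
    """One mass spectrum.

    Parameters
    ----------
    positions
        m/z values, strictly ascending, length ``q >= 1``.
    intensities
        Nonnegative intensity values, same length as ``positions``.
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1:
            raise ValueError("positions and intensities must be 1-D")
        if pos.size == 0:
            raise ValueError("spectrum must contain at least one point")
        if pos.size != inten.size:
            raise ValueError(
                f"length mismatch: {pos.size} positions vs {inten.size} intensities"
            )
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("m/z positions must be strictly ascending")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.positions.size

    @property
    def q(self) -> int:
        """Number of m/z grid points."""
        return self.positions.size


def as_spectrum(obj, positions=None) -> Spectrum:
    """Coerce ``obj`` to a :class:`Spectrum`.

    Accepts an existing :class:`Spectrum` (returned unchanged) or a 1-D
    array of intensities, in which case ``positions`` defaults to the
    integer grid ``0 .. q-1``.
    """
    if isinstance(obj, Spectrum):
        return obj
    inten = np.asarray(obj, dtype=float)
    if positions is None:
        positions = np.arange(inten.size, dtype=float)
    return Spectrum(positions=np.asarray(positions, dtype=float), intensities=inten)


def condense_plateaus(intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive intensities to single points.

    Returns ``(values, starts)`` where ``starts[i]`` is the leftmost original
    index of the ``i``-th run.  Plateau collapse makes every condensed value
    differ from its neighbours, so births, merges, and local maxima are
    unambiguous on the condensed sequence.
    """
    v = np.asarray(intensities, dtype=float)
    if v.size == 0:
        raise ValueError("empty spectrum")
    keep = np.empty(v.size, dtype=bool)
    keep[0] = True
    np.not_equal(v[1:], v[:-1], out=keep[1:])
    starts = np.flatnonzero(keep)
    return v[starts], starts
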