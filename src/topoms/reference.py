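"""Brute-force reference for the persistence transformation.

This module recomputes births, deaths and merge parents by an explicit
descending threshold sweep over the raw grid with a disjoint-set structure,
exactly as the upper-level-set filtration is defined: indices are activated
in descending order of intensity (left to right within one value), a birth
is recorded when an activated index has no active neighbour, and a merge is
recorded when an activated index bridges two components — the component
whose elder has the smaller birth (on ties, the larger elder index) dies at
the current value.  The surviving component's elder finally receives the
global minimum as its death.

The implementation is deliberately simple and independent of
:mod:`topoms.persistence`; it exists to cross-check that module and is
quadratic-friendly, not fast.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import DisjointSet

from .spectrum import as_spectrum

__all__ = ["sweep_persistence", "component_count_at"]


def component_count_at(intensities: np.ndarray, threshold: float) -> int:
    """Number of maximal contiguous index runs with intensity >= threshold."""
    m = np.asarray(intensities, dtype=float) >= threshold
    if m.size == 0:
        return 0
    return int(m[0]) + int(np.count_nonzero(m[1:] & ~m[:-1]))


def sweep_persistence(spectrum, record_counts: bool = False):
    """Descending threshold sweep with a disjoint set.

    Returns ``(features, parents)`` where ``features`` is a list of
    ``(index, birth, death)`` tuples sorted by index and ``parents`` maps
    each feature index to the index of the feature absorbing it at its
    death (``None`` for the root).  With ``record_counts=True`` a third
    element is returned: a list of ``(threshold, n_components)`` pairs
    observed after all indices of each distinct intensity were activated.
    """
    spectrum = as_spectrum(spectrum)
    vals = spectrum.intensities
    q = vals.size

    # Activation order: descending value, ascending index within ties.
    order = np.lexsort((np.arange(q), -vals))

    ds = DisjointSet()
    active = np.zeros(q, dtype=bool)
    elder = {}  # disjoint-set root -> grid index of the component's elder peak
    birth = {}  # elder grid index -> birth value
    death = {}
    parents = {}
    counts = []

    pos = 0
    while pos < q:
        a = vals[order[pos]]
        # Activate every index carrying this intensity, left to right.
        while pos < q and vals[order[pos]] == a:
            i = int(order[pos])
            pos += 1
            ds.add(i)
            active[i] = True
            neighbours = [j for j in (i - 1, i + 1) if 0 <= j < q and active[j]]
            if not neighbours:
                elder[ds[i]] = i
                birth[i] = float(a)
                continue
            for j in neighbours:
                ri, rj = ds[i], ds[j]
                if ri == rj:
                    continue
                ei = elder.pop(ri, None)
                ej = elder.pop(rj)
                if ei is None:
                    # i joined an existing component without founding one.
                    winner = ej
                else:
                    # Genuine merge of two components: elder rule with the
                    # induced order on ties.
                    if (birth[ei], -ei) >= (birth[ej], -ej):
                        winner, loser = ei, ej
                    else:
                        winner, loser = ej, ei
                    death[loser] = float(a)
                    parents[loser] = winner
                ds.merge(i, j)
                elder[ds[i]] = winner
        if record_counts:
            counts.append((float(a), len(elder)))

    (root_elder,) = elder.values()
    death[root_elder] = float(vals.min())
    parents[root_elder] = None

    # A non-peak plateau whose leftmost member activates before its taller
    # flank is reached founds a component that dies within the same
    # threshold pass, at persistence exactly zero.  Genuine peaks have
    # strictly lower flanks and therefore die strictly below their birth,
    # so these trivial births are exactly the non-root zero-persistence
    # records; drop them to honour the plateau-collapse convention.
    trivial = {
        idx
        for idx in death
        if idx != root_elder and death[idx] == birth[idx]
    }
    for idx in trivial:
        del death[idx]
        del parents[idx]

    features = sorted((idx, birth[idx], death[idx]) for idx in death)
    if record_counts:
        return features, parents, counts
    return features, parents
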