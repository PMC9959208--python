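"""Independent oracles shared by the test suite.

These deliberately re-derive results through routes disjoint from the
implementation: a naive O(nm) affine-gap dynamic program for local
alignment, graph connected components for clustering, and atomic
composition summation for peptide masses.
"""

from __future__ import annotations

import networkx as nx
from pyteomics import mass as pyteomass

from venomest.cluster import pairwise_overlap_identity


def blosum62_lut():
    import biotite.sequence.align as balign

    mat = balign.SubstitutionMatrix.std_protein_matrix()
    syms = list(mat.get_alphabet1())
    score = mat.score_matrix()
    return {
        s1: {s2: int(score[i][j]) for j, s2 in enumerate(syms)}
        for i, s1 in enumerate(syms)
    }


def sw_affine_score(a, b, lut, open_pen=11, ext_pen=1):
    """Naive affine-gap Smith-Waterman; a gap of length l costs
    open_pen + (l - 1) * ext_pen."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = lut[a[i - 1]][b[j - 1]]
            M[i][j] = max(
                0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            )
            X[i][j] = max(M[i - 1][j] - open_pen, X[i - 1][j] - ext_pen)
            Y[i][j] = max(M[i][j - 1] - open_pen, Y[i][j - 1] - ext_pen)
            best = max(best, M[i][j])
    return int(best)


def brute_force_components(records, min_overlap, min_identity_pct):
    """Clustering oracle: connected components of the exact similarity graph."""
    g = nx.Graph()
    g.add_nodes_from(r.id for r in records)
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            ov, ident = pairwise_overlap_identity(a.trimmed_seq, b.trimmed_seq)
            if ov >= min_overlap and ident >= min_identity_pct:
                g.add_edge(a.id, b.id)
    return {frozenset(c) for c in nx.connected_components(g)}


def composition_mass(seq, n_disulfides=0, amidated=False, average=False):
    """Peptide-mass oracle: atomic-composition summation (pyteomics)."""
    comp = pyteomass.Composition(sequence=seq)
    comp["H"] -= 2 * n_disulfides
    if amidated:
        comp["O"] -= 1
        comp["H"] += 1
        comp["N"] += 1
    return pyteomass.calculate_mass(composition=comp, average=average)
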