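"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written with a different mechanism from the
library code (itertools enumeration instead of DFS, per-codon arithmetic
instead of shared helpers, full DP instead of Biopython) so agreement is
meaningful.
"""
from __future__ import annotations

import itertools

import numpy as np


# --------------------------------------------------------------------------
# Defensin scanning
# --------------------------------------------------------------------------

def all_motif_spans(seq: str, forms) -> list[tuple[int, int]]:
    """Every (start, end) 0-based inclusive span realising any form, by
    exhaustive enumeration over cysteine subsets."""
    cys = [i for i, a in enumerate(seq) if a == "C"]
    spans = set()
    for form in forms:
        k = len(form) + 2                  # structural cys incl. CC doublet
        for combo in itertools.combinations(cys, k):
            if combo[-1] != combo[-2] + 1:
                continue
            gaps = [b - a - 1 for a, b in zip(combo, combo[1:-1])]
            if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, form)):
                if "*" not in seq[combo[0]:combo[-1] + 1]:
                    spans.add((combo[0], combo[-1]))
    return sorted(spans)


def select_spans(seq: str, spans: list[tuple[int, int]],
                 extend_trailing: bool, window: int, min_cys: int
                 ) -> list[tuple[int, int]]:
    """Leftmost-first non-overlapping selection with the scanner's
    tie-break (most cysteines in span, then longest), plus trailing
    extension, re-derived from the specification of the behaviour."""
    cys = [i for i, a in enumerate(seq) if a == "C"]

    def n_cys(span):
        return sum(1 for c in cys if span[0] <= c <= span[1])

    chosen = []
    cursor = 0
    while True:
        live = [s for s in spans if s[0] >= cursor]
        if not live:
            break
        first = min(s[0] for s in live)
        at_first = [s for s in live if s[0] == first]
        best = max(at_first, key=lambda s: (n_cys(s), s[1] - s[0]))
        chosen.append(best)
        cursor = best[1] + 1
    if not extend_trailing:
        return chosen
    extended = []
    for idx, (lo, hi) in enumerate(chosen):
        limit = chosen[idx + 1][0] if idx + 1 < len(chosen) else len(seq)
        absorbed, prev = [], hi
        for c in cys:
            if c <= hi or c >= limit:
                continue
            if c - prev - 1 <= window and "*" not in seq[prev:c + 1]:
                absorbed.append(c)
                prev = c
            else:
                break
        if len(absorbed) >= min_cys:
            hi = absorbed[-1]
        extended.append((lo, hi))
    return extended


def oracle_domains(seq: str, config) -> list[tuple[int, int]]:
    """0-based inclusive spans the scanner is expected to report."""
    spans = all_motif_spans(seq, config.forms)
    return select_spans(seq, spans, config.extend_trailing,
                        config.extension_window, config.extension_min_cys)


# --------------------------------------------------------------------------
# Six-frame coordinates
# --------------------------------------------------------------------------

def codon_interval_oracle(length: int, strand: str, offset: int,
                          index: int) -> tuple[int, int]:
    """1-based genomic interval of peptide[index], by explicit base lists."""
    if strand == "+":
        bases = [offset + 3 * index + k for k in range(3)]
    else:
        rc_positions = list(range(length - 1, -1, -1))
        bases = [rc_positions[offset + 3 * index + k] for k in range(3)]
    return min(bases) + 1, max(bases) + 1


# --------------------------------------------------------------------------
# Alignment (affine-gap DP, end gaps free)
# --------------------------------------------------------------------------

def nw_score(a: str, b: str, matrix, gap_open: float = 10.0,
             gap_extend: float = 0.5) -> float:
    """Optimal global score with free end gaps; gap of length k costs
    open + (k-1)*extend, matching the aligner's convention."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)   # gap in b (moving along a)
    Iy = np.full((n + 1, m + 1), neg)   # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = 0.0                  # free leading end gap
    for j in range(1, m + 1):
        Iy[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i-1][j-1], Ix[i-1][j-1], Iy[i-1][j-1]) + s
            Ix[i][j] = max(M[i-1][j] - gap_open, Ix[i-1][j] - gap_extend,
                           Iy[i-1][j] - gap_open)
            Iy[i][j] = max(M[i][j-1] - gap_open, Iy[i][j-1] - gap_extend,
                           Ix[i][j-1] - gap_open)
    # free trailing end gaps: best over last row/column of M
    best = max(M[n][m], Ix[n][m], Iy[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m], Ix[i][m] if i else neg)
    for j in range(m + 1):
        best = max(best, M[n][j], Iy[n][j] if j else neg)
    # the fully-disjoint layout (both sequences in end gaps) scores zero
    return float(max(best, 0.0))


# --------------------------------------------------------------------------
# Clustering / evaluation
# --------------------------------------------------------------------------

def closure_clusters(loci, max_gap: int) -> list[frozenset]:
    """Transitive closure of the pairwise 'gap <= max_gap' relation."""
    groups = []
    for locus in loci:
        linked = [g for g in groups if any(
            l.scaffold_id == locus.scaffold_id
            and (max(l.start, locus.start) - min(l.end, locus.end) - 1
                 <= max_gap)
            for l in g)]
        merged = {locus}
        for g in linked:
            merged |= g
            groups.remove(g)
        groups.append(merged)
    return [frozenset(g) for g in groups]


def max_bipartite_matches(call_iv, truth_iv, min_frac: float = 0.5) -> int:
    """Maximum one-to-one matching size via networkx, as the independent
    check of the evaluator's greedy matching."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from((("c", i) for i in range(len(call_iv))))
    g.add_nodes_from((("t", j) for j in range(len(truth_iv))))
    for i, c in enumerate(call_iv):
        for j, t in enumerate(truth_iv):
            if c[0] != t[0] or c[1] != t[1]:
                continue
            ol = min(c[3], t[3]) - max(c[2], t[2]) + 1
            if ol > 0 and ol >= min_frac * (c[3] - c[2] + 1) \
                    and ol >= min_frac * (t[3] - t[2] + 1):
                g.add_edge(("c", i), ("t", j))
    return len(nx.algorithms.matching.max_weight_matching(
        g, maxcardinality=True))


def random_peptide(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet),
                                                     size=length))
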