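"""Independent pure-Python reference implementations used as test oracles.

Everything here is deliberately written without the package's scoring code
(and without scipy's rank machinery): ranks, Pearson correlation, the tree
traversal and the top-set bookkeeping are all re-derived from first
principles so agreement with the package is a real cross-check.
"""

from __future__ import annotations

import itertools
import math


def average_ranks(values):
    """1-based average ranks with ties averaged, via explicit tie runs."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def naive_expdist(x, y):
    return 1.0 - pearson(average_ranks(list(x)), average_ranks(list(y)))


def naive_combination_scores(tree, stage_vectors):
    """Score every stage combination of a nested-tuple tree.

    ``tree`` is a species name or a 2-tuple of subtrees, e.g.
    ``("Anj", ("Apj", ("Sp", "Lv")))``.  ``stage_vectors`` maps species to
    an ordered dict of stage -> list of floats.  Returns a list of
    (combo dict, total distance) in lexicographic stage-index order over the
    left-to-right leaf sequence.
    """

    def leaves(node):
        if isinstance(node, str):
            return [node]
        return leaves(node[0]) + leaves(node[1])

    leaf_order = leaves(tree)

    def evaluate(node, combo):
        if isinstance(node, str):
            return list(stage_vectors[node][combo[node]]), 0.0
        lp, ld = evaluate(node[0], combo)
        rp, rd = evaluate(node[1], combo)
        d = naive_expdist(lp, rp)
        prof = [(a + b) / 2.0 for a, b in zip(lp, rp)]
        return prof, ld + rd + d

    stage_lists = [list(stage_vectors[sp]) for sp in leaf_order]
    out = []
    for picks in itertools.product(*stage_lists):
        combo = dict(zip(leaf_order, picks))
        _, total = evaluate(tree, combo)
        out.append((combo, total))
    return out


def naive_ptop(scored, q):
    """Ptop per species-stage from (combo, distance) pairs; stable ties."""
    n_top = max(1, round(q * len(scored)))
    indexed = sorted(range(len(scored)), key=lambda i: scored[i][1])
    # re-sort is not stable w.r.t. equal keys unless we keep index order:
    indexed = sorted(range(len(scored)), key=lambda i: (scored[i][1], i))
    top = indexed[:n_top]
    species = list(scored[0][0])
    counts = {sp: {} for sp in species}
    for combo, _ in scored:
        for sp in species:
            counts[sp].setdefault(combo[sp], 0)
    for i in top:
        for sp in species:
            counts[sp][scored[i][0][sp]] += 1
    return {
        sp: {st: 100.0 * c / n_top for st, c in counts[sp].items()} for sp in species
    }


def naive_rbbh(hits_ab, hits_ba, evalue_max=1e-5):
    """Brute-force double-loop RBBH on two hit DataFrames."""

    def best(df):
        out = {}
        for _, row in df.iterrows():
            if row["evalue"] > evalue_max or row["qseqid"] == row["sseqid"]:
                continue
            q = row["qseqid"]
            key = (-row["bitscore"], row["evalue"], row["sseqid"])
            if q not in out or key < out[q][0]:
                out[q] = (key, row["sseqid"])
        return {q: s for q, (_, s) in out.items()}

    ab, ba = best(hits_ab), best(hits_ba)
    pairs = []
    for a, b in ab.items():
        if ba.get(b) == a:
            pairs.append((a, b))
    return sorted(pairs)
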