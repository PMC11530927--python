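"""Independent brute-force oracles shared by the acceptance-level tests.

These deliberately avoid any package code paths: the alignment oracle is a
plain-Python Gotoh DP, and the LCA oracles operate on raw parent dicts with
direct set/sum arithmetic.
"""

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


def gotoh_oracle(a, b, matrix, gap_open, gap_extend):
    """Local affine-gap alignment score; a gap of length k costs
    gap_open + k * gap_extend (BLAST convention)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_ladder(tree, taxid):
    out = {}
    node = taxid
    while True:
        r = tree.rank.get(node)
        if r in RANKS and r not in out:
            out[r] = node
        if node == tree.parent[node]:
            break
        node = tree.parent[node]
    return out


def oracle_con(ladders):
    out = {}
    for r in RANKS:
        vals = set(l.get(r) for l in ladders)
        if len(vals) == 1 and None not in vals:
            out[r] = vals.pop()
        else:
            break
    return out


def oracle_weighted(taxa_per_hit, weights, cutoff, tree):
    taxa = sorted(set(taxa_per_hit), key=lambda t: (-weights.get(t, 0), t))
    total = sum(weights.get(t, 0) for t in taxa) or 1
    retained, cum = [], 0.0
    for t in taxa:
        retained.append(t)
        cum += weights.get(t, 0) / total
        if cum >= cutoff:
            break
    return oracle_con([oracle_ladder(tree, t) for t in retained])


def oracle_bitscore(hits, cutoff, tree):
    ladders = [(oracle_ladder(tree, t), bs) for t, bs in hits]
    out = {}
    for r in RANKS:
        sums = {}
        for lad, bs in ladders:
            t = lad.get(r)
            if t is not None:
                sums[t] = sums.get(t, 0.0) + bs
        total = sum(sums.values())
        if total <= 0:
            break
        best = min(sums, key=lambda t: (-sums[t], t))
        if sums[best] / total > cutoff:
            out[r] = best
        else:
            break
    return out
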