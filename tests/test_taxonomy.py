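"""Taxonomy tree, lineage projection, and the three LCA algorithms.

The LCA tests check agreement with an independent brute-force oracle that
works on raw parent dicts with plain set/sum arithmetic and shares no code
with the package implementation.
"""

import numpy as np
import pytest

from novolign.aligner import AlignmentHit
from novolign.fixtures import synth_taxonomy, write_taxdump
from novolign.taxonomy import (
    LcaParams,
    Lineage,
    RANKS,
    TaxTree,
    assign_lca,
    compute_global_weights,
    lca_bitscore,
    lca_conventional,
    lca_weighted,
    load_taxdump,
)


# ---------------------------------------------------------------------------
# independent oracle helpers (raw dict walking, no package code)
# ---------------------------------------------------------------------------


def oracle_ladder(tree, taxid):
    """rank -> taxid by walking the parent dict directly."""
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
    ladders = []
    for taxid, bs in hits:
        ladders.append((oracle_ladder(tree, taxid), bs))
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


@pytest.fixture(scope="module")
def tree():
    return synth_taxonomy(4, 3, seed=13)


def species_of(tree):
    return sorted(t for t, r in tree.rank.items() if r == "species")


# ---------------------------------------------------------------------------
# taxdump loading
# ---------------------------------------------------------------------------


class TestTaxdump:
    def test_round_trip(self, tree, tmp_path):
        d = write_taxdump(tree, tmp_path / "dump")
        loaded = load_taxdump(d)
        for sp in species_of(tree):
            assert loaded.lineage(sp).names == tree.lineage(sp).names

    def test_full_seven_ranks(self, tree):
        for sp in species_of(tree):
            assert tree.lineage(sp).depth == 7

    def test_missing_names_dmp(self, tree, tmp_path):
        d = write_taxdump(tree, tmp_path / "dump")
        (d / "names.dmp").unlink()
        with pytest.raises(FileNotFoundError, match="names.dmp"):
            load_taxdump(d)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            TaxTree(parent={1: 1, 2: 3, 3: 2}, rank={}, name={})

    def test_lineage_table_alternative(self, tree, tmp_path):
        rows = ["taxid\t" + "\t".join(RANKS)]
        for sp in species_of(tree):
            lin = tree.lineage(sp)
            rows.append(f"{sp}\t" + "\t".join(lin.names[r] for r in RANKS))
        p = tmp_path / "lineages.tsv"
        p.write_text("\n".join(rows) + "\n")
        loaded = load_taxdump(p)
        for sp in species_of(tree):
            assert loaded.lineage(sp).names == tree.lineage(sp).names


# ---------------------------------------------------------------------------
# LCA algorithms
# ---------------------------------------------------------------------------


class TestConventional:
    def test_agreement_through_family(self, tree):
        sps = species_of(tree)
        fam_mates = [
            (a, b)
            for a in sps
            for b in sps
            if a < b
            and tree.lineage(a).taxid_at("family") == tree.lineage(b).taxid_at("family")
            and tree.lineage(a).taxid_at("genus") != tree.lineage(b).taxid_at("genus")
        ]
        a, b = fam_mates[0]
        res = lca_conventional([tree.lineage(a), tree.lineage(b)])
        assert res.depth == 5  # through family, genus unset
        assert res.taxid_at("family") == tree.lineage(a).taxid_at("family")

    def test_single_lineage_is_identity(self, tree):
        sp = species_of(tree)[0]
        assert lca_conventional([tree.lineage(sp)]).names == tree.lineage(sp).names

    def test_empty_input_gives_empty_lineage(self):
        assert lca_conventional([]).is_empty()

    def test_result_is_ancestor_of_every_input(self, tree, rng):
        sps = species_of(tree)
        for _ in range(50):
            chosen = [sps[i] for i in rng.integers(0, len(sps), rng.integers(1, 5))]
            res = lca_conventional([tree.lineage(t) for t in chosen])
            for r, t in res.taxids.items():
                for c in chosen:
                    assert tree.lineage(c).taxid_at(r) == t


def _random_hitsets(tree, rng, n_sets):
    sps = species_of(tree)
    for i in range(n_sets):
        n_hits = int(rng.integers(1, 6))
        yield [
            (int(sps[rng.integers(len(sps))]), float(rng.integers(20, 80)))
            for _ in range(n_hits)
        ]


class TestAgainstOracle:
    def test_three_methods_match_bruteforce_on_random_hit_sets(self, tree, rng):
        params_w = LcaParams(method="W", weight_cutoff=0.6)
        params_b = LcaParams(method="BIT", weight_cutoff=0.6)
        weights_pool = {}
        for hitset in _random_hitsets(tree, rng, 300):
            hits = [
                AlignmentHit(f"q", "s", 90.0, 90.0, bs, subject_taxids=[t])
                for t, bs in hitset
            ]
            # CON
            got = lca_conventional([tree.lineage(t) for t, _ in hitset])
            want = oracle_con([oracle_ladder(tree, t) for t, _ in hitset])
            assert got.taxids == want
            # W with per-run weights == taxid multiplicity in this set
            weights = {}
            for t, _ in hitset:
                weights[t] = weights.get(t, 0) + 1
            from collections import Counter

            got_w = lca_weighted(hits, Counter(weights), params_w, tree)
            want_w = oracle_weighted([t for t, _ in hitset], weights, 0.6, tree)
            assert got_w.taxids == want_w
            # BIT
            got_b = lca_bitscore(hits, params_b, tree)
            want_b = oracle_bitscore(hitset, 0.6, tree)
            assert got_b.taxids == want_b

    def test_weighted_at_cutoff_one_equals_conventional(self, tree, rng):
        from collections import Counter

        params = LcaParams(method="W", weight_cutoff=1.0)
        for hitset in _random_hitsets(tree, rng, 100):
            hits = [
                AlignmentHit("q", "s", 90.0, 90.0, bs, subject_taxids=[t])
                for t, bs in hitset
            ]
            weights = Counter(t for t, _ in hitset)
            got = lca_weighted(hits, weights, params, tree)
            con = lca_conventional([tree.lineage(t) for t, _ in hitset])
            assert got.taxids == con.taxids

    def test_consensus_never_shallower_than_conventional(self, tree, rng):
        from collections import Counter

        params = LcaParams(method="W", weight_cutoff=0.6)
        for hitset in _random_hitsets(tree, rng, 100):
            hits = [
                AlignmentHit("q", "s", 90.0, 90.0, bs, subject_taxids=[t])
                for t, bs in hitset
            ]
            weights = Counter(t for t, _ in hitset)
            w = lca_weighted(hits, weights, params, tree)
            con = lca_conventional([tree.lineage(t) for t, _ in hitset])
            assert w.depth >= con.depth

    def test_order_invariance(self, tree, rng):
        from collections import Counter

        hitset = [(species_of(tree)[i], float(20 + i)) for i in (0, 3, 5, 5, 9)]
        hits = [
            AlignmentHit("q", "s", 90.0, 90.0, bs, subject_taxids=[t])
            for t, bs in hitset
        ]
        weights = Counter(t for t, _ in hitset)
        ref_w = lca_weighted(hits, weights, LcaParams(method="W"), tree).taxids
        ref_b = lca_bitscore(hits, LcaParams(method="BIT"), tree).taxids
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            assert lca_weighted(perm, weights, LcaParams(method="W"), tree).taxids == ref_w
            assert lca_bitscore(perm, LcaParams(method="BIT"), tree).taxids == ref_b


class TestWeightedArithmetic:
    def test_dominant_taxon_retained_alone(self, tree):
        from collections import Counter

        sps = species_of(tree)
        a, b = sps[0], sps[-1]
        hits = [
            AlignmentHit("q", "s", 90.0, 90.0, 30.0, subject_taxids=[a]),
            AlignmentHit("q", "s2", 90.0, 90.0, 30.0, subject_taxids=[b]),
        ]
        weights = Counter({a: 9, b: 1})
        res = lca_weighted(hits, weights, LcaParams(method="W", weight_cutoff=0.6), tree)
        assert res.taxids == tree.lineage(a).taxids  # 0.9 >= 0.6 after first taxon

    def test_equal_weights_keep_both(self, tree):
        from collections import Counter

        sps = species_of(tree)
        a, b = sps[0], sps[-1]
        hits = [
            AlignmentHit("q", "s", 90.0, 90.0, 30.0, subject_taxids=[a]),
            AlignmentHit("q", "s2", 90.0, 90.0, 30.0, subject_taxids=[b]),
        ]
        weights = Counter({a: 1, b: 1})
        res = lca_weighted(hits, weights, LcaParams(method="W", weight_cutoff=0.6), tree)
        con = lca_conventional([tree.lineage(a), tree.lineage(b)])
        assert res.taxids == con.taxids  # 0.5 then 1.0 crosses the cutoff


class TestBitscoreArithmetic:
    def test_two_thirds_share_assigned(self, tree):
        sps = species_of(tree)
        a, b = sps[0], sps[1]  # same family, different genus
        hits = [
            AlignmentHit("q", "s", 90.0, 90.0, 60.0, subject_taxids=[a]),
            AlignmentHit("q", "s2", 90.0, 90.0, 30.0, subject_taxids=[b]),
        ]
        res = lca_bitscore(hits, LcaParams(method="BIT", weight_cutoff=0.6), tree)
        assert res.taxid_at("species") == a  # share 0.667 > 0.6 at every rank

    def test_tied_genera_stop_at_family(self, tree):
        sps = species_of(tree)
        a, b = sps[0], sps[1]
        assert tree.lineage(a).taxid_at("family") == tree.lineage(b).taxid_at("family")
        hits = [
            AlignmentHit("q", "s", 90.0, 90.0, 50.0, subject_taxids=[a]),
            AlignmentHit("q", "s2", 90.0, 90.0, 50.0, subject_taxids=[b]),
        ]
        res = lca_bitscore(hits, LcaParams(method="BIT", weight_cutoff=0.6), tree)
        assert res.taxid_at("family") is not None
        assert res.taxid_at("genus") is None

    def test_at_most_one_taxon_per_rank_above_half(self, tree, rng):
        # cutoff > 0.5 makes multiple qualifying taxa impossible; the result
        # is always a single prefix-consistent lineage
        for hitset in _random_hitsets(tree, rng, 50):
            hits = [
                AlignmentHit("q", "s", 90.0, 90.0, bs, subject_taxids=[t])
                for t, bs in hitset
            ]
            res = lca_bitscore(hits, LcaParams(method="BIT", weight_cutoff=0.51), tree)
            filled = [r in res.taxids for r in RANKS]
            assert filled == sorted(filled, reverse=True)  # prefix-consistent


class TestAssign:
    def test_single_hit_gives_its_lineage_for_all_methods(self, tree):
        sp = species_of(tree)[0]
        hits = [AlignmentHit("q0", "s", 100.0, 100.0, 40.0, subject_taxids=[sp])]
        for method in ("CON", "W", "BIT"):
            res = assign_lca(hits, LcaParams(method=method), tree)
            assert res[0].lineage.taxids == tree.lineage(sp).taxids

    def test_decoys_flagged_and_excluded_from_weights(self, tree):
        sps = species_of(tree)
        hits = [
            AlignmentHit("q0", "s", 90.0, 90.0, 40.0, subject_taxids=[sps[0]]),
            AlignmentHit(
                "q1_DECOY", "s", 90.0, 90.0, 40.0, subject_taxids=[sps[1]],
                is_decoy_query=True,
            ),
        ]
        weights = compute_global_weights(hits)
        assert sps[1] not in weights
        res = assign_lca(hits, LcaParams(method="W"), tree)
        flags = {r.query_id: r.is_decoy_query for r in res}
        assert flags == {"q0": False, "q1_DECOY": True}

    def test_unknown_taxids_dropped(self, tree, caplog):
        hits = [AlignmentHit("q0", "s", 90.0, 90.0, 40.0, subject_taxids=[999999])]
        res = assign_lca(hits, LcaParams(method="CON"), tree)
        assert res[0].lineage.is_empty()
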