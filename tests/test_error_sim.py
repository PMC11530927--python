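"""Error-simulator correctness: mass classes, generators, dataset assembly."""

from collections import Counter

import numpy as np
import pytest

from conftest import random_peptides
from novolign.error_sim import (
    ALPHABET,
    DEFAULT_COMBINED_RATES,
    ErrorSimConfig,
    RESIDUE_MASS,
    build_isobaric_table,
    invert_fragments,
    levenshtein,
    make_combined_dataset,
    make_error_datasets,
    mutate_codons,
    peptide_mass,
    substitute_equal_mass,
)


@pytest.fixture(scope="module")
def table():
    return build_isobaric_table(6, 1e-4)


class TestIsobaricTable:
    def test_asparagine_equals_two_glycines(self, table):
        # canonical de novo ambiguity: N and GG share elemental composition
        assert table.has_alternative("N", 2)
        assert table.has_alternative("GG", 1)
        assert abs(RESIDUE_MASS["N"] - 2 * RESIDUE_MASS["G"]) < 1e-4

    def test_glutamine_equals_ala_gly(self, table):
        # independent arithmetic check, then table agreement
        assert abs(RESIDUE_MASS["Q"] - (RESIDUE_MASS["A"] + RESIDUE_MASS["G"])) < 1e-4
        alts = table.alternatives("Q", 2)
        assert [ms for ms, _ in alts] == [("A", "G")]

    def test_no_two_single_residues_share_a_class(self, table):
        # brute force over the 19-letter mass table at 1e-4 Da
        for a in ALPHABET:
            for b in ALPHABET:
                if a != b:
                    assert abs(RESIDUE_MASS[a] - RESIDUE_MASS[b]) > 1e-4
            assert table.alternatives(a, 1) == []

    def test_symmetry(self, table, rng):
        # if A substitutes to B then B substitutes to A
        for window in random_peptides(rng, 50, 2, 3):
            for ms, _ in table.alternatives(window, len(window)):
                back = table.alternatives("".join(ms), len(window))
                assert tuple(sorted(window)) in [m for m, _ in back]

    def test_rejects_bad_length(self):
        with pytest.raises(ValueError):
            build_isobaric_table(0, 1e-4)


class TestSubstitution:
    def test_forced_n_to_gg(self, table):
        rec = substitute_equal_mass("PNP", (1, 2), 1.0, table, np.random.default_rng(0))
        assert rec.altered == "PGGP"
        assert rec.error_type == "sub_1_2"

    def test_prob_zero_is_identity(self, table, rng):
        for seq in random_peptides(rng, 20):
            assert substitute_equal_mass(seq, (2, 2), 0.0, table, rng).altered == seq

    def test_mass_conservation(self, table, rng):
        for seq in random_peptides(rng, 300):
            rec = substitute_equal_mass(seq, None, 1.0, table, rng)
            assert abs(peptide_mass(rec.altered) - peptide_mass(seq)) <= 1e-4

    def test_inapplicable_window_is_flagged_not_dropped(self, table):
        # A run of a single residue with no 1<->2 partner stays unchanged
        rec = substitute_equal_mass("PPPPP", (1, 2), 1.0, table, np.random.default_rng(0))
        assert rec.altered == "PPPPP"
        assert rec.levenshtein == 0


class TestInversion:
    def test_prob_zero_is_identity(self, rng):
        for seq in random_peptides(rng, 20):
            assert invert_fragments(seq, 0.0, rng).altered == seq

    def test_conserves_multiset_and_length(self, rng):
        for seq in random_peptides(rng, 200):
            rec = invert_fragments(seq, 1.0, rng)
            assert sorted(rec.altered) == sorted(seq)
            assert len(rec.altered) == len(seq)

    def test_short_peptide_unchanged(self, rng):
        assert invert_fragments("K", 1.0, rng).altered == "K"


class TestMutation:
    def test_prob_zero_is_identity(self, rng):
        for seq in random_peptides(rng, 20):
            assert mutate_codons(seq, 0.0, rng).altered == seq

    def test_output_alphabet_is_residues_only(self, rng):
        for seq in random_peptides(rng, 100):
            rec = mutate_codons(seq, 0.3, rng)
            assert set(rec.altered) <= set(ALPHABET)
            assert len(rec.altered) == len(seq)

    def test_per_residue_rate_matches_monte_carlo_oracle(self):
        """Observed residue-change rate vs an independent vectorized
        simulation of the same codon process over the standard genetic code
        (agreement within 3 sigma at n=10^6 oracle draws)."""
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        code = unambiguous_dna_by_id[1]
        base_idx = {b: i for i, b in enumerate("ACGT")}
        trans = np.full(64, -1, dtype=np.int64)  # codon index -> aa index (I->L)
        aa_order = {a: i for i, a in enumerate(ALPHABET)}
        stops = np.zeros(64, dtype=bool)
        for codon, aa in code.forward_table.items():
            ci = base_idx[codon[0]] * 16 + base_idx[codon[1]] * 4 + base_idx[codon[2]]
            trans[ci] = aa_order[aa.replace("I", "L")]
        for codon in code.stop_codons:
            ci = base_idx[codon[0]] * 16 + base_idx[codon[1]] * 4 + base_idx[codon[2]]
            stops[ci] = True
        codons_of = {a: [] for a in ALPHABET}
        for codon, aa in code.forward_table.items():
            ci = base_idx[codon[0]] * 16 + base_idx[codon[1]] * 4 + base_idx[codon[2]]
            codons_of[aa.replace("I", "L")].append(ci)

        prob = 0.01
        oracle_rng = np.random.default_rng(123)
        n_oracle = 1_000_000
        aa_draw = oracle_rng.integers(0, len(ALPHABET), n_oracle)
        codon0 = np.empty(n_oracle, dtype=np.int64)
        for ai in range(len(ALPHABET)):
            mask = aa_draw == ai
            syn = np.array(codons_of[ALPHABET[ai]])
            codon0[mask] = syn[oracle_rng.integers(0, len(syn), mask.sum())]
        bases0 = np.stack([codon0 // 16, (codon0 // 4) % 4, codon0 % 4], axis=1)

        def mutate(rows):
            b = bases0[rows].copy()
            hit = oracle_rng.random(b.shape) < prob
            b[hit] = (b[hit] + 1 + oracle_rng.integers(0, 3, hit.sum())) % 4
            return b[:, 0] * 16 + b[:, 1] * 4 + b[:, 2]

        mutated = mutate(np.arange(n_oracle))
        while True:
            bad = np.where(stops[mutated])[0]
            if len(bad) == 0:
                break
            mutated[bad] = mutate(bad)
        p_oracle = float(np.mean(trans[mutated] != aa_draw))

        impl_rng = np.random.default_rng(7)
        n_impl = 0
        changed_impl = 0
        for seq in random_peptides(impl_rng, 20_000, 10, 10):
            rec = mutate_codons(seq, prob, impl_rng)
            n_impl += len(seq)
            changed_impl += sum(a != b for a, b in zip(seq, rec.altered))
        p_impl = changed_impl / n_impl

        sigma = np.sqrt(
            p_oracle * (1 - p_oracle) / n_oracle + p_impl * (1 - p_impl) / n_impl
        )
        assert abs(p_impl - p_oracle) < 3 * sigma


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [("PEPTLDE", "PEPTLDE", 0), ("PEPTIDE", "PEPTLDE", 1), ("", "ABC", 3)],
    )
    def test_examples(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_matches_exhaustive_recursion(self, rng):
        def oracle(a, b):
            if not a:
                return len(b)
            if not b:
                return len(a)
            return min(
                oracle(a[1:], b) + 1,
                oracle(a, b[1:]) + 1,
                oracle(a[1:], b[1:]) + (a[0] != b[0]),
            )

        letters = np.array(list("ACDG"))
        for _ in range(60):
            a = "".join(letters[rng.integers(0, 4, rng.integers(0, 9))])
            b = "".join(letters[rng.integers(0, 4, rng.integers(0, 9))])
            assert levenshtein(a, b) == oracle(a, b)


class TestDatasets:
    def test_combined_counts_and_determinism(self, tryptic_pool):
        peps = tryptic_pool[:300]
        a = make_combined_dataset(peps, ErrorSimConfig(seed=3))
        b = make_combined_dataset(peps, ErrorSimConfig(seed=3))
        assert len(a) == len(peps)
        assert [(r.altered, r.error_type) for r in a] == [
            (r.altered, r.error_type) for r in b
        ]

    def test_combined_type_fractions_follow_rates(self, tryptic_pool, rng):
        peps = [tryptic_pool[i] for i in rng.integers(0, len(tryptic_pool), 4000)]
        recs = make_combined_dataset(peps, ErrorSimConfig(seed=9))
        counts = Counter(r.error_type for r in recs)
        for etype, rate in DEFAULT_COMBINED_RATES.items():
            se = np.sqrt(rate * (1 - rate) / len(peps))
            assert abs(counts[etype] / len(peps) - rate) < 4 * se

    def test_thirteen_datasets_each_full_size(self, tryptic_pool):
        peps = tryptic_pool[:120]
        datasets = make_error_datasets(peps, ErrorSimConfig(seed=2))
        assert len(datasets) == 13
        assert all(len(v) == len(peps) for v in datasets.values())

    def test_inversion_and_mutation_have_similar_edit_medians(self, tryptic_pool):
        peps = tryptic_pool[:300]
        datasets = make_error_datasets(peps, ErrorSimConfig(seed=2))
        med_inv = np.median([r.levenshtein for r in datasets["inversion@5"]])
        med_mut = np.median([r.levenshtein for r in datasets["mutation@1nt"]])
        assert abs(med_inv - med_mut) <= 1

    def test_substitutions_conserve_mass_mutations_do_not(self, tryptic_pool):
        peps = tryptic_pool[:200]
        datasets = make_error_datasets(peps, ErrorSimConfig(seed=2))
        for r in datasets["sub_all@100"]:
            assert abs(peptide_mass(r.altered) - peptide_mass(r.original)) <= 1e-4
        deltas = [
            abs(peptide_mass(r.altered) - peptide_mass(r.original))
            for r in datasets["mutation@1nt"]
            if r.altered != r.original
        ]
        assert deltas and max(deltas) > 1e-3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            make_combined_dataset([], ErrorSimConfig())


def test_config_validates_rates():
    with pytest.raises(ValueError):
        ErrorSimConfig(combined_rates={"inversion": 0.5, "other": 0.4})
    with pytest.raises(ValueError):
        ErrorSimConfig(substitution_prob=1.5)
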