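"""Simulation of de novo peptide-sequencing errors.

De novo sequencing infers a peptide from its fragmentation spectrum, and
gaps or ambiguities in the fragment-ion series produce characteristic
sequence-level errors: equal-mass (isobaric) substitutions (the canonical
example being N <-> GG), local inversions of two or three consecutive
residues, and less structured mutations modeled here at the codon level.
This module generates peptides carrying such errors at configurable rates,
measures how different the altered peptide is via the Levenshtein edit
distance, and assembles a combined error dataset at the per-type occurrence
frequencies observed for common de novo sequencing tools.

All sequences are over the 19-letter, I-free alphabet (I is normalized to
the isobaric L throughout the pipeline).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import edlib
import numpy as np
from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

#: 19-letter residue alphabet (no I; L-normalized)
ALPHABET = tuple(sorted(set("ACDEFGHKLMNPQRSTVWY")))

#: monoisotopic residue masses (Da)
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in ALPHABET}

#: the seven equal-mass substitution length pairs, keyed by their error-type name
SUBSTITUTION_PAIRS = {
    "sub_1_2": (1, 2),
    "sub_2_2": (2, 2),
    "sub_2_3": (2, 3),
    "sub_3_3": (3, 3),
    "sub_4_4": (4, 4),
    "sub_5_5": (5, 5),
    "sub_6_6": (6, 6),
}

ERROR_TYPES = tuple(SUBSTITUTION_PAIRS) + ("inversion", "other")

#: per-type occurrence rates of de novo errors in common sequencing tools,
#: used to assemble the combined dataset (they sum to 0.999 as printed)
DEFAULT_COMBINED_RATES = {
    "sub_1_2": 0.063,
    "sub_2_2": 0.137,
    "sub_3_3": 0.063,
    "sub_2_3": 0.037,
    "sub_4_4": 0.097,
    "sub_5_5": 0.076,
    "sub_6_6": 0.068,
    "inversion": 0.161,
    "other": 0.297,
}


@dataclass
class ErrorSimConfig:
    """Rates and tolerances of the error simulator.

    ``substitution_prob`` is the per-detected-window chance of performing an
    equal-mass substitution (the generator was calibrated with 25/50/100%
    window chances; 25% feeds the combined dataset).  ``inversion_prob`` is
    the per-fragment randomization chance, ``mutation_prob`` the per-
    nucleotide substitution chance of the codon-level mutation model.
    """

    substitution_prob: float = 0.25
    inversion_prob: float = 0.05
    mutation_prob: float = 0.01
    max_combo_len: int = 6
    mass_tolerance: float = 1e-4
    combined_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMBINED_RATES)
    )
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.substitution_prob, self.inversion_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        total = sum(self.combined_rates.values())
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"combined_rates sum to {total}, expected 1 within 0.005")
        unknown = set(self.combined_rates) - set(ERROR_TYPES)
        if unknown:
            raise ValueError(f"unknown error types in combined_rates: {unknown}")


@dataclass
class ErroredPeptide:
    """A peptide with one applied (or attempted) error."""

    original: str
    altered: str
    error_type: str
    levenshtein: int


def peptide_mass(seq: str) -> float:
    """Sum of monoisotopic residue masses (no water; residue-level)."""
    return sum(RESIDUE_MASS[a] for a in seq)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b)["editDistance"]


# ---------------------------------------------------------------------------
# Isobaric substitution table
# ---------------------------------------------------------------------------


def _perm_count(multiset: tuple[str, ...]) -> int:
    n = math.factorial(len(multiset))
    for c in Counter(multiset).values():
        n //= math.factorial(c)
    return n


class IsobaricTable:
    """Equal-mass residue-combination classes up to ``max_combo_len`` residues.

    A mass class is the set of residue multisets (over the 19-letter
    alphabet) whose total monoisotopic masses agree within
    ``mass_tolerance``; at the default 1e-4 Da tolerance the classes are
    effectively equal-elemental-composition sets.  Strings are the distinct
    arrangements of a multiset; a *substitution alternative* for a window is
    any string in the window's class with a different multiset (same-multiset
    reorderings are inversions, not substitutions).
    """

    def __init__(self, max_combo_len: int = 6, mass_tolerance: float = 1e-4):
        if max_combo_len < 1:
            raise ValueError("max_combo_len must be >= 1")
        self.max_combo_len = max_combo_len
        self.mass_tolerance = mass_tolerance
        # mass key -> length -> list of (multiset tuple, n distinct strings)
        self._classes: dict[int, dict[int, list[tuple[tuple[str, ...], int]]]] = {}
        for k in range(1, max_combo_len + 1):
            for combo in itertools.combinations_with_replacement(ALPHABET, k):
                key = self._key(sum(RESIDUE_MASS[a] for a in combo))
                self._classes.setdefault(key, {}).setdefault(k, []).append(
                    (combo, _perm_count(combo))
                )

    def _key(self, m: float) -> int:
        return int(round(m / self.mass_tolerance))

    def members(self, mass: float, length: int) -> list[tuple[tuple[str, ...], int]]:
        """All (multiset, n_arrangements) of the given length in the mass class."""
        out: list[tuple[tuple[str, ...], int]] = []
        key = self._key(mass)
        for k in (key - 1, key, key + 1):  # absorb quantization boundaries
            for ms, n in self._classes.get(k, {}).get(length, []):
                if abs(sum(RESIDUE_MASS[a] for a in ms) - mass) <= self.mass_tolerance:
                    out.append((ms, n))
        return out

    def alternatives(self, window: str, target_len: int) -> list[tuple[tuple[str, ...], int]]:
        """Substitution alternatives: same mass, given length, different multiset."""
        own = tuple(sorted(window))
        return [
            (ms, n)
            for ms, n in self.members(peptide_mass(window), target_len)
            if ms != own
        ]

    def has_alternative(self, window: str, target_len: int) -> bool:
        return bool(self.alternatives(window, target_len))

    def sample_alternative(
        self, window: str, target_len: int, rng: np.random.Generator
    ) -> str | None:
        """Uniform draw over all alternative *strings* (arrangements) of the class."""
        alts = self.alternatives(window, target_len)
        if not alts:
            return None
        weights = np.array([n for _, n in alts], dtype=float)
        ms = alts[rng.choice(len(alts), p=weights / weights.sum())][0]
        return "".join(rng.permutation(list(ms)))


@lru_cache(maxsize=4)
def build_isobaric_table(
    max_combo_len: int = 6, mass_tolerance: float = 1e-4
) -> IsobaricTable:
    """Build (and cache) the equal-mass combination table."""
    table = IsobaricTable(max_combo_len, mass_tolerance)
    logger.info(
        "isobaric table built: combos up to length %d at tolerance %g Da",
        max_combo_len,
        mass_tolerance,
    )
    return table


# ---------------------------------------------------------------------------
# Error generators
# ---------------------------------------------------------------------------


def _window_options(
    seq: str, i: int, length_pair: tuple[int, int] | None, table: IsobaricTable
) -> list[tuple[int, int]]:
    """Eligible (window_len, target_len) substitutions at position i."""
    if length_pair is None:
        pairs = list(SUBSTITUTION_PAIRS.values())
    else:
        pairs = [tuple(length_pair)]
    options: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for m, n in pairs:
        for w, t in ((m, n), (n, m)):
            if (w, t) in seen:
                continue
            seen.add((w, t))
            if i + w <= len(seq) and table.has_alternative(seq[i : i + w], t):
                options.append((w, t))
    return options


def substitute_equal_mass(
    seq: str,
    length_pair: tuple[int, int] | None,
    prob: float,
    table: IsobaricTable,
    rng: np.random.Generator,
    error_type: str | None = None,
) -> ErroredPeptide:
    """Slide over ``seq`` and apply equal-mass substitutions of one length pair.

    A sliding window scans left to right; every window whose residue string
    has an equal-mass alternative of the target length is substituted with
    probability ``prob``.  After a substitution the scan resumes after the
    replaced span, so edits never overlap.  ``length_pair=None`` pools all
    seven pairs (any eligible window length at a position, shortest first).
    Monoisotopic mass is conserved within the table's tolerance.
    """
    if error_type is None:
        error_type = (
            "sub_all"
            if length_pair is None
            else next(k for k, v in SUBSTITUTION_PAIRS.items() if tuple(v) == tuple(length_pair))
        )
    out: list[str] = []
    i = 0
    while i < len(seq):
        options = _window_options(seq, i, length_pair, table)
        replaced = False
        if options and rng.random() < prob:
            w, t = options[0] if len(options) == 1 else options[rng.choice(len(options))]
            repl = table.sample_alternative(seq[i : i + w], t, rng)
            if repl is not None:
                out.append(repl)
                i += w
                replaced = True
        if not replaced:
            out.append(seq[i])
            i += 1
    altered = "".join(out)
    return ErroredPeptide(seq, altered, error_type, levenshtein(seq, altered))


def invert_fragments(
    seq: str, prob: float, rng: np.random.Generator, fragment_lengths: tuple[int, ...] = (2, 3)
) -> ErroredPeptide:
    """Partition into fragments of 2 or 3 residues and shuffle each with ``prob``.

    Fragment lengths are drawn uniformly per fragment; a trailing single
    residue is appended unchanged.  Residue multiset and length are
    conserved.
    """
    if len(seq) < 2:
        logger.warning("invert_fragments: %r too short, returned unchanged", seq)
        return ErroredPeptide(seq, seq, "inversion", 0)
    frags: list[str] = []
    i = 0
    while i < len(seq):
        remaining = len(seq) - i
        if remaining == 1:
            frags.append(seq[i:])
            break
        eligible = [f for f in fragment_lengths if f <= remaining]
        flen = int(eligible[rng.integers(len(eligible))])
        frag = seq[i : i + flen]
        if rng.random() < prob:
            frag = "".join(rng.permutation(list(frag)))
        frags.append(frag)
        i += flen
    altered = "".join(frags)
    return ErroredPeptide(seq, altered, "inversion", levenshtein(seq, altered))


def _codon_maps() -> tuple[dict[str, list[str]], dict[str, str], set[str]]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]  # standard genetic code
    fwd: dict[str, str] = dict(table.forward_table)
    back: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        back.setdefault(aa, []).append(codon)
    return back, fwd, set(table.stop_codons)


_BACK_TABLE, _FWD_TABLE, _STOP_CODONS = _codon_maps()
_BASES = "ACGT"


def mutate_codons(seq: str, prob: float, rng: np.random.Generator) -> ErroredPeptide:
    """Reverse-translate, mutate each nucleotide with ``prob``, translate back.

    Each residue is mapped to a codon drawn uniformly among its standard-
    genetic-code synonyms; each nucleotide flips to one of the three other
    bases with probability ``prob``.  A codon mutating to a stop is
    re-mutated until non-stop, keeping the output length fixed.  The result
    is I->L normalized to stay on the pipeline's 19-letter alphabet.
    """
    out: list[str] = []
    for aa in seq:
        codons = _BACK_TABLE[aa]
        codon = codons[rng.integers(len(codons))]
        while True:
            mutated = "".join(
                _BASES[(
                    _BASES.index(b) + 1 + rng.integers(3)
                ) % 4] if rng.random() < prob else b
                for b in codon
            )
            if mutated not in _STOP_CODONS:
                break
        out.append(_FWD_TABLE[mutated])
    altered = "".join(out).replace("I", "L")
    return ErroredPeptide(seq, altered, "other", levenshtein(seq, altered))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _applicable(
    error_type: str, seq: str, table: IsobaricTable
) -> bool:
    if error_type == "other":
        return True
    if error_type == "inversion":
        return len(seq) >= 2
    pair = SUBSTITUTION_PAIRS[error_type]
    return any(_window_options(seq, i, pair, table) for i in range(len(seq)))


def _apply(
    error_type: str,
    seq: str,
    cfg: ErrorSimConfig,
    table: IsobaricTable,
    rng: np.random.Generator,
) -> ErroredPeptide:
    if error_type == "other":
        return mutate_codons(seq, cfg.mutation_prob, rng)
    if error_type == "inversion":
        return invert_fragments(seq, cfg.inversion_prob, rng)
    return substitute_equal_mass(
        seq, SUBSTITUTION_PAIRS[error_type], cfg.substitution_prob, table, rng
    )


def make_combined_dataset(
    peptides: Sequence[str],
    cfg: ErrorSimConfig | None = None,
    rng: np.random.Generator | None = None,
    max_redraws: int = 0,
) -> list[ErroredPeptide]:
    """One errored record per input peptide, error types drawn at the
    observed per-type occurrence rates.

    The drawn type is recorded even when the peptide offers no applicable
    site (altered = original in that case), so the observed type fractions
    converge to ``combined_rates`` for large n.  With ``max_redraws`` > 0 an
    inapplicable type is instead redrawn up to that many times and then
    falls back to the always-applicable codon-mutation type; this skews the
    fractions toward the applicable types and is off by default.
    """
    if not peptides:
        raise ValueError("no peptides supplied")
    cfg = cfg or ErrorSimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    table = build_isobaric_table(cfg.max_combo_len, cfg.mass_tolerance)
    types = list(cfg.combined_rates)
    probs = np.array([cfg.combined_rates[t] for t in types], dtype=float)
    probs /= probs.sum()
    out: list[ErroredPeptide] = []
    for seq in peptides:
        etype = types[rng.choice(len(types), p=probs)]
        if max_redraws and not _applicable(etype, seq, table):
            for _ in range(max_redraws):
                etype = types[rng.choice(len(types), p=probs)]
                if _applicable(etype, seq, table):
                    break
            else:
                etype = "other"
        rec = _apply(etype, seq, cfg, table, rng)
        rec.error_type = etype
        out.append(rec)
    return out


def make_error_datasets(
    peptides: Sequence[str], cfg: ErrorSimConfig | None = None
) -> dict[str, list[ErroredPeptide]]:
    """The 13 named error datasets used to calibrate alignment parameters.

    Seven per-length-pair substitution datasets at the default 25% window
    chance, pooled substitutions at the three window chances (25/50/100%),
    fragment inversion at 5%, codon mutation at 1% per nucleotide, and the
    combined dataset.  Every dataset has one record per input peptide.
    """
    if not peptides:
        raise ValueError("no peptides supplied")
    cfg = cfg or ErrorSimConfig()
    table = build_isobaric_table(cfg.max_combo_len, cfg.mass_tolerance)
    rng = np.random.default_rng(cfg.seed)
    datasets: dict[str, list[ErroredPeptide]] = {}
    for name, pair in SUBSTITUTION_PAIRS.items():
        datasets[f"{name}@25"] = [
            substitute_equal_mass(s, pair, 0.25, table, rng) for s in peptides
        ]
    for chance in (0.25, 0.50, 1.00):
        datasets[f"sub_all@{int(chance * 100)}"] = [
            substitute_equal_mass(s, None, chance, table, rng) for s in peptides
        ]
    datasets["inversion@5"] = [
        invert_fragments(s, cfg.inversion_prob, rng) for s in peptides
    ]
    datasets["mutation@1nt"] = [
        mutate_codons(s, cfg.mutation_prob, rng) for s in peptides
    ]
    datasets["combined"] = make_combined_dataset(peptides, cfg, rng)
    return datasets


def dataset_to_frame(records: Sequence[ErroredPeptide]):
    """Delimited-table view: original, altered, error_type, levenshtein."""
    import pandas as pd

    return pd.DataFrame(
        {
            "original": [r.original for r in records],
            "altered": [r.altered for r in records],
            "error_type": [r.error_type for r in records],
            "levenshtein": [r.levenshtein for r in records],
        }
    )
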