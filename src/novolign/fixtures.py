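"""Synthetic communities with ground truth for end-to-end testing.

Generates a full seven-rank taxonomy in the NCBI taxdump dialect, random
proteomes over the 19-letter (I-free) alphabet, in-silico tryptic digests,
and PEAKS-dialect de novo tables whose peptides carry simulated sequencing
errors — everything the pipeline consumes, with a ground-truth table keyed
by query id, so no external download is needed.

The generator emulates the *shape* of real experiments (tryptic peptides,
abundance-weighted sampling, lower scores for error-bearing spectra); it
does not emulate spectral noise, retention time or instrument effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .error_sim import ALPHABET, ErrorSimConfig, make_combined_dataset
from .taxonomy import RANKS, TaxTree

logger = logging.getLogger(__name__)

_SYLLABLES = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu "
    "ga ge gi go gu la le li lo lu ma me mi mo mu na ne ni no nu "
    "ra re ri ro ru sa se si so su ta te ti to tu va ve vi vo vu"
).split()


def _make_name(rng: np.random.Generator, suffix: str = "") -> str:
    n = rng.integers(3, 5)
    word = "".join(_SYLLABLES[rng.integers(len(_SYLLABLES))] for _ in range(n))
    return word.capitalize() + suffix


@dataclass
class SyntheticCommunity:
    tree: TaxTree
    proteins: list[tuple[str, str, int]]  # (accession, sequence, species taxid)
    abundance: dict[int, float]  # species taxid -> expected peptide fraction
    taxdump_dir: Path | None = None
    fasta_path: Path | None = None

    @property
    def species_taxids(self) -> list[int]:
        return sorted(self.abundance)

    def family_shares(self) -> dict[str, float]:
        """Expected peptide share per family name (sums to 1)."""
        shares: dict[str, float] = {}
        for taxid, frac in self.abundance.items():
            fam = self.tree.lineage(taxid).name_at("family")
            shares[fam] = shares.get(fam, 0.0) + frac
        return shares


def synth_taxonomy(
    n_families: int, species_per_family: int, seed: int = 1
) -> TaxTree:
    """A full seven-rank synthetic taxonomy, deterministic under ``seed``.

    One superkingdom/phylum/class; families are spread over up to
    ``max(1, n_families // 2)`` orders; each species gets its own genus.
    Species taxids start at 1000 and are stable for a given shape.
    """
    if n_families < 1 or species_per_family < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    parent = {1: 1}
    rank = {1: "no rank"}
    name = {1: "root"}
    next_id = 2

    def add(par: int, rk: str, nm: str) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        parent[nid] = par
        rank[nid] = rk
        name[nid] = nm
        return nid

    sk = add(1, "superkingdom", _make_name(rng, "bacteria"))
    ph = add(sk, "phylum", _make_name(rng, "ota"))
    cl = add(ph, "class", _make_name(rng, "ia"))
    n_orders = max(1, n_families // 2)
    orders = [add(cl, "order", _make_name(rng, "ales")) for _ in range(n_orders)]
    species_id = 1000
    for fi in range(n_families):
        fam = add(orders[fi % n_orders], "family", _make_name(rng, "aceae"))
        for _ in range(species_per_family):
            gen = add(fam, "genus", _make_name(rng))
            sp_name = f"{name[gen]} {_make_name(rng).lower()}"
            parent[species_id] = gen
            rank[species_id] = "species"
            name[species_id] = sp_name
            species_id += 1
    return TaxTree(parent=parent, rank=rank, name=name, root=1)


def write_taxdump(tree: TaxTree, out_dir: str | Path) -> Path:
    """Write nodes.dmp / names.dmp in the pipe-delimited dump dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "nodes.dmp", "w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.parent[taxid]}\t|\t{tree.rank[taxid]}\t|\n")
    with open(out_dir / "names.dmp", "w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.name[taxid]}\t|\t\t|\tscientific name\t|\n")
    return out_dir


def synth_proteomes(
    tree: TaxTree,
    n_proteins: int = 20,
    length_range: tuple[int, int] = (150, 400),
    seed: int = 1,
) -> list[tuple[str, str, int]]:
    """Random proteins per species, uniform over the 19-letter alphabet.

    With 19 equiprobable residues the tryptic sites K/R occur at ~10.5%,
    giving realistic peptide lengths after digestion.  Headers written by
    :func:`write_proteome_fasta` carry ``OX=<taxid>``.
    """
    rng = np.random.default_rng(seed)
    species = sorted(t for t, r in tree.rank.items() if r == "species")
    letters = np.array(list(ALPHABET))
    proteins = []
    for taxid in species:
        for i in range(n_proteins):
            ln = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(letters[rng.integers(0, len(letters), ln)])
            proteins.append((f"SP{taxid}_{i}", seq, taxid))
    return proteins


def write_proteome_fasta(
    proteins: Sequence[tuple[str, str, int]], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for acc, seq, taxid in proteins:
            fh.write(f">{acc} synthetic protein OX={taxid}\n{seq}\n")
    return path


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 0,
    min_len: int | None = None,
    max_len: int | None = None,
) -> list[str]:
    """Cleave C-terminal to K/R except before P; optional length filter."""
    if not protein:
        raise ValueError("empty protein")
    if not 0 <= missed_cleavages <= 2:
        raise ValueError("missed_cleavages must be 0..2")
    frags: list[str] = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and (i + 1 >= len(protein) or protein[i + 1] != "P"):
            frags.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        frags.append(protein[start:])
    peptides: list[str] = []
    for mc in range(missed_cleavages + 1):
        for i in range(len(frags) - mc):
            peptides.append("".join(frags[i : i + mc + 1]))
    if min_len is not None:
        peptides = [p for p in peptides if len(p) >= min_len]
    if max_len is not None:
        peptides = [p for p in peptides if len(p) <= max_len]
    return peptides


def make_community(
    n_families: int = 3,
    species_per_family: int = 2,
    n_proteins: int = 20,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> SyntheticCommunity:
    """Taxonomy + proteomes + Dirichlet abundance profile in one call."""
    tree = synth_taxonomy(n_families, species_per_family, seed)
    proteins = synth_proteomes(tree, n_proteins=n_proteins, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    species = sorted(t for t, r in tree.rank.items() if r == "species")
    weights = rng.dirichlet(np.ones(len(species)))
    abundance = {t: float(w) for t, w in zip(species, weights)}
    community = SyntheticCommunity(tree=tree, proteins=proteins, abundance=abundance)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        community.taxdump_dir = write_taxdump(tree, out_dir / "taxdump")
        community.fasta_path = write_proteome_fasta(proteins, out_dir / "reference.fasta")
    return community


def synth_denovo_experiment(
    community: SyntheticCommunity,
    n_peptides: int = 2000,
    error_cfg: ErrorSimConfig | None = None,
    seed: int = 1,
    out_csv: str | Path | None = None,
    out_truth: str | Path | None = None,
    clean_score: tuple[float, float] = (88.0, 5.0),
    error_score: tuple[float, float] = (76.0, 8.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample peptides per abundance, perturb them, and emit a PEAKS-dialect CSV.

    Error-bearing peptides draw their ALC from a lower-mean normal than
    clean ones, emulating the score/accuracy coupling of real de novo
    output.  Returns (denovo_table, ground_truth); ground truth records the
    source species, protein and applied error per query id.
    """
    rng = np.random.default_rng(seed)
    by_species: dict[int, list[tuple[str, str]]] = {}
    for acc, seq, taxid in community.proteins:
        peps = tryptic_digest(seq, min_len=7, max_len=30)
        by_species.setdefault(taxid, []).extend((p, acc) for p in peps)

    species = community.species_taxids
    probs = np.array([community.abundance[t] for t in species])
    probs /= probs.sum()
    picks = rng.choice(len(species), size=n_peptides, p=probs)
    originals: list[str] = []
    sources: list[tuple[int, str]] = []
    for k in picks:
        taxid = species[k]
        pool = by_species[taxid]
        pep, acc = pool[rng.integers(len(pool))]
        originals.append(pep)
        sources.append((taxid, acc))

    if error_cfg is not None:
        errored = make_combined_dataset(originals, error_cfg, rng)
    else:
        from .error_sim import ErroredPeptide

        errored = [ErroredPeptide(p, p, "none", 0) for p in originals]

    rows = []
    truth = []
    for i, (rec, (taxid, acc)) in enumerate(zip(errored, sources)):
        changed = rec.altered != rec.original
        mu, sd = error_score if changed else clean_score
        alc = float(np.clip(rng.normal(mu, sd), 0, 99))
        scan = f"F1:{i}"
        rows.append(
            {
                "Scan": scan,
                "Peptide": rec.altered,
                "ALC (%)": round(alc, 1),
                "ppm": round(float(rng.normal(0, 3)), 2),
                "Area": round(float(rng.lognormal(10, 1)), 1),
            }
        )
        fam = community.tree.lineage(taxid).name_at("family")
        truth.append(
            {
                "query_id": scan,
                "original": rec.original,
                "altered": rec.altered,
                "error_type": rec.error_type,
                "levenshtein": rec.levenshtein,
                "species_taxid": taxid,
                "family": fam,
                "accession": acc,
            }
        )
    df = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_truth is not None:
        truth_df.to_csv(out_truth, sep="\t", index=False)
    return df, truth_df
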