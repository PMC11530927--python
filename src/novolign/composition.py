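"""Community composition from consensus lineages, and database construction.

Peptide counts per taxon (one count per query record) are the abundance
unit.  Taxa below the reporting threshold ``freq_cut`` are pooled into an
``other`` row rather than dropped, so fractions stay normalized.  The
decoy retained-alignment rate is reported alongside as the false-positive
control but never enters the fractions.

The module also extracts all reference sequences of identified taxa into a
specialized protein FASTA and complements an incomplete (e.g. metagenome-
derived) database with them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .aligner import ReferenceDatabase
from .denovo_io import DenovoRecord, normalize_il
from .taxonomy import LcaResult, RANKS, TaxTree

logger = logging.getLogger(__name__)


@dataclass
class CompositionParams:
    freq_cut: int = 5
    rank: str = "family"

    def __post_init__(self) -> None:
        if self.freq_cut < 0:
            raise ValueError("freq_cut must be >= 0")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


@dataclass
class CompositionTable:
    rank: str
    rows: pd.DataFrame  # columns: taxon, taxid, count, fraction
    decoy_match_rate: float
    n_classified: int
    n_unclassified: int

    def fraction_of(self, taxon: str) -> float:
        m = self.rows[self.rows["taxon"] == taxon]
        return float(m["fraction"].iloc[0]) if len(m) else 0.0


def compose(
    lca_results: Sequence[LcaResult],
    params: CompositionParams | None = None,
    n_target_queries: int | None = None,
    n_decoy_queries: int | None = None,
) -> CompositionTable:
    """Aggregate target LCA results into a composition at ``params.rank``.

    ``n_decoy_queries`` is the total number of decoy queries submitted to
    alignment (defaults to the number of decoy LCA results), the
    denominator of the decoy retained-alignment rate.
    """
    params = params or CompositionParams()
    targets = [r for r in lca_results if not r.is_decoy_query]
    decoys = [r for r in lca_results if r.is_decoy_query]

    n_decoy_total = n_decoy_queries if n_decoy_queries is not None else len(decoys)
    n_decoy_matched = sum(1 for r in decoys if r.n_hits >= 1)
    decoy_rate = n_decoy_matched / n_decoy_total if n_decoy_total else 0.0

    counts: Counter = Counter()
    taxids: dict[str, int | None] = {}
    n_classified = 0
    for r in targets:
        name = r.lineage.name_at(params.rank)
        if name is None:
            continue
        n_classified += 1
        counts[name] += 1
        taxids[name] = r.lineage.taxid_at(params.rank)
    n_total = n_target_queries if n_target_queries is not None else len(targets)
    n_unclassified = n_total - n_classified

    if n_classified == 0:
        logger.warning("compose: no classified peptides at rank %s", params.rank)
        return CompositionTable(
            rank=params.rank,
            rows=pd.DataFrame(columns=["taxon", "taxid", "count", "fraction"]),
            decoy_match_rate=decoy_rate,
            n_classified=0,
            n_unclassified=n_unclassified,
        )

    rows = []
    other = 0
    for name, c in counts.items():
        if c >= params.freq_cut:
            rows.append((name, taxids[name], c, c / n_classified))
        else:
            other += c
    rows.sort(key=lambda r: (-r[2], r[0]))
    if other:
        rows.append(("other", None, other, other / n_classified))
    df = pd.DataFrame(rows, columns=["taxon", "taxid", "count", "fraction"])
    return CompositionTable(
        rank=params.rank,
        rows=df,
        decoy_match_rate=decoy_rate,
        n_classified=n_classified,
        n_unclassified=n_unclassified,
    )


def spearman_compare(
    comp_a: CompositionTable, comp_b: CompositionTable
) -> float:
    """Spearman rank correlation over the union of reported taxa.

    Taxa absent from one table count 0 there; the pooled ``other`` row is
    excluded.  With fewer than 3 taxa in the union the correlation is
    undefined and NaN is returned with a warning.
    """
    if comp_a.rank != comp_b.rank:
        raise ValueError("composition tables are at different ranks")
    a = {r.taxon: r.count for r in comp_a.rows.itertuples() if r.taxon != "other"}
    b = {r.taxon: r.count for r in comp_b.rows.itertuples() if r.taxon != "other"}
    taxa = sorted(set(a) | set(b))
    if len(taxa) < 3:
        logger.warning("spearman_compare: <3 taxa in union; undefined")
        return float("nan")
    va = [a.get(t, 0) for t in taxa]
    vb = [b.get(t, 0) for t in taxa]
    rho, _ = _stats.spearmanr(va, vb)
    return float(rho)


def extract_taxon_sequences(
    ref_db: ReferenceDatabase,
    taxa: Sequence[int | str],
    rank: str,
    tree: TaxTree,
    out_path: str | Path,
    exclude: Sequence[int | str] | None = None,
    add_decoys: bool = False,
    decoy_rng: np.random.Generator | None = None,
    query_records: Sequence[DenovoRecord] | None = None,
) -> Path:
    """Write all reference sequences whose TaxID projects to ``taxa`` at ``rank``.

    ``taxa`` and ``exclude`` accept taxids or names; ``exclude`` also
    accepts accessions.  Options mirror specialized-database construction:
    an exclusion list, appended scrambled decoy proteins, and appended query
    de novo peptides as entries.
    """
    if not taxa:
        raise ValueError("empty taxa set")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    wanted = {str(t) for t in taxa}
    excluded = {str(t) for t in (exclude or ())}
    out_path = Path(out_path)
    n = 0
    with open(out_path, "w") as fh:
        for acc, seq, taxid in zip(ref_db.accessions, ref_db.sequences, ref_db.taxids):
            if taxid is None or taxid not in tree or acc in excluded:
                continue
            lin = tree.lineage(taxid)
            t_at = lin.taxid_at(rank)
            n_at = lin.name_at(rank)
            key_hits = {str(t_at), str(n_at)}
            if not (key_hits & wanted) or (key_hits & excluded):
                continue
            fh.write(f">{acc} OX={taxid}\n{seq}\n")
            n += 1
            if add_decoys:
                rng = decoy_rng if decoy_rng is not None else np.random.default_rng(0)
                fh.write(
                    f">DECOY_{acc} OX={taxid}\n"
                    + "".join(rng.permutation(list(seq)))
                    + "\n"
                )
        if query_records:
            for r in query_records:
                fh.write(f">QUERY_{r.query_id}\n{r.peptide}\n")
    if n == 0:
        logger.warning("extract_taxon_sequences: no sequences matched %s", wanted)
    logger.info("extract_taxon_sequences: wrote %d entries to %s", n, out_path)
    return out_path


def complement_db(
    metagenomic_fasta: str | Path,
    extracted_fasta: str | Path,
    out_path: str | Path,
) -> Path:
    """Merge a metagenome-derived database with extracted reference sequences.

    Exact duplicate sequences (after I->L normalization) are removed,
    keeping the first occurrence; a provenance token is kept in each
    header.  The merged database is a superset of the metagenomic one.
    """
    from Bio import SeqIO

    out_path = Path(out_path)
    seen: set[str] = set()
    n_in = n_out = 0
    with open(out_path, "w") as fh:
        for src, fasta in (
            ("metagenome", metagenomic_fasta),
            ("denovo_complement", extracted_fasta),
        ):
            for rec in SeqIO.parse(str(fasta), "fasta"):
                n_in += 1
                seq = normalize_il(str(rec.seq).upper())
                if seq in seen:
                    continue
                seen.add(seq)
                desc = rec.description
                fh.write(f">{desc} src={src}\n{seq}\n")
                n_out += 1
    logger.info("complement_db: %d entries in, %d after dedup", n_in, n_out)
    return out_path


def write_composition_tsv(table: CompositionTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.rows.copy()
    df.to_csv(path, sep="\t", index=False)
    return path


def plot_composition_bar(
    tables: dict[str, CompositionTable], path: str | Path
) -> Path:
    """Stacked-bar figure of one or more composition tables (basic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    taxa = sorted({t for tab in tables.values() for t in tab.rows["taxon"]})
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(tables)), 5))
    bottoms = {k: 0.0 for k in tables}
    for taxon in taxa:
        vals = [tables[k].fraction_of(taxon) for k in tables]
        ax.bar(list(tables), vals, bottom=[bottoms[k] for k in tables], label=taxon)
        for k, v in zip(tables, vals):
            bottoms[k] += v
    ax.set_ylabel("fraction of classified peptides")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
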