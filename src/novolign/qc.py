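"""Spectral-quality classification and database-coverage evaluation.

Aligned de novo peptides are grouped by their best hit into ``exact``
(100% identity, 100% query cover), ``exact_tag`` (100% identity, partial
cover), ``aligned`` (<100% identity, full cover), ``aligned_tag`` (both
partial) and ``unmatched``.  When a database-search PSM table is supplied,
each de novo spectrum is additionally marked ``matched``/``not_detected``
in database searching, which shows whether high-quality spectra escaped
the reference database.

``db_coverage_report`` compares the taxonomic distributions of four peptide
sets — DN_only, DN_all, DB_only, DB_all — at the order/family/genus ranks;
disagreement between DN_all and DB_all signals database incompleteness.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .aligner import AlignmentHit, ReferenceDatabase
from .denovo_io import DenovoRecord, normalize_il, strip_modifications
from .taxonomy import LcaResult, Lineage, TaxTree, lca_conventional

logger = logging.getLogger(__name__)

CATEGORIES = ("exact", "exact_tag", "aligned", "aligned_tag", "unmatched")

_FULL = 100.0 - 1e-6  # tolerance absorbing tabular rounding


@dataclass
class SpectralQcRecord:
    query_id: str
    category: str
    score: float
    db_status: str = "unknown"


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """Best hit by bitscore; ties by pident, qcov, then accession."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, -h.pident, -h.qcov, h.subject_id))


def classify_alignment_quality(hit: AlignmentHit | None) -> str:
    if hit is None:
        return "unmatched"
    full_id = hit.pident >= _FULL
    full_cov = hit.qcov >= _FULL
    if full_id and full_cov:
        return "exact"
    if full_id:
        return "exact_tag"
    if full_cov:
        return "aligned"
    return "aligned_tag"


def _peptide_key(raw: str) -> str:
    return normalize_il(strip_modifications(raw))


def match_psms(
    records: Sequence[DenovoRecord], psm_table: pd.DataFrame
) -> dict[str, str]:
    """Per-query db_status (matched / not_detected) from a PSM table.

    The join key is the scan reference when both sides carry one, else the
    L-normalized, modification-stripped peptide string (cross-tool scan
    numbering is unreliable).
    """
    if "Peptide" not in psm_table.columns:
        raise ValueError("PSM table has no 'Peptide' column")
    scan_col = next((c for c in ("Scan", "scan", "Spectrum") if c in psm_table.columns), None)
    use_scan = scan_col is not None and all(r.scan_ref is not None for r in records)
    if use_scan:
        keys = set(psm_table[scan_col].astype(str))
        return {
            r.query_id: "matched" if str(r.scan_ref) in keys else "not_detected"
            for r in records
        }
    keys = {_peptide_key(p) for p in psm_table["Peptide"].astype(str)}
    return {
        r.query_id: "matched" if r.peptide in keys else "not_detected"
        for r in records
    }


def spectral_qc(
    records: Sequence[DenovoRecord],
    hits: Sequence[AlignmentHit],
    psm_table: pd.DataFrame | None = None,
) -> list[SpectralQcRecord]:
    """Category + db_status per target query; partition is exhaustive."""
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    status = match_psms(records, psm_table) if psm_table is not None else {}
    out = []
    for r in records:
        cat = classify_alignment_quality(best_hit(by_query.get(r.query_id, [])))
        out.append(
            SpectralQcRecord(
                query_id=r.query_id,
                category=cat,
                score=r.score,
                db_status=status.get(r.query_id, "unknown"),
            )
        )
    return out


def high_quality_matched_fraction(
    qc_records: Sequence[SpectralQcRecord], alc_threshold: float = 90.0
) -> float:
    """Among spectra with score >= threshold, the fraction matched in
    database searching; NaN (flagged) when none qualify."""
    hq = [r for r in qc_records if r.score >= alc_threshold]
    if not hq:
        logger.warning(
            "high_quality_matched_fraction: no records with score >= %s", alc_threshold
        )
        return float("nan")
    return sum(1 for r in hq if r.db_status == "matched") / len(hq)


# ---------------------------------------------------------------------------
# Database coverage (DN_only / DN_all / DB_only / DB_all)
# ---------------------------------------------------------------------------


@dataclass
class CoverageReport:
    """Per-rank taxon distributions of the four peptide sets."""

    distributions: dict[str, dict[str, dict[str, float]]]  # rank -> set -> taxon -> frac
    peptide_sets: dict[str, set[str]]  # set name -> peptide strings

    def taxa(self, rank: str, set_name: str) -> dict[str, float]:
        return self.distributions.get(rank, {}).get(set_name, {})


def psm_taxa(
    psm_table: pd.DataFrame,
    search_db: ReferenceDatabase,
    tree: TaxTree,
) -> dict[str, Lineage]:
    """Map database-search peptides to lineages via their protein accessions.

    Uses the PSM table's ``Accession`` column (semicolon-separated lists
    tolerated); a peptide hitting several proteins gets the conventional
    LCA of their lineages.  Without an Accession column, peptides are
    located by substring search over the search database (fixture scale).
    """
    taxmap = search_db.taxid_map
    by_pep: dict[str, list[Lineage]] = defaultdict(list)
    if "Accession" in psm_table.columns:
        for pep, accs in zip(
            psm_table["Peptide"].astype(str), psm_table["Accession"].astype(str)
        ):
            key = _peptide_key(pep)
            for acc in accs.split(";"):
                t = taxmap.get(acc.strip())
                if t is not None and t in tree:
                    by_pep[key].append(tree.lineage(t))
    else:
        logger.info("psm_taxa: no Accession column; substring search over database")
        for pep in psm_table["Peptide"].astype(str):
            key = _peptide_key(pep)
            for acc, seq, t in zip(
                search_db.accessions, search_db.sequences, search_db.taxids
            ):
                if t is not None and t in tree and key in seq:
                    by_pep[key].append(tree.lineage(t))
    return {pep: lca_conventional(lins) for pep, lins in by_pep.items() if lins}


def db_coverage_report(
    dn_lca: Sequence[LcaResult],
    dn_peptides: Mapping[str, str],
    db_peptide_lineages: Mapping[str, Lineage] | None,
    ranks: Sequence[str] = ("order", "family", "genus"),
) -> CoverageReport:
    """Taxon distributions of DN_only / DN_all / DB_only / DB_all peptide sets.

    ``dn_peptides`` maps query_id -> peptide string (the cross-set join
    key); ``db_peptide_lineages`` comes from :func:`psm_taxa` (None omits
    the DB sets with a warning).  Distributions at each rank are normalized
    to 1 over classified peptides of the set.
    """
    dn_lineages: dict[str, Lineage] = {}
    for r in dn_lca:
        if r.is_decoy_query and r.query_id in dn_peptides:
            continue
        pep = dn_peptides.get(r.query_id)
        if pep is not None and not r.is_decoy_query:
            dn_lineages[pep] = r.lineage

    dn_all = set(dn_lineages)
    if db_peptide_lineages is None:
        logger.warning("db_coverage_report: no database-search input; DB sets omitted")
        db_all: set[str] = set()
    else:
        db_all = set(db_peptide_lineages)
    sets = {
        "DN_all": dn_all,
        "DN_only": dn_all - db_all,
        "DB_all": db_all,
        "DB_only": db_all - dn_all,
    }

    def _lineage_of(pep: str, set_name: str) -> Lineage | None:
        if set_name.startswith("DN"):
            return dn_lineages.get(pep)
        return db_peptide_lineages.get(pep) if db_peptide_lineages else None

    dists: dict[str, dict[str, dict[str, float]]] = {}
    for rank in ranks:
        dists[rank] = {}
        for set_name, peps in sets.items():
            counts: Counter = Counter()
            for pep in peps:
                lin = _lineage_of(pep, set_name)
                if lin is None:
                    continue
                name = lin.name_at(rank)
                if name is not None:
                    counts[name] += 1
            total = sum(counts.values())
            dists[rank][set_name] = (
                {t: c / total for t, c in counts.items()} if total else {}
            )
    return CoverageReport(distributions=dists, peptide_sets=sets)


# ---------------------------------------------------------------------------
# Basic figures
# ---------------------------------------------------------------------------


def plot_spectral_qc(
    qc_records: Sequence[SpectralQcRecord],
    records: Sequence[DenovoRecord],
    out_dir: str | Path,
) -> list[Path]:
    """Score-vs-ppm scatter, score histogram, and category stacked bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots()
    xs = [r.score for r in records if r.ppm_error is not None]
    ys = [r.ppm_error for r in records if r.ppm_error is not None]
    ax.scatter(xs, ys, s=4, alpha=0.4)
    ax.set_xlabel("de novo score")
    ax.set_ylabel("ppm error")
    p = out_dir / "score_vs_ppm.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    ax.hist([r.score for r in qc_records], bins=30)
    ax.set_xlabel("de novo score")
    p = out_dir / "score_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    counts = Counter(r.category for r in qc_records)
    bottom = 0.0
    for cat in CATEGORIES:
        v = counts.get(cat, 0)
        ax.bar(["queries"], [v], bottom=[bottom], label=cat)
        bottom += v
    ax.legend()
    p = out_dir / "alignment_categories.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
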