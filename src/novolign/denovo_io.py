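"""Reading, filtering and normalization of de novo peptide tables.

De novo sequencing tools (PEAKS, DeepNovo, ...) export one peptide per
fragmentation spectrum together with a per-peptide quality score (ALC% for
PEAKS, a log-probability-like score <= 1 for DeepNovo).  This module parses
those tables into :class:`DenovoRecord` lists, applies quality filters,
generates scrambled decoy peptides, and writes the query FASTA used for
homology alignment.

Peptides are normalized before alignment: in-line modification annotations
are stripped and isoleucine is rewritten to leucine (I and L are isobaric
and indistinguishable by standard fragmentation).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DECOY_SUFFIX = "_DECOY"

#: residue alphabet after I->L normalization
ALPHABET = "ACDEFGHKLMNPQRSTVWY"

_MOD_SPAN = re.compile(r"\(.*?\)|\[.*?\]")

_PEAKS_SCORE_COLUMNS = ("ALC (%)", "ALC")
_DEEPNOVO_SCORE_COLUMNS = ("predicted_score", "Score")
_PEPTIDE_COLUMNS = ("Peptide", "predicted_sequence")


class DialectError(ValueError):
    """Raised when a de novo table does not match any known dialect."""


@dataclass
class DenovoRecord:
    """One de novo sequenced peptide (one spectrum)."""

    query_id: str
    peptide: str
    raw_peptide: str
    score: float
    ppm_error: float | None = None
    intensity: float | None = None
    scan_ref: str | None = None
    source_tool: str = "generic"
    is_decoy: bool = False

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass
class FilterConfig:
    """Quality filters applied to parsed de novo records.

    ``min_score_peaks`` is an ALC% in [0, 100]; ``min_score_deepnovo`` is on
    DeepNovo's native scale (<= 1, typically negative).  The optional filters
    are applied only when set.
    """

    min_score_peaks: float = 70.0
    min_score_deepnovo: float = -0.1
    max_abs_ppm: float | None = None
    min_length: int | None = None
    min_intensity: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_score_peaks <= 100.0:
            raise ValueError("min_score_peaks must be in [0, 100]")


def strip_modifications(raw: str) -> str:
    """Remove in-line modification annotations like ``M(+15.99)`` or ``[+42]``.

    Only parenthesized and bracketed spans are recognized; any other
    character passes through.  Commas are tolerated (DeepNovo writes
    residue,residue,... sequences) and removed.
    """
    if not raw:
        raise ValueError("empty peptide string")
    out = _MOD_SPAN.sub("", raw).replace(",", "").replace(" ", "")
    if not out:
        raise ValueError(f"peptide {raw!r} empty after stripping modifications")
    return out


def normalize_il(seq: str) -> str:
    """Replace every I by L (applied to queries and database sequences)."""
    return seq.replace("I", "L")


def _detect_dialect(columns: Sequence[str]) -> str:
    cols = set(columns)
    if cols & set(_PEAKS_SCORE_COLUMNS):
        return "peaks"
    if cols & set(_DEEPNOVO_SCORE_COLUMNS) or "predicted_sequence" in cols:
        return "deepnovo"
    return "generic"


def _first_col(df: pd.DataFrame, names: Iterable[str]) -> str | None:
    for n in names:
        if n in df.columns:
            return n
    return None


def read_denovo(path: str | Path, dialect: str = "auto") -> list[DenovoRecord]:
    """Read a de novo peptide table (PEAKS CSV, DeepNovo TSV, or generic).

    Any delimited table is accepted provided it contains a peptide column
    with the header ``Peptide`` (or DeepNovo's ``predicted_sequence``).
    Unparseable rows are skipped with a logged count.
    """
    path = Path(path)
    if dialect not in ("auto", "peaks", "deepnovo", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    if dialect == "auto":
        dialect = _detect_dialect(df.columns)

    pep_col = _first_col(df, _PEPTIDE_COLUMNS)
    if pep_col is None:
        raise DialectError(
            f"{path.name}: no 'Peptide' column found "
            f"(columns: {', '.join(map(str, df.columns))})"
        )
    if dialect == "peaks":
        score_col = _first_col(df, _PEAKS_SCORE_COLUMNS)
    elif dialect == "deepnovo":
        score_col = _first_col(df, _DEEPNOVO_SCORE_COLUMNS)
    else:
        score_col = _first_col(df, _PEAKS_SCORE_COLUMNS + _DEEPNOVO_SCORE_COLUMNS)
    ppm_col = _first_col(df, ("ppm", "PPM", "ppm error"))
    area_col = _first_col(df, ("Area", "area", "Intensity"))
    scan_col = _first_col(df, ("Scan", "scan", "Spectrum"))

    records: list[DenovoRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        raw = rowd[pep_col]
        try:
            if not isinstance(raw, str) or not raw:
                raise ValueError("missing peptide")
            peptide = normalize_il(strip_modifications(raw))
            if not set(peptide) <= set(ALPHABET):
                raise ValueError(f"non-residue characters in {raw!r}")
            score = float(rowd[score_col]) if score_col else float("nan")
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        scan = str(rowd[scan_col]) if scan_col and pd.notna(rowd[scan_col]) else None
        qid = scan if scan is not None else f"row{i}"
        ppm = float(rowd[ppm_col]) if ppm_col and pd.notna(rowd[ppm_col]) else None
        inten = float(rowd[area_col]) if area_col and pd.notna(rowd[area_col]) else None
        records.append(
            DenovoRecord(
                query_id=qid,
                peptide=peptide,
                raw_peptide=str(raw),
                score=score,
                ppm_error=ppm,
                intensity=inten,
                scan_ref=scan,
                source_tool=dialect,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d unreadable rows", path.name, n_skipped)
    logger.info("%s: parsed %d de novo records (dialect=%s)", path.name, len(records), dialect)
    return records


def filter_denovo(records: Sequence[DenovoRecord], cfg: FilterConfig) -> list[DenovoRecord]:
    """Apply score/ppm/length/intensity thresholds; retention is logged."""
    out: list[DenovoRecord] = []
    for r in records:
        if r.source_tool == "peaks" and not (r.score >= cfg.min_score_peaks):
            continue
        if r.source_tool == "deepnovo" and not (r.score >= cfg.min_score_deepnovo):
            continue
        if cfg.max_abs_ppm is not None and (
            r.ppm_error is None or abs(r.ppm_error) > cfg.max_abs_ppm
        ):
            continue
        if cfg.min_length is not None and r.length < cfg.min_length:
            continue
        if cfg.min_intensity is not None and (
            r.intensity is None or r.intensity < cfg.min_intensity
        ):
            continue
        out.append(r)
    logger.info("filter_denovo: retained %d/%d records", len(out), len(records))
    return out


def make_decoy(peptide: str, rng: np.random.Generator) -> str:
    """Scramble a peptide in front of its tryptic cleavage site.

    If the peptide ends in K or R the terminal residue is kept fixed and the
    preceding residues are uniformly permuted; otherwise the whole sequence
    is permuted.  Length and residue multiset are conserved.
    """
    if len(peptide) < 2:
        logger.warning("make_decoy: peptide %r too short to scramble", peptide)
        return peptide
    if peptide[-1] in "KR":
        head, tail = peptide[:-1], peptide[-1]
    else:
        head, tail = peptide, ""
    scrambled = "".join(rng.permutation(list(head)))
    return scrambled + tail


def make_decoys(
    records: Sequence[DenovoRecord], rng: np.random.Generator
) -> list[DenovoRecord]:
    """One scrambled decoy per target record, query_id suffixed ``_DECOY``."""
    return [
        replace(
            r,
            query_id=r.query_id + DECOY_SUFFIX,
            peptide=make_decoy(r.peptide, rng),
            is_decoy=True,
        )
        for r in records
    ]


def write_query_fasta(
    records: Sequence[DenovoRecord],
    decoys: Sequence[DenovoRecord],
    path: str | Path,
) -> Path:
    """Write targets + decoys to FASTA; the decoy flag lives in the id suffix."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    with open(path, "w") as fh:
        for r in list(records) + list(decoys):
            fh.write(f">{r.query_id}\n{r.peptide}\n")
    logger.info(
        "wrote %d targets + %d decoys to %s", len(records), len(decoys), path
    )
    return path


def read_query_fasta(path: str | Path) -> list[tuple[str, str, bool]]:
    """Round-trip reader: (query_id, peptide, is_decoy) per entry."""
    out: list[tuple[str, str, bool]] = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        qid = rec.id
        out.append((qid, str(rec.seq), qid.endswith(DECOY_SUFFIX)))
    return out
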