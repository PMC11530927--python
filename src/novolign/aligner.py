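"""Short-peptide homology alignment against protein reference databases.

Two engines share one parameter set (:class:`AlignParams`, defaults tuned
for short de novo peptides with sequencing errors: PAM70, gap open/extend
2/4, min identity 85%, min query cover 80%, contiguous-seed mode):

* ``diamond`` — wraps the external DIAMOND binary (blastp mode) with
  masking and composition-based statistics disabled, which otherwise
  silently drop short-peptide hits;
* ``internal`` — an exact affine-gap Smith–Waterman search (via
  Bio.Align.PairwiseAligner) over a seed-indexed sequence store.  It serves
  as a DIAMOND-free engine at fixture scale and as the reference aligner.

Internal bitscores use ungapped Karlin–Altschul statistics (lambda and K
solved numerically from the scoring matrix and Robinson–Robinson background
frequencies); gapped DIAMOND bitscores are authoritative when present.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.optimize import brentq

from .denovo_io import DECOY_SUFFIX, normalize_il

logger = logging.getLogger(__name__)

#: Robinson & Robinson amino acid background frequencies
BACKGROUND_FREQS = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

#: blast-tabular column layout written/read by this module
TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qcovhsp staxids"
).split()


@dataclass
class AlignParams:
    """Alignment parameters optimized for short peptides with errors."""

    matrix: str = "PAM70"
    gap_open: int = 2
    gap_extend: int = 4
    min_pident: float = 85.0
    min_qcov: float = 80.0
    seed_mode: str = "ctg"
    custom_seed_shapes: list[str] | None = None
    max_hits_per_query: int = 25

    def __post_init__(self) -> None:
        if self.matrix not in ("PAM30", "PAM70", "BLOSUM62"):
            raise ValueError(f"unsupported matrix {self.matrix!r}")
        if not (0 < self.min_pident <= 100 and 0 < self.min_qcov <= 100):
            raise ValueError("min_pident and min_qcov must be in (0, 100]")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.seed_mode not in ("default", "query_indexed", "ctg"):
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")


@dataclass
class AlignmentHit:
    """One query->subject local alignment."""

    query_id: str
    subject_id: str
    pident: float
    qcov: float
    bitscore: float
    raw_score: int | None = None
    evalue: float | None = None
    subject_taxids: list[int] = field(default_factory=list)
    is_decoy_query: bool = False
    length: int = 0
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

_TAXID_PATTERNS = (re.compile(r"OX=(\d+)"), re.compile(r"TaxID=(\d+)"))


@dataclass
class ReferenceDatabase:
    """L-normalized sequence store with an accession->TaxID map."""

    accessions: list[str]
    sequences: list[str]
    taxids: list[int | None]
    source_fasta: Path | None = None

    def __len__(self) -> int:
        return len(self.accessions)

    @property
    def taxid_map(self) -> dict[str, int | None]:
        return dict(zip(self.accessions, self.taxids))

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.sequences)


def build_reference_db(
    fasta: str | Path,
    taxid_map_file: str | Path | None = None,
    taxid_regex: str | None = None,
) -> ReferenceDatabase:
    """Load a protein FASTA and derive per-entry NCBI TaxIDs.

    TaxIDs are parsed from UniProtKB ``OX=`` or UniRef ``TaxID=`` header
    tokens, a custom regex, or a 2-column accession->taxid map file.  If
    more than half the entries yield no TaxID the header dialect is
    rejected.
    """
    fasta = Path(fasta)
    extmap: dict[str, int] = {}
    if taxid_map_file is not None:
        import pandas as pd

        df = pd.read_csv(taxid_map_file, sep="\t", header=None, names=["acc", "taxid"])
        extmap = dict(zip(df["acc"].astype(str), df["taxid"].astype(int)))
    patterns = [re.compile(taxid_regex)] if taxid_regex else list(_TAXID_PATTERNS)

    accs: list[str] = []
    seqs: list[str] = []
    taxids: list[int | None] = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        accs.append(rec.id)
        seqs.append(normalize_il(str(rec.seq).upper()))
        taxid: int | None = extmap.get(rec.id)
        if taxid is None:
            for pat in patterns:
                m = pat.search(rec.description)
                if m:
                    taxid = int(m.group(1))
                    break
        taxids.append(taxid)
    if not accs:
        raise ValueError(f"{fasta}: empty FASTA")
    n_missing = sum(t is None for t in taxids)
    if n_missing > 0.5 * len(accs):
        raise ValueError(
            f"{fasta.name}: no TaxID derivable for {n_missing}/{len(accs)} entries "
            "(tried OX=/TaxID= header tokens"
            + (", custom regex" if taxid_regex else "")
            + (", map file" if taxid_map_file else "")
            + ")"
        )
    if n_missing:
        logger.warning("%s: %d entries without TaxID", fasta.name, n_missing)
    return ReferenceDatabase(accs, seqs, taxids, source_fasta=fasta)


# ---------------------------------------------------------------------------
# DIAMOND wrapper
# ---------------------------------------------------------------------------


def build_diamond_command(
    query_fasta: str | Path,
    db: str | Path,
    out: str | Path,
    params: AlignParams,
) -> list[str]:
    """Construct the ``diamond blastp`` invocation for the given parameters."""
    cmd = [
        "diamond", "blastp",
        "--query", str(query_fasta),
        "--db", str(db),
        "--out", str(out),
        "--matrix", params.matrix,
        "--gapopen", str(params.gap_open),
        "--gapextend", str(params.gap_extend),
        "--id", str(params.min_pident),
        "--query-cover", str(params.min_qcov),
        "--masking", "0",
        "--comp-based-stats", "0",
        "--max-target-seqs", str(params.max_hits_per_query),
        "--algo", params.seed_mode,
    ]
    if params.custom_seed_shapes:
        cmd += ["--shape-mask", ",".join(params.custom_seed_shapes)]
    cmd += ["--outfmt", "6", *TABULAR_COLUMNS]
    return cmd


def run_diamond(
    query_fasta: str | Path,
    db: str | Path,
    out: str | Path,
    params: AlignParams | None = None,
) -> Path:
    """Run DIAMOND blastp; raises with captured output on failure."""
    params = params or AlignParams()
    query_fasta = Path(query_fasta)
    if not query_fasta.exists() or query_fasta.stat().st_size == 0:
        raise ValueError(f"empty or missing query FASTA: {query_fasta}")
    if shutil.which("diamond") is None:
        raise FileNotFoundError(
            "diamond binary not found on PATH; use engine='internal' "
            "(exact Smith–Waterman) instead"
        )
    cmd = build_diamond_command(query_fasta, db, out, params)
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"diamond failed ({proc.returncode}):\n{proc.stderr}")
    return Path(out)


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics (ungapped)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def karlin_altschul_params(matrix_name: str) -> tuple[float, float, float]:
    """Solve (lambda, K, H) for a scoring matrix under background frequencies.

    lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1; H is the relative
    entropy lambda * E[s e^(lambda s)]; K follows the lattice-case formula
    K = lambda * exp(-2 sigma) / (H (1 - e^-lambda)) with sigma the Karlin
    sum over k-fold convolutions of the score distribution.
    """
    mat = substitution_matrices.load(matrix_name)
    probs: dict[int, float] = {}
    for a, pa in BACKGROUND_FREQS.items():
        for b, pb in BACKGROUND_FREQS.items():
            s = int(mat[a][b])
            probs[s] = probs.get(s, 0.0) + pa * pb
    lo, hi = min(probs), max(probs)
    p = np.zeros(hi - lo + 1)
    for s, q in probs.items():
        p[s - lo] = q
    p /= p.sum()
    scores = np.arange(lo, hi + 1)
    lam = brentq(lambda l: (p * np.exp(l * scores)).sum() - 1.0, 1e-6, 10.0, xtol=1e-14)
    H = lam * (p * scores * np.exp(lam * scores)).sum()
    Pk = p.copy()
    lo_k = lo
    sigma = 0.0
    for k in range(1, 500):
        if k > 1:
            Pk = np.convolve(Pk, p)
            lo_k += lo
        sc = np.arange(lo_k, lo_k + len(Pk))
        neg = sc < 0
        inner = (Pk[neg] * np.exp(lam * sc[neg])).sum() + Pk[~neg].sum()
        sigma += inner / k
        if inner / k < 1e-10:
            break
    K = lam * np.exp(-2.0 * sigma) / (H * (1.0 - np.exp(-lam)))
    return float(lam), float(K), float(H)


def bitscore_from_raw(raw_score: float, matrix_name: str) -> float:
    lam, K, _ = karlin_altschul_params(matrix_name)
    return (lam * raw_score - np.log(K)) / np.log(2.0)


# ---------------------------------------------------------------------------
# Internal exact aligner
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _pairwise_aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def reference_align(
    query: str,
    subject: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Exact affine-gap local alignment of one query against one subject."""
    params = params or AlignParams()
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = _pairwise_aligner(params.matrix, params.gap_open, params.gap_extend)
    if aligner.score(query, subject) <= 0:
        # no positive-scoring local alignment exists
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            pident=0.0,
            qcov=0.0,
            bitscore=bitscore_from_raw(0, params.matrix),
            raw_score=0,
            is_decoy_query=query_id.endswith(DECOY_SUFFIX),
        )
    alignments = aligner.align(query, subject)
    aln = alignments[0]
    raw = int(aln.score)
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / ncols if ncols else 0.0
    qblocks = aln.aligned[0]
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sblocks = aln.aligned[1]
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    qcov = 100.0 * (qend - qstart) / len(query)
    gapopens = 0
    for k in range(1, len(qblocks)):
        gapopens += 1  # every block boundary is one gap opening
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pident=pident,
        qcov=qcov,
        bitscore=bitscore_from_raw(raw, params.matrix),
        raw_score=raw,
        subject_taxids=[],
        is_decoy_query=query_id.endswith(DECOY_SUFFIX),
        length=ncols,
        mismatch=counts.mismatches,
        gapopen=gapopens,
        qstart=qstart + 1,
        qend=qend,
        sstart=sstart + 1,
        send=send,
    )


def _seed_index(db: ReferenceDatabase, seed_len: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for idx, seq in enumerate(db.sequences):
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i : i + seed_len], set()).add(idx)
    return index


def align_all(
    queries: Iterable[tuple[str, str]],
    db: ReferenceDatabase,
    params: AlignParams | None = None,
    seed_len: int = 4,
) -> list[AlignmentHit]:
    """Align every query peptide against the seed-indexed reference store.

    Candidate subjects are those sharing at least one exact ``seed_len``-mer
    with the query (contiguous seeds, mirroring the short-peptide seed
    mode); candidates are then aligned exactly and filtered by
    ``min_pident``/``min_qcov``.  Per query the best ``max_hits_per_query``
    hits by bitscore are kept (ties: pident, qcov, accession).
    """
    params = params or AlignParams()
    index = _seed_index(db, seed_len)
    dbsize = db.total_residues
    lam, K, _ = karlin_altschul_params(params.matrix)
    hits: list[AlignmentHit] = []
    for qid, qseq in queries:
        if len(qseq) < seed_len:
            continue
        candidates: set[int] = set()
        for i in range(len(qseq) - seed_len + 1):
            candidates |= index.get(qseq[i : i + seed_len], set())
        qhits: list[AlignmentHit] = []
        for idx in candidates:
            hit = reference_align(
                qseq, db.sequences[idx], params, query_id=qid,
                subject_id=db.accessions[idx],
            )
            if hit.pident >= params.min_pident and hit.qcov >= params.min_qcov:
                taxid = db.taxids[idx]
                hit.subject_taxids = [taxid] if taxid is not None else []
                hit.evalue = float(K * len(qseq) * dbsize * np.exp(-lam * hit.raw_score))
                qhits.append(hit)
        qhits.sort(key=lambda h: (-h.bitscore, -h.pident, -h.qcov, h.subject_id))
        hits.extend(qhits[: params.max_hits_per_query])
    logger.info("align_all: %d hits", len(hits))
    return hits


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def write_hits_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> Path:
    """Write hits in the blast-tabular (outfmt-6) column layout."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            taxcell = ";".join(str(t) for t in h.subject_taxids)
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pident:.1f}", str(h.length),
                        str(h.mismatch), str(h.gapopen), str(h.qstart), str(h.qend),
                        str(h.sstart), str(h.send),
                        f"{h.evalue:.2e}" if h.evalue is not None else "*",
                        f"{h.bitscore:.1f}", f"{h.qcov:.1f}", taxcell,
                    ]
                )
                + "\n"
            )
    return path


def parse_hits(
    path: str | Path, taxid_map: dict[str, int | None] | None = None
) -> list[AlignmentHit]:
    """Parse a blast-tabular file back into hits; malformed rows are skipped."""
    hits: list[AlignmentHit] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 12:
                    raise ValueError("too few columns")
                qid, sid = fields[0], fields[1]
                taxids: list[int] = []
                if len(fields) >= 14 and fields[13]:
                    taxids = [int(t) for t in fields[13].split(";") if t]
                elif taxid_map is not None and taxid_map.get(sid) is not None:
                    taxids = [int(taxid_map[sid])]
                hits.append(
                    AlignmentHit(
                        query_id=qid,
                        subject_id=sid,
                        pident=float(fields[2]),
                        qcov=float(fields[12]) if len(fields) >= 13 else 100.0,
                        bitscore=float(fields[11]),
                        evalue=None if fields[10] in ("*", "") else float(fields[10]),
                        subject_taxids=taxids,
                        is_decoy_query=qid.endswith(DECOY_SUFFIX),
                        length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                    )
                )
            except (ValueError, IndexError):
                n_bad += 1
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)
    return hits


def filter_hits(hits: Sequence[AlignmentHit], min_bitscore: float = 25.0) -> list[AlignmentHit]:
    """Retain hits with bitscore >= ``min_bitscore`` (inclusive)."""
    return [h for h in hits if h.bitscore >= min_bitscore]
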