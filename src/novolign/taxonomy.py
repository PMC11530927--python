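"""Taxonomic lineages and per-peptide consensus (LCA) assignment.

TaxIDs carried by alignment hits are mapped onto the fixed seven-rank
ladder (superkingdom..species) using an NCBI-taxdump-style tree, and each
peptide's hits are collapsed to a consensus lineage by one of three
algorithms of decreasing stringency:

* ``CON`` — conventional LCA: deepest rank at which *all* hit lineages agree;
* ``W`` — weighted LCA: taxa are weighted by their frequency over all
  target hits of the run; per peptide the most frequent taxa are kept until
  their normalized cumulative weight reaches ``weight_cutoff``, then CON is
  applied to the retained lineages;
* ``BIT`` — bitscore LCA: per rank, hits' bitscores are summed per taxon
  and a taxon is assigned when its share of the rank total exceeds
  ``weight_cutoff`` (with the default 0.6 at most one taxon can qualify).

Decoy queries are processed identically and flagged, but never contribute
to the global weights.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .aligner import AlignmentHit

logger = logging.getLogger(__name__)

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxTree:
    """Parent/rank/name maps in the NCBI taxdump sense; root is self-parented."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int = 1

    def __post_init__(self) -> None:
        self._lineage_cache: dict[int, "Lineage"] = {}
        self.validate()

    def validate(self) -> None:
        if self.parent.get(self.root) != self.root:
            raise ValueError("root must be its own parent")
        for taxid in self.parent:
            seen = set()
            node = taxid
            while node != self.root:
                if node in seen:
                    raise ValueError(f"cycle detected at taxid {node}")
                seen.add(node)
                if node not in self.parent:
                    raise ValueError(f"taxid {node} has no parent entry")
                node = self.parent[node]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def lineage(self, taxid: int) -> "Lineage":
        """Project a taxid onto the fixed rank ladder by parent-chasing."""
        if taxid in self._lineage_cache:
            return self._lineage_cache[taxid]
        taxids: dict[str, int] = {}
        names: dict[str, str] = {}
        node = taxid
        while True:
            r = self.rank.get(node, "no rank")
            if r in RANKS and r not in taxids:
                taxids[r] = node
                names[r] = self.name.get(node, str(node))
            if node == self.root:
                break
            node = self.parent[node]
        lin = Lineage(taxids=taxids, names=names)
        self._lineage_cache[taxid] = lin
        return lin


@dataclass
class Lineage:
    """Per-rank taxid and name on the fixed ladder; absent ranks are empty."""

    taxids: dict[str, int] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def taxid_at(self, rank: str) -> int | None:
        return self.taxids.get(rank)

    def name_at(self, rank: str) -> str | None:
        return self.names.get(rank)

    @property
    def depth(self) -> int:
        """Number of leading ladder ranks that are filled."""
        d = 0
        for r in RANKS:
            if r in self.taxids:
                d += 1
            else:
                break
        return d

    def is_empty(self) -> bool:
        return not self.taxids

    def truncate(self, depth: int) -> "Lineage":
        kept = RANKS[:depth]
        return Lineage(
            taxids={r: self.taxids[r] for r in kept if r in self.taxids},
            names={r: self.names[r] for r in kept if r in self.names},
        )


@dataclass
class LcaParams:
    method: str = "W"
    weight_cutoff: float = 0.6
    min_bitscore: float = 25.0

    def __post_init__(self) -> None:
        if self.method not in ("CON", "W", "BIT"):
            raise ValueError(f"unknown LCA method {self.method!r}")
        if not 0.0 < self.weight_cutoff <= 1.0:
            raise ValueError("weight_cutoff must be in (0, 1]")


@dataclass
class LcaResult:
    query_id: str
    lineage: Lineage
    method: str
    n_hits: int
    is_decoy_query: bool


# ---------------------------------------------------------------------------
# taxdump loading
# ---------------------------------------------------------------------------


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def load_taxdump(source: str | Path) -> TaxTree:
    """Load a taxonomy from an NCBI taxdump directory or a lineage TSV.

    A directory must contain ``nodes.dmp`` and ``names.dmp`` in the
    pipe-delimited dump dialect.  Alternatively an 8-column TSV
    (taxid + the seven rank names, with header) is accepted; internal
    nodes then get synthetic taxids.
    """
    source = Path(source)
    if source.is_dir():
        nodes = source / "nodes.dmp"
        names = source / "names.dmp"
        if not nodes.exists():
            raise FileNotFoundError(f"missing {nodes}")
        if not names.exists():
            raise FileNotFoundError(f"missing {names}")
        parent: dict[int, int] = {}
        rank: dict[int, str] = {}
        with open(nodes) as fh:
            for line in fh:
                fields = _parse_dmp_line(line)
                taxid, par, rk = int(fields[0]), int(fields[1]), fields[2]
                parent[taxid] = par
                rank[taxid] = rk if rk in RANKS else "no rank"
        name: dict[int, str] = {}
        with open(names) as fh:
            for line in fh:
                fields = _parse_dmp_line(line)
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                name[int(fields[0])] = fields[1]
        return TaxTree(parent=parent, rank=rank, name=name, root=min(parent))
    return _tree_from_lineage_table(source)


def _tree_from_lineage_table(path: Path) -> TaxTree:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 8:
        raise ValueError(f"{path}: expected 8 columns (taxid + {len(RANKS)} ranks)")
    df.columns = ["taxid", *RANKS]
    parent = {1: 1}
    rank = {1: "no rank"}
    name = {1: "root"}
    next_id = int(df["taxid"].max()) + 1
    node_ids: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        prev = 1
        for i, r in enumerate(RANKS):
            label = row[r]
            if pd.isna(label) or label == "":
                break
            if r == "species":
                nid = int(row["taxid"])
            else:
                key = (r, str(label))
                if key not in node_ids:
                    node_ids[key] = next_id
                    next_id += 1
                nid = node_ids[key]
            parent[nid] = prev
            rank[nid] = r
            name[nid] = str(label)
            prev = nid
    return TaxTree(parent=parent, rank=rank, name=name, root=1)


# ---------------------------------------------------------------------------
# LCA algorithms
# ---------------------------------------------------------------------------


def lca_conventional(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest rank at which all lineages agree; deeper ranks stay empty."""
    if not lineages:
        return Lineage()
    taxids: dict[str, int] = {}
    names: dict[str, str] = {}
    for r in RANKS:
        vals = {lin.taxid_at(r) for lin in lineages}
        if len(vals) == 1 and None not in vals:
            (t,) = vals
            taxids[r] = t
            names[r] = lineages[0].names.get(r, str(t))
        else:
            break
    return Lineage(taxids=taxids, names=names)


def compute_global_weights(hits: Iterable[AlignmentHit]) -> Counter:
    """Taxid frequencies over all target (non-decoy) hits of a run."""
    weights: Counter = Counter()
    for h in hits:
        if h.is_decoy_query:
            continue
        for t in h.subject_taxids:
            weights[t] += 1
    return weights


def lca_weighted(
    hits: Sequence[AlignmentHit],
    global_weights: Counter,
    params: LcaParams,
    tree: TaxTree,
) -> Lineage:
    """Weighted LCA: retain the globally most frequent taxa of this peptide
    until their normalized cumulative weight reaches the cutoff, then CON."""
    taxa = sorted(
        {t for h in hits for t in h.subject_taxids if t in tree},
        key=lambda t: (-global_weights.get(t, 0), t),
    )
    if not taxa:
        return Lineage()
    w = [global_weights.get(t, 0) for t in taxa]
    total = sum(w) or 1
    retained: list[int] = []
    cum = 0.0
    for t, wi in zip(taxa, w):
        retained.append(t)
        cum += wi / total
        if cum >= params.weight_cutoff:
            break
    return lca_conventional([tree.lineage(t) for t in retained])


def lca_bitscore(
    hits: Sequence[AlignmentHit], params: LcaParams, tree: TaxTree
) -> Lineage:
    """Bitscore LCA: per rank top-down, assign the taxon whose summed
    bitscore share exceeds the cutoff; stop at the first rank without one."""
    lineages = []
    for h in hits:
        for t in h.subject_taxids:
            if t in tree:
                lineages.append((tree.lineage(t), h.bitscore))
    if not lineages:
        return Lineage()
    taxids: dict[str, int] = {}
    names: dict[str, str] = {}
    for r in RANKS:
        sums: dict[int, float] = defaultdict(float)
        labels: dict[int, str] = {}
        for lin, bs in lineages:
            t = lin.taxid_at(r)
            if t is not None:
                sums[t] += bs
                labels[t] = lin.names.get(r, str(t))
        total = sum(sums.values())
        if total <= 0:
            break
        # ties broken by taxid ascending for determinism
        best = min(sums, key=lambda t: (-sums[t], t))
        if sums[best] / total > params.weight_cutoff:
            taxids[r] = best
            names[r] = labels[best]
        else:
            break
    return Lineage(taxids=taxids, names=names)


def assign_lca(
    hits: Sequence[AlignmentHit],
    params: LcaParams,
    tree: TaxTree,
) -> list[LcaResult]:
    """Per-query consensus lineage for bitscore-filtered hits.

    Hits whose taxids are absent from the tree are dropped with a logged
    count; decoy queries are processed identically and flagged.
    """
    n_unknown = sum(
        1 for h in hits for t in h.subject_taxids if t not in tree
    )
    if n_unknown:
        logger.warning("assign_lca: %d hit taxids absent from the tree", n_unknown)

    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    global_weights = compute_global_weights(hits)

    results: list[LcaResult] = []
    for qid, qhits in by_query.items():
        if params.method == "CON":
            lins = [
                tree.lineage(t)
                for h in qhits
                for t in h.subject_taxids
                if t in tree
            ]
            lineage = lca_conventional(lins) if lins else Lineage()
        elif params.method == "W":
            lineage = lca_weighted(qhits, global_weights, params, tree)
        else:
            lineage = lca_bitscore(qhits, params, tree)
        results.append(
            LcaResult(
                query_id=qid,
                lineage=lineage,
                method=params.method,
                n_hits=len(qhits),
                is_decoy_query=qhits[0].is_decoy_query,
            )
        )
    return results


def write_lca_tsv(results: Sequence[LcaResult], path: str | Path) -> Path:
    """Delimited LCA table: query, method, n_hits, decoy flag, rank names."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("query_id\tmethod\tn_hits\tis_decoy\t" + "\t".join(RANKS) + "\n")
        for r in results:
            cells = [r.lineage.names.get(rk, "") for rk in RANKS]
            fh.write(
                f"{r.query_id}\t{r.method}\t{r.n_hits}\t{int(r.is_decoy_query)}\t"
                + "\t".join(cells)
                + "\n"
            )
    return path
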