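"""Genus-level host assignment by lowest-common-ancestor placement.

Each annotated read carries up to ten homology hits; the hits vote on a
taxon in the MEGAN style.  Hits below a minimum bit score (50) are dropped;
of the survivors only those within a fixed percentage (10%) of the best bit
score are kept; the read is placed on the lowest common ancestor of the
surviving genera.  After all reads of a sample are placed, taxa supported by
less than a minimum fraction of the sample's assigned reads (1%) have their
reads promoted toward the root until a sufficiently supported ancestor is
reached.  Reads that do not rest on a genus node are reported UNCLASSIFIED:
classification is deliberately restricted to the genus rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .abundance import AbundanceTable, AbundanceUnit
from .refdb import BACTERIAL_SUBTYPES, Subtype
from .screen import AlignmentHit, AnnotatedRead, ScreeningSummary

RANKS = ("root", "superkingdom", "phylum", "class", "order", "family", "genus", "species")

UNCLASSIFIED = "UNCLASSIFIED"

DEFAULT_MIN_SCORE = 50.0
DEFAULT_TOP_PERCENT = 10.0
DEFAULT_MIN_SUPPORT = 0.01


@dataclass(frozen=True)
class TaxNode:
    id: int
    name: str
    rank: str
    parent_id: int


class TaxonomyTree:
    """Rooted, rank-annotated tree (subset of an NCBI-style node dump)."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.id: n for n in nodes}
        roots = [n for n in self.nodes.values() if n.parent_id == n.id]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._name_index: dict[str, int] = {}
        for n in self.nodes.values():
            if n.parent_id not in self.nodes:
                raise ValueError(f"node {n.id} has unknown parent {n.parent_id}")
            self._name_index.setdefault(n.name, n.id)
        # cycle check via root-path computation for every node
        for nid in self.nodes:
            self.path_to_root(nid)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Columns (tab-separated, header required): tax_id, parent_id, rank, name."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"tax_id", "parent_id", "rank", "name"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: taxonomy TSV needs columns {sorted(required)}")
        return cls(
            TaxNode(int(r.tax_id), str(r.name), str(r.rank), int(r.parent_id))
            for r in df.itertuples()
        )

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from the node up to (and including) the root."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown taxon id {node_id}")
        path = [node_id]
        seen = {node_id}
        cur = node_id
        while self.nodes[cur].parent_id != cur:
            cur = self.nodes[cur].parent_id
            if cur in seen:
                raise ValueError(f"cycle in taxonomy at node {cur}")
            seen.add(cur)
            path.append(cur)
        return path

    def genus_id(self, name: str) -> int | None:
        nid = self._name_index.get(name)
        if nid is not None and self.nodes[nid].rank == "genus":
            return nid
        return None

    def is_genus(self, node_id: int) -> bool:
        return self.nodes[node_id].rank == "genus"


def lca(taxa: Iterable[int], tree: TaxonomyTree) -> int:
    """Deepest node ancestral to (or equal to) every input node."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("lca: empty taxon set")
    paths = [tree.path_to_root(t)[::-1] for t in taxa]  # root-first
    deepest = tree.root.id
    for level in zip(*paths):
        if len(set(level)) == 1:
            deepest = level[0]
        else:
            break
    return deepest


@dataclass(frozen=True)
class Assignment:
    read_id: str
    taxon_id: int | None  # None == UNCLASSIFIED
    genus_name: str | None
    subtype: Subtype

    @property
    def rank_reported(self) -> str:
        return "genus" if self.taxon_id is not None else UNCLASSIFIED


def assign_read(
    hits: Sequence[AlignmentHit],
    ref_genus_map: Mapping[str, str | None],
    tree: TaxonomyTree,
    min_score: float = DEFAULT_MIN_SCORE,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> int | None:
    """Provisional LCA placement of one read from its top hits.

    Hits must arrive sorted by bit score descending.  Hits with bit score
    below ``min_score`` are dropped; survivors must score within
    ``top_percent`` percent of the best survivor; hits from references
    without a genus tag are dropped.  Returns a taxon id or None
    (unclassified) when no hit survives.
    """
    scored = [h for h in hits if h.bit_score >= min_score]
    if not scored:
        return None
    cutoff = (1.0 - top_percent / 100.0) * scored[0].bit_score
    kept = [h for h in scored if h.bit_score >= cutoff]
    genera: set[int] = set()
    for h in kept:
        genus = ref_genus_map.get(h.ref_id)
        if genus is None:
            continue
        gid = tree.genus_id(genus)
        if gid is not None:
            genera.add(gid)
    if not genera:
        return None
    return lca(genera, tree)


def apply_min_support(
    provisional: Mapping[str, int | None],
    tree: TaxonomyTree,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> dict[str, int | None]:
    """Promote weakly supported placements toward the root.

    Support of a node is the fraction of the sample's placed reads resting at
    or below it.  Reads on a node with support strictly below ``min_support``
    move to the nearest ancestor whose support reaches the threshold (the
    root, with support 1, is the final fallback).  Single leaf-to-root pass.
    """
    placed = {rid: t for rid, t in provisional.items() if t is not None}
    out: dict[str, int | None] = {
        rid: None for rid in provisional if provisional[rid] is None
    }
    total = len(placed)
    if total == 0:
        return out
    weight: dict[int, int] = {}
    for t in placed.values():
        weight[t] = weight.get(t, 0) + 1
    support: dict[int, float] = {}
    for node in weight:
        for anc in tree.path_to_root(node):
            support[anc] = support.get(anc, 0.0) + weight[node] / total
    for rid, t in placed.items():
        cur = t
        while support.get(cur, 0.0) < min_support and tree.nodes[cur].parent_id != cur:
            cur = tree.nodes[cur].parent_id
        out[rid] = cur
    return out


def assign_sample(
    annotated: Sequence[AnnotatedRead],
    ref_genus_map: Mapping[str, str | None],
    tree: TaxonomyTree,
    min_score: float = DEFAULT_MIN_SCORE,
    top_percent: float = DEFAULT_TOP_PERCENT,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> list[Assignment]:
    """Full per-sample placement: LCA votes, min-support pass, genus filter."""
    provisional = {
        ann.read_id: assign_read(
            ann.top_hits, ref_genus_map, tree, min_score, top_percent
        )
        for ann in annotated
    }
    final = apply_min_support(provisional, tree, min_support)
    assignments: list[Assignment] = []
    for ann in annotated:
        node = final[ann.read_id]
        if node is not None and tree.is_genus(node):
            assignments.append(
                Assignment(ann.read_id, node, tree.nodes[node].name, ann.subtype)
            )
        else:
            assignments.append(Assignment(ann.read_id, None, None, ann.subtype))
    return assignments


@dataclass
class CommunityProfile:
    """Signaled-community summary across samples."""

    relative: AbundanceTable  # per-sample genus fractions among annotated reads
    signaled_flags: dict[str, str]  # genus -> "signaled-bacterial" | "signaled-algal"
    signaled_read_ratio: pd.Series  # signaled reads / total sample reads


def community_profile(
    assignments_by_sample: Mapping[str, Sequence[Assignment]],
    summaries: Mapping[str, ScreeningSummary],
) -> CommunityProfile:
    """Relative genus abundances among annotated reads, with signaled flags.

    A genus reached through an IAA-synthetase subtype is flagged
    signaled-bacterial; one reached through the algal cyclin, signaled-algal.
    Each sample row (genus fractions plus an explicit unclassified column)
    sums to one.
    """
    flags: dict[str, str] = {}
    rows: dict[str, dict[str, float]] = {}
    ratio: dict[str, float] = {}
    for sample_id, assignments in assignments_by_sample.items():
        counts: dict[str, int] = {}
        for a in assignments:
            key = a.genus_name if a.genus_name is not None else UNCLASSIFIED
            counts[key] = counts.get(key, 0) + 1
            if a.genus_name is not None:
                flag = (
                    "signaled-bacterial"
                    if a.subtype in BACTERIAL_SUBTYPES
                    else "signaled-algal"
                )
                flags.setdefault(a.genus_name, flag)
        n = sum(counts.values())
        rows[sample_id] = (
            {g: c / n for g, c in counts.items()} if n else {UNCLASSIFIED: 1.0}
        )
        total = summaries[sample_id].total_reads
        signaled = sum(c for g, c in counts.items() if g != UNCLASSIFIED)
        ratio[sample_id] = signaled / total if total else 0.0
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    if UNCLASSIFIED not in table.columns:
        table[UNCLASSIFIED] = 0.0
    return CommunityProfile(
        relative=AbundanceTable(values=table, unit=AbundanceUnit.RELATIVE),
        signaled_flags=flags,
        signaled_read_ratio=pd.Series(ratio).sort_index(),
    )


def write_assignments_tsv(
    assignments_by_sample: Mapping[str, Sequence[Assignment]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tread_id\ttaxon_id\tgenus\trank_reported\tsubtype\n")
        for sample_id in sorted(assignments_by_sample):
            for a in assignments_by_sample[sample_id]:
                fh.write(
                    f"{sample_id}\t{a.read_id}\t"
                    f"{a.taxon_id if a.taxon_id is not None else 'NA'}\t"
                    f"{a.genus_name or UNCLASSIFIED}\t{a.rank_reported}\t"
                    f"{a.subtype.value}\n"
                )
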