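"""Curated protein reference database with greedy identity dedup.

The screening stage aligns translated reads against a small, curated set of
proteins: the last-step enzymes of the three bacterial IAA biosynthesis
pathways (indoleacetamide hydrolase for IAM, indoleacetaldehyde dehydrogenase
for IPA, indoleacetonitrile nitrilase for IAOx/IAN) plus the algal cyclin that
bacterial IAA regulates.  Before screening, each subtype's sequence set is made
non-redundant by greedy incremental clustering at a fractional-identity
threshold (0.97 by default), in the style of cd-hit: sequences are visited
longest-first and each either joins the first cluster whose representative it
matches at or above the threshold, or founds a new cluster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_IDENTITY_THRESHOLD = 0.97


class Subtype(str, Enum):
    """Functional-gene subtype screened for.

    The three bacterial members are IAA-synthetase last-step enzymes; the
    algal cyclin marks IAA-responsive ("signaled") phytoplankton.
    """

    IAM_HYDROLASE = "IAM_HYDROLASE"
    IPA_DEHYDROGENASE = "IPA_DEHYDROGENASE"
    IAN_NITRILASE = "IAN_NITRILASE"
    ALGAL_CYCLIN = "ALGAL_CYCLIN"


BACTERIAL_SUBTYPES = frozenset(
    {Subtype.IAM_HYDROLASE, Subtype.IPA_DEHYDROGENASE, Subtype.IAN_NITRILASE}
)


@dataclass(frozen=True)
class ProteinRecord:
    """A single curated reference protein."""

    id: str
    subtype: Subtype
    sequence: str
    source_genus: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r} "
                "(stops and gaps are not allowed)"
            )

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDB:
    """Non-redundant, subtype-labelled protein reference set."""

    records: list[ProteinRecord]
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    # representative_id -> ids of absorbed members (incl. the representative)
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in ReferenceDB")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, rid: str) -> ProteinRecord:
        return self._index[rid]

    @property
    def _index(self) -> dict[str, ProteinRecord]:
        return {r.id: r for r in self.records}

    @property
    def total_residues(self) -> int:
        """Aggregate database length in amino acids (E-value search space n)."""
        return sum(r.length_aa for r in self.records)

    def genus_map(self) -> dict[str, str | None]:
        return {r.id: r.source_genus for r in self.records}


_GENUS_RE = re.compile(r"genus=(\S+)")


def read_protein_fasta(path: str | Path, subtype: Subtype) -> list[ProteinRecord]:
    """Read one subtype's curated proteins from FASTA.

    Headers may carry a ``genus=<name>`` token that populates ``source_genus``.
    Sequences are upper-cased; a single trailing ``*`` (stop) is stripped;
    internal stops are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper().rstrip("*")
        if "*" in seq:
            raise ValueError(
                f"{path}: entry {rec.id!r} (#{i}) has an internal stop codon"
            )
        m = _GENUS_RE.search(rec.description)
        records.append(
            ProteinRecord(
                id=rec.id,
                subtype=subtype,
                sequence=seq,
                source_genus=m.group(1) if m else None,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


# Overlap alignment maximising matched positions: match=1, mismatch=0, gaps
# free.  The optimum equals the longest common subsequence, which is what the
# identity numerator should count when no gap penalty is imposed.
_identity_aligner = PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=0.0,
    extend_gap_score=0.0,
)


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Fractional identity between two proteins, cd-hit style.

    Identity = (identical aligned positions on the optimal global-overlap
    alignment) / (length of the shorter sequence).  Symmetric, in [0, 1].
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("pairwise_identity: empty sequence")
    matches = _identity_aligner.score(sa, sb)
    return matches / min(len(sa), len(sb))


def dedupe(
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> ReferenceDB:
    """Greedy incremental clustering per subtype; returns representatives.

    Records are visited per subtype in length-descending order (ties broken
    lexicographically by id).  Each record joins the first existing cluster
    whose representative matches it at identity >= threshold, else founds a
    new cluster.  Only representatives appear in the returned database.
    """
    if not records:
        raise ValueError("dedupe: empty input")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"dedupe: threshold {threshold} outside (0, 1]")
    reps: list[ProteinRecord] = []
    clusters: dict[str, list[str]] = {}
    by_subtype: dict[Subtype, list[ProteinRecord]] = {}
    for r in records:
        by_subtype.setdefault(r.subtype, []).append(r)
    for subtype in sorted(by_subtype, key=lambda s: s.value):
        ordered = sorted(by_subtype[subtype], key=lambda r: (-r.length_aa, r.id))
        subtype_reps: list[ProteinRecord] = []
        for rec in ordered:
            for rep in subtype_reps:
                if pairwise_identity(rec, rep) >= threshold:
                    clusters[rep.id].append(rec.id)
                    break
            else:
                subtype_reps.append(rec)
                clusters[rec.id] = [rec.id]
        reps.extend(subtype_reps)
    return ReferenceDB(records=reps, identity_threshold=threshold, clusters=clusters)


def build_reference_db(
    fasta_by_subtype: dict[Subtype, str | Path],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> ReferenceDB:
    """Read per-subtype FASTAs and dedupe into one ReferenceDB."""
    records: list[ProteinRecord] = []
    for subtype, path in fasta_by_subtype.items():
        records.extend(read_protein_fasta(path, subtype))
    return dedupe(records, threshold)


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> None:
    """Write representatives as ``><id> subtype=<SUBTYPE> [genus=<name>]``."""
    with open(path, "w") as fh:
        for r in db.records:
            header = f">{r.id} subtype={r.subtype.value}"
            if r.source_genus:
                header += f" genus={r.source_genus}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def write_cluster_tsv(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\n")
        for rep_id, members in db.clusters.items():
            for mid in members:
                fh.write(f"{rep_id}\t{mid}\n")


def read_reference_fasta(path: str | Path) -> ReferenceDB:
    """Read back a combined reference FASTA written by write_reference_fasta."""
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m_sub = re.search(r"subtype=(\S+)", rec.description)
        if m_sub is None:
            raise ValueError(f"{path}: entry {rec.id!r} lacks subtype= tag")
        m_gen = _GENUS_RE.search(rec.description)
        records.append(
            ProteinRecord(
                id=rec.id,
                subtype=Subtype(m_sub.group(1)),
                sequence=str(rec.seq).upper(),
                source_genus=m_gen.group(1) if m_gen else None,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return ReferenceDB(records=records)
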