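"""Translated homology screening of metagenomic reads.

Each nucleotide read is translated in all six frames, split at stop codons,
and every resulting peptide fragment is aligned locally (Smith-Waterman,
BLOSUM62, affine gaps open 11 / extend 1) against every reference protein.
Statistical significance follows the Karlin-Altschul model,
``E = K * m * n * exp(-lambda * S)``, with m the fragment length and n the
total residue count of the reference database.  A read is annotated with the
subtype of its best hit only when that hit clears the study's rule: E-value
<= 1e-5, identity strictly greater than 50%, and alignment length strictly
greater than 25 amino acids.  Up to ten passing hits are retained per read
for downstream taxonomic placement.

This is an exact search, not a seeded heuristic: at the read counts this
package targets, exhaustive dynamic programming is affordable and removes
any dependence on an external aligner binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .refdb import ProteinRecord, ReferenceDB, Subtype

# Standard gapped BLOSUM62 (open 11, extend 1) Karlin-Altschul parameters.
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041

MIN_FRAGMENT_AA = 8

NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Read:
    """A nucleotide read belonging to one sample."""

    id: str
    sequence: str
    sample_id: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"read {self.id!r}: non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    raw_score: int
    bit_score: float
    identity: float
    alignment_length_aa: int
    evalue: float


@dataclass(frozen=True)
class AnnotatedRead:
    read_id: str
    sample_id: str
    subtype: Subtype
    best_hit: AlignmentHit
    top_hits: tuple[AlignmentHit, ...]


@dataclass(frozen=True)
class ScreenThresholds:
    """Annotation rule; identity and alignment length are strict inequalities."""

    evalue_max: float = 1e-5
    identity_min: float = 0.50
    alnlen_min: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.evalue_max:
            raise ValueError("evalue_max must be positive")
        if not 0 <= self.identity_min <= 1:
            raise ValueError("identity_min must lie in [0, 1]")
        if self.alnlen_min < 0:
            raise ValueError("alnlen_min must be non-negative")


@dataclass
class ScreeningSummary:
    sample_id: str
    total_reads: int
    annotated_by_subtype: dict[Subtype, int] = field(default_factory=dict)

    @property
    def total_annotated(self) -> int:
        return sum(self.annotated_by_subtype.values())


def reverse_complement(seq: str) -> str:
    return seq.translate(NT_COMPLEMENT)[::-1]


def six_frame_translate(
    read: Read, min_fragment_aa: int = MIN_FRAGMENT_AA
) -> list[tuple[int, str]]:
    """Translate all six frames; split at stops; drop short fragments.

    Codons containing N translate to X.  Returns (frame, peptide) pairs with
    frame in {+1,+2,+3,-1,-2,-3}.
    """
    out: list[tuple[int, str]] = []
    rc = reverse_complement(read.sequence)
    for strand, seq in ((1, read.sequence), (-1, rc)):
        for offset in range(3):
            frame = strand * (offset + 1)
            sub = seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            peptide = str(Seq(sub).translate())
            for fragment in peptide.split("*"):
                if len(fragment) >= min_fragment_aa:
                    out.append((frame, fragment))
    return out


_blosum62 = substitution_matrices.load("BLOSUM62")

# BLAST convention: a gap of length k costs 11 + k, i.e. the first gapped
# position costs 12 and each extension 1.
_sw_aligner = PairwiseAligner(
    mode="local",
    substitution_matrix=_blosum62,
    open_gap_score=-12.0,
    extend_gap_score=-1.0,
)


def smith_waterman_score(query: str, target: str) -> int:
    """Optimal local-alignment raw score only (no traceback; fast path)."""
    if not query or not target:
        raise ValueError("smith_waterman: empty peptide")
    return int(_sw_aligner.score(query, target))


def smith_waterman(query: str, target: str) -> tuple[int, float, int]:
    """Optimal local alignment under BLOSUM62 with affine gaps (11/1).

    Returns (raw_score, identity, alignment_length_aa).  Identity counts
    identical aligned positions over all alignment columns, gap columns
    included (the BLAST convention — distinct from the clustering identity
    used to build the reference database).
    """
    if not query or not target:
        raise ValueError("smith_waterman: empty peptide")
    alignments = _sw_aligner.align(query, target)
    score = int(alignments.score)
    if score <= 0:
        return 0, 0.0, 0
    best = alignments[0]
    counts = best.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / length if length else 0.0
    return score, identity, length


def evalue(
    raw_score: float,
    query_len_aa: int,
    db_len_aa: int,
    K: float = K_GAPPED,
    lam: float = LAMBDA_GAPPED,
) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if query_len_aa <= 0 or db_len_aa <= 0:
        raise ValueError("sequence lengths must be positive")
    return K * query_len_aa * db_len_aa * math.exp(-lam * raw_score)


def bit_score(raw_score: float, K: float = K_GAPPED, lam: float = LAMBDA_GAPPED) -> float:
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return (lam * raw_score - math.log(K)) / math.log(2.0)


def _min_score_for_evalue(
    evalue_max: float, query_len_aa: int, db_len_aa: int, K: float, lam: float
) -> float:
    """Smallest raw score whose E-value can still pass the cutoff."""
    return math.log(K * query_len_aa * db_len_aa / evalue_max) / lam


def passes_annotation(hit: AlignmentHit, thresholds: ScreenThresholds) -> bool:
    """The study's best-hit rule: identity > 50% AND alignment length > 25 aa.

    Both are strict inequalities; a hit at exactly 0.50 identity or exactly
    25 aligned residues is rejected.
    """
    return (
        hit.evalue <= thresholds.evalue_max
        and hit.identity > thresholds.identity_min
        and hit.alignment_length_aa > thresholds.alnlen_min
    )


def screen_read(
    read: Read,
    db: ReferenceDB,
    thresholds: ScreenThresholds = ScreenThresholds(),
    K: float = K_GAPPED,
    lam: float = LAMBDA_GAPPED,
) -> AnnotatedRead | None:
    """Align all translated fragments of one read against the full database.

    Keeps hits with E <= evalue_max (best frame per reference); the best hit
    is the maximum bit score, ties broken by lower E-value then lexicographic
    reference id.  The read is annotated only when the best hit passes the
    identity/length rule; the annotation carries up to ten passing hits for
    taxonomic placement.
    """
    if not db.records:
        raise ValueError("screen_read: empty reference database")
    n = db.total_residues
    fragments = six_frame_translate(read)
    best_per_ref: dict[str, AlignmentHit] = {}
    for frame, peptide in fragments:
        m = len(peptide)
        s_min = _min_score_for_evalue(thresholds.evalue_max, m, n, K, lam)
        for ref in db.records:
            score = smith_waterman_score(peptide, ref.sequence)
            if score < s_min:
                continue
            raw, ident, alen = smith_waterman(peptide, ref.sequence)
            e = evalue(raw, m, n, K, lam)
            if e > thresholds.evalue_max:
                continue
            hit = AlignmentHit(
                read_id=read.id,
                ref_id=ref.id,
                frame=frame,
                raw_score=raw,
                bit_score=bit_score(raw, K, lam),
                identity=ident,
                alignment_length_aa=alen,
                evalue=e,
            )
            prev = best_per_ref.get(ref.id)
            if prev is None or (hit.bit_score, -hit.evalue) > (
                prev.bit_score,
                -prev.evalue,
            ):
                best_per_ref[ref.id] = hit
    if not best_per_ref:
        return None
    ranked = sorted(
        best_per_ref.values(), key=lambda h: (-h.bit_score, h.evalue, h.ref_id)
    )
    best = ranked[0]
    if not passes_annotation(best, thresholds):
        return None
    return AnnotatedRead(
        read_id=read.id,
        sample_id=read.sample_id,
        subtype=db.by_id(best.ref_id).subtype,
        best_hit=best,
        top_hits=tuple(ranked[:10]),
    )


def screen_sample(
    reads: Iterable[Read],
    db: ReferenceDB,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> tuple[list[AnnotatedRead], ScreeningSummary]:
    """Screen every read of one sample; the summary keeps the total input
    read count, which is the per-million denominator for RPKM."""
    annotated: list[AnnotatedRead] = []
    total = 0
    sample_id = ""
    counts: dict[Subtype, int] = {}
    for read in reads:
        total += 1
        sample_id = read.sample_id
        result = screen_read(read, db, thresholds)
        if result is not None:
            annotated.append(result)
            counts[result.subtype] = counts.get(result.subtype, 0) + 1
    return annotated, ScreeningSummary(
        sample_id=sample_id, total_reads=total, annotated_by_subtype=counts
    )


def read_reads(path: str | Path, sample_id: str) -> list[Read]:
    """Load nucleotide reads from FASTQ or FASTA (qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = [
        Read(id=rec.id, sequence=str(rec.seq), sample_id=sample_id)
        for rec in SeqIO.parse(str(path), fmt)
    ]
    if not reads:
        raise ValueError(f"{path}: no reads found")
    return reads


def write_hits_tsv(annotated: Sequence[AnnotatedRead], path: str | Path) -> None:
    """blast-outfmt6-like table of every retained hit."""
    with open(path, "w") as fh:
        fh.write(
            "qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tframe\tsubtype\n"
        )
        for ann in annotated:
            for hit in ann.top_hits:
                fh.write(
                    f"{hit.read_id}\t{hit.ref_id}\t{100 * hit.identity:.2f}\t"
                    f"{hit.alignment_length_aa}\t{hit.evalue:.3g}\t"
                    f"{hit.bit_score:.1f}\t{hit.frame:+d}\t{ann.subtype.value}\n"
                )
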