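"""Length-normalized functional-gene quantification (RPKM).

Annotated-read counts are converted to Reads Per Kilobase per Million mapped
reads.  References are proteins, so the "kilobase" uses the coding-nucleotide
length 3 * length_aa.  The per-million denominator is the sample's total
clean read count, not just the annotated reads: the screened gene set is tiny
and per-annotated normalization would be degenerate (configurable upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .refdb import ReferenceDB, Subtype
from .screen import AnnotatedRead


class AbundanceUnit(str, Enum):
    RPKM = "RPKM"
    RELATIVE = "RELATIVE"


@dataclass
class AbundanceTable:
    """Sample-by-feature matrix; features are subtypes or genera."""

    values: pd.DataFrame  # rows: sample_id, columns: feature id
    unit: AbundanceUnit

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.unit is AbundanceUnit.RELATIVE:
            sums = self.values.sum(axis=1)
            if not ((sums - 1.0).abs() < 1e-9).all():
                raise ValueError("RELATIVE rows must sum to 1")

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.to_csv(fh, sep="\t", index_label="sample_id")


def rpkm(count: int, ref_length_aa: int, total_reads: int) -> float:
    """RPKM = count * 1e9 / (3 * L_aa * total_reads)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if ref_length_aa <= 0:
        raise ValueError("reference length must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive (zero mapped reads)")
    return count * 1e9 / (3 * ref_length_aa * total_reads)


def subtype_abundance(
    annotated: Iterable[AnnotatedRead],
    db: ReferenceDB,
    totals: Mapping[str, int],
) -> AbundanceTable:
    """Per sample and subtype, the sum over references of per-reference RPKM.

    ``totals`` maps sample_id to the sample's total clean read count; a
    missing sample is an error because the denominator would be undefined.
    """
    counts: dict[tuple[str, str], int] = {}
    samples: set[str] = set()
    for ann in annotated:
        if ann.sample_id not in totals:
            raise KeyError(f"no total read count for sample {ann.sample_id!r}")
        db.by_id(ann.best_hit.ref_id)  # KeyError if reference missing
        counts[(ann.sample_id, ann.best_hit.ref_id)] = (
            counts.get((ann.sample_id, ann.best_hit.ref_id), 0) + 1
        )
        samples.add(ann.sample_id)
    samples.update(totals)
    sample_ids = sorted(samples)
    features = [s.value for s in Subtype]
    table = pd.DataFrame(0.0, index=sample_ids, columns=features)
    for (sample_id, ref_id), n in counts.items():
        ref = db.by_id(ref_id)
        table.loc[sample_id, ref.subtype.value] += rpkm(
            n, ref.length_aa, totals[sample_id]
        )
    return AbundanceTable(values=table, unit=AbundanceUnit.RPKM)
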