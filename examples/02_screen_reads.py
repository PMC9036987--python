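"""Screen metagenomic reads for IAA-synthetase and cyclin genes.

Translates each read in six frames, aligns every fragment against the
reference database (Smith-Waterman, BLOSUM62), keeps hits with E <= 1e-5,
and annotates a read when its best hit has >50% identity over >25 aligned
amino acids.  Annotated counts become length-normalized RPKM abundances.
"""

from phycosignal.abundance import subtype_abundance
from phycosignal.refdb import dedupe
from phycosignal.screen import Read, screen_sample
from phycosignal.simulate import (
    SimulationConfig,
    make_abundance_series,
    make_reads,
    make_references,
)

config = SimulationConfig(seed=1, n_samples=4, reads_per_sample=100)
records, _ = make_references(config)
db = dedupe(records, 0.97)
abundance_series, _ = make_abundance_series(config)
reads, truth = make_reads(config, records, abundance_series)

sample_id = "S01"
sample = [Read(rid, seq, sample_id) for rid, seq in reads[sample_id]]
annotated, summary = screen_sample(sample, db)

print(f"{sample_id}: {summary.total_annotated} / {summary.total_reads} reads annotated")
for subtype, n in sorted(summary.annotated_by_subtype.items()):
    print(f"  {subtype.value}: {n} reads")

table = subtype_abundance(annotated, db, {sample_id: summary.total_reads})
print("\nsubtype abundances (RPKM, reads per kilobase per million sample reads):")
print(table.values.round(1).to_string())
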