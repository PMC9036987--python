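"""Self-contained synthetic fixtures for every pipeline stage.

The generator emulates the study design the pipeline targets: a handful of
photo-bioreactor metagenome samples containing short nucleotide reads, where
"signaled" bacterial genera carry diverged copies of IAA-synthetase genes
and the signaled alga carries a cyclin gene, embedded in random background
reads; plus genus-abundance series with planted monotone associations
between bacteria and phytoplankton, driven by shared log-normal latent
factors so that Spearman detection is a genuine statistical event.

Everything is a pure function of (config, seed): the same configuration
yields byte-identical files.  Background reads are uniform-random
nucleotides, which guarantees no accidental homology with the reference
proteins and keeps screening precision measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import GenusNode, Kingdom
from .refdb import ProteinRecord, Subtype
from .taxonomy import RANKS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Codons per amino acid (standard code), used for reverse translation.
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_CODE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_CODE):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class GenusSpec:
    name: str
    kingdom: Kingdom
    signaled: bool
    carried_subtypes: tuple[Subtype, ...] = ()


@dataclass(frozen=True)
class PlantedPair:
    """A bacterium-phytoplankton association driven by a shared latent factor."""

    bacterium: str
    phytoplankton: str
    loading: float = 1.0  # magnitude of the bacterial loading on the factor
    sign: int = 1  # +1 monotone-increasing association, -1 decreasing


def default_genera() -> tuple[GenusSpec, ...]:
    """The default community: dominant signaled genera of algal bioreactors
    (Pseudomonas, Hydrogenophaga, Zoogloea carrying IAA synthetases, Serratia
    with the nitrilase route, Chlorella as the IAA-responsive alga) plus
    non-signaled bacteria and a non-signaled green alga."""
    return (
        GenusSpec("Pseudomonas", Kingdom.BACTERIA, True, (Subtype.IPA_DEHYDROGENASE,)),
        GenusSpec("Hydrogenophaga", Kingdom.BACTERIA, True, (Subtype.IAM_HYDROLASE,)),
        GenusSpec("Zoogloea", Kingdom.BACTERIA, True, (Subtype.IAM_HYDROLASE,)),
        GenusSpec("Serratia", Kingdom.BACTERIA, True, (Subtype.IAN_NITRILASE,)),
        GenusSpec("Bradyrhizobium", Kingdom.BACTERIA, False),
        GenusSpec("Thauera", Kingdom.BACTERIA, False),
        GenusSpec("Streptomyces", Kingdom.BACTERIA, False),
        GenusSpec("Chlorella", Kingdom.PHYTOPLANKTON, True, (Subtype.ALGAL_CYCLIN,)),
        GenusSpec("Scenedesmus", Kingdom.PHYTOPLANKTON, False),
    )


def default_correlation_structure() -> tuple[PlantedPair, ...]:
    return (
        PlantedPair("Pseudomonas", "Chlorella", 1.0, +1),
        PlantedPair("Hydrogenophaga", "Chlorella", 1.0, +1),
        PlantedPair("Zoogloea", "Chlorella", 1.0, +1),
        PlantedPair("Serratia", "Scenedesmus", 1.0, +1),
        PlantedPair("Thauera", "Scenedesmus", 1.0, +1),
        PlantedPair("Bradyrhizobium", "Chlorella", 1.0, -1),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 12
    genera: tuple[GenusSpec, ...] = field(default_factory=default_genera)
    read_length_nt: int = 150
    reads_per_sample: int = 150
    gene_read_fraction: float = 0.4
    gene_mutation_rate: float = 0.02
    sequencing_error_rate: float = 0.005
    genus_divergence: float = 0.15
    abundance_noise_sd: float = 0.1
    correlation_structure: tuple[PlantedPair, ...] = field(
        default_factory=default_correlation_structure
    )

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        for rate in (
            self.gene_mutation_rate,
            self.sequencing_error_rate,
            self.genus_divergence,
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        names = [g.name for g in self.genera]
        if len(names) != len(set(names)):
            raise ValueError("duplicate genus names in configuration")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def genus_flags(self) -> dict[str, GenusNode]:
        return {
            g.name: GenusNode(g.name, g.kingdom, g.signaled) for g in self.genera
        }


def planted_fraction_config(
    fraction: float,
    n_positive_pairs: int = 10,
    n_samples: int = 24,
    seed: int = 0,
    loading: float = 1.0,
    noise_sd: float = 0.1,
    n_noise_bacteria: int = 5,
) -> SimulationConfig:
    """A community whose true signaled positive-edge fraction is ``fraction``.

    ``n_positive_pairs`` bacteria each share a latent factor with one
    phytoplankton; the first ``round(fraction * n_positive_pairs)`` bacteria
    are flagged signaled.  Extra unpaired bacteria contribute null pairs.
    Intended for recovery experiments on the network stage alone (the genera
    carry no genes, so no reads are simulated for them).
    """
    n_signaled = int(round(fraction * n_positive_pairs))
    genera: list[GenusSpec] = [GenusSpec("Phyto01", Kingdom.PHYTOPLANKTON, False)]
    pairs: list[PlantedPair] = []
    for i in range(n_positive_pairs):
        name = f"Bact{i + 1:02d}"
        genera.append(GenusSpec(name, Kingdom.BACTERIA, i < n_signaled))
        pairs.append(PlantedPair(name, "Phyto01", loading, +1))
    for i in range(n_noise_bacteria):
        genera.append(GenusSpec(f"Noise{i + 1:02d}", Kingdom.BACTERIA, False))
    return SimulationConfig(
        seed=seed,
        n_samples=n_samples,
        genera=tuple(genera),
        abundance_noise_sd=noise_sd,
        correlation_structure=tuple(pairs),
    )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# Real-world family placements for the default genera; anything else gets a
# synthetic one-genus lineage.  Shared families (Zoogloea/Thauera) exercise
# the LCA fallback above genus rank.
_KNOWN_LINEAGES: dict[str, tuple[str, str, str, str, str]] = {
    "Pseudomonas": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae"),
    "Serratia": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Yersiniaceae"),
    "Hydrogenophaga": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae"),
    "Zoogloea": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Rhodocyclales", "Zoogloeaceae"),
    "Thauera": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Rhodocyclales", "Zoogloeaceae"),
    "Bradyrhizobium": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Nitrobacteraceae"),
    "Streptomyces": ("Bacteria", "Actinobacteria", "Actinomycetia", "Streptomycetales", "Streptomycetaceae"),
    "Chlorella": ("Eukaryota", "Chlorophyta", "Trebouxiophyceae", "Chlorellales", "Chlorellaceae"),
    "Scenedesmus": ("Eukaryota", "Chlorophyta", "Chlorophyceae", "Sphaeropleales", "Scenedesmaceae"),
}


def make_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """Taxonomy table (tax_id, parent_id, rank, name) covering all genera."""
    rows: list[tuple[int, int, str, str]] = [(1, 1, "root", "root")]
    index: dict[tuple[str, str], int] = {("root", "root"): 1}
    next_id = 2

    def node(rank: str, name: str, parent: int) -> int:
        nonlocal next_id
        key = (rank, name)
        if key in index:
            return index[key]
        index[key] = next_id
        rows.append((next_id, parent, rank, name))
        next_id += 1
        return index[key]

    for spec in config.genera:
        if spec.name in _KNOWN_LINEAGES:
            sk, phylum, cls, order, family = _KNOWN_LINEAGES[spec.name]
        else:
            sk = "Bacteria" if spec.kingdom is Kingdom.BACTERIA else "Eukaryota"
            phylum = f"{spec.name}_phylum"
            cls = f"{spec.name}_class"
            order = f"{spec.name}_order"
            family = f"{spec.name}_family"
        parent = node("superkingdom", sk, 1)
        parent = node("phylum", phylum, parent)
        parent = node("class", cls, parent)
        parent = node("order", order, parent)
        parent = node("family", family, parent)
        node("genus", spec.name, parent)
    return pd.DataFrame(rows, columns=["tax_id", "parent_id", "rank", "name"])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n_mut = int(round(rate * len(seq)))
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    for i in sites:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_references(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Curated-reference stand-ins plus subtype template proteins.

    For each subtype a hidden template protein (300-500 aa) is drawn; each
    genus carrying the subtype contributes a genus-tagged variant diverged
    from the template at ``genus_divergence``.  One additional near-duplicate
    (~1% divergence from an existing variant, same genus) is appended per
    subtype that has any carrier, to exercise redundancy removal.  Returns
    (records, templates) where templates maps subtype value to its template.
    """
    rng = _rng(config, 1)
    templates: dict[str, str] = {}
    records: list[ProteinRecord] = []
    for subtype in Subtype:
        length = int(rng.integers(300, 501))
        templates[subtype.value] = _random_protein(rng, length)
    for subtype in Subtype:
        carriers = [g for g in config.genera if subtype in g.carried_subtypes]
        first_variant: ProteinRecord | None = None
        for g in carriers:
            variant = _mutate_protein(
                rng, templates[subtype.value], config.genus_divergence
            )
            rec = ProteinRecord(
                id=f"{subtype.value}_{g.name}",
                subtype=subtype,
                sequence=variant,
                source_genus=g.name,
            )
            records.append(rec)
            if first_variant is None:
                first_variant = rec
        if first_variant is not None:
            dup = _mutate_protein(rng, first_variant.sequence, 0.01)
            records.append(
                ProteinRecord(
                    id=f"{first_variant.id}_dup",
                    subtype=subtype,
                    sequence=dup,
                    source_genus=first_variant.source_genus,
                )
            )
    return records, templates


def make_abundance_series(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Genus-by-sample abundance matrix with planted monotone associations.

    Each phytoplankton that anchors planted pairs gets a latent factor
    F_s ~ N(0,1) per sample; its own abundance is exp(F + eps) and each
    paired bacterium's is exp(sign * loading * F + eps), eps ~ N(0, noise_sd).
    Unpaired genera are pure log-normal noise.  Returns the matrix and the
    truth list of intended edges with signs.
    """
    rng = _rng(config, 2)
    samples = config.sample_ids
    names = [g.name for g in config.genera]
    known = set(names)
    for pair in config.correlation_structure:
        if pair.bacterium not in known or pair.phytoplankton not in known:
            raise KeyError(f"planted pair references unknown genus: {pair}")
    factors: dict[str, np.ndarray] = {}
    values = pd.DataFrame(0.0, index=names, columns=samples)
    paired_bacteria = {p.bacterium for p in config.correlation_structure}
    anchored_phyto = {p.phytoplankton for p in config.correlation_structure}
    for phyto in sorted(anchored_phyto):
        factors[phyto] = rng.standard_normal(config.n_samples)
    for g in config.genera:
        noise = rng.standard_normal(config.n_samples) * config.abundance_noise_sd
        if g.name in anchored_phyto:
            values.loc[g.name] = np.exp(factors[g.name] + noise)
        elif g.name in paired_bacteria:
            pair = next(
                p for p in config.correlation_structure if p.bacterium == g.name
            )
            f = factors[pair.phytoplankton]
            values.loc[g.name] = np.exp(pair.sign * pair.loading * f + noise)
        else:
            values.loc[g.name] = np.exp(rng.standard_normal(config.n_samples))
    truth = [
        {
            "bacterium": p.bacterium,
            "phytoplankton": p.phytoplankton,
            "sign": "POSITIVE" if p.sign > 0 else "NEGATIVE",
        }
        for p in config.correlation_structure
    ]
    return values, truth


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def make_community_genes(
    config: SimulationConfig, references: Sequence[ProteinRecord]
) -> dict[str, str]:
    """Nucleotide gene copies actually present in the community.

    Each genus's carried gene is its reference protein mutated at
    ``gene_mutation_rate`` (the within-genus divergence between database
    entry and resident strain), reverse-translated with uniformly sampled
    synonymous codons.  Keyed by reference id; near-duplicate database
    records do not seed community genes.
    """
    rng = _rng(config, 3)
    genes: dict[str, str] = {}
    for rec in references:
        if rec.id.endswith("_dup") or rec.source_genus is None:
            continue
        mutated = _mutate_protein(rng, rec.sequence, config.gene_mutation_rate)
        genes[rec.id] = _reverse_translate(rng, mutated)
    return genes


_NT = np.array(list("ACGT"))


def _sequencing_errors(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def make_reads(
    config: SimulationConfig,
    references: Sequence[ProteinRecord],
    abundance: pd.DataFrame,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Per-sample reads plus a truth table.

    A fixed fraction of each sample's reads is gene-bearing, allocated across
    carrying genera in proportion to their abundance in that sample (largest
    remainder rounding); the rest is uniform-random background.  Reads are
    windows of the community gene copies, hit by per-base sequencing errors,
    on either strand.  Returns ({sample_id: [(read_id, sequence), ...]},
    truth DataFrame with read_id, sample_id, source_genus, subtype).
    """
    rng = _rng(config, 4)
    genes = make_community_genes(config, references)
    carriers = [
        rec
        for rec in references
        if rec.id in genes
    ]
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[tuple[str, str, str, str]] = []
    L = config.read_length_nt
    for sample_id in config.sample_ids:
        n_gene_total = int(round(config.gene_read_fraction * config.reads_per_sample))
        weights = np.array(
            [abundance.loc[rec.source_genus, sample_id] for rec in carriers],
            dtype=float,
        )
        if weights.sum() <= 0 or not carriers:
            alloc = np.zeros(len(carriers), dtype=int)
        else:
            ideal = n_gene_total * weights / weights.sum()
            alloc = np.floor(ideal).astype(int)
            remainder = ideal - alloc
            short = n_gene_total - alloc.sum()
            for i in np.argsort(-remainder)[:short]:
                alloc[i] += 1
        sample_reads: list[tuple[str, str]] = []
        idx = 0
        for rec, n_reads in zip(carriers, alloc):
            gene = genes[rec.id]
            for _ in range(int(n_reads)):
                start = int(rng.integers(0, max(1, len(gene) - L + 1)))
                window = gene[start : start + L]
                window = _sequencing_errors(
                    rng, window, config.sequencing_error_rate
                )
                if rng.random() < 0.5:
                    window = _revcomp(window)
                read_id = f"{sample_id}_r{idx:05d}"
                idx += 1
                sample_reads.append((read_id, window))
                truth_rows.append(
                    (read_id, sample_id, rec.source_genus, rec.subtype.value)
                )
        while idx < config.reads_per_sample:
            seq = "".join(_NT[rng.integers(0, 4, size=L)])
            read_id = f"{sample_id}_r{idx:05d}"
            idx += 1
            sample_reads.append((read_id, seq))
            truth_rows.append((read_id, sample_id, "background", "background"))
        reads[sample_id] = sample_reads
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "source_genus", "subtype"]
    )
    return reads, truth


def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit the complete fixture directory; deterministic bytes for a fixed
    config.  Returns a map of artifact name to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    taxonomy = make_taxonomy(config)
    paths["taxonomy"] = outdir / "taxonomy.tsv"
    taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)

    references, _ = make_references(config)
    for subtype in Subtype:
        recs = [r for r in references if r.subtype is subtype]
        if not recs:
            continue
        p = outdir / f"references_{subtype.value}.fasta"
        with open(p, "w") as fh:
            for r in recs:
                fh.write(f">{r.id} genus={r.source_genus}\n")
                for i in range(0, len(r.sequence), 60):
                    fh.write(r.sequence[i : i + 60] + "\n")
        paths[f"references_{subtype.value}"] = p

    abundance, edge_truth = make_abundance_series(config)
    paths["abundance"] = outdir / "abundance.tsv"
    abundance.to_csv(paths["abundance"], sep="\t", index_label="genus")
    paths["edge_truth"] = outdir / "edge_truth.tsv"
    pd.DataFrame(edge_truth).to_csv(paths["edge_truth"], sep="\t", index=False)

    reads, read_truth = make_reads(config, references, abundance)
    for sample_id, sample_reads in reads.items():
        p = outdir / f"reads_{sample_id}.fastq"
        with open(p, "w") as fh:
            for read_id, seq in sample_reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[f"reads_{sample_id}"] = p
    paths["read_truth"] = outdir / "read_truth.tsv"
    read_truth.to_csv(paths["read_truth"], sep="\t", index=False)

    flags = pd.DataFrame(
        [
            (g.name, g.kingdom.value, g.signaled)
            for g in config.genera
        ],
        columns=["genus", "kingdom", "signaled"],
    )
    paths["genus_flags"] = outdir / "genus_flags.tsv"
    flags.to_csv(paths["genus_flags"], sep="\t", index=False)
    return paths
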