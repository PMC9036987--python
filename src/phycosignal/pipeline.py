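"""End-to-end orchestration of the inference chain.

Stage order: simulate (optional) -> refdb -> screen -> abundance / taxonomy
-> network.  Each stage reads its inputs from and writes its outputs to a
working directory; outputs are TSV/JSON with a header comment naming the
configuration hash that produced them, so a rerun with the same
configuration is byte-identical and provenance is auditable.

The network stage correlates the genus abundance series across samples and
marks a bacterial genus "signaled" when the screening + taxonomy stages
detected IAA-synthetase reads assigned to it — the signaled flag is a
pipeline result, not an input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import abundance as abundance_mod
from . import network as network_mod
from . import refdb as refdb_mod
from . import screen as screen_mod
from . import simulate as simulate_mod
from . import taxonomy as taxonomy_mod
from .network import GenusNode, Kingdom
from .refdb import Subtype
from .screen import AlignmentHit, AnnotatedRead, ScreenThresholds, ScreeningSummary

logger = logging.getLogger("phycosignal")

STAGE_ORDER = ("simulate", "refdb", "screen", "abundance", "taxonomy", "network")


@dataclass(frozen=True)
class PipelineConfig:
    workdir: str = "phycosignal_run"
    seed: int = 0
    # screening thresholds (study defaults)
    evalue_max: float = 1e-5
    identity_min: float = 0.50
    alnlen_min: int = 25
    # reference dedup
    dedupe_threshold: float = 0.97
    # LCA parameters
    lca_min_score: float = 50.0
    lca_top_percent: float = 10.0
    lca_min_support: float = 0.01
    # network thresholds
    network_rho: float = 0.6
    network_p: float = 0.01
    # synthetic fixture size
    n_samples: int = 12
    reads_per_sample: int = 150

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.evalue_max, "evalue_max must be positive"),
            (0.0 <= self.identity_min <= 1.0, "identity_min must be in [0, 1]"),
            (self.alnlen_min >= 0, "alnlen_min must be non-negative"),
            (0.0 < self.dedupe_threshold <= 1.0, "dedupe_threshold must be in (0, 1]"),
            (self.lca_min_score >= 0, "lca_min_score must be non-negative"),
            (0.0 <= self.lca_top_percent <= 100.0, "lca_top_percent must be in [0, 100]"),
            (0.0 <= self.lca_min_support <= 1.0, "lca_min_support must be in [0, 1]"),
            (0.0 <= self.network_rho < 1.0, "network_rho must be in [0, 1)"),
            (0.0 < self.network_p <= 1.0, "network_p must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters only; the working directory is
        deployment detail and must not change provenance."""
        params = dataclasses.asdict(self)
        params.pop("workdir")
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def thresholds(self) -> ScreenThresholds:
        return ScreenThresholds(
            evalue_max=self.evalue_max,
            identity_min=self.identity_min,
            alnlen_min=self.alnlen_min,
        )


def _header(config: PipelineConfig) -> str:
    return f"# config_hash={config.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, **to_csv_kw) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", **to_csv_kw)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path.name}: run the '{produced_by}' stage first"
        )
    return path


def run_simulate(config: PipelineConfig) -> Path:
    outdir = Path(config.workdir) / "fixture"
    sim = simulate_mod.SimulationConfig(
        seed=config.seed,
        n_samples=config.n_samples,
        reads_per_sample=config.reads_per_sample,
    )
    paths = simulate_mod.write_fixture(sim, outdir)
    logger.info("simulate: wrote %d artifacts to %s", len(paths), outdir)
    return outdir


def run_refdb(config: PipelineConfig) -> refdb_mod.ReferenceDB:
    workdir = Path(config.workdir)
    fixture = workdir / "fixture"
    records: list[refdb_mod.ProteinRecord] = []
    for subtype in Subtype:
        p = fixture / f"references_{subtype.value}.fasta"
        if p.exists():
            records.extend(refdb_mod.read_protein_fasta(p, subtype))
    if not records:
        raise FileNotFoundError(
            "missing input references_*.fasta: run the 'simulate' stage first "
            "(or place curated subtype FASTAs in the fixture directory)"
        )
    db = refdb_mod.dedupe(records, config.dedupe_threshold)
    refdb_mod.write_reference_fasta(db, workdir / "reference_db.fasta")
    refdb_mod.write_cluster_tsv(db, workdir / "reference_clusters.tsv")
    logger.info("refdb: %d records -> %d representatives", len(records), len(db))
    return db


_HIT_COLUMNS = [
    "sample_id", "read_id", "ref_id", "frame", "raw_score", "bit_score",
    "identity", "alignment_length_aa", "evalue", "subtype", "is_best",
]


def run_screen(config: PipelineConfig) -> None:
    workdir = Path(config.workdir)
    fixture = workdir / "fixture"
    _require(workdir / "reference_db.fasta", "refdb")
    db = refdb_mod.read_reference_fasta(workdir / "reference_db.fasta")
    read_files = sorted(fixture.glob("reads_*.fastq")) + sorted(
        fixture.glob("reads_*.fasta")
    )
    if not read_files:
        raise FileNotFoundError(
            "missing input reads_*.fastq: run the 'simulate' stage first"
        )
    rows: list[list] = []
    summary_rows: list[dict] = []
    for rf in read_files:
        sample_id = rf.stem.removeprefix("reads_")
        reads = screen_mod.read_reads(rf, sample_id)
        annotated, summary = screen_mod.screen_sample(
            reads, db, config.thresholds()
        )
        for ann in annotated:
            for hit in ann.top_hits:
                rows.append(
                    [
                        ann.sample_id, ann.read_id, hit.ref_id, hit.frame,
                        hit.raw_score, hit.bit_score, hit.identity,
                        hit.alignment_length_aa, hit.evalue,
                        ann.subtype.value, hit is ann.best_hit,
                    ]
                )
        srow = {
            "sample_id": summary.sample_id,
            "total_reads": summary.total_reads,
            "total_annotated": summary.total_annotated,
        }
        for subtype in Subtype:
            srow[subtype.value] = summary.annotated_by_subtype.get(subtype, 0)
        summary_rows.append(srow)
        logger.info(
            "screen: %s annotated %d / %d reads",
            sample_id, summary.total_annotated, summary.total_reads,
        )
    _write_tsv(
        pd.DataFrame(rows, columns=_HIT_COLUMNS),
        workdir / "screen_hits.tsv", config, index=False,
    )
    _write_tsv(
        pd.DataFrame(summary_rows),
        workdir / "screen_summary.tsv", config, index=False,
    )


def load_annotated(workdir: Path) -> tuple[dict[str, list[AnnotatedRead]], dict[str, ScreeningSummary]]:
    """Rebuild per-sample annotations from the screen stage's TSVs."""
    hits = pd.read_csv(_require(workdir / "screen_hits.tsv", "screen"), sep="\t", comment="#")
    summary = pd.read_csv(
        _require(workdir / "screen_summary.tsv", "screen"), sep="\t", comment="#"
    )
    annotated: dict[str, list[AnnotatedRead]] = {}
    if not hits.empty:
        for (sample_id, read_id), grp in hits.groupby(
            ["sample_id", "read_id"], sort=True
        ):
            grp = grp.sort_values(["bit_score", "ref_id"], ascending=[False, True])
            top = tuple(
                AlignmentHit(
                    read_id=read_id, ref_id=r.ref_id, frame=int(r.frame),
                    raw_score=int(r.raw_score), bit_score=float(r.bit_score),
                    identity=float(r.identity),
                    alignment_length_aa=int(r.alignment_length_aa),
                    evalue=float(r.evalue),
                )
                for r in grp.itertuples()
            )
            annotated.setdefault(str(sample_id), []).append(
                AnnotatedRead(
                    read_id=read_id, sample_id=str(sample_id),
                    subtype=Subtype(grp.iloc[0]["subtype"]),
                    best_hit=top[0], top_hits=top,
                )
            )
    summaries = {
        str(r.sample_id): ScreeningSummary(
            sample_id=str(r.sample_id),
            total_reads=int(r.total_reads),
            annotated_by_subtype={
                s: int(getattr(r, s.value)) for s in Subtype if getattr(r, s.value, 0)
            },
        )
        for r in summary.itertuples()
    }
    for sid in summaries:
        annotated.setdefault(sid, [])
    return annotated, summaries


def run_abundance(config: PipelineConfig) -> abundance_mod.AbundanceTable:
    workdir = Path(config.workdir)
    db = refdb_mod.read_reference_fasta(_require(workdir / "reference_db.fasta", "refdb"))
    annotated, summaries = load_annotated(workdir)
    totals = {sid: s.total_reads for sid, s in summaries.items()}
    flat = [a for sample in sorted(annotated) for a in annotated[sample]]
    table = abundance_mod.subtype_abundance(flat, db, totals)
    _write_tsv(table.values, workdir / "subtype_rpkm.tsv", config, index_label="sample_id")
    logger.info("abundance: wrote subtype RPKM for %d samples", len(totals))
    return table


def run_taxonomy(config: PipelineConfig) -> taxonomy_mod.CommunityProfile:
    workdir = Path(config.workdir)
    fixture = workdir / "fixture"
    tree = taxonomy_mod.TaxonomyTree.from_tsv(
        _require(fixture / "taxonomy.tsv", "simulate")
    )
    db = refdb_mod.read_reference_fasta(_require(workdir / "reference_db.fasta", "refdb"))
    annotated, summaries = load_annotated(workdir)
    genus_map = db.genus_map()
    assignments = {
        sid: taxonomy_mod.assign_sample(
            anns, genus_map, tree,
            min_score=config.lca_min_score,
            top_percent=config.lca_top_percent,
            min_support=config.lca_min_support,
        )
        for sid, anns in annotated.items()
    }
    taxonomy_mod.write_assignments_tsv(assignments, workdir / "read_assignments.tsv")
    profile = taxonomy_mod.community_profile(assignments, summaries)
    _write_tsv(
        profile.relative.values, workdir / "genus_profile.tsv", config,
        index_label="sample_id",
    )
    flags = pd.DataFrame(
        sorted(profile.signaled_flags.items()), columns=["genus", "signaled_via"]
    )
    _write_tsv(flags, workdir / "signaled_genera.tsv", config, index=False)
    logger.info("taxonomy: %d signaled genera detected", len(flags))
    return profile


def run_network(config: PipelineConfig) -> dict:
    workdir = Path(config.workdir)
    fixture = workdir / "fixture"
    profiles = pd.read_csv(
        _require(fixture / "abundance.tsv", "simulate"),
        sep="\t", comment="#", index_col="genus",
    )
    kingdoms = pd.read_csv(
        _require(fixture / "genus_flags.tsv", "simulate"), sep="\t", comment="#"
    ).set_index("genus")["kingdom"]
    detected = pd.read_csv(
        _require(workdir / "signaled_genera.tsv", "taxonomy"), sep="\t", comment="#"
    )
    signaled = set(detected["genus"]) if not detected.empty else set()
    flags = {
        g: GenusNode(g, Kingdom(kingdoms[g]), g in signaled) for g in profiles.index
    }
    net = network_mod.build_network(
        profiles, flags, rho_threshold=config.network_rho, p_threshold=config.network_p
    )
    network_mod.write_edge_tsv(net, workdir / "network_edges.tsv")
    network_mod.write_node_tsv(net, workdir / "network_nodes.tsv")
    network_mod.write_graphml(net, workdir / "network.graphml")
    report: dict = {"config_hash": config.config_hash()}
    for label, sub in (
        ("signaled", net.subgraph(signaled=True)),
        ("nonsignaled", net.subgraph(signaled=False)),
    ):
        if sub.nodes and len(sub.nodes) >= 3:
            report[f"{label}_metrics"] = network_mod.metrics(sub).to_dict()
        report[f"{label}_edges"] = len(sub.edges)
    try:
        n_sig, n_non, frac = network_mod.signaled_positive_fraction(net)
        report["signaled_positive_edges"] = n_sig
        report["nonsignaled_positive_edges"] = n_non
        report["signaled_positive_fraction_pct"] = frac
    except ValueError:
        report["signaled_positive_fraction_pct"] = None
    with open(workdir / "network_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info(
        "network: %d edges; signaled positive fraction %s%%",
        len(net.edges), report.get("signaled_positive_fraction_pct"),
    )
    return report


_RUNNERS = {
    "simulate": run_simulate,
    "refdb": run_refdb,
    "screen": run_screen,
    "abundance": run_abundance,
    "taxonomy": run_taxonomy,
    "network": run_network,
}


def run_stage(stage: str, config: PipelineConfig):
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGE_ORDER}")
    logger.info("running stage %s (config %s)", stage, config.config_hash())
    return _RUNNERS[stage](config)


def run_all(config: PipelineConfig) -> dict:
    Path(config.workdir).mkdir(parents=True, exist_ok=True)
    for stage in STAGE_ORDER:
        result = run_stage(stage, config)
    return result
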