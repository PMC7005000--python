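"""Config-driven end-to-end runs: simulate -> analyze, or ingest -> analyze.

A run is described by one YAML file; every random draw flows from the single
seed it contains, so simulate-mode reruns with an identical config produce
byte-identical outputs. Each stage logs its record counts and the manifest
records the config hash, seed, package versions and per-stage bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

import numpy as np

from . import io, readprep, simulate, sites, stats
from .model import (
    AnnotationSet,
    ConfigurationError,
    SelectionScenario,
    SiteTable,
)

logger = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    plating: int
    depth: int
    baseline_survival: Optional[float] = None  # None for the control


@dataclass
class RunConfig:
    """Validated run description (see `load_config` for the YAML layout)."""

    mode: str
    out_dir: Path
    seed: int = 0
    min_sites: int = 3
    geometric_mean: bool = False
    pseudocount: int = 0
    # simulate mode
    genome_length: int = 200_000
    gc: float = 0.5
    circular: bool = True
    n_genes: int = 100
    mean_gene_len: int = 800
    density: float = simulate.DEFAULT_DENSITY
    n_replicates: int = 3
    control_growth: float = 40.0
    samples: dict[str, SampleSpec] = field(default_factory=dict)
    control_sample: str = "control"
    resistant_n: int = 0
    resistant_factor: float = 1.0
    # planted genes must be long enough to carry several insertion mutants at
    # the configured density, else there is no lineage to recover
    resistant_min_gene_len: int = 300
    survival_factor: dict[str, float] = field(default_factory=dict)
    emit_fastq: bool = False
    junction: str = simulate.DEFAULT_JUNCTION
    read_len: int = 50
    # real mode
    genbank: Optional[Path] = None
    replicates: list[dict[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ConfigurationError(f"mode must be simulate|real, got {self.mode!r}")
        if self.min_sites < 0:
            raise ConfigurationError("min_sites must be >= 0")
        if self.mode == "simulate":
            if not self.samples:
                raise ConfigurationError("simulate mode needs a samples mapping")
            if self.control_sample not in self.samples:
                raise ConfigurationError(
                    f"control sample {self.control_sample!r} missing from samples"
                )
            if len(self.samples) < 2:
                raise ConfigurationError("need the control plus >= 1 treated sample")
            if self.n_replicates < 1:
                raise ConfigurationError("n_replicates must be >= 1")
            for name, spec in self.samples.items():
                if name != self.control_sample and spec.baseline_survival is None:
                    raise ConfigurationError(
                        f"treated sample {name!r} needs baseline_survival"
                    )
        else:
            if self.genbank is None:
                raise ConfigurationError("real mode needs a genbank path")
            if not self.replicates:
                raise ConfigurationError("real mode needs a replicates list")
            for i, rep in enumerate(self.replicates):
                if "control" not in rep:
                    raise ConfigurationError(f"replicate {i + 1} has no control sample")
                if len(rep) < 2:
                    raise ConfigurationError(f"replicate {i + 1} has no treated sample")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return config_from_dict(doc, base=Path(path).parent)


def config_from_dict(doc: dict[str, Any], base: Path = Path(".")) -> RunConfig:
    sim = doc.get("simulate", {}) or {}
    samples = {}
    for name, spec in (sim.get("samples") or {}).items():
        samples[name] = SampleSpec(
            plating=int(spec["plating"]),
            depth=int(spec["depth"]),
            baseline_survival=(
                float(spec["baseline_survival"]) if "baseline_survival" in spec else None
            ),
        )
    resistant = sim.get("resistant", {}) or {}
    cfg = RunConfig(
        mode=doc.get("mode", "simulate"),
        out_dir=base / doc.get("out_dir", "tnsi_out"),
        seed=int(doc.get("seed", 0)),
        min_sites=int(doc.get("min_sites", 3)),
        geometric_mean=bool(doc.get("geometric_mean", False)),
        pseudocount=int(doc.get("pseudocount", 0)),
        genome_length=int(sim.get("genome_length", 200_000)),
        gc=float(sim.get("gc", 0.5)),
        circular=bool(sim.get("circular", True)),
        n_genes=int(sim.get("n_genes", 100)),
        mean_gene_len=int(sim.get("mean_gene_len", 800)),
        density=float(sim.get("density", simulate.DEFAULT_DENSITY)),
        n_replicates=int(sim.get("n_replicates", 3)),
        control_growth=float(sim.get("control_growth", 40.0)),
        samples=samples,
        control_sample=sim.get("control_sample", "control"),
        resistant_n=int(resistant.get("n", 0)),
        resistant_factor=float(resistant.get("factor", 1.0)),
        resistant_min_gene_len=int(resistant.get("min_gene_len", 300)),
        survival_factor={k: float(v) for k, v in (sim.get("survival_factor") or {}).items()},
        emit_fastq=bool(sim.get("emit_fastq", False)),
        junction=sim.get("junction", simulate.DEFAULT_JUNCTION),
        read_len=int(sim.get("read_len", 50)),
        genbank=(base / doc["genbank"]) if doc.get("genbank") else None,
        replicates=doc.get("replicates", []) or [],
    )
    cfg.validate()
    return cfg


def _config_fingerprint(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (the output location is not part
    of what the run computes)."""
    doc = {k: str(v) if isinstance(v, Path) else v for k, v in vars(cfg).items()}
    doc.pop("out_dir", None)
    doc["samples"] = {k: vars(v) for k, v in cfg.samples.items()}
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _scenario_for(cfg: RunConfig, survival_factor: dict[str, float], rep: int) -> SelectionScenario:
    return SelectionScenario(
        plating_counts={s: spec.plating for s, spec in cfg.samples.items()},
        read_depth={s: spec.depth for s, spec in cfg.samples.items()},
        survival_factor=survival_factor,
        baseline_survival={
            s: spec.baseline_survival
            for s, spec in cfg.samples.items()
            if spec.baseline_survival is not None
        },
        control_growth=cfg.control_growth,
        control_sample=cfg.control_sample,
        seed=cfg.seed + 1000 + rep,
    )


def _tables_via_fastq(
    cfg: RunConfig,
    tables: dict[str, SiteTable],
    genome,
    out_dir: Path,
    rep: int,
    manifest: dict,
) -> dict[str, SiteTable]:
    """Round-trip simulated tables through FASTQ + trim + locate (the full
    read-level path) instead of passing counts straight through."""
    reads_by_sample = simulate.emit_reads(
        tables, genome, junction=cfg.junction, read_len=cfg.read_len,
        seed=cfg.seed + 2000 + rep,
    )
    recovered = {}
    for sample, reads in reads_by_sample.items():
        fq = out_dir / "reads" / f"rep{rep}_{sample}.fastq"
        fq.parent.mkdir(parents=True, exist_ok=True)
        io.write_fastq(reads, fq)
        placements, tally = readprep.prepare_reads(reads, genome, cfg.junction)
        rejected = tally["no_junction"] + tally["too_short"]
        assert tally["total"] == (
            tally["placed"] + tally["unmapped"] + tally["ambiguous"] + rejected
        ), "read bookkeeping does not balance"
        manifest["stages"][f"rep{rep}/{sample}/reads"] = tally
        recovered[sample] = sites.enumerate_sites(placements, sample)
    return recovered


def _analyze_replicate(
    cfg: RunConfig,
    annotation: AnnotationSet,
    tables: dict[str, SiteTable],
    control: str,
    out_dir: Path,
    rep: int,
    manifest: dict,
):
    """Aggregate + Dval for every sample of one replicate, then SI of each
    treated sample against the control."""
    per_sample = {}
    for sample, table in tables.items():
        io.write_site_table(table, out_dir / "site_tables" / f"rep{rep}_{sample}.tsv")
        counts, unassigned = sites.aggregate_counts(table, annotation)
        counts = stats.add_dval(
            counts, annotation, table.total_reads(), pseudocount=cfg.pseudocount
        )
        io.write_feature_counts(
            counts, annotation, out_dir / "feature_counts" / f"rep{rep}_{sample}.tsv"
        )
        manifest["stages"][f"rep{rep}/{sample}/counts"] = {
            "total_reads": table.total_reads(),
            "n_sites": table.n_sites(),
            "unassigned_reads": unassigned,
        }
        per_sample[sample] = counts
    results = {}
    for sample in tables:
        if sample == control:
            continue
        results[sample] = stats.compute_survival(
            per_sample[control], per_sample[sample], annotation, min_sites=cfg.min_sites
        )
    return results


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run; returns the output directory.

    Outputs: per-replicate site tables and feature-count tables, one ranked
    SI report per treated sample, a summary JSON and a manifest with config
    hash, seed, versions and stage bookkeeping.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    for sub in ("site_tables", "feature_counts"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_sha256": _config_fingerprint(config),
        "seed": config.seed,
        "versions": {
            "tnsi": _version(),
            "numpy": np.__version__,
        },
        "stages": {},
    }

    if config.mode == "simulate":
        per_replicate_results = _run_simulate(config, out_dir, manifest)
    else:
        per_replicate_results = _run_real(config, out_dir, manifest)

    summary: dict[str, Any] = {"mode": config.mode, "treated_samples": {}}
    for treated in sorted(per_replicate_results):
        reps = per_replicate_results[treated]
        combined = stats.combine_replicates(reps, geometric=config.geometric_mean)
        filtered = [c for c in combined if c.passes_filter]
        ranked = stats.rank_report(combined, "resistant") if combined else []
        io.write_si_report(ranked, out_dir / f"si_report_{treated}.tsv")
        report = stats.filter_report(reps[0], config.min_sites)
        top = [c.feature_id for c in stats.rank_report(filtered, "resistant")[:10]] if filtered else []
        summary["treated_samples"][treated] = {
            "n_features": len(combined),
            "filter": report,
            "top10_resistant": top,
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished: %s", out_dir)
    return out_dir


def _version() -> str:
    from . import __version__

    return __version__


def _run_simulate(config: RunConfig, out_dir: Path, manifest: dict):
    genome = simulate.make_genome(
        config.genome_length, config.gc, seed=config.seed, circular=config.circular
    )
    annotation = simulate.make_annotation(
        genome, config.n_genes, config.mean_gene_len, seed=config.seed + 1
    )
    library = simulate.make_library(annotation, config.density, seed=config.seed + 2)
    manifest["stages"]["library"] = {
        "n_sites": len(library),
        "n_genes": len(annotation.genes()),
        "n_intergenic": len(annotation.intergenic()),
    }

    survival_factor = dict(config.survival_factor)
    if config.resistant_n > 0:
        rng = np.random.default_rng(config.seed + 3)
        gene_ids = [
            g.feature_id
            for g in annotation.genes()
            if g.length() >= config.resistant_min_gene_len
        ]
        if config.resistant_n > len(gene_ids):
            raise ConfigurationError(
                "resistant.n exceeds the number of sufficiently long genes"
            )
        planted = rng.choice(gene_ids, size=config.resistant_n, replace=False)
        for gid in planted:
            survival_factor[str(gid)] = config.resistant_factor
    manifest["stages"]["planted"] = {
        "survival_factor": {k: survival_factor[k] for k in sorted(survival_factor)}
    }

    io.write_fasta(genome, out_dir / "genome.fasta")
    io.write_gff3(annotation, out_dir / "annotation.gff3")
    io.write_scenario_yaml(
        _scenario_for(config, survival_factor, 0), out_dir / "scenario.yaml"
    )

    per_replicate: dict[str, list] = {}
    for rep in range(1, config.n_replicates + 1):
        scenario = _scenario_for(config, survival_factor, rep)
        tables = simulate.simulate_selection(library, annotation, scenario)
        if config.emit_fastq:
            tables = _tables_via_fastq(config, tables, genome, out_dir, rep, manifest)
        results = _analyze_replicate(
            config, annotation, tables, config.control_sample, out_dir, rep, manifest
        )
        for treated, res in results.items():
            per_replicate.setdefault(treated, []).append(res)
    return per_replicate


def _run_real(config: RunConfig, out_dir: Path, manifest: dict):
    annotation = sites.derive_intergenic(sites.read_genbank(str(config.genbank)))
    manifest["stages"]["annotation"] = {
        "n_genes": len(annotation.genes()),
        "n_intergenic": len(annotation.intergenic()),
    }
    per_replicate: dict[str, list] = {}
    for rep, mapping in enumerate(config.replicates, start=1):
        tables: dict[str, SiteTable] = {}
        for sample, rel_path in mapping.items():
            path = Path(rel_path)
            if not path.is_absolute():
                path = Path(config.genbank).parent / path if config.genbank else path
            ingest = readprep.ingest_alignments(path)
            manifest["stages"][f"rep{rep}/{sample}/ingest"] = dict(ingest.counts)
            tables[sample] = sites.enumerate_sites(ingest.placements, sample)
        results = _analyze_replicate(
            config, annotation, tables, "control", out_dir, rep, manifest
        )
        for treated, res in results.items():
            per_replicate.setdefault(treated, []).append(res)
    return per_replicate
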