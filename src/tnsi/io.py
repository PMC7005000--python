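"""Readers and writers for the package's file boundaries.

Internal coordinates are 0-based half-open; GenBank output converts to its
1-based inclusive convention via Biopython. Site tables are plain TSV
(position, orientation, count). All writers are deterministic: fixed column
orders, fixed float formatting, no timestamps — reruns at the same seed are
byte-identical.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    AnnotationSet,
    CombinedResult,
    Feature,
    FeatureCounts,
    FormatError,
    Genome,
    InsertionSite,
    RawRead,
    SelectionScenario,
    SiteTable,
)


# ---------------------------------------------------------------- sequences

def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    if genome.sequence is None:
        raise FormatError("cannot write FASTA for a genome without sequence")
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[RawRead]:
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(RawRead(rec.id, str(rec.seq), qual))
    return reads


# --------------------------------------------------------------- annotation

def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome.id} 1 {annotation.genome.length}\n")
        for f in sorted(annotation.features, key=lambda x: (x.start, x.feature_id)):
            gff_type = "gene" if f.kind == "gene" else "intergenic_region"
            fh.write(
                "\t".join(
                    [
                        annotation.genome.id,
                        "tnsi",
                        gff_type,
                        str(f.start + 1),
                        str(f.end),  # may exceed L for a wrap-around feature
                        ".",
                        f.strand if f.strand != "." else ".",
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


def write_genbank(annotation: AnnotationSet, path: str | Path) -> None:
    """Minimal GenBank output (readable back by `sites.read_genbank`).

    Wrap-around intergenic features are emitted as join() locations. The
    LOCUS date is fixed so output is reproducible.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    g = annotation.genome
    seq = Seq(g.sequence) if g.sequence is not None else Seq(None, length=g.length)
    record = SeqRecord(
        seq,
        id=g.id,
        name=g.id[:16],
        description="synthetic Tn-seq reference",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if g.circular else "linear",
            "date": "01-JAN-1980",
        },
    )
    for f in sorted(annotation.features, key=lambda x: (x.start, x.feature_id)):
        strand = {"+": 1, "-": -1}.get(f.strand)
        if f.wraps(g.length):
            loc = CompoundLocation(
                [
                    FeatureLocation(f.start, g.length, strand),
                    FeatureLocation(0, f.end - g.length, strand),
                ]
            )
        else:
            loc = FeatureLocation(f.start, f.end, strand)
        record.features.append(
            SeqFeature(loc, type="gene", qualifiers={"locus_tag": [f.feature_id]})
        )
    SeqIO.write(record, str(path), "genbank")


# -------------------------------------------------------------- site tables

def write_site_table(table: SiteTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\torientation\tcount\n")
        for site, count in table.sorted_items():
            fh.write(f"{site.position}\t{site.orientation}\t{count}\n")


def read_site_table(path: str | Path, sample_id: Optional[str] = None) -> SiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"position": int, "orientation": str, "count": int})
    expected = {"position", "orientation", "count"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: site table needs columns {sorted(expected)}")
    counts = {
        InsertionSite(int(row.position), str(row.orientation)): int(row.count)
        for row in df.itertuples()
        if row.count > 0
    }
    return SiteTable(sample_id=sample_id or Path(path).stem, counts=counts)


def write_feature_counts(
    counts: Sequence[FeatureCounts], annotation: AnnotationSet, path: str | Path
) -> None:
    fmap = annotation.by_id()
    rows = []
    for fc in counts:
        f: Feature = fmap[fc.feature_id]
        rows.append(
            {
                "feature_id": fc.feature_id,
                "kind": f.kind,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "n_sites": fc.n_sites,
                "actual_reads": fc.actual_reads,
                "predicted_reads": "" if fc.predicted_reads is None else f"{fc.predicted_reads:.6g}",
                "dval": "" if fc.dval is None else f"{fc.dval:.6g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ reports

def _fmt(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.6g}"


def write_si_report(combined: Sequence[CombinedResult], path: str | Path) -> None:
    n_rep = max((len(c.si_per_replicate) for c in combined), default=0)
    with open(path, "w") as fh:
        cols = ["feature_id", "kind", "n_sites"]
        cols += [f"si_rep{i + 1}" for i in range(n_rep)]
        cols += ["si_mean", "si_sem", "n_replicates_defined", "passes_filter"]
        fh.write("\t".join(cols) + "\n")
        for c in combined:
            row = [c.feature_id, c.kind, str(c.n_sites)]
            row += [_fmt(s) for s in c.si_per_replicate]
            row += [
                _fmt(c.si_mean),
                _fmt(c.si_sem),
                str(c.n_replicates_defined),
                str(c.passes_filter),
            ]
            fh.write("\t".join(row) + "\n")


# ------------------------------------------------------------------- config

def write_scenario_yaml(scenario: SelectionScenario, path: str | Path) -> None:
    doc = {
        "plating_counts": dict(scenario.plating_counts),
        "read_depth": dict(scenario.read_depth),
        "survival_factor": dict(scenario.survival_factor),
        "baseline_survival": (
            dict(scenario.baseline_survival)
            if not isinstance(scenario.baseline_survival, float)
            else scenario.baseline_survival
        ),
        "control_growth": scenario.control_growth,
        "control_sample": scenario.control_sample,
        "seed": scenario.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_scenario_yaml(path: str | Path) -> SelectionScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return SelectionScenario(
            plating_counts=doc["plating_counts"],
            read_depth=doc["read_depth"],
            survival_factor=doc.get("survival_factor", {}),
            baseline_survival=doc.get("baseline_survival", 0.5),
            control_growth=doc.get("control_growth", 40.0),
            control_sample=doc.get("control_sample", "control"),
            seed=doc.get("seed", 0),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing scenario key {exc}") from exc
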