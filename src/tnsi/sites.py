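"""Insertion-site enumeration and aggregation onto genes and intergenic regions.

Sites are keyed by (position, orientation); membership of a site in a
feature uses only its position — both orientations at one base fall in the
same feature. Intergenic regions are the maximal intervals not covered by
any gene, so gene + intergenic features tile the genome exactly whenever
genes do not overlap; insertions in promoters and other non-coding DNA are
thereby counted.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable

from intervaltree import IntervalTree

from .model import (
    AnnotationSet,
    Feature,
    FeatureCounts,
    FormatError,
    Genome,
    InsertionSite,
    Placement,
    SiteTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


class FeatureIndex:
    """Position -> features lookup over an annotation (wrap-around features on
    circular genomes are split into their two arcs)."""

    def __init__(self, annotation: AnnotationSet):
        self.genome_length = annotation.genome.length
        self._tree = IntervalTree()
        for f in annotation.features:
            for lo, hi in f.intervals(self.genome_length):
                self._tree[lo:hi] = f

    def features_at(self, position: int) -> list[Feature]:
        hits = {iv.data.feature_id: iv.data for iv in self._tree[position]}
        # genes before intergenic, then leftmost first: a stable order for
        # callers that need one representative feature
        return sorted(hits.values(), key=lambda f: (f.kind != "gene", f.start, f.feature_id))


def enumerate_sites(placements: Iterable[Placement], sample_id: str) -> SiteTable:
    """Tally placed reads into per-site counts; total reads are conserved."""
    counts: Counter[InsertionSite] = Counter()
    for p in placements:
        if p.status != "placed":
            raise ValidationError(
                f"enumerate_sites expects placed reads only; {p.read_id!r} is {p.status}"
            )
        counts[p.site()] += 1
    return SiteTable(sample_id=sample_id, counts=dict(counts))


def read_genbank(path: str) -> AnnotationSet:
    """Load a GenBank annotation as gene features.

    One feature per gene; `gene` records are preferred over `CDS` when both
    are present for the same locus (id = locus_tag, else gene name). GenBank
    1-based inclusive spans arrive from Biopython already converted to
    0-based half-open; join/complement locations resolve to their min..max
    span with the feature's strand.
    """
    from Bio import SeqIO
    from Bio.Seq import UndefinedSequenceError

    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc

    length = len(record.seq)
    try:
        sequence: str | None = str(record.seq).upper()
    except UndefinedSequenceError:
        sequence = None
    circular = record.annotations.get("topology", "linear") == "circular"
    genome = Genome(id=record.id or "genome", length=length, sequence=sequence, circular=circular)

    features: list[Feature] = []
    seen: set[str] = set()
    for ftype in ("gene", "CDS"):  # two passes: gene wins over CDS
        for n, f in enumerate(record.features):
            if f.type != ftype:
                continue
            quals = f.qualifiers
            fid = (quals.get("locus_tag") or quals.get("gene") or [f"{ftype}_{n}"])[0]
            if fid in seen:
                continue
            try:
                start, end = int(f.location.start), int(f.location.end)
            except Exception as exc:
                raise FormatError(
                    f"feature {fid!r} in {path}: unresolvable location {f.location}"
                ) from exc
            strand = {1: "+", -1: "-"}.get(f.location.strand, ".")
            features.append(
                Feature(feature_id=fid, kind="gene", start=start, end=end, strand=strand)
            )
            seen.add(fid)
    features.sort(key=lambda f: (f.start, f.feature_id))
    return AnnotationSet(genome=genome, features=features)


def derive_intergenic(annotation: AnnotationSet) -> AnnotationSet:
    """Add one intergenic feature per maximal interval not covered by a gene.

    Existing intergenic features are discarded and recomputed from the gene
    spans. On a circular genome the two terminal gaps join across the origin
    into a single wrap-around feature (stored with end > genome length,
    interpreted modulo the length). Ids are ``IG_<start>_<end>`` in stored
    coordinates.
    """
    genome = annotation.genome
    L = genome.length
    genes = sorted(annotation.genes(), key=lambda f: (f.start, f.end))

    # merge gene spans into disjoint covered intervals
    covered: list[list[int]] = []
    for g in genes:
        if covered and g.start <= covered[-1][1]:
            covered[-1][1] = max(covered[-1][1], g.end)
        else:
            covered.append([g.start, g.end])

    gaps: list[tuple[int, int]] = []
    prev = 0
    for lo, hi in covered:
        if lo > prev:
            gaps.append((prev, lo))
        prev = hi
    if prev < L:
        gaps.append((prev, L))

    if genome.circular and len(gaps) >= 2 and gaps[0][0] == 0 and gaps[-1][1] == L:
        # join [x, L) and [0, y) into one wrap-around feature [x, L + y)
        first, last = gaps[0], gaps[-1]
        gaps = gaps[1:-1] + [(last[0], L + first[1])]

    intergenic = [
        Feature(feature_id=f"IG_{lo}_{hi}", kind="intergenic", start=lo, end=hi, strand=".")
        for lo, hi in sorted(gaps)
    ]
    return AnnotationSet(genome=genome, features=genes + intergenic)


def aggregate_counts(
    table: SiteTable, annotation: AnnotationSet
) -> tuple[list[FeatureCounts], int]:
    """Aggregate a site table onto features.

    A site belongs to every feature whose interval contains its position
    (orientation is ignored for membership; with overlapping genes its reads
    count fully toward each overlapping feature). Returns per-feature counts
    in annotation order plus the total reads at sites covered by no feature
    (also logged). Dval fields are left unset here.
    """
    L = annotation.genome.length
    index = FeatureIndex(annotation)
    n_sites: Counter[str] = Counter()
    reads: Counter[str] = Counter()
    unassigned = 0
    for site, count in table.counts.items():
        if count <= 0:
            continue
        if not 0 <= site.position < L:
            raise ValidationError(
                f"site position {site.position} outside genome [0,{L})"
            )
        hits = index.features_at(site.position)
        if not hits:
            unassigned += count
            continue
        for f in hits:
            n_sites[f.feature_id] += 1
            reads[f.feature_id] += count
    if unassigned:
        logger.info(
            "aggregate_counts[%s]: %d reads at sites covered by no feature",
            table.sample_id,
            unassigned,
        )
    out = [
        FeatureCounts(
            feature_id=f.feature_id,
            sample_id=table.sample_id,
            n_sites=n_sites[f.feature_id],
            actual_reads=reads[f.feature_id],
        )
        for f in annotation.features
    ]
    return out, unassigned
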