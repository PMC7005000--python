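"""Read preprocessing: junction/poly(C) trimming, fragment placement, and
ingest of external alignments.

Raw Tn-seq reads have the structure junction + genomic fragment + poly(C)
tail. Trimming strips the junction prefix (allowing a bounded number of
mismatches) and the terminal poly(C) run, leaving the genomic fragment whose
first base is the insertion site. `locate_fragment` places fragments by exact
string search — a desk-scale stand-in for a genome-scale aligner; real data
goes through an external aligner (e.g. Bowtie) and enters via
`ingest_alignments` (SAM or BED6).

The insertion coordinate of a minus-orientation read is the *rightmost*
aligned base: the junction-adjacent genomic base is the one nearest the
transposon regardless of strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .model import FormatError, Genome, Placement, RawRead, ValidationError, revcomp

logger = logging.getLogger(__name__)


@dataclass
class TrimResult:
    """Outcome of trimming one read: ``ok`` with the genomic fragment, or a
    rejection reason (``no_junction`` / ``too_short``)."""

    read_id: str
    status: str  # "ok" | "no_junction" | "too_short"
    fragment: RawRead | None = None


def _hamming_prefix(seq: str, junction: str) -> int | None:
    if len(seq) < len(junction):
        return None
    return sum(a != b for a, b in zip(seq, junction))


def trim_read(
    read: RawRead,
    junction: str,
    max_junction_mismatch: int = 1,
    min_polyc_run: int = 5,
    min_fragment_len: int = 20,
) -> TrimResult:
    """Strip the junction prefix and the terminal poly(C) run from one read.

    The junction must match the read prefix within ``max_junction_mismatch``
    substitutions, else the read is rejected as ``no_junction``. The maximal
    3' run of C is removed only when it is at least ``min_polyc_run`` long
    (a shorter run is genuine genomic sequence). A surviving fragment shorter
    than ``min_fragment_len`` is rejected as ``too_short``.
    """
    if not junction:
        raise ValidationError("junction must be non-empty")
    mism = _hamming_prefix(read.sequence, junction)
    if mism is None or mism > max_junction_mismatch:
        return TrimResult(read.read_id, "no_junction")
    seq = read.sequence[len(junction):]
    qual = read.quality[len(junction):] if read.quality else None

    run = len(seq) - len(seq.rstrip("C"))
    if run >= min_polyc_run:
        seq = seq[: len(seq) - run]
        qual = qual[: len(seq)] if qual else None
    if len(seq) < min_fragment_len:
        return TrimResult(read.read_id, "too_short")
    return TrimResult(read.read_id, "ok", RawRead(read.read_id, seq, qual))


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_fragment(fragment: str, genome: Genome, read_id: str = "") -> Placement:
    """Place a genomic fragment by exact search of it and its reverse
    complement.

    A unique hit yields a placed result whose position is the fragment's
    junction-facing base: the first matched base for a forward hit, the last
    matched base for a reverse-complement hit (orientation '-'). Zero hits
    -> unmapped; multiple -> ambiguous. Circular genomes are searched across
    the origin.
    """
    if genome.sequence is None:
        raise ValidationError("locate_fragment needs a genome with a sequence")
    if not fragment:
        return Placement(read_id, "unmapped")
    L = genome.length
    k = len(fragment)
    haystack = genome.sequence
    if genome.circular and k > 1:
        haystack = genome.sequence + genome.sequence[: k - 1]

    hits: set[tuple[int, str]] = set()
    for c in _find_all(haystack, fragment):
        hits.add((c % L, "+"))
    for c in _find_all(haystack, revcomp(fragment)):
        hits.add(((c + k - 1) % L, "-"))
    if not hits:
        return Placement(read_id, "unmapped")
    if len(hits) > 1:
        return Placement(read_id, "ambiguous")
    (pos, orient), = hits
    return Placement(read_id, "placed", position=pos, orientation=orient)


def prepare_reads(
    reads: list[RawRead],
    genome: Genome,
    junction: str,
    max_junction_mismatch: int = 1,
    min_polyc_run: int = 5,
    min_fragment_len: int = 20,
) -> tuple[list[Placement], dict[str, int]]:
    """trim + locate over a read list; returns placements for the placed
    reads and a full bookkeeping tally (reads in = placed + unmapped +
    ambiguous + rejected)."""
    placements: list[Placement] = []
    tally = {"total": 0, "placed": 0, "unmapped": 0, "ambiguous": 0,
             "no_junction": 0, "too_short": 0}
    for read in reads:
        tally["total"] += 1
        trimmed = trim_read(read, junction, max_junction_mismatch,
                            min_polyc_run, min_fragment_len)
        if trimmed.status != "ok":
            tally[trimmed.status] += 1
            continue
        placement = locate_fragment(trimmed.fragment.sequence, genome, read.read_id)
        tally[placement.status] += 1
        if placement.status == "placed":
            placements.append(placement)
    return placements, tally


@dataclass
class IngestResult:
    """Placements from an external alignment file plus record bookkeeping;
    ``counts['total']`` equals the sum of all other categories."""

    placements: list[Placement] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _ingest_sam(path: str) -> IngestResult:
    import pysam

    res = IngestResult(counts={"total": 0, "placed": 0, "unmapped": 0, "dropped": 0})
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            res.counts["total"] += 1
            if rec.is_secondary or rec.is_supplementary:
                res.counts["dropped"] += 1
                continue
            if rec.is_unmapped:
                res.counts["unmapped"] += 1
                continue
            if rec.is_reverse:
                pos, orient = rec.reference_end - 1, "-"
            else:
                pos, orient = rec.reference_start, "+"
            res.placements.append(
                Placement(rec.query_name or "", "placed", position=pos, orientation=orient)
            )
            res.counts["placed"] += 1
    return res


def _ingest_bed(path: str) -> IngestResult:
    res = IngestResult(counts={"total": 0, "placed": 0, "unmapped": 0, "dropped": 0})
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[5]
            if strand not in ("+", "-") or end <= start:
                raise FormatError(f"{path}:{lineno}: bad strand or empty interval")
            res.counts["total"] += 1
            pos = start if strand == "+" else end - 1
            res.placements.append(
                Placement(parts[3], "placed", position=pos, orientation=strand)
            )
            res.counts["placed"] += 1
    return res


def ingest_alignments(path: str | Path) -> IngestResult:
    """Read pre-aligned positions from SAM or BED6.

    SAM: only primary mapped records are used; the insertion position is the
    leftmost aligned base for forward-strand records and the rightmost for
    reverse-strand records (SAM 1-based POS converts to 0-based internally).
    Unmapped / secondary / supplementary records are dropped and counted.
    BED6 intervals are already 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        res = _ingest_sam(str(path))
    elif path.suffix.lower() == ".bed":
        res = _ingest_bed(str(path))
    else:
        raise FormatError(f"cannot tell SAM from BED by extension: {path.name}")
    dropped = res.counts["total"] - res.counts["placed"]
    if dropped:
        logger.info("ingest_alignments[%s]: %d of %d records dropped",
                    path.name, dropped, res.counts["total"])
    return res
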