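"""Core domain types for the Tn-seq survival-index pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the only
conversions happen at file boundaries (SAM and GenBank are 1-based inclusive,
BED is 0-based half-open).

An *insertion site* is the pair (position, orientation): the first genomic
base adjacent to the transposon junction, plus the direction the genomic
fragment extends from it. Two orientations at the same base are distinct
mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class TnsiError(Exception):
    """Base class for package errors."""


class ValidationError(TnsiError):
    """Invalid argument or contract violation."""


class ConfigurationError(TnsiError):
    """Inconsistent or incomplete run configuration."""


class FormatError(TnsiError):
    """Malformed input file."""


@dataclass(frozen=True)
class Genome:
    """A single replicon: label, length in bp, optional sequence, topology."""

    id: str
    length: int
    sequence: Optional[str] = None
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"genome length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    def fetch(self, position: int, length: int, orientation: str = "+") -> str:
        """Genomic sequence of `length` bp starting at `position`, extending
        rightward for '+' and leftward (reverse-complemented) for '-'.

        Wraps around the origin on circular genomes; truncates at the ends of
        linear genomes.
        """
        if self.sequence is None:
            raise ValidationError("genome has no sequence")
        if not 0 <= position < self.length:
            raise ValidationError(f"position {position} outside genome [0,{self.length})")
        if orientation == "+":
            lo, hi = position, position + length
        elif orientation == "-":
            lo, hi = position - length + 1, position + 1
        else:
            raise ValidationError(f"orientation must be '+' or '-', got {orientation!r}")
        if self.circular:
            doubled = self.sequence + self.sequence
            lo_m = lo % self.length
            frag = doubled[lo_m : lo_m + (hi - lo)]
            # a fragment longer than the genome cannot be fetched meaningfully
            frag = frag[: self.length]
        else:
            frag = self.sequence[max(lo, 0) : min(hi, self.length)]
        return revcomp(frag) if orientation == "-" else frag


@dataclass(frozen=True)
class Feature:
    """Gene or intergenic interval, 0-based half-open.

    On a circular genome a single wrap-around intergenic feature may have
    end > genome length; its end is interpreted modulo the genome length and
    it covers [start, L) + [0, end - L).
    """

    feature_id: str
    kind: str  # "gene" | "intergenic"
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "intergenic"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"feature {self.feature_id}: need 0 <= start < end, got [{self.start},{self.end})"
            )

    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def contains(self, position: int, genome_length: int) -> bool:
        if self.wraps(genome_length):
            return position >= self.start or position < self.end - genome_length
        return self.start <= position < self.end

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """The feature as a list of non-wrapping [start, end) arcs."""
        if self.wraps(genome_length):
            return [(self.start, genome_length), (0, self.end - genome_length)]
        return [(self.start, self.end)]


@dataclass
class AnnotationSet:
    """Genome plus gene and derived intergenic features: the aggregation frame."""

    genome: Genome
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature ids: {dup[:5]}")
        for f in self.features:
            limit = 2 * self.genome.length if f.wraps(self.genome.length) else self.genome.length
            if f.end > limit or (f.wraps(self.genome.length) and not self.genome.circular):
                raise ValidationError(
                    f"feature {f.feature_id} [{f.start},{f.end}) exceeds genome "
                    f"length {self.genome.length}"
                )

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def intergenic(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "intergenic"]

    def by_id(self) -> dict[str, Feature]:
        return {f.feature_id: f for f in self.features}


class InsertionSite(NamedTuple):
    """A unique transposon insertion: one site = one mutant lineage."""

    position: int
    orientation: str  # "+" | "-"


@dataclass
class SiteTable:
    """Per-sample read counts keyed by insertion site.

    Only sites with >= 1 read are stored; a site absent from `counts` has
    zero reads in this sample.
    """

    sample_id: str
    counts: dict[InsertionSite, int] = field(default_factory=dict)

    def total_reads(self) -> int:
        return sum(self.counts.values())

    def n_sites(self) -> int:
        return len(self.counts)

    def sorted_items(self) -> Iterator[tuple[InsertionSite, int]]:
        return iter(sorted(self.counts.items()))


@dataclass
class SelectionScenario:
    """Ground truth of one simulated selection experiment.

    survival_factor maps feature_id -> s_g, the relative survival of mutants
    in that feature under treatment (1 = neutral; features not listed are
    neutral). baseline_survival is the survival fraction of a neutral mutant
    under treatment — a single float applied to every treated sample, or a
    per-sample mapping. control_growth is the deterministic CFU fold-change
    of the control culture over the incubation (default 40).
    """

    plating_counts: Mapping[str, int]
    read_depth: Mapping[str, int]
    survival_factor: Mapping[str, float] = field(default_factory=dict)
    baseline_survival: float | Mapping[str, float] = 0.5
    control_growth: float = 40.0
    control_sample: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.plating_counts) != set(self.read_depth):
            raise ConfigurationError(
                "plating_counts and read_depth must cover the same samples: "
                f"{sorted(self.plating_counts)} vs {sorted(self.read_depth)}"
            )
        if self.control_sample not in self.plating_counts:
            raise ConfigurationError(
                f"control sample {self.control_sample!r} missing from plating_counts"
            )
        for name, value in self.plating_counts.items():
            if value < 1:
                raise ConfigurationError(f"plating count for {name!r} must be >= 1")
        for name, value in self.read_depth.items():
            if value < 1:
                raise ConfigurationError(f"read depth for {name!r} must be >= 1")
        for fid, s in self.survival_factor.items():
            if s < 0:
                raise ConfigurationError(f"survival factor for {fid!r} must be >= 0")
        if self.control_growth <= 0:
            raise ConfigurationError("control_growth must be > 0")
        for sample in self.samples():
            if sample != self.control_sample:
                b = self.survival_for(sample)
                if not 0 < b <= 1:
                    raise ConfigurationError(
                        f"baseline_survival for {sample!r} must be in (0,1], got {b}"
                    )

    def samples(self) -> list[str]:
        """Sample order is the insertion order of plating_counts (control first
        by convention of the constructors)."""
        return list(self.plating_counts)

    def treated_samples(self) -> list[str]:
        return [s for s in self.samples() if s != self.control_sample]

    def survival_for(self, sample: str) -> float:
        if isinstance(self.baseline_survival, Mapping):
            if sample not in self.baseline_survival:
                raise ConfigurationError(f"no baseline_survival for sample {sample!r}")
            return float(self.baseline_survival[sample])
        return float(self.baseline_survival)


@dataclass
class RawRead:
    """A sequencing read: junction + genomic fragment + poly(C) tail."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.read_id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(f"read {self.read_id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class Placement:
    """Where one read's genomic fragment landed on the reference."""

    read_id: str
    status: str  # "placed" | "unmapped" | "ambiguous" | "too_short"
    position: Optional[int] = None
    orientation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "placed":
            if self.position is None or self.orientation not in ("+", "-"):
                raise ValidationError("placed Placement needs position and orientation")
        elif self.position is not None:
            raise ValidationError(f"{self.status} Placement must not carry a position")

    def site(self) -> InsertionSite:
        if self.status != "placed":
            raise ValidationError(f"read {self.read_id!r} is {self.status}, not placed")
        return InsertionSite(self.position, self.orientation)  # type: ignore[arg-type]


@dataclass
class FeatureCounts:
    """Per feature, per sample: distinct sites, actual reads and the
    length-normalized expectation (predicted reads) with its ratio Dval."""

    feature_id: str
    sample_id: str
    n_sites: int
    actual_reads: int
    predicted_reads: Optional[float] = None
    dval: Optional[float] = None


@dataclass
class SurvivalResult:
    """One feature in one replicate: Dvals, SI and the >=3-site filter flag.

    si is None when dval_control is zero (undefined, never a silent 0)."""

    feature_id: str
    kind: str
    dval_control: float
    dval_treated: float
    si: Optional[float]
    n_sites: int
    passes_filter: bool


@dataclass
class CombinedResult:
    """One feature across replicates: per-replicate SIs, their mean and SEM."""

    feature_id: str
    kind: str
    si_per_replicate: list[Optional[float]]
    si_mean: Optional[float]
    si_sem: Optional[float]
    n_replicates_defined: int
    n_sites: int = 0
    passes_filter: bool = False
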