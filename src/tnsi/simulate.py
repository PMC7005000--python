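"""Generative model of a mini-Tn10 library selection experiment.

The simulator emulates the screen that the analysis side of this package is
built for: a saturated transposon library (~1 insert per 20 bp, ~25 mutants
per gene or intergenic region) is grown for 3 h either untreated (the control,
~40-fold CFU increase) or under a bactericidal agent that kills all but a
fraction of the cells; survivors are plated, a fixed number of colonies is
scraped (the plating bottleneck), and transposon-junction reads are sequenced
to a fixed depth.

Modeling choices:

* Growth and killing are deterministic scalars per mutant lineage. A lineage
  carrying an insertion in feature g survives treatment with probability
  baseline_survival x s_g relative to its control-equivalent abundance, where
  s_g is the per-feature survival factor (1 = neutral).
* Stochasticity enters at exactly two multinomial sampling steps: the colony
  bottleneck (plating_counts colonies drawn from lineage abundances) and
  sequencing (read_depth reads drawn from colony counts). These are the
  dominant variance sources; per-cell branching noise during growth is not
  modeled.
* Every random draw flows from one explicit seed, so outputs are
  bit-identical across runs with the same inputs.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import (
    AnnotationSet,
    ConfigurationError,
    Feature,
    Genome,
    InsertionSite,
    RawRead,
    SelectionScenario,
    SiteTable,
    ValidationError,
)
from .sites import FeatureIndex, derive_intergenic

logger = logging.getLogger(__name__)

#: Placeholder transposon-junction sequence prepended to every simulated read
#: and expected by the trimmer. The real junction is primer-defined and
#: configurable at every call site; simulator and trimmer only need to agree.
DEFAULT_JUNCTION = "TGACTTATCATCCAACCTGT"

#: 1 insert per 20 bp on average — the saturation of the screened library.
DEFAULT_DENSITY = 1.0 / 20.0

#: E. coli K-12 MG1655 chromosome size, for chromosome-scale runs (configurable).
MG1655_LENGTH = 4_641_652

BASES = np.array(["A", "C", "G", "T"])


def make_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    genome_id: str = "sim_genome",
    circular: bool = False,
) -> Genome:
    """Random i.i.d. nucleotide sequence with expected GC fraction ``gc``."""
    if length < 1:
        raise ValidationError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValidationError(f"gc must be in [0,1], got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=length, p=p))
    return Genome(id=genome_id, length=length, sequence=seq, circular=circular)


def make_annotation(
    genome: Genome,
    n_genes: int,
    mean_gene_len: int = 800,
    seed: int = 0,
    fixed_length: bool = False,
) -> AnnotationSet:
    """Pack ``n_genes`` non-overlapping genes onto the genome and derive the
    complementary intergenic features.

    Gene lengths are geometric with mean ``mean_gene_len`` (clipped to
    [30, 5 x mean]) unless ``fixed_length`` is set, in which case every gene
    is exactly ``mean_gene_len`` bp. Genes are separated by >= 1 bp gaps so
    that gene + intergenic features tile the genome exactly.
    """
    L = genome.length
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    if n_genes == 0:
        return derive_intergenic(AnnotationSet(genome=genome, features=[]))
    if n_genes * mean_gene_len >= L:
        raise ValidationError(
            f"cannot pack {n_genes} genes of mean length {mean_gene_len} into {L} bp"
        )
    rng = np.random.default_rng(seed)
    lengths = None
    for _ in range(100):
        if fixed_length:
            cand = np.full(n_genes, mean_gene_len, dtype=int)
        else:
            cand = rng.geometric(1.0 / mean_gene_len, size=n_genes)
            cand = np.clip(cand, 30, 5 * mean_gene_len)
        if cand.sum() + (n_genes - 1) < L:
            lengths = cand
            break
    if lengths is None:
        raise ValidationError("infeasible packing: drawn gene lengths exceed genome")

    # n_genes + 1 gaps; interior gaps get a guaranteed 1 bp, ends may be 0
    free = L - int(lengths.sum()) - (n_genes - 1)
    extra = rng.multinomial(free, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    gaps = extra + np.r_[0, np.ones(n_genes - 1, dtype=int), 0]
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)

    features = []
    cursor = 0
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        features.append(
            Feature(
                feature_id=f"gene_{i + 1:0{width}d}",
                kind="gene",
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        cursor = end
    return derive_intergenic(AnnotationSet(genome=genome, features=features))


def make_library(
    annotation: AnnotationSet,
    density: float = DEFAULT_DENSITY,
    seed: int = 0,
) -> list[InsertionSite]:
    """Draw a saturated random insertion library.

    ``density`` is the density of *unique mutants*: the library size is
    Poisson with mean density x genome length, and that many distinct sites
    are sampled uniformly without replacement from the 2L possible
    (position, orientation) slots — each slot holds at most one mutant
    lineage, and the expected nearest-mutant spacing is exactly 1/density.
    """
    if density <= 0:
        raise ValidationError(f"density must be > 0, got {density}")
    L = annotation.genome.length
    rng = np.random.default_rng(seed)
    n = min(int(rng.poisson(density * L)), 2 * L)
    slots = rng.choice(2 * L, size=n, replace=False)
    sites = [
        InsertionSite(int(s // 2), "+" if s % 2 == 0 else "-") for s in slots
    ]
    return sorted(sites)


def _site_survival_factors(
    library: list[InsertionSite],
    annotation: AnnotationSet,
    scenario: SelectionScenario,
) -> np.ndarray:
    known = set(annotation.by_id())
    missing = set(scenario.survival_factor) - known
    if missing:
        raise ConfigurationError(
            f"survival_factor names unknown features: {sorted(missing)[:5]}"
        )
    index = FeatureIndex(annotation)
    s = np.ones(len(library))
    for i, site in enumerate(library):
        hits = index.features_at(site.position)
        if hits:
            # non-overlapping tiling => exactly one feature; with overlapping
            # genes the first (leftmost gene) wins for selection purposes
            s[i] = scenario.survival_factor.get(hits[0].feature_id, 1.0)
    return s


def simulate_selection(
    library: list[InsertionSite],
    annotation: AnnotationSet,
    scenario: SelectionScenario,
) -> dict[str, SiteTable]:
    """Run the selection, plating-bottleneck and sequencing model.

    Returns one SiteTable per sample, in the scenario's sample order,
    deterministic for a fixed scenario seed.
    """
    if not library:
        raise ValidationError("empty library")
    library = sorted(library)
    s = _site_survival_factors(library, annotation, scenario)
    rng = np.random.default_rng(scenario.seed)
    tables: dict[str, SiteTable] = {}
    for sample in scenario.samples():
        if sample == scenario.control_sample:
            weights = np.full(len(library), scenario.control_growth)
        else:
            weights = scenario.control_growth * scenario.survival_for(sample) * s
        total = weights.sum()
        if total <= 0:
            raise ConfigurationError(f"sample {sample!r}: no surviving lineages")
        colonies = rng.multinomial(int(scenario.plating_counts[sample]), weights / total)
        n_col = colonies.sum()
        reads = rng.multinomial(int(scenario.read_depth[sample]), colonies / n_col)
        counts = {
            site: int(c) for site, c in zip(library, reads) if c > 0
        }
        tables[sample] = SiteTable(sample_id=sample, counts=counts)
    return tables


def cfu_totals(
    library: list[InsertionSite],
    annotation: AnnotationSet,
    scenario: SelectionScenario,
) -> dict[str, float]:
    """Deterministic pre-plating CFU totals implied by the scenario.

    Each lineage contributes one CFU unit to the inoculum; the control grows
    by control_growth; a treated sample keeps control_growth x
    baseline_survival x s_g of each lineage. Keys: 'inoculum' plus every
    sample.
    """
    s = _site_survival_factors(library, annotation, scenario)
    out: dict[str, float] = {"inoculum": float(len(library))}
    for sample in scenario.samples():
        if sample == scenario.control_sample:
            out[sample] = scenario.control_growth * len(library)
        else:
            out[sample] = float(
                scenario.control_growth * scenario.survival_for(sample) * s.sum()
            )
    return out


def expected_frequencies(
    library: list[InsertionSite],
    annotation: AnnotationSet,
    scenario: SelectionScenario,
    sample: str,
) -> dict[InsertionSite, float]:
    """Closed-form expected per-site read frequency for one sample (the
    multinomial probabilities before any sampling noise)."""
    library = sorted(library)
    s = _site_survival_factors(library, annotation, scenario)
    if sample == scenario.control_sample:
        weights = np.full(len(library), scenario.control_growth)
    elif sample in scenario.plating_counts:
        weights = scenario.control_growth * scenario.survival_for(sample) * s
    else:
        raise ConfigurationError(f"unknown sample {sample!r}")
    p = weights / weights.sum()
    return {site: float(q) for site, q in zip(library, p)}


def study_scenario(
    survival_factor: dict[str, float] | None = None,
    read_depth: int | dict[str, int] = 1_000_000,
    seed: int = 0,
) -> SelectionScenario:
    """The screen's three-sample design: a control (~100,000 colonies,
    40-fold growth), a bacteriostatic dose (~50% survival, ~50,000 colonies)
    and a bactericidal dose (<1% survival, ~1,000 colonies)."""
    plating = {"control": 100_000, "treated_50": 50_000, "treated_1": 1_000}
    if isinstance(read_depth, int):
        read_depth = {sample: read_depth for sample in plating}
    return SelectionScenario(
        plating_counts=plating,
        read_depth=read_depth,
        survival_factor=survival_factor or {},
        baseline_survival={"treated_50": 0.5, "treated_1": 0.01},
        control_growth=40.0,
        control_sample="control",
        seed=seed,
    )


def emit_reads(
    tables: dict[str, SiteTable],
    genome: Genome,
    junction: str = DEFAULT_JUNCTION,
    fragment_len_range: tuple[int, int] = (200, 600),
    polyc_len_range: tuple[int, int] = (5, 20),
    read_len: int = 50,
    seed: int = 0,
) -> dict[str, list[RawRead]]:
    """Turn site tables into junction + fragment + poly(C) reads.

    Each read is the junction, then the genomic sequence starting at the site
    position extending in the site orientation (reverse-complemented for '-'
    sites), then a poly(C) tail, truncated to ``read_len``. Per-site read
    multiplicity equals the table count. Fragments running past a linear
    genome end are truncated (counted in the log), never an error.
    """
    if genome.sequence is None:
        raise ValidationError("emit_reads needs a genome with a sequence")
    if not junction:
        raise ValidationError("junction must be non-empty")
    f_lo, f_hi = fragment_len_range
    c_lo, c_hi = polyc_len_range
    if not (0 < f_lo <= f_hi and 0 <= c_lo <= c_hi):
        raise ValidationError("bad fragment or poly(C) length range")
    rng = np.random.default_rng(seed)
    out: dict[str, list[RawRead]] = {}
    n_truncated = 0
    for sample, table in tables.items():
        reads: list[RawRead] = []
        serial = 0
        for site, count in table.sorted_items():
            for _ in range(count):
                flen = int(rng.integers(f_lo, f_hi + 1))
                clen = int(rng.integers(c_lo, c_hi + 1))
                frag = genome.fetch(site.position, flen, site.orientation)
                if len(frag) < flen:
                    n_truncated += 1
                seq = (junction + frag + "C" * clen)[:read_len]
                serial += 1
                reads.append(
                    RawRead(
                        read_id=f"{sample}.{serial}",
                        sequence=seq,
                        quality="I" * len(seq),
                    )
                )
        out[sample] = reads
    if n_truncated:
        logger.info("emit_reads: %d fragments truncated at a linear genome end", n_truncated)
    return out
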