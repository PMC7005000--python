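# Methods

## The experiment being modeled

A saturated transposon-insertion library is grown briefly, split, and
incubated for 3 h either with an inert control protein or with a
bactericidal agent. Survivors are plated; a fixed number of colonies is
scraped and pooled; junction-adjacent genomic fragments are sequenced. A
mutant whose disrupted gene is required for killing survives treatment
disproportionately and its insertion sites gain read share; a mutant whose
disrupted gene is protective loses share. The analysis quantifies this per
feature as the survival index (SI) described in the README.

## Simulator model and assumptions

One mutant lineage = one unique insertion site, keyed by
`(position, orientation)`; the two orientations at a base are distinct
mutants because transposon insertions are oriented. The generative model
has four stages:

1. **Library.** The number of unique mutants is Poisson with mean
   `density × L` (default density 1/20 bp — one unique insert per 20 bp,
   hence ~25 mutants in a 500-bp gene) and sites are sampled uniformly
   without replacement from the `2L` possible slots. Density of *unique*
   mutants is the primitive: it is the property screens report, and it
   makes expected nearest-mutant spacing exactly `1/density`.
2. **Growth/killing.** Deterministic per-lineage scalars: every lineage
   grows `control_growth`-fold in the control (default 40, the observed
   3-h CFU increase); under treatment a lineage in feature *g* retains
   `control_growth × baseline_survival × s_g` of that, where
   `baseline_survival` is the neutral survival fraction of the dose
   (0.5 bacteriostatic, 0.01 bactericidal) and `s_g` is the per-feature
   survival factor (1 = neutral). Selection is uniform within a feature;
   within-gene position effects are out of scope. Per-cell branching noise
   during growth is not modeled — with a 1,000-colony bottleneck downstream
   it is a negligible variance source by comparison.
3. **Plating bottleneck.** `plating_counts[sample]` colonies drawn
   multinomially from lineage abundances. The default three-sample design
   mirrors the screen: control 100,000 colonies; bacteriostatic dose
   50,000; bactericidal dose 1,000. This is the dominant noise source at
   low survivor counts.
4. **Sequencing.** `read_depth[sample]` reads drawn multinomially from the
   colony counts (default 10^6). No PCR-duplicate, sequencing-error,
   quality or chimera model: read identity is exact by design so that the
   read-level path can be verified exactly against ground truth.

All randomness flows from one integer seed per scenario; outputs are
bit-identical across reruns.

Simulated reads are `junction + genomic fragment + poly(C) tail`, truncated
to the read length (default 50 nt). The junction constant is a placeholder:
the real junction is primer-defined and configurable everywhere; simulator
and trimmer only need to agree. Fragment lengths are uniform on 200–600 bp
(the sonication range), poly(C) tail lengths uniform on 5–20 nt — tailing
length is enzyme-controlled and unreported, so a modest spread was chosen
once; only the tail's presence matters to the trimmer.

### What the simulator does *not* emulate

Real libraries have insertion-site bias (hot/cold spots), PCR jackpots,
sequencing errors and multi-mapping reads; real genomes have repeats that
make placement ambiguous. Passing tests therefore demonstrate correctness
of the accounting and the statistic under the idealized sampling model, and
the statistic's calibration and power under bottleneck noise — not
robustness to alignment artifacts or amplification bias, which enter real
analyses upstream of this package through the external aligner.

## Coordinates and formats

0-based half-open everywhere internally; conversions happen only at file
boundaries (SAM and GenBank are 1-based inclusive, BED 0-based half-open).
The insertion coordinate of a reverse-strand alignment is the *rightmost*
aligned base — the junction-adjacent base is the one nearest the transposon
regardless of strand — so a 30M alignment at SAM POS 101 maps to position
100 forward and 129 reverse. Ambiguous (multi-hit) placements are excluded
from counting and logged, never randomly assigned. On circular genomes the
two terminal intergenic gaps join across the origin into a single feature,
stored with `end > L` and interpreted modulo `L`.

## Statistics: numerical choices

- `Dval = actual / (N·l/L)` uses feature length `end − start`; whether to
  exclude overlap with neighboring features is an open choice and the plain
  length was used. `N` is the sample's site-table total, not the sum over
  features (which double-counts under overlapping genes).
- Sites in overlapping genes count fully toward every overlapping feature;
  per-feature completeness matters more for SI than global read
  additivity, and the unassigned/total bookkeeping is reported so the
  conservation identity can still be audited.
- `Dval_control = 0` makes SI undefined (`None`), never a pseudocounted
  infinity; an optional pseudocount (default 0) can be added to all
  features in both samples.
- The ≥3-site filter is evaluated on the control library, since selection
  strips sites from treated samples; the threshold is the saturation of the
  library, not of the survivor pool.
- Replicates are combined by the arithmetic mean of defined SIs with the
  textbook SEM; a geometric mean (natural for a ratio) is available by
  flag. Undefined replicate values are excluded, and a feature undefined in
  all replicates is reported as such.
- Ranking sorts by mean SI (descending for resistance), ties broken
  lexicographically on feature id, undefined last.
- An optional one-sample t-test on ln(SI) across replicates is provided as
  labeled auxiliary plumbing; the screen's published statistic defines no
  per-feature test.

## Recovery experiments and problem sizes

The validation suite runs on 5 kb–200 kb genomes with 10^2–10^4 mutants and
10^6 reads — sizes at which a neutral screen yields ~290 filter-passing
features and each check runs in seconds while preserving the study's
per-base density, plating counts and depth. At plating 50,000 / depth 10^6
the statistic recovers a planted survival factor of 10 within ±30% and
orders factors {0.1, 1, 10, 50} correctly; in the demo (bactericidal dose,
1,000-colony bottleneck) all five planted resistance genes rank top-5.
Recovered SI for strong effects sits below `s_g` because SI is a relative
frequency change: resistant lineages inflate the treated sample's
denominator. The neutral null is checked both for mean SI = 1 and for tail
behavior against a two-stage (plating + sequencing) multinomial bootstrap.

Planted-effect genes are drawn only from genes ≥ 300 bp (≈15 expected
mutants at default density): an effect planted in a gene with no insertion
mutants is unrecoverable by construction, and a recovery experiment is
about the statistic, not about library gaps — which the ≥3-site filter
already handles.

## Known limitations

- Single replicon; multi-contig genomes are not handled.
- `locate_fragment` is exact-match and desk-scale; genome-scale or
  error-containing reads require an external aligner via `ingest`.
- No FDR machinery and no essentiality calling beyond the SI statistic
  itself; comparisons across treatment doses are separate SI tables.
- The simulator's survival factors are per-feature constants; epistasis,
  dose–response shapes and within-feature heterogeneity are out of scope.
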