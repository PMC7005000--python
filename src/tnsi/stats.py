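"""The screen's statistics: predicted reads, Dval, survival index (SI),
the minimum-site filter, replicate combination and ranked reporting.

For a feature of length l on a genome of length L sequenced to N total
reads, the predicted read count is N * l / L — the reads the feature would
receive if insertions and reads were spread uniformly. Dval is the ratio of
actual to predicted reads, a depth- and length-normalized abundance, and the
survival index is

    SI = Dval_treated / Dval_control.

A neutral mutation has SI = 1; SI > 1 marks mutants enriched by treatment
(the wild-type gene product promotes killing), SI < 1 marks depleted,
sensitized mutants. Features with fewer than three distinct insertion sites
in the library are filtered out as too sparse for reliable frequency
estimates.

Undefined values (Dval_control = 0) propagate as explicit ``None``, never as
silent zeros or pseudocounted infinities; an optional pseudocount is
available but off by default.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .model import (
    AnnotationSet,
    CombinedResult,
    FeatureCounts,
    SurvivalResult,
    ValidationError,
)


def predicted_reads(feature_len: int, genome_len: int, total_reads: int) -> float:
    """Expected reads for a feature under uniform coverage:
    total_reads * feature_len / genome_len."""
    if feature_len < 1:
        raise ValidationError(f"feature_len must be >= 1, got {feature_len}")
    if genome_len < feature_len:
        raise ValidationError(
            f"genome_len {genome_len} smaller than feature_len {feature_len}"
        )
    if total_reads < 0:
        raise ValidationError(f"total_reads must be >= 0, got {total_reads}")
    return total_reads * feature_len / genome_len


def dval(actual_reads: int, predicted: float) -> float:
    """Actual over predicted reads; undefined (raises) when predicted <= 0."""
    if predicted <= 0:
        raise ValidationError(f"dval undefined for predicted reads {predicted}")
    return actual_reads / predicted


def survival_index(dval_treated: float, dval_control: float) -> Optional[float]:
    """Dval_treated / Dval_control, or None when the control Dval is zero."""
    if dval_control > 0:
        return dval_treated / dval_control
    return None


def add_dval(
    counts: Sequence[FeatureCounts],
    annotation: AnnotationSet,
    total_reads: int,
    pseudocount: int = 0,
) -> list[FeatureCounts]:
    """Fill predicted_reads and dval on per-feature counts for one sample.

    ``total_reads`` is the sample's library total (the site-table total, not
    the sum over features, which double-counts overlaps). ``pseudocount``
    reads are added to every feature's actual reads before Dval when set.
    """
    lengths = {f.feature_id: f.length() for f in annotation.features}
    genome_len = annotation.genome.length
    out = []
    for fc in counts:
        pred = predicted_reads(lengths[fc.feature_id], genome_len, total_reads + pseudocount)
        d = dval(fc.actual_reads + pseudocount, pred) if pred > 0 else None
        out.append(
            FeatureCounts(
                feature_id=fc.feature_id,
                sample_id=fc.sample_id,
                n_sites=fc.n_sites,
                actual_reads=fc.actual_reads,
                predicted_reads=pred,
                dval=d,
            )
        )
    return out


def compute_survival(
    control: Sequence[FeatureCounts],
    treated: Sequence[FeatureCounts],
    annotation: AnnotationSet,
    min_sites: int = 3,
) -> list[SurvivalResult]:
    """Per-feature SI for one replicate from Dval-annotated counts.

    The site filter counts insertion sites observed in the *control* library
    (selection removes sites from treated samples, so the treated site count
    understates library saturation).
    """
    kinds = {f.feature_id: f.kind for f in annotation.features}
    tmap = {fc.feature_id: fc for fc in treated}
    results = []
    for fc in control:
        tc = tmap.get(fc.feature_id)
        if tc is None:
            raise ValidationError(f"feature {fc.feature_id!r} missing from treated counts")
        if fc.dval is None or tc.dval is None:
            raise ValidationError(f"feature {fc.feature_id!r}: Dval not computed")
        results.append(
            SurvivalResult(
                feature_id=fc.feature_id,
                kind=kinds[fc.feature_id],
                dval_control=fc.dval,
                dval_treated=tc.dval,
                si=survival_index(tc.dval, fc.dval),
                n_sites=fc.n_sites,
                passes_filter=fc.n_sites >= min_sites,
            )
        )
    return results


def filter_min_sites(
    results: Sequence[SurvivalResult], min_sites: int = 3
) -> list[SurvivalResult]:
    """Keep features with at least ``min_sites`` distinct insertion sites."""
    if min_sites < 0:
        raise ValidationError("min_sites must be >= 0")
    return [r for r in results if r.n_sites >= min_sites]


def filter_report(results: Sequence[SurvivalResult], min_sites: int = 3) -> dict[str, int]:
    """Kept-feature tallies by kind, as reported alongside a filtered table."""
    kept = filter_min_sites(results, min_sites)
    return {
        "kept_genes": sum(r.kind == "gene" for r in kept),
        "kept_intergenic": sum(r.kind == "intergenic" for r in kept),
        "dropped": len(results) - len(kept),
    }


def _mean_sem(values: list[float]) -> tuple[float, Optional[float]]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def combine_replicates(
    per_replicate: Sequence[Sequence[SurvivalResult]],
    geometric: bool = False,
) -> list[CombinedResult]:
    """Combine per-replicate SIs into one row per feature.

    The mean and SEM run over the replicates where SI is defined; a feature
    undefined everywhere is reported with n_replicates_defined = 0 and no
    mean. The default is the arithmetic mean; ``geometric`` switches to the
    geometric mean (natural for a ratio; features with any zero SI get mean
    0 in that mode). The combined n_sites / filter flag are the most
    permissive across replicates.
    """
    if not per_replicate:
        raise ValidationError("need at least one replicate")
    order: list[str] = []
    rows: dict[str, list[Optional[float]]] = {}
    meta: dict[str, SurvivalResult] = {}
    n_rep = len(per_replicate)
    for r, rep in enumerate(per_replicate):
        for res in rep:
            if res.feature_id not in rows:
                order.append(res.feature_id)
                rows[res.feature_id] = [None] * n_rep
                meta[res.feature_id] = res
            rows[res.feature_id][r] = res.si
            if res.n_sites > meta[res.feature_id].n_sites:
                meta[res.feature_id] = res

    combined = []
    for fid in order:
        sis = rows[fid]
        defined = [s for s in sis if s is not None]
        if not defined:
            mean: Optional[float] = None
            sem: Optional[float] = None
        elif geometric:
            if any(s == 0 for s in defined):
                mean, sem = 0.0, None
            else:
                logs = [math.log(s) for s in defined]
                m, s_ = _mean_sem(logs)
                mean = math.exp(m)
                sem = None if s_ is None else mean * s_
        else:
            mean, sem = _mean_sem(defined)
        combined.append(
            CombinedResult(
                feature_id=fid,
                kind=meta[fid].kind,
                si_per_replicate=sis,
                si_mean=mean,
                si_sem=sem,
                n_replicates_defined=len(defined),
                n_sites=meta[fid].n_sites,
                passes_filter=meta[fid].passes_filter,
            )
        )
    return combined


def rank_report(
    combined: Sequence[CombinedResult], direction: str = "resistant"
) -> list[CombinedResult]:
    """Order features by mean SI: descending for ``resistant`` (SI > 1 first),
    ascending for ``sensitive``. Ties break lexicographically on feature_id;
    features with undefined SI sort last."""
    if direction not in ("resistant", "sensitive"):
        raise ValidationError(f"direction must be resistant|sensitive, got {direction!r}")
    if not combined:
        raise ValidationError("rank_report needs a non-empty result list")
    sign = -1.0 if direction == "resistant" else 1.0

    def key(r: CombinedResult):
        if r.si_mean is None:
            return (1, 0.0, r.feature_id)
        return (0, sign * r.si_mean, r.feature_id)

    return sorted(combined, key=key)


def log_si_test(sis: Sequence[float]) -> tuple[float, float]:
    """One-sample t-test of ln(SI) against 0 across replicates.

    Auxiliary plumbing, not part of the screen's published statistic: it
    asks whether a feature's replicate SIs differ systematically from 1.
    Returns (t, two-sided p). Requires >= 2 positive SIs.
    """
    from scipy import stats as sp_stats

    vals = [math.log(s) for s in sis if s is not None and s > 0]
    if len(vals) < 2:
        raise ValidationError("log_si_test needs >= 2 positive SIs")
    t, p = sp_stats.ttest_1samp(vals, 0.0)
    return float(t), float(p)
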