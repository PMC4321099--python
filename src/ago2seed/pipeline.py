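"""End-to-end orchestration: normalize -> diffexp -> classify -> scan -> call.

Ties the stage modules together under one configuration object, mirroring
the study design: single-channel miRNA arrays (IRI vs replicate-matched sham,
between-array ratios) feed the responsiveness classification; two-color
whole-genome arrays (within-array ratios) feed the 2-fold transcript lists;
sequence scanning supplies the in silico arm; the evidence intersection
produces the final per-miRNA target calls and multiplicity summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cluster as _cluster
from .arrays import (ArraySample, ExpressionMatrix, build_ratio_matrix,
                     collapse_duplicate_features, filter_flags,
                     lowess_normalize, percentile_scale_normalize)
from .diffexp import (classify_responsive, fold_lists, genotype_fold_table,
                      replicate_stats, select_differential)
from .evidence import MultiplicitySummary, intersect_evidence, multiplicity
from .sequences import MiRNASeq, UTRSeq
from .targets import DEFAULT_PARAMS, ScoringParams, predict_targets


@dataclass
class PipelineConfig:
    """Tunable thresholds; defaults reproduce the reference analysis rules."""

    percentile: float = 0.75
    span: float = 0.3
    rank_tolerance: float = 0.05
    min_abs_log2: float = 1.0
    max_p: float = 0.05
    wt_min: float = 1.0
    ko_max: float = -1.0
    use_wildtype_p: bool = True
    min_fold: float = 2.0
    scoring: ScoringParams = field(default_factory=lambda: DEFAULT_PARAMS)
    multiplicity_k: int = 2
    responsive_timepoint: str = "rep1d"


@dataclass
class PipelineResult:
    mirna_matrix: ExpressionMatrix
    group_stats: dict[tuple[str, str], pd.DataFrame]
    upregulated_by_timepoint: dict[str, list[str]]
    genotype_folds: pd.DataFrame | None
    responsive: list[str]
    dendrogram: object | None
    ago2_up: list[str]
    mrna_down: list[str]
    predicted: dict[str, list[str]]
    evidence: pd.DataFrame
    multiplicity: MultiplicitySummary


def normalize_mirna_arm(samples: list[ArraySample],
                        config: PipelineConfig) -> ExpressionMatrix:
    """Flag-filter, 75th-percentile scale, collapse and ratio the miRNA arm.

    Pipeline order is fixed: filter -> normalize -> ratio.  Each IRI array is
    paired with the sham array of the same genotype, timepoint and replicate.
    """
    filtered = [filter_flags(s) for s in samples if s.arm == "mirna"]
    scaled, _ = percentile_scale_normalize(filtered, percentile=config.percentile)
    scaled = [collapse_duplicate_features(s) for s in scaled]
    by_key = {(s.genotype, s.timepoint, s.replicate, s.condition): s for s in scaled}
    pairs = []
    for (genotype, tp, rep, condition), s in sorted(by_key.items(),
                                                    key=lambda kv: str(kv[0])):
        if condition != "iri":
            continue
        sham = by_key.get((genotype, tp, rep, "sham"))
        if sham is None:
            raise ValueError(f"no sham array for {s.sample_id}")
        pairs.append((s, sham))
    return build_ratio_matrix(pairs)


def normalize_mrna_arm(samples: list[ArraySample], arm: str,
                       config: PipelineConfig) -> ExpressionMatrix:
    """Flag-filter, LOWESS-normalize and ratio one two-color mRNA arm."""
    arm_samples = [s for s in samples if s.arm == arm]
    if not arm_samples:
        raise ValueError(f"no samples for arm {arm!r}")
    pairs = []
    for s in sorted(arm_samples, key=lambda s: s.sample_id):
        s = filter_flags(s)
        s = lowess_normalize(s, span=config.span,
                             rank_tolerance=config.rank_tolerance)
        s = collapse_duplicate_features(s)
        pairs.append((s, None))
    return build_ratio_matrix(pairs)


def run_pipeline(mirna_samples: list[ArraySample],
                 mrna_samples: list[ArraySample],
                 mirnas: list[MiRNASeq], utrs: list[UTRSeq],
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Execute every stage and return the assembled result."""
    config = config or PipelineConfig()

    matrix = normalize_mirna_arm(mirna_samples, config)
    groups = matrix.metadata.groupby(["genotype", "timepoint"]).groups
    group_stats: dict[tuple[str, str], pd.DataFrame] = {}
    for (genotype, tp), sample_ids in groups.items():
        group_stats[(genotype, tp)] = replicate_stats(
            matrix.values[list(sample_ids)])
    upregulated = {
        tp: select_differential(stats, config.min_abs_log2, config.max_p, "up")
        for (genotype, tp), stats in group_stats.items() if genotype == "wildtype"}

    tp = config.responsive_timepoint
    per_genotype = {g: stats for (g, t), stats in group_stats.items() if t == tp}
    genotype_folds, responsive = None, []
    if len(per_genotype) == 3:
        genotype_folds = genotype_fold_table(per_genotype)
        responsive = classify_responsive(
            genotype_folds, wt_min=config.wt_min, ko_max=config.ko_max,
            max_p=config.max_p if config.use_wildtype_p else float("inf"))

    # cluster the selected-differential features across all samples
    dendrogram = None
    selected: set[str] = set()
    for stats in group_stats.values():
        selected |= set(select_differential(stats, config.min_abs_log2,
                                            config.max_p, "both"))
    if len(selected) >= 2:
        sub = matrix.dropna().values.loc[sorted(selected & set(matrix.dropna().features))]
        try:
            dendrogram = _cluster.cluster_matrix(sub, axis="samples")
        except ValueError:
            dendrogram = None

    total = normalize_mrna_arm(mrna_samples, "mrna_total", config)
    ip = normalize_mrna_arm(mrna_samples, "mrna_ago2ip", config)
    _, mrna_down = fold_lists(total, "mrna_total", config.min_fold)
    ago2_up, _ = fold_lists(ip, "mrna_ago2ip", config.min_fold)

    responsive_mirnas = [m for m in mirnas if m.id in set(responsive)]
    predicted = predict_targets(responsive_mirnas, utrs, config.scoring)

    table = intersect_evidence(predicted, ago2_up, mrna_down)
    summary = multiplicity(table, k=config.multiplicity_k)
    return PipelineResult(
        mirna_matrix=matrix, group_stats=group_stats,
        upregulated_by_timepoint=upregulated, genotype_folds=genotype_folds,
        responsive=responsive, dendrogram=dendrogram, ago2_up=ago2_up,
        mrna_down=mrna_down, predicted=predicted, evidence=table,
        multiplicity=summary)
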