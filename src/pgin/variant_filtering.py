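"""Post-calling somatic variant filter cascade.

Stages, in order: hard quality thresholds on the caller's site metrics,
exclusion of known artefact classes (RNA-editing sites, low-complexity
regions, common variants), the rare-variant filter (expressed depth,
population allele frequency, and cohort recurrence), and finally the
damaging classification from in-silico impact annotations.

All thresholds are strict inequalities exactly as applied upstream:
DP>10, GQ>20, QD>5, MQ>40, ReadPosRankSum>-3, MQRankSum>-10, FS<200,
QUAL>50 for quality; depth > preset threshold and MAX_AF < 0.01 for
rarity; recurrence cuts at >70% of samples for a variant and >50% for a
gene (33% for the WGS preset, variant-level only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_formats import RunConfig

__all__ = [
    "QUALITY_THRESHOLDS",
    "FilterOutcome",
    "quality_filter",
    "somatic_exclusions",
    "rare_filter",
    "damaging_filter",
    "run_cascade",
    "CascadeResult",
]

#: metric -> (direction, threshold); ">" keeps values strictly above,
#: "<" keeps values strictly below.
QUALITY_THRESHOLDS: dict[str, tuple[str, float]] = {
    "dp": (">", 10),
    "gq": (">", 20),
    "qd": (">", 5),
    "mq": (">", 40),
    "read_pos_rank_sum": (">", -3),
    "mq_rank_sum": (">", -10),
    "fs": ("<", 200),
    "qual": (">", 50),
}

ARTIFACT_FLAGS = ("rna_editing_site", "low_complexity", "common_variant")


@dataclass
class FilterOutcome:
    """Cascade verdict for one variant."""

    index: int
    stage_failed: str | None
    is_rare: bool
    is_rare_damaging: bool

    def __post_init__(self) -> None:
        if self.is_rare_damaging and not self.is_rare:
            raise ValueError("is_rare_damaging implies is_rare")


def _metric_pass(series: pd.Series, direction: str, threshold: float, strict_missing: bool) -> pd.Series:
    """Boolean pass vector for one metric; missing handled per policy.

    With ``strict_missing=False`` (default) an absent metric satisfies its
    predicate vacuously — RNA-seq callers omit rank-sum statistics at
    homozygous sites and dropping on absence would empty real data.
    """
    vals = series.astype("Float64")
    if direction == ">":
        ok = vals > threshold
    else:
        ok = vals < threshold
    missing = vals.isna()
    ok = ok.fillna(False).astype(bool)
    if not strict_missing:
        ok = ok | missing.to_numpy()
    return pd.Series(np.asarray(ok, dtype=bool), index=series.index)


def quality_filter(
    variants: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eight hard quality thresholds.

    Returns the surviving rows and a tally of failures per metric (a
    variant failing several metrics is counted under each).
    """
    config = config or RunConfig()
    keep = pd.Series(True, index=variants.index)
    tally: dict[str, int] = {}
    for metric, (direction, threshold) in QUALITY_THRESHOLDS.items():
        ok = _metric_pass(variants[metric], direction, threshold, config.strict_missing_quality)
        tally[metric] = int((~ok).sum())
        keep &= ok
    return variants[keep], tally


def somatic_exclusions(variants: pd.DataFrame) -> pd.DataFrame:
    """Drop records flagged as RNA-editing sites, low-complexity, or common."""
    flagged = pd.Series(False, index=variants.index)
    for flag in ARTIFACT_FLAGS:
        flagged |= variants[flag].fillna(False).astype(bool)
    return variants[~flagged]


def _recurrence_keep(variants: pd.DataFrame, n_samples: int, config: RunConfig) -> pd.Series:
    """Keep mask after variant- and gene-level cohort recurrence cuts.

    A variant is identified across samples by (chrom, pos, ref, alt); the
    denominator is the number of samples in the analysis set.
    """
    key = pd.MultiIndex.from_frame(variants[["chrom", "pos", "ref", "alt"]])
    var_samples = (
        variants.assign(_key=key.to_flat_index())
        .groupby("_key")["sample_id"]
        .nunique()
    )
    var_frac = key.to_flat_index().map(var_samples) / n_samples
    keep = pd.Series(np.asarray(var_frac) <= config.variant_recurrence_max, index=variants.index)

    gene_samples = variants.groupby("gene")["sample_id"].nunique()
    gene_frac = variants["gene"].map(gene_samples) / n_samples
    keep &= (gene_frac <= config.gene_recurrence_max).fillna(True).to_numpy()
    return keep


def rare_filter(
    variants: pd.DataFrame, config: RunConfig, n_samples: int | None = None
) -> pd.DataFrame:
    """Retain rare, well-covered, non-recurrent variants.

    Depth must exceed the preset burden threshold (strictly) and MAX_AF must
    be strictly below the rarity cut; a missing MAX_AF counts as rare when
    ``missing_af_is_rare`` (absence from the population catalog is itself
    evidence of rarity). Recurrence cuts then drop variants seen in more
    than ``variant_recurrence_max`` of samples and all variants in genes
    mutated in more than ``gene_recurrence_max`` of samples.
    """
    if n_samples is None:
        n_samples = int(variants["sample_id"].nunique())
    if n_samples == 0:
        raise ParameterError("rare_filter requires at least one sample in the analysis set")

    dp_ok = (variants["dp"] > config.burden_depth_threshold).fillna(False)
    af = variants["max_af"]
    af_ok = (af < config.rare_af_threshold).fillna(False)
    if config.missing_af_is_rare:
        af_ok = af_ok | af.isna()
    candidates = variants[np.asarray(dp_ok & af_ok, dtype=bool)]
    if candidates.empty:
        return candidates
    keep = _recurrence_keep(candidates, n_samples, config)
    return candidates[keep]


def damaging_filter(rare_variants: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Classify rare variants as damaging.

    ``union`` rule (default): PolyPhen "damaging" OR SIFT "deleterious" OR a
    nonsense/nonstop classification. ``intersection``: PolyPhen AND SIFT
    jointly, with nonsense/nonstop always retained. Either way a ClinVar
    "benign" assertion vetoes the call.
    """
    pp = rare_variants["polyphen"].astype("string").str.lower() == "damaging"
    sift = rare_variants["sift"].astype("string").str.lower() == "deleterious"
    trunc = rare_variants["classification"].isin(["nonsense", "nonstop"])
    pp = pp.fillna(False)
    sift = sift.fillna(False)
    if config.damaging_rule == "union":
        dam = pp | sift | trunc
    else:
        dam = (pp & sift) | trunc
    benign = (rare_variants["clinvar_sig"].astype("string").str.lower() == "benign").fillna(False)
    return rare_variants[np.asarray(dam & ~benign, dtype=bool)]


@dataclass
class CascadeResult:
    """Output of the full cascade on one cohort table."""

    outcomes: list[FilterOutcome]
    somatic: pd.DataFrame  # passed quality + artefact exclusion
    rare: pd.DataFrame
    rare_damaging: pd.DataFrame
    quality_tally: dict[str, int]
    summary: dict[str, int]


def run_cascade(
    variants: pd.DataFrame, config: RunConfig, n_samples: int | None = None
) -> CascadeResult:
    """Quality -> artefact exclusion -> rarity/recurrence -> damaging.

    Summary counts report surviving variants and unique genes at the rare
    and rare-damaging stages; stage output is always a subset of its input.
    """
    q, tally = quality_filter(variants, config)
    s = somatic_exclusions(q)
    if n_samples is None:
        n_samples = int(variants["sample_id"].nunique())
    if n_samples == 0:
        raise ParameterError("run_cascade requires a non-empty analysis set")
    rare = rare_filter(s, config, n_samples=n_samples)
    dam = damaging_filter(rare, config)

    stage_of = pd.Series("quality", index=variants.index, dtype=object)
    stage_of[q.index] = "somatic_exclusions"
    stage_of[s.index] = "rare"
    stage_of[rare.index] = "damaging"
    stage_of[dam.index] = None
    rare_idx = set(rare.index)
    dam_idx = set(dam.index)
    outcomes = [
        FilterOutcome(
            index=int(i),
            stage_failed=stage_of[i],
            is_rare=i in rare_idx,
            is_rare_damaging=i in dam_idx,
        )
        for i in variants.index
    ]
    summary = {
        "n_input": len(variants),
        "n_pass_quality": len(q),
        "n_pass_somatic": len(s),
        "n_rare": len(rare),
        "n_rare_genes": int(rare["gene"].nunique()),
        "n_rare_damaging": len(dam),
        "n_rare_damaging_genes": int(dam["gene"].nunique()),
    }
    return CascadeResult(
        outcomes=outcomes,
        somatic=s,
        rare=rare,
        rare_damaging=dam,
        quality_tally=tally,
        summary=summary,
    )
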