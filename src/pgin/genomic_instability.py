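"""Per-sample genomic instability: expressed mutational burden.

The score is the number of rare somatic variants detected in a sample's
expressed transcripts divided by the megabases of its capture region — the
genome positions reaching the design's depth threshold (50x for placental
RNA, 10x for circulating RNA, 30x for WGS cell lines) in that sample's own
coverage histogram. The denominator uses depth >= threshold; the variant
depth filter upstream is strictly greater-than, mirroring how each cut is
stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import UndefinedScoreError
from .io_formats import CoverageProfile, RunConfig

__all__ = ["InstabilityScore", "covered_region_size", "instability", "cohort_instability"]


@dataclass
class InstabilityScore:
    sample_id: str
    n_rare_variants: int
    covered_bases: int
    depth_threshold: int
    burden: float  # rare variants per megabase of capture region

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_rare_variants": self.n_rare_variants,
            "covered_bases": self.covered_bases,
            "depth_threshold": self.depth_threshold,
            "burden": self.burden,
        }


def covered_region_size(profile: CoverageProfile, depth_threshold: int) -> int:
    """Positions at depth >= threshold; non-increasing in the threshold."""
    return int(sum(c for d, c in profile.depth_hist.items() if d >= depth_threshold))


def instability(
    rare_variants: pd.DataFrame,
    profile: CoverageProfile,
    config: RunConfig,
) -> InstabilityScore:
    """Burden = rare variants / (covered bases / 1e6) for one sample.

    ``rare_variants`` is this sample's surviving set from the filter
    cascade; indels count unless ``include_indels_in_burden`` is off.
    A sample with no position at the threshold has no defined score and is
    treated as failing coverage QC.
    """
    covered = covered_region_size(profile, config.burden_depth_threshold)
    if covered == 0:
        raise UndefinedScoreError(
            f"sample {profile.sample_id}: no position at depth >= "
            f"{config.burden_depth_threshold}; burden undefined"
        )
    sub = rare_variants[rare_variants["sample_id"] == profile.sample_id]
    if not config.include_indels_in_burden:
        sub = sub[sub["variant_type"] == "SNV"]
    n = len(sub)
    return InstabilityScore(
        sample_id=profile.sample_id,
        n_rare_variants=n,
        covered_bases=covered,
        depth_threshold=config.burden_depth_threshold,
        burden=n / (covered / 1e6),
    )


def cohort_instability(
    rare_variants: pd.DataFrame,
    profiles: dict[str, CoverageProfile],
    config: RunConfig,
) -> pd.DataFrame:
    """Instability scores for every sample with a coverage profile."""
    rows = [instability(rare_variants, p, config).to_dict() for p in profiles.values()]
    return pd.DataFrame(rows).set_index("sample_id")
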