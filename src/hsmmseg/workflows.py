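"""Two-track differentially-methylated-region (DMR) workflow.

Methylation differences carry the direction and size of a change; the
per-site test p-values carry the confidence.  Both tracks are segmented
independently with a 3-state model — for the effect track the states read
hypomethylated / null / hypermethylated, for the p-value track
high-confidence / low-confidence / null.  Because both value distributions
are asymmetric and non-uniform, emissions are initialized in cluster mode
rather than from quantiles.  Runs spanning inter-site gaps larger than
``max_gap`` (CpG sites are irregularly spaced) are split, and DMRs are the
intersections of extreme-effect segments (states 1 or 3) with
high-confidence segments (state 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import GenomicProfile, SegmentConfig, intersect_extreme, segment_profile

__all__ = ["detect_dmrs"]


def detect_dmrs(
    profile: GenomicProfile,
    effect_col: str,
    pval_col: str,
    max_gap: float = 100.0,
    seed: int = 0,
    J: int = 3,
) -> pd.DataFrame:
    """Locate DMRs by intersecting extreme-effect and low-p-value segments.

    Returns one row per region with the average effect (``mean_effect``) and
    average p-value (``mean_pval``) over the contained sites, plus a
    ``direction`` column (hyper/hypo) from the sign of the mean effect.
    """
    cfg = SegmentConfig(J=J, emission_family="norm", prior_mode="cluster",
                        max_gap=max_gap, seed=seed)
    ia = profile.samples.index(effect_col)
    ib = profile.samples.index(pval_col)
    track_a = GenomicProfile(profile.seqnames, profile.positions,
                             profile.values[:, [ia]], samples=[effect_col])
    track_b = GenomicProfile(profile.seqnames, profile.positions,
                             profile.values[:, [ib]], samples=[pval_col])
    res_a = segment_profile(track_a, cfg)
    res_b = segment_profile(track_b, cfg)
    regions = intersect_extreme(res_a, {1, J}, res_b, {1})
    regions = regions.rename(columns={"mean_a": "mean_effect", "mean_b": "mean_pval"})
    if len(regions):
        regions["direction"] = np.where(regions["mean_effect"] > 0, "hyper", "hypo")
    else:
        regions["direction"] = pd.Series(dtype=str)
    return regions
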