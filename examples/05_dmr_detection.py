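"""Two-track differentially-methylated-region detection.

Segments a methylation-difference track and a p-value track separately
(3 states each, cluster-mode emission priors because both distributions are
asymmetric), splits runs across CpG gaps larger than 100 bp, and intersects
extreme-effect segments (states 1/3) with high-confidence segments (state 1).
"""

from hsmmseg import detect_dmrs, simulate_methylation

profile, truth = simulate_methylation(seed=11)
print("planted regions:")
print(truth.to_string(index=False))

regions = detect_dmrs(profile, "meth.diff", "p.val", max_gap=100.0)
print("\ndetected DMRs:")
print(regions.to_string(index=False))
# Each detected region reports the average methylation difference
# (mean_effect, sign = direction of the change) and the average test p-value
# (mean_pval) over the CpG sites it contains.
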