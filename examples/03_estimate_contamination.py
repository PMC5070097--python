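"""Estimate tumor-in-normal contamination from consolidated counts.

Reconstructs a worked example: a marker SNV at 23% VAF in the neoplasm
observed at 2% VAF in adjacent tissue (blood clean) implies roughly
8.7% neoplasm content, since a tissue that is a fraction c tumor shows
each marker at c times its tumor VAF.
"""

from tinc import (
    SiteCounts,
    SiteLocus,
    estimate_sample_contamination,
    estimate_snv_contamination,
)

locus = SiteLocus("chr13", 32_936_732, "C", "T")


def counts(sample, vaf, coverage=10_000):
    m = round(vaf * coverage)
    return SiteCounts(locus=locus, sample_id=sample, mutant_pairs=m, non_mutant_pairs=coverage - m)


single = estimate_snv_contamination(
    adj=counts("adjacent", 0.02),
    blood=counts("blood", 0.0),
    tumor=counts("neoplasm", 0.23),
)
print(f"VAF neoplasm 23%, adjacent 2%, blood 0% -> c = {single.c:.4f} "
      f"({100 * single.c:.2f}% neoplasm content)")

# A sample is summarized by the median over its marker SNVs.  Negative
# per-SNV values (blood noise exceeding adjacent signal) are kept.
per_snv = []
for i, (vaf_adj, vaf_tumor) in enumerate(
    [(0.020, 0.23), (0.031, 0.28), (0.015, 0.19), (0.000, 0.24), (0.022, 0.21)]
):
    lo = SiteLocus("chr1", 1_000_000 + i, "A", "G")
    per_snv.append(
        estimate_snv_contamination(
            adj=SiteCounts(lo, "adjacent", round(vaf_adj * 10_000), 10_000 - round(vaf_adj * 10_000)),
            blood=SiteCounts(lo, "blood", 0, 10_000),
            tumor=SiteCounts(lo, "neoplasm", round(vaf_tumor * 10_000), 10_000 - round(vaf_tumor * 10_000)),
        )
    )

sample = estimate_sample_contamination(per_snv)
print(f"per-SNV c values: {[f'{e.c:.3f}' for e in sample.per_snv]}")
print(f"median contamination over {sample.n_snvs} SNVs: {100 * sample.median_c:.2f}%")
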