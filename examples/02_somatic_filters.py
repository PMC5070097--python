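"""Apply the three post-call filters and the coverage gate.

Constructs one clean somatic candidate and three candidates that each
trip a different filter, then prints every verdict with its reasons.
"""

from tinc import (
    FilterConfig,
    ReadObservation,
    SiteCounts,
    SiteLocus,
    VariantCandidate,
    filter_variants,
    fisher_exact_two_sided,
)


def counts(locus, sample, mutant, non_mutant):
    return SiteCounts(locus=locus, sample_id=sample, mutant_pairs=mutant, non_mutant_pairs=non_mutant)


def tumor_reads(alt, n_mut, n_ref, one_strand=False, qual_drop=False):
    reads = []
    for i in range(n_mut):
        reads.append(
            ReadObservation(
                read_id=f"m{i}",
                mate=1,
                strand="+" if (one_strand or i % 2 == 0) else "-",
                base=alt,
                base_quality=20 if qual_drop else 35,
                qual_5p=35,
                qual_3p=35,
            )
        )
    for i in range(n_ref):
        reads.append(
            ReadObservation(read_id=f"w{i}", mate=1, strand="+-"[i % 2], base="A",
                            base_quality=35, qual_5p=35, qual_3p=35)
        )
    return reads


def candidate(pos, blood=(0, 200), **read_kw):
    locus = SiteLocus("chr1", pos, "A", "C")
    cand = VariantCandidate(chrom="chr1", pos=pos, ref="A", alt="C")
    cand.tumor_observations = tumor_reads("C", 60, 140, **read_kw)
    cand.counts_by_sample = {
        "neoplasm": counts(locus, "neoplasm", 60, 140),
        "blood": counts(locus, "blood", *blood),
        "adjacent": counts(locus, "adjacent", 2, 198),
    }
    return cand


cands = [
    candidate(1_000_000),                        # clean somatic call
    candidate(2_000_000, blood=(55, 145)),       # present in blood at the same fraction
    candidate(3_000_000, one_strand=True),       # mutant support on one strand only
    candidate(4_000_000, qual_drop=True),        # systematic quality drop at the site
]

report = filter_variants(
    cands, FilterConfig(), mode="WES",
    tumor_sample="neoplasm", blood_sample="blood",
    required_samples=["neoplasm", "blood", "adjacent"],
)

p_germ = fisher_exact_two_sided(60, 140, 55, 145)
print(f"germline Fisher p for candidate 2 (tumor 60/140 vs blood 55/145): {p_germ:.3f}")
print()
for verdict in report.verdicts:
    status = "PASS" if verdict.passed else "fail: " + ", ".join(verdict.failed_rules)
    print(f"chr1:{verdict.pos:<9} {status}")
print()
print("attrition:", report.attrition())
# Only the first candidate survives; the germline candidate fails because
# p >= 0.05 cannot distinguish the tumor and blood allele fractions.
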