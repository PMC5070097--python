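"""Classify reads at an SNV site and consolidate mate pairs.

Builds a small pile of reads at one site: plain reference and mutant
reads, one insert whose two overlapping mates agree (counted once),
one insert whose mates disagree (excluded as a conflict), and one
low-quality read (unknown).
"""

from tinc import ReadObservation, SiteLocus, site_counts_from_observations

locus = SiteLocus(chrom="chr13", pos=32_936_732, ref="C", alt="T")

pile = [
    # five single-mate reference reads
    *[
        ReadObservation(read_id=f"ref{i}", mate=1, strand="+-"[i % 2], base="C", base_quality=36)
        for i in range(5)
    ],
    # two single-mate mutant reads
    ReadObservation(read_id="mut1", mate=1, strand="+", base="T", base_quality=35),
    ReadObservation(read_id="mut2", mate=1, strand="-", base="T", base_quality=38),
    # one insert with both mates mutant: one pair, not two reads
    ReadObservation(read_id="overlap", mate=1, strand="+", base="T", base_quality=37),
    ReadObservation(read_id="overlap", mate=2, strand="-", base="T", base_quality=33),
    # one insert whose mates disagree: excluded from the analysis
    ReadObservation(read_id="discord", mate=1, strand="+", base="T", base_quality=35),
    ReadObservation(read_id="discord", mate=2, strand="-", base="C", base_quality=35),
    # one low-quality base: unknown, contributes nothing to coverage
    ReadObservation(read_id="lowq", mate=1, strand="+", base="T", base_quality=8),
]

counts = site_counts_from_observations(pile, locus, sample_id="neoplasm")

print(f"site {locus}")
print(f"  mutant pairs      : {counts.mutant_pairs}")
print(f"  non-mutant pairs  : {counts.non_mutant_pairs}")
print(f"  unknown pairs     : {counts.unknown_pairs}")
print(f"  excluded conflicts: {counts.excluded_conflicts}")
print(f"  coverage          : {counts.coverage} pairs")
print(f"  VAF               : {counts.vaf:.3f}")
# The overlapping insert contributes a single mutant pair, so the VAF is
# 3 mutant / 8 informative pairs = 0.375, not inflated by double counting.
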