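# Methods

## Model

A grossly non-neoplastic tissue sample that is in truth a mixture of a
fraction `c` of neoplasm and `1 − c` of normal tissue shows each
somatic marker SNV at an expected allele fraction

    VAF_adjacent = VAF_blood + c · VAF_neoplasm

where `VAF_blood` absorbs the patient-specific noise floor (sequencing
error, residual germline signal) and `VAF_neoplasm` is the marker's
allele fraction in the tumor tissue itself — already diluted by
stromal cells, heterozygosity and copy-number state, which is why it
enters as the observed tumor VAF rather than the neoplastic
cellularity.  Inverting per SNV gives the estimator

    c = (VAF_adjacent − VAF_blood) / VAF_neoplasm,

and a sample is summarized by the median of `c` over its marker SNVs.
The model assumes markers are clonal in the neoplasm, diploid-stable
between the tissues, and that the contaminating material has the same
marker VAFs as the sequenced neoplasm section.  Tumor heterogeneity
between the section used for discovery and the contaminating cells is
not modeled; it would bias individual markers but is damped by the
median.

Per-SNV `c` values are **not clamped** at zero before taking the
median: sampling noise at an uncontaminated site is symmetric around
zero, and clamping would bias the median upward exactly where the
method should read 0.  Because the convention is genuinely ambiguous,
reports carry both the raw median and a clamped-at-zero median; they
coincide whenever contamination is real.

## Read classification and pair consolidation

At each marker, a read is `mutant` iff it carries the alternate allele
with base quality at or above `min_base_quality` (default Phred 20, a
conventional pileup floor; the value is configurable because the
"low quality" boundary of the unknown class is a judgement call),
`unknown` for an `N` or any base under the floor, and `non_mutant`
otherwise — both the reference base and third alleles, which make no
claim for the somatic allele.  Mates of one insert consolidate to a
single call: identical statuses collapse; `{mutant, non_mutant}` is a
conflict and the pair is excluded; `{x, unknown}` consolidates to `x`,
since an unknown base carries no allele claim and only *conflicting*
claims warrant exclusion; a third allele opposite an alternate allele
is a conflict (third alleles are non-mutant by definition).  Coverage
and VAF count informative consolidated pairs only.  This is what
protects ultra-deep small-amplicon data, where mates almost always
overlap the site, from counting each DNA molecule twice — the failure
mode that can conjure a low-level "mutation" out of a single
library-preparation artifact duplicated across a read pair.

Zero consolidated coverage leaves the VAF *undefined* rather than 0;
the coverage gates, not the classifier, own the exclusion.

Coordinates are 1-based fully-closed (VCF convention) everywhere; the
SAM adapter converts pysam's 0-based positions internally and reads
flank qualities from the adjacent aligned query bases.  Flank labels
follow reference orientation; the quality-drop rule ORs over both
flanks, so read orientation does not change its outcome.

## Filters

All thresholds live in `FilterConfig`:

| parameter | default | meaning |
|---|---|---|
| `germline_alpha` | 0.05 | fail when blood carries the allele and p ≥ α |
| `strand_alpha` | 0.05 | fail when mutant support is one-stranded and p < α |
| `qual_drop_delta` | 10 Phred | per-read drop threshold vs either flank |
| `qual_drop_fraction` | 0.70 | fraction of mutant reads that must show drop (strictly greater) |
| `min_cov_wes` / `min_cov_tas` | 20X / 5000X | per-sample consolidated coverage floor |
| `min_base_quality` | 20 | unknown-class floor for classification |

Boundary semantics follow the rule statements exactly: the germline
rule fails at p **≥** α, the quality-drop rule needs **more than**
70 %, coverage gates use **≥**.  Both Fisher tests are two-sided —
standard for 2×2 allele-count tables, with directionality already
encoded in the presence/one-strandedness clauses.  The germline table
is `[[tumor mutant, tumor non-mutant], [blood mutant, blood
non-mutant]]`, so p measures whether the two allele fractions are
distinguishable.  Strand-bias counts are per-read (pre-consolidation):
strand is a property of each aligned read and the filter belongs to
the calling stage.  The "5′ or 3′" comparison is a logical OR over
whichever flanks exist on each read; a read with neither flank cannot
show drop.  The exome coverage gate requires the floor in *all*
related samples — neoplasm, blood and every adjacent sample under
comparison.

The two-sided p-value itself sums hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's, with a 1e−7 relative tolerance for ties; per-margin
probability vectors are cached.  Degenerate tables (any empty margin)
return 1.  The test suite checks it against exhaustive exact-integer
enumeration on every table with margins ≤ 30 (164,176 tables, max
deviation ~6e−16) and cross-checks against an independent library
implementation.

Filters are evaluated exhaustively per candidate — no short-circuit —
so QC verdicts list every failure reason.  For attrition bookkeeping
(which must partition the candidates), each failed variant is
attributed to its *first* failed rule in application order: indel,
germline presence, strand bias, quality drop, coverage.

A consequence worth stating explicitly: since the germline rule fails
at p ≥ α, the fail set *shrinks* as α rises; the monotonicity test
asserts exactly that direction (passing at a lower α implies passing
at a higher α).

## Synthetic data

The generator emulates the study design the estimator was built for:
two patients, each with a neoplasm sample, a blood sample and four
adjacent samples collected under Clean/Dirty grossing × Clean/Dirty
procurement conditions.  Defaults (the `SimulationConfig` fields) are
the study conditions:

* tumor VAFs uniform on [0.10, 0.30] — the observed range after 50–70 %
  cellularity, heterozygosity and stromal dilution (`vaf_range`
  already folds cellularity in; the `tumor_cellularity` field is
  config metadata, echoed into the truth record);
* contamination per condition: Patient1 preset {0, 0.002, 0.022,
  0.035}, Patient2 preset {0, 0.003, 0, 0.209} — the reported
  per-condition medians, adopted as *scenario presets*, not as ground
  truth of the original tissues;
* 25 (Patient1) / 12 (Patient2) marker SNVs — the counts that
  qualified for ultra-deep estimation; the discovery stage's slightly
  larger counts arise from coverage attrition the simulator does not
  re-enact;
* depth Poisson with mean 200X (exome regime) or 20,000X (targeted
  regime, within the reported 17,585X–158,918X span); Poisson rather
  than empirical depth — the published ranges set the means only;
* per-base miscall 1e−3, symmetric to the three other bases (so the
  mutant-allele noise floor is `error_rate/3`); both mates of an
  insert overlap the site with probability 0.1 at exome depth;
  overlapping mates are discordant with probability 1e−3;
* Phred qualities ≈ N(35, 3) clipped to [2, 41].

Two artifact switches reshape the evidence so filter detectability can
be measured: `strand_bias_artifact` maps every mutant-carrying read to
the forward strand, and `qual_drop_artifact` gives alternate-allele
calls systematically depressed quality (flank = base + threshold +
margin) — "systematic" meaning every mutant read shows the drop, as at
a genuinely degraded cycle.

Granularities: `mode="reads"` generates per-read observations and
exercises classification, consolidation and all filters; it is used
for the exome regime and artifact studies.  `mode="counts"` draws
consolidated pair counts directly from the exact marginal of the same
model (`pairs ~ Poisson(depth)`, `mutant ~ Binomial(pairs,
v(1−e) + (1−v)e/3)`) and is used for the ultra-deep regime, where the
estimator consumes only counts; a test verifies the two routes agree
in distribution.  Per-sample RNG streams derive from `(seed, sample
index)`, so adding a sample never perturbs another's reads, and a
fixed seed reproduces every output byte-for-byte.

What the generator does **not** model — and hence what passing tests
do not certify about real tissue: copy-number alterations and
subclonal structure (marker VAFs are independent uniforms),
mapping/alignment error, GC- or amplicon-specific depth bias,
position-in-read effects, field-effect mutations or circulating tumor
DNA in the "clean" samples, and FFPE-style damage artifacts beyond the
two injected classes.

## Numerical and reporting choices

* Medians use the mean-of-central-pair convention for even n.
* Presence bins: `zero` iff no mutant pair; then VAF in (0, 1 %),
  [1 %, 5 %] closed on both ends (so "between 1 and 5 %" is disjoint
  from "less than 1 %"), and (5 %, 100 %].
* Cross-platform concordance is the squared Pearson correlation of
  untransformed VAF pairs — note r² is sign-blind and measures linear
  association, not agreement; the undefined zero-variance case raises
  rather than returning a number.
* Reports are deterministic: natural chromosome order (1–22, X, Y,
  then lexicographic), fractions at six significant digits,
  percentages only in log lines; logging to stderr, data to files;
  exit codes 0 / 2 (config) / 3 (input format).
* Problem sizes in the validation suite — 164k Fisher tables, 10,000
  random consolidation piles, 200 replicates for parameter recovery
  (counts mode at 20,000X) and artifact detection (reads mode at
  300X) — were chosen so the full suite completes in well under a
  minute while estimator standard errors stay an order of magnitude
  below the tolerances being asserted.

## Known limitations

* The estimator is a point estimate; no confidence interval is
  attached to the per-sample median (a bootstrap over markers would be
  the natural extension).
* VAF-level mixing ignores copy-number and cellularity corrections;
  where the neoplasm VAF is depressed by CNV, `c` inherits that bias.
* The blood subtraction assumes blood and adjacent tissue share the
  same error floor; platform differences between regimes are not
  corrected.
* `platform_concordance` quantifies association only; systematic
  VAF offsets between platforms would need a calibration line, not r².
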