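"""Post-call filters that turn candidate somatic SNVs into marker sites.

Three bespoke filters remove the recurrent false-call classes of a
tumor-vs-blood comparison, followed by a per-sample coverage gate:

1. **germline presence** — the alternate allele is seen in the matched
   blood sample *and* a two-sided Fisher exact test cannot distinguish
   the tumor and blood allele fractions (p >= alpha): the call is most
   likely a germline polymorphism, not a somatic event.
2. **strand bias** — all mutant-carrying reads sit on a single strand
   and the mutant/non-mutant x strand table is significantly skewed
   (p < alpha): a classic alignment/chemistry artifact signature.
3. **base-quality drop** — more than 70% of mutant reads show a Phred
   drop of at least 10 at the variant base relative to either flanking
   base: a systematic miscall at a locally degraded cycle.

Indel records are excluded outright (mapping bias makes them unusable
as contamination markers), and a minimum-coverage gate (20X for exome
discovery, 5000X for ultra-deep targeted validation) is enforced across
all related samples.  All rules are evaluated for every candidate — no
short-circuiting — so QC reports list every failure reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import ConfigError, InputFormatError, PipelineError
from .read_classification import (
    ReadObservation,
    ReadStatus,
    SiteCounts,
    SiteLocus,
    classify_read,
)

__all__ = [
    "FilterConfig",
    "FilterVerdict",
    "VariantCandidate",
    "FilterReport",
    "RULE_ORDER",
    "fisher_exact_two_sided",
    "germline_presence_filter",
    "strand_bias_filter",
    "quality_drop_filter",
    "coverage_gate",
    "filter_variants",
]

#: Application (and attrition bookkeeping) order of the filter rules.
RULE_ORDER = ("indel", "germline_presence", "strand_bias", "quality_drop", "coverage")

# Relative tolerance when deciding which tables tie with the observed one.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the post-call filters and coverage gates.

    Defaults are the published constants: alpha 0.05 for both Fisher
    tests, a Phred drop of >=10 in >70% of mutant reads for the
    quality-drop rule, and 20X / 5000X minimum coverage for the exome
    and targeted ultra-deep regimes respectively.
    """

    germline_alpha: float = 0.05
    strand_alpha: float = 0.05
    qual_drop_delta: int = 10
    qual_drop_fraction: float = 0.70
    min_cov_wes: int = 20
    min_cov_tas: int = 5000
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.germline_alpha < 1 and 0 < self.strand_alpha < 1):
            raise ConfigError("significance levels must lie in (0, 1)")
        if not 0 < self.qual_drop_fraction < 1:
            raise ConfigError("qual_drop_fraction must lie in (0, 1)")
        if min(self.qual_drop_delta, self.min_cov_wes, self.min_cov_tas) <= 0:
            raise ConfigError("thresholds must be strictly positive")

    def min_coverage(self, mode: str) -> int:
        mode = mode.upper()
        if mode == "WES":
            return self.min_cov_wes
        if mode == "TAS":
            return self.min_cov_tas
        raise ConfigError(f"mode must be WES or TAS, got {mode!r}")


@lru_cache(maxsize=65536)
def _pmf_table(n: int, row1: int, col1: int) -> tuple[int, np.ndarray]:
    """Hypergeometric pmf over the support of cell ``a`` given margins."""
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, row1, col1)
    probs.setflags(write=False)
    return lo, probs


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's
    (ties resolved with a small relative tolerance).  The degenerate
    all-zero table, and any table with an empty margin, carries no
    evidence and returns 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"table cells must be non-negative, got {(a, b, c, d)}")
    n = a + b + c + d
    if n == 0:
        return 1.0
    lo, probs = _pmf_table(n, a + b, a + c)
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def germline_presence_filter(
    tumor: SiteCounts, blood: SiteCounts, cfg: FilterConfig
) -> bool:
    """Return ``True`` (pass) unless the call looks germline.

    Fails iff the blood sample carries at least one mutant pair *and*
    Fisher's exact test on [[tumor mutant, tumor non-mutant],
    [blood mutant, blood non-mutant]] yields p >= alpha, i.e. the tumor
    and blood allele fractions are statistically indistinguishable.
    """
    if tumor.locus != blood.locus:
        raise PipelineError(
            f"germline filter got mismatched loci {tumor.locus} vs {blood.locus}"
        )
    if blood.mutant_pairs < 1:
        return True
    p = fisher_exact_two_sided(
        tumor.mutant_pairs, tumor.non_mutant_pairs, blood.mutant_pairs, blood.non_mutant_pairs
    )
    return p < cfg.germline_alpha


def strand_bias_filter(
    mutant_fwd: int,
    mutant_rev: int,
    non_mutant_fwd: int,
    non_mutant_rev: int,
    cfg: FilterConfig,
) -> bool:
    """Return ``True`` (pass) unless mutant support is one-stranded.

    Fails iff mutant alleles appear on only one strand *and* the
    mutant/non-mutant x forward/reverse table is significant
    (p < alpha).  Counts are per-read tallies in the neoplasm sample —
    strand is a property of each aligned read, and this filter belongs
    to the calling stage, before pair consolidation.
    """
    if min(mutant_fwd, mutant_rev, non_mutant_fwd, non_mutant_rev) < 0:
        raise ValueError("strand tallies must be non-negative")
    if mutant_fwd > 0 and mutant_rev > 0:
        return True
    p = fisher_exact_two_sided(mutant_fwd, mutant_rev, non_mutant_fwd, non_mutant_rev)
    return p >= cfg.strand_alpha


def quality_drop_filter(
    mutant_reads: Sequence[ReadObservation], cfg: FilterConfig
) -> bool:
    """Return ``True`` (pass) unless base quality drops systematically.

    A mutant read "shows drop" iff the Phred score of either flanking
    base exceeds the variant-base score by at least ``qual_drop_delta``
    (only the flanks present are considered; a read with no flank
    qualities cannot show drop).  Fails iff strictly more than
    ``qual_drop_fraction`` of the mutant reads show drop.  An empty
    mutant list passes vacuously.
    """
    if not mutant_reads:
        return True
    n_drop = 0
    for obs in mutant_reads:
        drop5 = obs.qual_5p is not None and obs.qual_5p - obs.base_quality >= cfg.qual_drop_delta
        drop3 = obs.qual_3p is not None and obs.qual_3p - obs.base_quality >= cfg.qual_drop_delta
        if drop5 or drop3:
            n_drop += 1
    return not (n_drop / len(mutant_reads) > cfg.qual_drop_fraction)


def coverage_gate(
    site_counts_by_sample: Mapping[str, SiteCounts],
    min_cov: int,
    required_samples: Iterable[str],
) -> tuple[bool, list[str]]:
    """Check the per-site coverage floor across every required sample.

    Returns ``(passed, failing_samples)``; a required sample with no
    counts at all fails explicitly.
    """
    required = list(required_samples)
    if not required:
        raise ConfigError("coverage gate needs a non-empty set of required samples")
    failing = []
    for sample_id in required:
        counts = site_counts_by_sample.get(sample_id)
        if counts is None:
            failing.append(f"{sample_id}:missing")
        elif counts.coverage < min_cov:
            failing.append(f"{sample_id}:{counts.coverage}X")
    return (not failing, failing)


@dataclass
class VariantCandidate:
    """One candidate variant record with the evidence the filters need.

    ``ref``/``alt`` are kept as raw strings so indel records survive
    parsing and can be excluded (rather than crash) at filter time.
    ``tumor_observations`` are the neoplasm-sample reads at the site
    (they feed the strand-bias and quality-drop rules);
    ``counts_by_sample`` holds consolidated pair counts per sample.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_observations: list[ReadObservation] = field(default_factory=list)
    counts_by_sample: dict[str, SiteCounts] = field(default_factory=dict)

    @property
    def is_indel(self) -> bool:
        return not (len(self.ref) == 1 and len(self.alt) == 1
                    and self.ref in "ACGT" and self.alt in "ACGT" and self.ref != self.alt)

    @property
    def locus(self) -> SiteLocus:
        return SiteLocus(self.chrom, self.pos, self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterVerdict:
    """Outcome of all filter rules for one candidate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    failed_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules

    @property
    def locus(self) -> SiteLocus:
        return SiteLocus(self.chrom, self.pos, self.ref, self.alt)

    @property
    def primary_failure(self) -> str | None:
        """First failed rule in application order (attrition bookkeeping)."""
        for rule in RULE_ORDER:
            if rule in self.failed_rules:
                return rule
        return None


@dataclass
class FilterReport:
    """Verdicts plus the records skipped for format errors."""

    verdicts: list[FilterVerdict] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def survivors(self) -> list[FilterVerdict]:
        return [v for v in self.verdicts if v.passed]

    def attrition(self) -> dict[str, int]:
        """Record bookkeeping: every candidate lands in exactly one bin."""
        out = {"candidates": len(self.verdicts) + len(self.skipped)}
        out["parse_skipped"] = len(self.skipped)
        for rule in RULE_ORDER:
            out[f"excluded_{rule}"] = sum(
                1 for v in self.verdicts if v.primary_failure == rule
            )
        out["survivors"] = len(self.survivors)
        return out


def _strand_tallies(
    observations: Iterable[ReadObservation], locus: SiteLocus, min_base_quality: int
) -> tuple[int, int, int, int, list[ReadObservation]]:
    """Per-read strand tallies and the mutant-read list at a site."""
    mf = mr = nf = nr = 0
    mutant_reads: list[ReadObservation] = []
    for obs in observations:
        status = classify_read(obs, locus, min_base_quality)
        if status is ReadStatus.MUTANT:
            mutant_reads.append(obs)
            if obs.strand == "+":
                mf += 1
            else:
                mr += 1
        elif status is ReadStatus.NON_MUTANT:
            if obs.strand == "+":
                nf += 1
            else:
                nr += 1
    return mf, mr, nf, nr, mutant_reads


def filter_variants(
    candidates: Iterable[VariantCandidate],
    cfg: FilterConfig,
    mode: str,
    tumor_sample: str,
    blood_sample: str,
    required_samples: Iterable[str] | None = None,
) -> FilterReport:
    """Apply every filter rule to every candidate.

    Rules run in the order indel exclusion, germline presence, strand
    bias, quality drop, coverage gate; each verdict records *all*
    failed rules.  Per-record format errors are collected in the
    report's ``skipped`` list instead of aborting the batch.
    """
    min_cov = cfg.min_coverage(mode)
    report = FilterReport()
    for cand in candidates:
        verdict = FilterVerdict(cand.chrom, cand.pos, cand.ref, cand.alt)
        if cand.is_indel:
            verdict.failed_rules.append("indel")
            report.verdicts.append(verdict)
            continue
        try:
            locus = cand.locus
            tumor = cand.counts_by_sample.get(tumor_sample)
            blood = cand.counts_by_sample.get(blood_sample)
            if tumor is None or blood is None:
                raise PipelineError(
                    f"candidate {locus} lacks counts for tumor/blood samples"
                )
            if not germline_presence_filter(tumor, blood, cfg):
                verdict.failed_rules.append("germline_presence")
            mf, mr, nf, nr, mutant_reads = _strand_tallies(
                cand.tumor_observations, locus, cfg.min_base_quality
            )
            if not strand_bias_filter(mf, mr, nf, nr, cfg):
                verdict.failed_rules.append("strand_bias")
            if not quality_drop_filter(mutant_reads, cfg):
                verdict.failed_rules.append("quality_drop")
            required = (
                list(required_samples)
                if required_samples is not None
                else sorted(cand.counts_by_sample)
            )
            passed_cov, _ = coverage_gate(cand.counts_by_sample, min_cov, required)
            if not passed_cov:
                verdict.failed_rules.append("coverage")
        except InputFormatError as exc:
            report.skipped.append((f"{cand.chrom}:{cand.pos}{cand.ref}>{cand.alt}", str(exc)))
            continue
        report.verdicts.append(verdict)
    return report
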