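"""Per-SNV and per-sample contamination estimation and WES summaries.

The contamination level of an adjacent non-neoplastic sample — the
fraction of neoplasm content it carries — is estimated per marker SNV
as

    c = (VAF_adjacent - VAF_blood) / VAF_neoplasm

and aggregated per sample as the median over its marker SNVs.  Blood
VAF subtracts the patient-specific noise floor; dividing by the
neoplasm VAF rescales from allele fraction to tissue fraction (a
marker at 20% VAF in pure tumor appears at 2% VAF when the adjacent
tissue is 10% tumor).  Per-SNV values are kept unclamped, so symmetric
sampling noise around zero yields a median near zero rather than a
positively biased one; a clamped-at-zero median is reported alongside.

At exome depth the same machinery supports only a coarser readout:
the fraction of marker SNVs with at least one mutant read, and a
four-way VAF binning (zero / below 1% / 1-5% / above 5%).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EstimationError, PipelineError
from .read_classification import SiteCounts, SiteLocus

__all__ = [
    "ContaminationEstimate",
    "SampleContamination",
    "PresenceSummary",
    "PRESENCE_BINS",
    "estimate_snv_contamination",
    "estimate_sample_contamination",
    "summarize_presence",
    "platform_concordance",
]

#: Labels of the four VAF presence bins, in order.
PRESENCE_BINS = ("zero", "below_1pct", "1_to_5pct", "above_5pct")


@dataclass(frozen=True)
class ContaminationEstimate:
    """Per-SNV contamination estimate for one adjacent sample.

    ``c`` may be negative before any clamping: blood-sample noise can
    exceed the adjacent-sample signal at an uncontaminated site.
    """

    locus: SiteLocus
    sample_id: str
    c: float
    vaf_adj: float
    vaf_blood: float
    vaf_tumor: float


@dataclass
class SampleContamination:
    """Median-aggregated contamination for one adjacent sample."""

    sample_id: str
    n_snvs: int
    median_c: float
    per_snv: list[ContaminationEstimate] = field(default_factory=list)

    @property
    def median_c_clamped(self) -> float:
        """Median with negative per-SNV values floored at zero."""
        return statistics.median(max(e.c, 0.0) for e in self.per_snv)


@dataclass
class PresenceSummary:
    """Exome-depth presence readout for one adjacent sample."""

    sample_id: str
    n_snvs: int
    n_with_mutant_read: int
    bin_counts: dict[str, int]

    @property
    def fraction_present(self) -> float:
        return self.n_with_mutant_read / self.n_snvs


def estimate_snv_contamination(
    adj: SiteCounts, blood: SiteCounts, tumor: SiteCounts
) -> ContaminationEstimate:
    """Estimate neoplasm content from one marker SNV.

    Requires all three samples to share the locus, defined VAFs (the
    coverage gates upstream own zero-coverage exclusion) and a strictly
    positive neoplasm VAF — a marker absent from the neoplasm itself
    carries no contamination information.
    """
    if not (adj.locus == blood.locus == tumor.locus):
        raise PipelineError(
            f"contamination estimate got mismatched loci "
            f"{adj.locus} / {blood.locus} / {tumor.locus}"
        )
    for counts in (adj, blood, tumor):
        if counts.vaf is None:
            raise EstimationError(
                f"undefined VAF (zero coverage) in sample {counts.sample_id} at {counts.locus}"
            )
    if tumor.vaf == 0:
        raise EstimationError(f"neoplasm VAF is zero at {tumor.locus}; marker uninformative")
    c = (adj.vaf - blood.vaf) / tumor.vaf
    return ContaminationEstimate(
        locus=adj.locus,
        sample_id=adj.sample_id,
        c=c,
        vaf_adj=adj.vaf,
        vaf_blood=blood.vaf,
        vaf_tumor=tumor.vaf,
    )


def estimate_sample_contamination(
    estimates: Sequence[ContaminationEstimate],
) -> SampleContamination:
    """Aggregate per-SNV estimates into a per-sample median.

    The median is the standard one (mean of the two central order
    statistics for even n), taken over unclamped per-SNV values.
    """
    if not estimates:
        raise EstimationError("cannot aggregate an empty list of estimates")
    sample_ids = {e.sample_id for e in estimates}
    if len(sample_ids) != 1:
        raise PipelineError(f"estimates mix samples: {sorted(sample_ids)}")
    return SampleContamination(
        sample_id=estimates[0].sample_id,
        n_snvs=len(estimates),
        median_c=statistics.median(e.c for e in estimates),
        per_snv=list(estimates),
    )


def summarize_presence(site_counts: Sequence[SiteCounts]) -> PresenceSummary:
    """Presence fraction and four-way VAF binning for one sample.

    Bins: ``zero`` iff no mutant pair was observed; otherwise the VAF
    falls in (0, 1%), [1%, 5%] (closed on both ends) or (5%, 100%].
    """
    if not site_counts:
        raise EstimationError("presence summary needs at least one site")
    sample_ids = {sc.sample_id for sc in site_counts}
    if len(sample_ids) != 1:
        raise PipelineError(f"site counts mix samples: {sorted(sample_ids)}")
    bins = {label: 0 for label in PRESENCE_BINS}
    n_present = 0
    for sc in site_counts:
        if sc.vaf is None:
            raise EstimationError(
                f"undefined VAF at {sc.locus} in {sc.sample_id}; apply coverage gates first"
            )
        if sc.mutant_pairs == 0:
            bins["zero"] += 1
            continue
        n_present += 1
        if sc.vaf < 0.01:
            bins["below_1pct"] += 1
        elif sc.vaf <= 0.05:
            bins["1_to_5pct"] += 1
        else:
            bins["above_5pct"] += 1
    return PresenceSummary(
        sample_id=site_counts[0].sample_id,
        n_snvs=len(site_counts),
        n_with_mutant_read=n_present,
        bin_counts=bins,
    )


def platform_concordance(vaf_pairs: Sequence[tuple[float, float]]) -> float:
    """Squared Pearson correlation between paired VAFs of two platforms.

    Note r-squared is sign-blind: a perfectly anti-correlated line also
    yields 1.0, so it measures linear association, not agreement.
    """
    if len(vaf_pairs) < 2:
        raise EstimationError("concordance needs at least two VAF pairs")
    x, y = np.asarray(vaf_pairs, dtype=float).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EstimationError("concordance undefined: zero variance on one platform")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
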