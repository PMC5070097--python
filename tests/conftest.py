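"""Shared fixtures: observation builders and the engineered toy batch."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tinc import (
    FilterConfig,
    ReadObservation,
    SiteCounts,
    SiteLocus,
    VariantCandidate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=200,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def locus() -> SiteLocus:
    return SiteLocus("chr1", 1_000_000, "A", "C")


@pytest.fixture
def make_obs():
    """Observation factory with sensible defaults."""

    def _make(
        read_id="r1",
        mate=1,
        strand="+",
        base="C",
        base_quality=35,
        qual_5p=35,
        qual_3p=35,
    ) -> ReadObservation:
        return ReadObservation(
            read_id=read_id,
            mate=mate,
            strand=strand,
            base=base,
            base_quality=base_quality,
            qual_5p=qual_5p,
            qual_3p=qual_3p,
        )

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160226)


def _counts(locus, sample_id, mutant, non_mutant):
    return SiteCounts(
        locus=locus, sample_id=sample_id, mutant_pairs=mutant, non_mutant_pairs=non_mutant
    )


def make_candidate(
    idx: int,
    *,
    ref="A",
    alt="C",
    tumor=(60, 140),
    blood=(0, 200),
    adjacent=(2, 198),
    strands="both",
    qual_drop=False,
    adjacent_coverage=None,
) -> VariantCandidate:
    """Build one fully-evidenced SNV candidate on chr1.

    ``strands``: "both" splits mutant reads over strands, "forward"
    puts them all on one strand.  ``qual_drop`` gives every mutant read
    flanks 15 Phred above the variant base.  ``adjacent_coverage``
    overrides the adjacent sample's pair count (e.g. to fail a gate).
    """
    pos = 1_000_000 + 1000 * idx
    loc = SiteLocus("chr1", pos, ref, alt)
    cand = VariantCandidate(chrom="chr1", pos=pos, ref=ref, alt=alt)

    t_mut, t_non = tumor
    obs = []
    for i in range(t_mut):
        strand = "+" if (strands == "forward" or i % 2 == 0) else "-"
        q = 20 if qual_drop else 35
        flank = 35 if qual_drop else 36
        obs.append(
            ReadObservation(
                read_id=f"m{i}", mate=1, strand=strand, base=alt,
                base_quality=q, qual_5p=flank, qual_3p=flank,
            )
        )
    for i in range(t_non):
        obs.append(
            ReadObservation(
                read_id=f"w{i}", mate=1, strand="+" if i % 2 else "-", base=ref,
                base_quality=35, qual_5p=35, qual_3p=35,
            )
        )
    cand.tumor_observations = obs

    a_mut, a_non = adjacent
    if adjacent_coverage is not None:
        a_mut, a_non = 0, adjacent_coverage
    cand.counts_by_sample = {
        "neoplasm": _counts(loc, "neoplasm", t_mut, t_non),
        "blood": _counts(loc, "blood", *blood),
        "adjacent": _counts(loc, "adjacent", a_mut, a_non),
    }
    return cand


@pytest.fixture
def toy_batch():
    """Six candidates engineered to fail one rule each, plus one clean.

    Returns (candidates, expected_survivor_key).  Composition:
    index 0 clean; 1 indel; 2 germline (blood carries the allele at the
    tumor's fraction); 3 one-stranded mutant support; 4 systematic
    quality drop; 5 adjacent coverage below any gate.
    """
    cands = [
        make_candidate(0),
        VariantCandidate(chrom="chr1", pos=1_001_000, ref="AT", alt="A"),
        make_candidate(2, blood=(60, 140)),
        make_candidate(3, strands="forward"),
        make_candidate(4, qual_drop=True),
        make_candidate(5, adjacent_coverage=10),
    ]
    return cands, cands[0].key


@pytest.fixture
def toy_filter_config() -> FilterConfig:
    return FilterConfig()
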