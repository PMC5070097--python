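"""Classification, pair consolidation and pair-level VAF computation."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tinc import (
    DuplicateReadError,
    InputFormatError,
    ReadStatus,
    SiteCounts,
    SiteLocus,
    classify_read,
    compute_site_counts,
    consolidate_pairs,
    site_counts_from_observations,
)
from tinc.read_classification import (
    ConsolidationResult,
    observations_by_site,
    read_observation_table,
    write_observation_table,
)

M, W, U = ReadStatus.MUTANT, ReadStatus.NON_MUTANT, ReadStatus.UNKNOWN


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "base, qual, expected",
    [
        ("C", 35, M),       # alternate allele, good quality
        ("C", 5, U),        # alternate allele but low quality
        ("A", 35, W),       # reference base
        ("A", 5, U),        # low quality trumps the allele
        ("G", 35, W),       # third allele counts as non-mutant
        ("N", 40, U),       # no-call is always unknown
        ("C", 20, M),       # threshold is inclusive
        ("C", 19, U),
    ],
)
def test_classify_read(make_obs, locus, base, qual, expected):
    obs = make_obs(base=base, base_quality=qual)
    assert classify_read(obs, locus, min_base_quality=20) is expected


def test_classify_rejects_bad_base_naming_the_record(make_obs, locus):
    with pytest.raises(InputFormatError, match="r1"):
        make_obs(base="X")


# ---------------------------------------------------------------------------
# consolidation: exhaustive mate-status matrix against the stated rules
# ---------------------------------------------------------------------------

def _status_base(status):
    return {M: "C", W: "A", U: "N"}[status]


def _expected_pair(a, b):
    """Literal consolidation rules for a two-mate insert."""
    if a == b:
        return a
    if U in (a, b):
        return a if b is U else b
    return "conflict"


@pytest.mark.parametrize("a, b", list(itertools.product([M, W, U], repeat=2)))
def test_consolidation_matrix(make_obs, locus, a, b):
    obs = [
        make_obs(read_id="p", mate=1, base=_status_base(a)),
        make_obs(read_id="p", mate=2, base=_status_base(b)),
    ]
    result = consolidate_pairs(obs, locus)
    expected = _expected_pair(a, b)
    if expected == "conflict":
        assert result.statuses == {} and result.n_conflicts == 1
    else:
        assert result.statuses == {"p": expected} and result.n_conflicts == 0


def test_double_count_prevention(make_obs, locus):
    """Both mates mutant at one insert yield a single mutant pair."""
    obs = [make_obs(read_id="ins", mate=1), make_obs(read_id="ins", mate=2)]
    counts = site_counts_from_observations(obs, locus, "s")
    assert counts.mutant_pairs == 1


def test_third_allele_vs_alt_is_a_conflict(make_obs, locus):
    obs = [
        make_obs(read_id="p", mate=1, base="C"),
        make_obs(read_id="p", mate=2, base="G"),  # third allele = non-mutant
    ]
    result = consolidate_pairs(obs, locus)
    assert result.n_conflicts == 1


def test_more_than_two_observations_is_a_duplicate_error(make_obs, locus):
    obs = [make_obs(read_id="d", mate=m) for m in (1, 2, 1)]
    with pytest.raises(DuplicateReadError, match="d"):
        consolidate_pairs(obs, locus)


def test_empty_input_gives_empty_result(locus):
    result = consolidate_pairs([], locus)
    assert result.statuses == {} and result.n_conflicts == 0


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------

def test_site_counts_vaf(locus):
    consolidated = ConsolidationResult(
        statuses={f"m{i}": M for i in range(23)} | {f"w{i}": W for i in range(77)}
    )
    counts = compute_site_counts(consolidated, locus, "neoplasm")
    assert (counts.coverage, counts.vaf) == (100, 0.23)


def test_site_counts_no_mutant_evidence(locus):
    counts = SiteCounts(locus, "s", mutant_pairs=0, non_mutant_pairs=50)
    assert counts.vaf == 0.0


def test_unknowns_and_conflicts_are_not_coverage(locus):
    consolidated = ConsolidationResult(
        statuses={f"m{i}": M for i in range(10)}
        | {f"w{i}": W for i in range(10)}
        | {f"u{i}": U for i in range(5)},
        n_conflicts=3,
    )
    counts = compute_site_counts(consolidated, locus, "s")
    assert (counts.coverage, counts.vaf) == (20, 0.5)
    assert (counts.unknown_pairs, counts.excluded_conflicts) == (5, 3)


def test_zero_coverage_vaf_is_undefined_not_zero(locus):
    counts = SiteCounts(locus, "s", mutant_pairs=0, non_mutant_pairs=0, unknown_pairs=4)
    assert counts.vaf is None


# ---------------------------------------------------------------------------
# property tests against a literal brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_counts(observations, locus, min_q=20):
    """Independent re-implementation: enumerate read ids, apply the rules."""
    def status_of(o):
        if o.base == "N" or o.base_quality < min_q:
            return "unknown"
        return "mutant" if o.base == locus.alt else "non_mutant"

    ids = []
    for o in observations:
        if o.read_id not in ids:
            ids.append(o.read_id)
    tally = {"mutant": 0, "non_mutant": 0, "unknown": 0, "conflict": 0}
    for rid in ids:
        statuses = sorted(status_of(o) for o in observations if o.read_id == rid)
        if len(statuses) == 1:
            tally[statuses[0]] += 1
        elif statuses[0] == statuses[1]:
            tally[statuses[0]] += 1
        elif "unknown" in statuses:
            other = statuses[0] if statuses[1] == "unknown" else statuses[1]
            tally[other] += 1
        else:
            tally["conflict"] += 1
    return tally


@st.composite
def observation_sets(draw):
    """Up to 20 reads with random mate/status structure at one site."""
    n_inserts = draw(st.integers(0, 12))
    obs = []
    for i in range(n_inserts):
        n_mates = draw(st.integers(1, 2))
        for mate in range(1, n_mates + 1):
            obs.append(
                dict(
                    read_id=f"r{i}",
                    mate=mate,
                    strand=draw(st.sampled_from("+-")),
                    base=draw(st.sampled_from("ACGTN")),
                    base_quality=draw(st.integers(0, 41)),
                )
            )
    return obs


@given(observation_sets())
def test_consolidation_matches_brute_force(make_obs, locus, raw):
    obs = [make_obs(qual_5p=None, qual_3p=None, **kw) for kw in raw]
    counts = site_counts_from_observations(obs, locus, "s")
    oracle = brute_force_counts(obs, locus)
    assert counts.mutant_pairs == oracle["mutant"]
    assert counts.non_mutant_pairs == oracle["non_mutant"]
    assert counts.unknown_pairs == oracle["unknown"]
    assert counts.excluded_conflicts == oracle["conflict"]


@given(observation_sets())
def test_conservation_of_inserts(make_obs, locus, raw):
    """Every distinct read id lands in exactly one of the four bins."""
    obs = [make_obs(qual_5p=None, qual_3p=None, **kw) for kw in raw]
    counts = site_counts_from_observations(obs, locus, "s")
    n_ids = len({o.read_id for o in obs})
    total = (
        counts.mutant_pairs
        + counts.non_mutant_pairs
        + counts.unknown_pairs
        + counts.excluded_conflicts
    )
    assert total == n_ids


@given(observation_sets())
def test_consolidation_idempotent_on_single_mate_sets(make_obs, locus, raw):
    """A one-observation-per-insert set consolidates to itself."""
    seen, singles = set(), []
    for kw in raw:
        if kw["read_id"] not in seen:
            seen.add(kw["read_id"])
            singles.append(make_obs(qual_5p=None, qual_3p=None, **kw))
    once = consolidate_pairs(singles, locus)
    assert once.n_conflicts == 0
    assert {rid: s for rid, s in once.statuses.items()} == {
        o.read_id: classify_read(o, locus) for o in singles
    }


# ---------------------------------------------------------------------------
# observation TSV dialect
# ---------------------------------------------------------------------------

def test_observation_table_round_trip(tmp_path, make_obs, locus):
    import pandas as pd

    rows = pd.DataFrame(
        [
            ("s1", locus.chrom, locus.pos, locus.ref, locus.alt, "r1", 1, "+", "C", 35, 34, None),
            ("s1", locus.chrom, locus.pos, locus.ref, locus.alt, "r1", 2, "-", "C", 33, None, 30),
            ("s2", locus.chrom, locus.pos, locus.ref, locus.alt, "r9", 1, "-", "A", 12, 20, 21),
        ],
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "read_id", "mate",
            "strand", "base", "base_qual", "qual_5p", "qual_3p",
        ],
    )
    path = tmp_path / "obs.tsv"
    write_observation_table(rows, path)
    assert "." in path.read_text()  # missing flank qualities

    grouped = observations_by_site(read_observation_table(path))
    assert set(grouped) == {("s1", locus), ("s2", locus)}
    pair = grouped[("s1", locus)]
    assert [o.mate for o in pair] == [1, 2]
    assert pair[0].qual_3p is None and pair[1].qual_5p is None


def test_observation_table_missing_column_is_a_format_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample_id\tchrom\n s\tchr1\n")
    with pytest.raises(InputFormatError, match="lacks columns"):
        read_observation_table(path)


# ---------------------------------------------------------------------------
# SAM adapter
# ---------------------------------------------------------------------------

def test_sam_adapter_extracts_pileup_rows(tmp_path):
    """0-based SAM positions convert to the 1-based locus convention."""
    sam = tmp_path / "toy.sam"
    # read "a" covers pos 100-109 forward; its mate reverse; read "d" has a
    # deletion spanning the site and must be skipped.
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "a\t99\tchr1\t100\t60\t10M\t=\t120\t30\tAACCGGTTAC\tIIIIIIIIII\n"
        "d\t0\tchr1\t100\t60\t4M3D6M\t*\t0\t0\tAACCGGTTAC\tIIIIIIIIII\n"
        "a\t147\tchr1\t120\t60\t10M\t=\t100\t-30\tAACCGGTTAC\tIIIIIIIIII\n"
    )
    loci = [SiteLocus("chr1", 105, "G", "T")]
    from tinc.read_classification import extract_observations_from_alignments

    df = extract_observations_from_alignments(str(sam), loci, "s1")
    assert list(df["read_id"]) == ["a"]  # deletion read skipped, mate elsewhere
    row = df.iloc[0]
    assert (row["pos"], row["base"], row["strand"], row["mate"]) == (105, "G", "+", 1)
    assert row["base_qual"] == 40  # 'I' = Phred 40
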