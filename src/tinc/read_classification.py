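"""Read-level mutant classification, mate-pair consolidation and VAF.

At each candidate somatic SNV the raw evidence is a pile of per-read
observations extracted from the alignments of one sample.  Every read is
classified against the site's alternate allele as ``mutant``,
``non_mutant`` (reference base *or* any third allele) or ``unknown``
(no-call or low base quality).  The two mates of a DNA insert are then
merged into a single consolidated call, and pairs whose mates make
conflicting allele claims are discarded.  Coverage and the variant
allele fraction (VAF) are defined over consolidated pairs only, so an
insert whose mates overlap the site is never counted twice — the
double-counting artifact this prevents is exactly what inflates
low-level VAFs at ultra-deep coverage.

Coordinates are 1-based and fully closed throughout (VCF convention);
the SAM adapter converts from pysam's 0-based positions internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import DuplicateReadError, InputFormatError

__all__ = [
    "SiteLocus",
    "ReadObservation",
    "ReadStatus",
    "ConsolidationResult",
    "SiteCounts",
    "classify_read",
    "consolidate_pairs",
    "compute_site_counts",
    "site_counts_from_observations",
    "OBSERVATION_COLUMNS",
    "read_observation_table",
    "write_observation_table",
    "observations_by_site",
    "extract_observations_from_alignments",
]

_BASES = frozenset("ACGT")
_CALLS = frozenset("ACGTN")

#: Default Phred floor below which a base call is uninformative.
DEFAULT_MIN_BASE_QUALITY = 20


@dataclass(frozen=True, order=True)
class SiteLocus:
    """One candidate somatic SNV site.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based genomic coordinate.
    ref, alt : str
        Single upper-case reference and alternate bases; indels are
        rejected at construction because only SNVs are usable as
        contamination markers.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputFormatError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise InputFormatError(
                f"SNV alleles must be single bases A/C/G/T, got "
                f"ref={self.ref!r} alt={self.alt!r} at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise InputFormatError(
                f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ReadObservation:
    """One sequencing read's evidence at a locus.

    ``read_id`` is shared by the two mates of a DNA insert.  ``qual_5p``
    and ``qual_3p`` are the Phred scores of the bases immediately 5' and
    3' of the site on the same read (``None`` when the site is at a read
    edge); they feed the systematic base-quality-drop filter.
    """

    read_id: str
    mate: int
    strand: str  # "+" or "-"
    base: str
    base_quality: int
    qual_5p: int | None = None
    qual_3p: int | None = None

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise InputFormatError(f"mate must be 1 or 2, got {self.mate} (read {self.read_id})")
        if self.strand not in ("+", "-"):
            raise InputFormatError(f"strand must be + or -, got {self.strand!r} (read {self.read_id})")
        if self.base not in _CALLS:
            raise InputFormatError(
                f"base call must be one of A/C/G/T/N, got {self.base!r} (read {self.read_id})"
            )
        if self.base_quality < 0:
            raise InputFormatError(f"negative base quality on read {self.read_id}")


class ReadStatus(enum.Enum):
    """Consolidated allele call of a read (or read pair) at a site."""

    MUTANT = "mutant"
    NON_MUTANT = "non_mutant"
    UNKNOWN = "unknown"


def classify_read(
    obs: ReadObservation,
    locus: SiteLocus,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> ReadStatus:
    """Classify a single read observation at ``locus``.

    A read is ``MUTANT`` iff it carries the alternate allele with
    quality at or above ``min_base_quality``; ``UNKNOWN`` for a no-call
    (``N``) or any low-quality base; ``NON_MUTANT`` otherwise — the
    reference base and any third allele both count as non-mutant.
    """
    if obs.base == "N" or obs.base_quality < min_base_quality:
        return ReadStatus.UNKNOWN
    if obs.base == locus.alt:
        return ReadStatus.MUTANT
    return ReadStatus.NON_MUTANT


@dataclass
class ConsolidationResult:
    """Consolidated per-insert statuses plus the conflict tally.

    ``statuses`` maps each read_id that yielded a usable call (mutant,
    non-mutant or unknown) to that call; inserts whose mates made
    conflicting allele claims are absent from the map and counted in
    ``n_conflicts``.
    """

    statuses: dict[str, ReadStatus]
    n_conflicts: int = 0

    @property
    def n_inserts(self) -> int:
        return len(self.statuses) + self.n_conflicts


def consolidate_pairs(
    observations: Iterable[ReadObservation],
    locus: SiteLocus,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> ConsolidationResult:
    """Merge mate observations into one call per DNA insert.

    Rules: identical mate statuses collapse to that status; a
    {mutant, non_mutant} pair is a conflict and is excluded (a third
    allele opposite an alternate allele is such a conflict, since third
    alleles are non-mutant by definition); unknown is uninformative, so
    {X, unknown} consolidates to X; a single overlapping mate keeps its
    own status.

    Raises
    ------
    DuplicateReadError
        If a read_id occurs more than twice — upstream duplicate
        marking should have removed such records.
    """
    per_insert: dict[str, list[ReadStatus]] = {}
    for obs in observations:
        statuses = per_insert.setdefault(obs.read_id, [])
        if len(statuses) >= 2:
            raise DuplicateReadError(
                f"read id {obs.read_id!r} has more than two observations at {locus}"
            )
        statuses.append(classify_read(obs, locus, min_base_quality))

    consolidated: dict[str, ReadStatus] = {}
    n_conflicts = 0
    for read_id, statuses in per_insert.items():
        if len(statuses) == 1:
            consolidated[read_id] = statuses[0]
            continue
        a, b = statuses
        if a == b:
            consolidated[read_id] = a
        elif ReadStatus.UNKNOWN in (a, b):
            consolidated[read_id] = a if b is ReadStatus.UNKNOWN else b
        else:  # {MUTANT, NON_MUTANT}
            n_conflicts += 1
    return ConsolidationResult(statuses=consolidated, n_conflicts=n_conflicts)


@dataclass
class SiteCounts:
    """Consolidated pair-level evidence for one sample at one site.

    ``coverage`` counts informative pairs only (mutant + non-mutant);
    unknown and conflicting pairs contribute nothing.  ``vaf`` is
    ``None`` (undefined, *not* zero) at zero coverage so that the
    downstream coverage gates own the exclusion.
    """

    locus: SiteLocus
    sample_id: str
    mutant_pairs: int
    non_mutant_pairs: int
    unknown_pairs: int = 0
    excluded_conflicts: int = 0

    def __post_init__(self) -> None:
        for name in ("mutant_pairs", "non_mutant_pairs", "unknown_pairs", "excluded_conflicts"):
            if getattr(self, name) < 0:
                raise InputFormatError(f"{name} must be non-negative")

    @property
    def coverage(self) -> int:
        return self.mutant_pairs + self.non_mutant_pairs

    @property
    def vaf(self) -> float | None:
        if self.coverage == 0:
            return None
        return self.mutant_pairs / self.coverage


def compute_site_counts(
    consolidated: ConsolidationResult, locus: SiteLocus, sample_id: str
) -> SiteCounts:
    """Tally consolidated statuses into a :class:`SiteCounts`."""
    tally = {status: 0 for status in ReadStatus}
    for status in consolidated.statuses.values():
        tally[status] += 1
    return SiteCounts(
        locus=locus,
        sample_id=sample_id,
        mutant_pairs=tally[ReadStatus.MUTANT],
        non_mutant_pairs=tally[ReadStatus.NON_MUTANT],
        unknown_pairs=tally[ReadStatus.UNKNOWN],
        excluded_conflicts=consolidated.n_conflicts,
    )


def site_counts_from_observations(
    observations: Iterable[ReadObservation],
    locus: SiteLocus,
    sample_id: str,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> SiteCounts:
    """Classify, consolidate and tally in one step."""
    return compute_site_counts(
        consolidate_pairs(observations, locus, min_base_quality), locus, sample_id
    )


# ---------------------------------------------------------------------------
# Observation table I/O (documented TSV dialect)
# ---------------------------------------------------------------------------

#: Column order of the read-observation TSV: one row per read per site,
#: header required, '.' for missing flank qualities.
OBSERVATION_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "read_id",
    "mate",
    "strand",
    "base",
    "base_qual",
    "qual_5p",
    "qual_3p",
]


def write_observation_table(rows: pd.DataFrame, path) -> None:
    """Write an observation table in the documented TSV dialect."""
    df = rows.loc[:, OBSERVATION_COLUMNS].copy()
    for col in ("qual_5p", "qual_3p"):
        df[col] = df[col].map(lambda v: "." if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def read_observation_table(path) -> pd.DataFrame:
    """Read and validate the observation TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"observation table {path} lacks columns: {missing}")
    df["pos"] = df["pos"].astype(int)
    df["mate"] = df["mate"].astype(int)
    df["base_qual"] = df["base_qual"].astype(int)
    for col in ("qual_5p", "qual_3p"):
        # object dtype keeps missing flanks as None, not NaN floats
        df[col] = pd.Series(
            [None if v in (".", "") else int(v) for v in df[col]],
            index=df.index,
            dtype=object,
        )
    return df


def observations_by_site(
    df: pd.DataFrame,
) -> dict[tuple[str, SiteLocus], list[ReadObservation]]:
    """Group an observation table by (sample_id, locus)."""
    grouped: dict[tuple[str, SiteLocus], list[ReadObservation]] = {}
    for row in df.itertuples(index=False):
        try:
            locus = SiteLocus(row.chrom, int(row.pos), row.ref, row.alt)
            obs = ReadObservation(
                read_id=row.read_id,
                mate=int(row.mate),
                strand=row.strand,
                base=row.base,
                base_quality=int(row.base_qual),
                qual_5p=row.qual_5p,
                qual_3p=row.qual_3p,
            )
        except InputFormatError as exc:
            raise InputFormatError(f"bad observation row {tuple(row)}: {exc}") from exc
        grouped.setdefault((row.sample_id, locus), []).append(obs)
    return grouped


def extract_observations_from_alignments(
    alignment_path: str,
    loci: Iterable[SiteLocus],
    sample_id: str,
    mode: str = "r",
) -> pd.DataFrame:
    """Pileup-extract the observation table from a SAM/BAM file.

    For each locus, every primary aligned read covering the (1-based)
    position contributes one row; reads with a deletion or reference
    skip at the site carry no base and are omitted.  Flank qualities
    are taken from the adjacent aligned query bases where present.
    """
    import pysam

    loci_by_chrom: dict[str, list[SiteLocus]] = {}
    for locus in loci:
        loci_by_chrom.setdefault(locus.chrom, []).append(locus)

    rows = []
    # streamed rather than region-fetched so unindexed SAM text works
    with pysam.AlignmentFile(alignment_path, mode) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            for locus in loci_by_chrom.get(read.reference_name, ()):
                target = locus.pos - 1  # pysam is 0-based
                if not read.reference_start <= target < read.reference_end:
                    continue
                qpos = None
                for q, r in read.get_aligned_pairs(matches_only=True):
                    if r == target:
                        qpos = q
                        break
                if qpos is None:
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                rows.append(
                    {
                        "sample_id": sample_id,
                        "chrom": locus.chrom,
                        "pos": locus.pos,
                        "ref": locus.ref,
                        "alt": locus.alt,
                        "read_id": read.query_name,
                        "mate": 2 if read.is_read2 else 1,
                        "strand": "-" if read.is_reverse else "+",
                        "base": seq[qpos].upper(),
                        "base_qual": int(quals[qpos]),
                        "qual_5p": int(quals[qpos - 1]) if qpos > 0 else None,
                        "qual_3p": int(quals[qpos + 1]) if qpos + 1 < len(quals) else None,
                    }
                )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
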