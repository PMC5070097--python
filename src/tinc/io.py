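"""Format adapters and deterministic report writers.

Candidates arrive as VCF (via pysam) or a minimal TSV (chrom, pos,
ref, alt); reports leave as TSV/JSON with a stable ordering (natural
chromosome order, then position, then sample) and fractions rendered
with six significant digits, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import re
from typing import Iterable, Sequence

import pandas as pd

from .contamination import ContaminationEstimate
from .errors import InputFormatError
from .somatic_filters import RULE_ORDER, FilterVerdict, VariantCandidate

__all__ = [
    "natural_chrom_key",
    "format_fraction",
    "read_candidates_vcf",
    "read_candidates_tsv",
    "write_verdicts_tsv",
    "write_estimates_tsv",
    "write_summary_json",
]

_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y|M|MT)$", re.IGNORECASE)


def natural_chrom_key(chrom: str) -> tuple[int, ...]:
    """Sort key: 1..22, X, Y, M first, then everything else lexically."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), 0)
        return (0, 22 + {"X": 1, "Y": 2, "M": 3, "MT": 3}[body], 0)
    return (1,) + tuple(ord(ch) for ch in chrom)


def format_fraction(x: float | None) -> str:
    """Six-significant-digit decimal rendering; 'NA' for undefined."""
    if x is None:
        return "NA"
    return f"{float(x):.6g}"


def read_candidates_vcf(path) -> list[VariantCandidate]:
    """Read candidate records from an uncompressed VCF.

    Every REF/ALT combination yields one candidate; non-SNV records are
    kept (flagged as indels downstream) rather than dropped silently.
    """
    import pysam

    candidates = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                candidates.append(
                    VariantCandidate(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                )
    return candidates


def read_candidates_tsv(path) -> list[VariantCandidate]:
    """Read candidates from a TSV with columns chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"candidate table {path} lacks columns: {missing}")
    return [
        VariantCandidate(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
        for r in df.itertuples(index=False)
    ]


def _sorted_by_locus(items: Sequence, chrom, pos):
    return sorted(items, key=lambda it: (natural_chrom_key(chrom(it)), pos(it)))


def write_verdicts_tsv(verdicts: Iterable[FilterVerdict], path) -> None:
    """One row per candidate: a failure flag per rule plus the final pass."""
    ordered = _sorted_by_locus(list(verdicts), lambda v: v.chrom, lambda v: v.pos)
    rows = []
    for v in ordered:
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
        for rule in RULE_ORDER:
            row[f"failed_{rule}"] = int(rule in v.failed_rules)
        row["passed"] = int(v.passed)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_estimates_tsv(estimates: Iterable[ContaminationEstimate], path) -> None:
    """Per-SNV contamination estimates, one row per (sample, locus)."""
    ordered = sorted(
        list(estimates),
        key=lambda e: (natural_chrom_key(e.locus.chrom), e.locus.pos, e.sample_id),
    )
    rows = [
        {
            "sample_id": e.sample_id,
            "chrom": e.locus.chrom,
            "pos": e.locus.pos,
            "ref": e.locus.ref,
            "alt": e.locus.alt,
            "vaf_tumor": format_fraction(e.vaf_tumor),
            "vaf_blood": format_fraction(e.vaf_blood),
            "vaf_adj": format_fraction(e.vaf_adj),
            "c": format_fraction(e.c),
        }
        for e in ordered
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def write_summary_json(summary: dict, path) -> None:
    """Deterministic JSON: sorted keys, floats at six significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
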