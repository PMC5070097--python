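"""Ground-truthed synthetic read generator emulating the study design.

The generator emulates a two-patient breast-lumpectomy design: for each
patient one neoplasm sample, one matched blood sample, and four
adjacent non-neoplastic samples collected under the four grossing /
tissue-procurement conditions (Clean/Clean, Clean/Dirty, Dirty/Clean,
Dirty/Dirty), each with a known contamination fraction.  Marker SNVs
carry tumor-tissue VAFs drawn uniformly from 10-30% (the range the
neoplastic cellularities of 50-70% support after heterozygosity and
stromal dilution); an adjacent sample with contamination ``c`` shows
each marker at VAF ``c * VAF_tumor``, blood at VAF 0, everything
observed through a symmetric per-base miscall error.

Two output granularities share one statistical model:

``mode="reads"``
    Per-read observations at the pileup abstraction — mate pairs, a
    configurable chance that both mates overlap the site, discordant
    pairs, Phred qualities, optional strand-bias and quality-drop
    artifact injection.  Used for exome-depth (~200X) end-to-end runs
    and for exercising the classification, consolidation and filter
    stages.

``mode="counts"``
    Consolidated pair counts drawn directly from the exact marginal of
    the read-level model (``pairs ~ Poisson(depth)``, ``mutant ~
    Binomial(pairs, v(1-e) + (1-v)e/3)``).  Used for ultra-deep
    targeted regimes (~20,000X), where the estimator consumes only the
    counts and object-per-read generation would add nothing but time.

Per-sample RNG streams are derived from ``(seed, sample index)``, so
adding a sample never perturbs another sample's reads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .read_classification import (
    OBSERVATION_COLUMNS,
    ReadObservation,
    SiteCounts,
    SiteLocus,
)

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "SimTruth",
    "SimulationResult",
    "simulate_site_reads",
    "simulate_site_counts",
    "simulate_patient",
    "expected_adjacent_vaf",
    "preset",
    "PRESET_NAMES",
    "write_truth_json",
    "read_truth_json",
    "write_candidates_vcf",
]

#: Adjacent-sample collection conditions, ordered as reported.
CONDITIONS = ("clean_clean", "clean_dirty", "dirty_clean", "dirty_dirty")

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated patient.

    Defaults are Patient2-like: 12 marker SNVs, 70% neoplastic
    cellularity, tumor VAFs uniform on [0.10, 0.30], contamination
    {0, 0.3%, 0, 20.9%} across the four conditions, ultra-deep
    targeted coverage (mean 20,000X) and a 1e-3 per-base miscall rate.
    """

    n_snvs: int = 12
    tumor_cellularity: float = 0.70
    vaf_range: tuple[float, float] = (0.10, 0.30)
    contamination_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "clean_clean": 0.0,
            "clean_dirty": 0.003,
            "dirty_clean": 0.0,
            "dirty_dirty": 0.209,
        }
    )
    coverage_mean: float = 20000.0
    error_rate: float = 1e-3
    pair_overlap_fraction: float = 0.1
    conflict_rate: float = 1e-3
    qual_drop_artifact: bool = False
    strand_bias_artifact: bool = False
    seed: int = 0
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_snvs < 1:
            raise ConfigError("n_snvs must be >= 1")
        if not 0 < self.tumor_cellularity <= 1:
            raise ConfigError("tumor_cellularity must lie in (0, 1]")
        lo, hi = self.vaf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError(f"vaf_range must satisfy 0 < lo <= hi < 1, got {self.vaf_range}")
        if set(self.contamination_by_condition) != set(CONDITIONS):
            raise ConfigError(
                f"contamination_by_condition must cover exactly {CONDITIONS}"
            )
        for cond, c in self.contamination_by_condition.items():
            if not 0 <= c <= 1:
                raise ConfigError(f"contamination for {cond} must lie in [0, 1], got {c}")
        if self.coverage_mean < 1:
            raise ConfigError("coverage_mean must be >= 1")
        for name in ("error_rate", "pair_overlap_fraction", "conflict_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


def preset(name: str) -> SimulationConfig:
    """Named study-condition presets.

    ``patient1-*`` — 25 marker SNVs, 50% cellularity, contamination
    rising monotonically Clean/Clean → Dirty/Dirty (0, 0.2%, 2.2%,
    3.5%).  ``patient2-*`` — 12 SNVs, 70% cellularity, contamination
    confined to Dirty/Dirty (0, 0.3%, 0, 20.9%).  ``*-wes`` uses mean
    200X coverage, ``*-tas`` mean 20,000X.  These presets adopt the
    reported per-condition medians as scenario ground truth; they are
    emulations of the study design, not the original tissues.
    """
    patient1 = dict(
        n_snvs=25,
        tumor_cellularity=0.50,
        contamination_by_condition={
            "clean_clean": 0.0,
            "clean_dirty": 0.002,
            "dirty_clean": 0.022,
            "dirty_dirty": 0.035,
        },
        patient_id="patient1",
    )
    patient2 = dict(
        n_snvs=12,
        tumor_cellularity=0.70,
        contamination_by_condition={
            "clean_clean": 0.0,
            "clean_dirty": 0.003,
            "dirty_clean": 0.0,
            "dirty_dirty": 0.209,
        },
        patient_id="patient2",
    )
    table = {
        "patient1-wes": {**patient1, "coverage_mean": 200.0},
        "patient1-tas": {**patient1, "coverage_mean": 20000.0},
        "patient2-wes": {**patient2, "coverage_mean": 200.0},
        "patient2-tas": {**patient2, "coverage_mean": 20000.0},
    }
    if name not in table:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(table)}")
    return SimulationConfig(**table[name])


PRESET_NAMES = ("patient1-wes", "patient1-tas", "patient2-wes", "patient2-tas")


def expected_adjacent_vaf(c: float, vaf_tumor: float, vaf_blood: float = 0.0) -> float:
    """Expected adjacent-tissue VAF under contamination fraction ``c``.

    The exact algebraic inverse of the contamination estimator:
    ``vaf_blood + c * vaf_tumor``.
    """
    return vaf_blood + c * vaf_tumor


def _draw_phred(rng: np.random.Generator, n: int, mean: float = 35.0, sd: float = 3.0) -> np.ndarray:
    """Realistic Phred scores: rounded normal clipped to [2, 41]."""
    return np.clip(np.rint(rng.normal(mean, sd, size=n)), 2, 41).astype(int)


def _observed_bases(
    true_bases: np.ndarray, rng: np.random.Generator, error_rate: float
) -> np.ndarray:
    """Apply a symmetric miscall to each base (uniform over the 3 others)."""
    out = true_bases.copy()
    err = rng.random(len(out)) < error_rate
    if err.any():
        idx = np.flatnonzero(err)
        for i in idx:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(3)]
    return out


def simulate_site_reads(
    true_vaf: float,
    coverage: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    locus: SiteLocus | None = None,
) -> list[ReadObservation]:
    """Generate per-read observations for one site of one sample.

    ``coverage`` is the number of DNA inserts; each insert carries the
    mutant allele with probability ``true_vaf``, emits one read (or two
    overlapping mates with probability ``pair_overlap_fraction``), and
    every read's base is subject to the symmetric miscall error.
    Overlapping mates are concordant unless ``conflict_rate`` triggers,
    in which case the second mate reports the opposite allele class.

    Artifact flags reshape the generated evidence: with
    ``strand_bias_artifact`` every mutant-carrying read maps to the
    forward strand; with ``qual_drop_artifact`` alternate-allele base
    calls get systematically depressed quality relative to their
    flanks (flank = base quality + drop threshold + margin).
    """
    if not 0 <= true_vaf <= 1:
        raise ConfigError(f"true_vaf must lie in [0, 1], got {true_vaf}")
    ref = locus.ref if locus is not None else "A"
    alt = locus.alt if locus is not None else "C"

    is_mutant = rng.random(coverage) < true_vaf
    true_base = np.where(is_mutant, alt, ref)
    base1 = _observed_bases(true_base, rng, cfg.error_rate)
    both_mates = rng.random(coverage) < cfg.pair_overlap_fraction
    conflict = both_mates & (rng.random(coverage) < cfg.conflict_rate)
    strand1 = np.where(rng.random(coverage) < 0.5, "+", "-")

    # mate 2: independent error on the same insert allele, unless a
    # library/chimeric conflict flips the allele class outright.
    base2 = _observed_bases(true_base, rng, cfg.error_rate)
    base2 = np.where(conflict, np.where(is_mutant, ref, alt), base2)

    reads: list[ReadObservation] = []
    for i in range(coverage):
        for mate, base in ((1, base1[i]), (2, base2[i])) if both_mates[i] else ((1, base1[i]),):
            strand = strand1[i] if mate == 1 else ("-" if strand1[i] == "+" else "+")
            if cfg.strand_bias_artifact and base == alt:
                strand = "+"
            q = int(_draw_phred(rng, 1)[0])
            q5, q3 = (int(v) for v in _draw_phred(rng, 2))
            if cfg.qual_drop_artifact and base == alt:
                q = int(np.clip(np.rint(rng.normal(22, 1.5)), 20, 41))
                margin = int(rng.integers(2, 8))
                q5 = min(q + 10 + margin, 41)
                q3 = min(q + 10 + margin, 41)
            reads.append(
                ReadObservation(
                    read_id=f"r{i:06d}",
                    mate=mate,
                    strand=str(strand),
                    base=str(base),
                    base_quality=q,
                    qual_5p=q5,
                    qual_3p=q3,
                )
            )
    return reads


def simulate_site_counts(
    true_vaf: float,
    coverage_mean: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    locus: SiteLocus,
    sample_id: str,
) -> SiteCounts:
    """Draw consolidated pair counts directly from the model marginal.

    The number of informative pairs is Poisson(``coverage_mean``); each
    pair reads mutant with probability ``v(1-e) + (1-v)e/3`` (true
    signal plus the symmetric miscall's contribution toward the
    alternate allele).
    """
    n = int(rng.poisson(coverage_mean))
    e = cfg.error_rate
    p = true_vaf * (1 - e) + (1 - true_vaf) * e / 3
    m = int(rng.binomial(n, p)) if n > 0 else 0
    return SiteCounts(
        locus=locus, sample_id=sample_id, mutant_pairs=m, non_mutant_pairs=n - m
    )


@dataclass
class SimTruth:
    """Generator ground truth, round-trippable through JSON bit-exactly."""

    seed: int
    snvs: list[dict]  # chrom, pos, ref, alt, vaf_tumor
    samples: dict[str, dict]  # sample_id -> {role, condition, contamination}
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class SimulationResult:
    """One simulated patient: truth plus reads or counts per sample."""

    truth: SimTruth
    loci: list[SiteLocus]
    observations: dict[str, dict[SiteLocus, list[ReadObservation]]] | None = None
    site_counts: dict[str, dict[SiteLocus, SiteCounts]] | None = None

    def observation_frame(self) -> pd.DataFrame:
        """Flatten read-level output into the observation TSV dialect."""
        if self.observations is None:
            raise ConfigError("observation_frame requires a reads-mode simulation")
        rows = []
        for sample_id in self.observations:
            for locus in self.loci:
                for obs in self.observations[sample_id].get(locus, []):
                    rows.append(
                        (
                            sample_id,
                            locus.chrom,
                            locus.pos,
                            locus.ref,
                            locus.alt,
                            obs.read_id,
                            obs.mate,
                            obs.strand,
                            obs.base,
                            obs.base_quality,
                            obs.qual_5p,
                            obs.qual_3p,
                        )
                    )
        return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def _make_loci(rng: np.random.Generator, n_snvs: int) -> list[SiteLocus]:
    loci = []
    for i in range(n_snvs):
        chrom = f"chr{(i % 22) + 1}"
        pos = 1_000_000 + 50_000 * i
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        loci.append(SiteLocus(chrom, pos, ref, alt))
    return loci


def simulate_patient(cfg: SimulationConfig, mode: str = "reads") -> SimulationResult:
    """Simulate one patient's six samples at every marker SNV.

    Tumor-tissue VAFs are drawn once per SNV from ``vaf_range`` (the
    range already folds in cellularity and heterozygosity); blood is
    VAF 0 everywhere; each adjacent sample shows VAF ``c x VAF_tumor``
    for its condition's contamination fraction ``c``.  Per-site depth
    is Poisson(``coverage_mean``).  ``mode`` selects read-level
    observations (``"reads"``) or direct consolidated counts
    (``"counts"``).
    """
    if mode not in ("reads", "counts"):
        raise ConfigError(f"mode must be 'reads' or 'counts', got {mode!r}")
    cfg.validate()

    truth_rng = np.random.default_rng([cfg.seed, 0])
    loci = _make_loci(truth_rng, cfg.n_snvs)
    vaf_tumor = truth_rng.uniform(*cfg.vaf_range, size=cfg.n_snvs)

    samples: dict[str, tuple[str, str | None, float]] = {
        f"{cfg.patient_id}_neoplasm": ("neoplasm", None, 1.0),
        f"{cfg.patient_id}_blood": ("blood", None, 0.0),
    }
    for cond in CONDITIONS:
        samples[f"{cfg.patient_id}_{cond}"] = (
            "adjacent",
            cond,
            cfg.contamination_by_condition[cond],
        )

    observations: dict[str, dict[SiteLocus, list[ReadObservation]]] = {}
    site_counts: dict[str, dict[SiteLocus, SiteCounts]] = {}
    for idx, (sample_id, (role, cond, c)) in enumerate(samples.items()):
        rng = np.random.default_rng([cfg.seed, idx + 1])
        per_site_reads: dict[SiteLocus, list[ReadObservation]] = {}
        per_site_counts: dict[SiteLocus, SiteCounts] = {}
        for i, locus in enumerate(loci):
            if role == "neoplasm":
                v = float(vaf_tumor[i])
            elif role == "blood":
                v = 0.0
            else:
                v = min(expected_adjacent_vaf(c, float(vaf_tumor[i])), 1.0)
            if mode == "reads":
                depth = int(rng.poisson(cfg.coverage_mean))
                per_site_reads[locus] = simulate_site_reads(v, depth, cfg, rng, locus=locus)
            else:
                per_site_counts[locus] = simulate_site_counts(
                    v, cfg.coverage_mean, cfg, rng, locus, sample_id
                )
        if mode == "reads":
            observations[sample_id] = per_site_reads
        else:
            site_counts[sample_id] = per_site_counts

    truth = SimTruth(
        seed=cfg.seed,
        snvs=[
            {
                "chrom": locus.chrom,
                "pos": locus.pos,
                "ref": locus.ref,
                "alt": locus.alt,
                "vaf_tumor": float(vaf_tumor[i]),
            }
            for i, locus in enumerate(loci)
        ],
        samples={
            sample_id: {"role": role, "condition": cond, "contamination": c}
            for sample_id, (role, cond, c) in samples.items()
        },
        config={**dataclasses.asdict(cfg), "vaf_range": list(cfg.vaf_range)},
    )
    return SimulationResult(
        truth=truth,
        loci=loci,
        observations=observations if mode == "reads" else None,
        site_counts=site_counts if mode == "counts" else None,
    )


def write_truth_json(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
        fh.write("\n")


def read_truth_json(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_json(fh.read())


def write_candidates_vcf(loci: Iterable[SiteLocus], path) -> None:
    """Write the marker SNVs as an uncompressed VCF."""
    import pysam

    header = pysam.VariantHeader()
    for i in range(1, 23):
        header.add_line(f"##contig=<ID=chr{i}>")
    header.add_line("##contig=<ID=chrX>")
    header.add_line("##contig=<ID=chrY>")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus in loci:
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=(locus.ref, locus.alt),
            )
            vcf.write(rec)
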