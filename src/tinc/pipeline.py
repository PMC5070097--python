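"""End-to-end orchestration: filter -> classify -> estimate -> summarize.

Mirrors the two-stage study workflow: an exome-depth discovery stage
(filters plus the presence readout) and an ultra-deep targeted stage
(per-SNV contamination and per-sample medians).  Attrition bookkeeping
conserves records at every stage boundary: every candidate ends up as
a survivor, excluded under exactly one primary rule, or parse-skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .contamination import (
    ContaminationEstimate,
    PresenceSummary,
    SampleContamination,
    estimate_sample_contamination,
    estimate_snv_contamination,
    summarize_presence,
)
from .errors import ConfigError, EstimationError
from .io import (
    natural_chrom_key,
    read_candidates_tsv,
    read_candidates_vcf,
    write_estimates_tsv,
    write_summary_json,
    write_verdicts_tsv,
)
from .read_classification import (
    ReadObservation,
    SiteCounts,
    SiteLocus,
    observations_by_site,
    read_observation_table,
    site_counts_from_observations,
)
from .somatic_filters import FilterConfig, FilterReport, VariantCandidate, filter_variants

__all__ = ["SampleRole", "RunConfig", "PipelineResult", "run_pipeline", "execute_run"]


@dataclass(frozen=True)
class SampleRole:
    """Role of one sample in the patient design."""

    role: str  # neoplasm | blood | adjacent
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("neoplasm", "blood", "adjacent"):
            raise ConfigError(f"sample role must be neoplasm/blood/adjacent, got {self.role!r}")


@dataclass
class RunConfig:
    """One pipeline run: mode, sample manifest, thresholds and paths."""

    mode: str
    manifest: dict[str, SampleRole]
    candidates: str
    observations: str
    out: str
    filters: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode.upper() not in ("WES", "TAS"):
            raise ConfigError(f"mode must be WES or TAS, got {self.mode!r}")
        roles = [s.role for s in self.manifest.values()]
        if roles.count("neoplasm") != 1 or roles.count("blood") != 1:
            raise ConfigError("manifest needs exactly one neoplasm and one blood sample")
        if roles.count("adjacent") < 1:
            raise ConfigError("manifest needs at least one adjacent sample")

    @property
    def tumor_sample(self) -> str:
        return next(s for s, r in self.manifest.items() if r.role == "neoplasm")

    @property
    def blood_sample(self) -> str:
        return next(s for s, r in self.manifest.items() if r.role == "blood")

    @property
    def adjacent_samples(self) -> list[str]:
        return [s for s, r in self.manifest.items() if r.role == "adjacent"]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"run config {path} is not a mapping")
        try:
            manifest = {
                sample_id: SampleRole(
                    role=spec["role"], condition=spec.get("condition")
                )
                for sample_id, spec in raw["samples"].items()
            }
            filters = FilterConfig(**raw.get("filters", {}))
            base = Path(path).parent
            return cls(
                mode=raw["mode"],
                manifest=manifest,
                candidates=str((base / raw["candidates"]).resolve()),
                observations=str((base / raw["observations"]).resolve()),
                out=str((base / raw.get("out", "results")).resolve()),
                filters=filters,
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"run config {path} lacks required field {exc}") from exc
        except TypeError as exc:
            raise ConfigError(f"run config {path}: {exc}") from exc


@dataclass
class PipelineResult:
    """Everything one run computes, ready for reporting."""

    mode: str
    report: FilterReport
    site_counts: dict[str, dict[SiteLocus, SiteCounts]]
    estimates: dict[str, SampleContamination]
    presence: dict[str, PresenceSummary]
    skipped_estimates: dict[str, list[str]]

    @property
    def survivors(self) -> list[SiteLocus]:
        return sorted(
            (v.locus for v in self.report.survivors),
            key=lambda lo: (natural_chrom_key(lo.chrom), lo.pos),
        )

    def summary(self, manifest: Mapping[str, SampleRole]) -> dict:
        samples = {}
        for sample_id, role in manifest.items():
            if role.role != "adjacent":
                continue
            block: dict = {"condition": role.condition}
            pres = self.presence.get(sample_id)
            if pres is not None:
                block.update(
                    n_snvs=pres.n_snvs,
                    n_with_mutant_read=pres.n_with_mutant_read,
                    fraction_present=pres.fraction_present,
                    bin_counts=pres.bin_counts,
                )
            est = self.estimates.get(sample_id)
            if est is not None:
                block.update(
                    median_contamination=est.median_c,
                    median_contamination_clamped=est.median_c_clamped,
                    n_snvs_estimated=est.n_snvs,
                )
            if self.skipped_estimates.get(sample_id):
                block["estimation_skipped_loci"] = self.skipped_estimates[sample_id]
            samples[sample_id] = block
        return {
            "mode": self.mode,
            "attrition": self.report.attrition(),
            "n_survivors": len(self.survivors),
            "evaluable": bool(self.survivors),
            "samples": samples,
        }


def run_pipeline(
    candidates: list[VariantCandidate],
    obs_by_site: Mapping[tuple[str, SiteLocus], list[ReadObservation]],
    config: RunConfig,
) -> PipelineResult:
    """Run filtering, consolidation and estimation over parsed inputs.

    Every manifest sample gets a (possibly zero) :class:`SiteCounts`
    per SNV candidate, so absent evidence fails the coverage gate
    rather than crashing; the neoplasm pile additionally feeds the
    strand-bias and quality-drop rules through each candidate.
    """
    cfg = config.filters
    sample_ids = list(config.manifest)

    for cand in candidates:
        if cand.is_indel:
            continue
        locus = cand.locus
        cand.tumor_observations = obs_by_site.get((config.tumor_sample, locus), [])
        for sample_id in sample_ids:
            obs = obs_by_site.get((sample_id, locus), [])
            cand.counts_by_sample[sample_id] = site_counts_from_observations(
                obs, locus, sample_id, cfg.min_base_quality
            )

    report = filter_variants(
        candidates,
        cfg,
        config.mode,
        tumor_sample=config.tumor_sample,
        blood_sample=config.blood_sample,
        required_samples=sample_ids,
    )

    survivor_keys = {v.locus for v in report.survivors}
    counts_by_sample: dict[str, dict[SiteLocus, SiteCounts]] = {
        s: {} for s in sample_ids
    }
    for cand in candidates:
        if cand.is_indel or cand.locus not in survivor_keys:
            continue
        for sample_id in sample_ids:
            counts_by_sample[sample_id][cand.locus] = cand.counts_by_sample[sample_id]

    ordered_loci = sorted(
        survivor_keys, key=lambda lo: (natural_chrom_key(lo.chrom), lo.pos)
    )
    estimates: dict[str, SampleContamination] = {}
    presence: dict[str, PresenceSummary] = {}
    skipped: dict[str, list[str]] = {}
    for sample_id in config.adjacent_samples:
        adj_counts = [counts_by_sample[sample_id][lo] for lo in ordered_loci]
        if adj_counts:
            presence[sample_id] = summarize_presence(adj_counts)
        per_snv: list[ContaminationEstimate] = []
        for locus in ordered_loci:
            try:
                per_snv.append(
                    estimate_snv_contamination(
                        counts_by_sample[sample_id][locus],
                        counts_by_sample[config.blood_sample][locus],
                        counts_by_sample[config.tumor_sample][locus],
                    )
                )
            except EstimationError as exc:
                skipped.setdefault(sample_id, []).append(str(exc))
        if per_snv:
            estimates[sample_id] = estimate_sample_contamination(per_snv)

    return PipelineResult(
        mode=config.mode.upper(),
        report=report,
        site_counts=counts_by_sample,
        estimates=estimates,
        presence=presence,
        skipped_estimates=skipped,
    )


def execute_run(config: RunConfig) -> tuple[PipelineResult, dict]:
    """Load inputs from disk, run the pipeline and write the reports.

    Emits ``verdicts.tsv``, ``estimates.tsv`` and ``summary.json`` under
    ``config.out``; returns the in-memory result and summary dict.
    """
    cand_path = config.candidates
    if cand_path.endswith((".vcf", ".vcf.gz")):
        candidates = read_candidates_vcf(cand_path)
    else:
        candidates = read_candidates_tsv(cand_path)
    obs_by_site = observations_by_site(read_observation_table(config.observations))

    result = run_pipeline(candidates, obs_by_site, config)

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    write_verdicts_tsv(result.report.verdicts, outdir / "verdicts.tsv")
    all_estimates = [e for sc in result.estimates.values() for e in sc.per_snv]
    write_estimates_tsv(all_estimates, outdir / "estimates.tsv")
    summary = result.summary(config.manifest)
    write_summary_json(summary, outdir / "summary.json")
    return result, summary
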