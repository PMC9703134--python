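"""End-to-end orchestration: simulate/load -> filter -> PCA -> classify -> enrich.

A run is driven by one flat key/value config (YAML).  Every stage writes
its tables under ``out_dir`` and the run ends with ``report.json`` (class
counts, PC-covariate associations, enrichment folds, distance-test
p-values) plus ``manifest.json`` (config echo, seed, package version).
All randomness flows from the single master seed, split per stage, so a
fixed config reproduces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import associate_pcs, run_pca
from .drift import PassageDesign, PassageDriftModel
from .enrichment import (
    cdmr_concordance,
    distance_permutation_test,
    feasibility_background,
    min_distance_to_boundaries,
    annotate_probes,
    sampling_enrichment,
)
from .io import (
    read_bed,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
    check_sample_agreement,
)
from .qc import filter_probes
from .simulate import SimulationConfig, generate_cohort, generate_tracks

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("methdrift")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat configuration of a pipeline run (all keys optional in YAML)."""

    mode: str = "simulate"
    out_dir: str = "methdrift_out"
    seed: int = 0
    # simulation
    n_cpgs: int = 5_000
    n_samples: int = 80
    n_donors: int = 46
    passage_min: int = 1
    passage_max: int = 16
    fraction_hypo: float = 0.022
    fraction_hyper: float = 0.008
    fraction_hetero: float = 0.052
    delta_beta_effect: float = 0.25
    hetero_sd_slope: float = 0.10
    donor_sd: float = 0.15
    base_noise_sd: float = 0.2
    segment_fraction: float = 0.10
    missing_rate: float = 0.0
    n_features: int = 300
    genome_length: int = 20_000_000
    # real-data inputs
    beta_path: str | None = None
    sample_sheet_path: str | None = None
    probe_annotation_path: str | None = None
    regulatory_bed: str | None = None
    cdmr_bed: str | None = None
    orc_bed: str | None = None
    transcripts_bed: str | None = None
    detection_p_path: str | None = None
    # classification design
    low_passage_max: int = 4
    high_passage_max: int = 16
    alpha: float = 0.05
    delta_beta_threshold: float = 0.15
    delta_beta_mode: str = "group"
    donor_covariate: bool = False
    # decomposition / enrichment
    n_components: int = 10
    n_samplings: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"mode must be 'simulate' or 'real', got {self.mode!r}")
        if self.n_samplings < 1:
            raise ValueError("n_samplings must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be positive")
        if self.mode == "real":
            for key in ("beta_path", "sample_sheet_path", "probe_annotation_path"):
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"real-data mode requires {key}")
                if not Path(value).exists():
                    raise ValueError(f"{key} does not exist: {value}")

    def design(self) -> PassageDesign:
        return PassageDesign(
            low_passages=(self.passage_min, self.low_passage_max),
            high_passages=(self.low_passage_max + 1, self.high_passage_max),
            donor_covariate=self.donor_covariate,
            alpha=self.alpha,
            delta_beta_threshold=self.delta_beta_threshold,
            delta_beta_mode=self.delta_beta_mode,
        )

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            n_cpgs=self.n_cpgs,
            n_samples=self.n_samples,
            n_donors=self.n_donors,
            passage_range=(self.passage_min, self.passage_max),
            fraction_hypo=self.fraction_hypo,
            fraction_hyper=self.fraction_hyper,
            fraction_hetero=self.fraction_hetero,
            delta_beta_effect=self.delta_beta_effect,
            hetero_sd_slope=self.hetero_sd_slope,
            donor_sd=self.donor_sd,
            base_noise_sd=self.base_noise_sd,
            segment_fraction=self.segment_fraction,
            missing_rate=self.missing_rate,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and type-check a flat YAML config (empty file -> defaults)."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path_or_dict}: config must be a mapping of key: value")
    known = {f.name: f.type for f in fields(PipelineConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage_seeds(master: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master).spawn(n)]


def _baseline_beta(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Per-probe mean beta over the lowest-passage sample(s) in the cohort."""
    p_min = sheet["passage"].min()
    cols = sheet.loc[sheet["passage"] == p_min, "sample_id"]
    return beta[cols].mean(axis=1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "mode": config.mode}
    rng_enrich, rng_orc = None, None

    # ---- stage: inputs (simulate or load)
    stage = "inputs"
    try:
        if config.mode == "simulate":
            log.info("simulating cohort: %d CpGs, %d samples", config.n_cpgs, config.n_samples)
            beta, sheet, truth = generate_cohort(config.simulation())
            annotation, tracks = generate_tracks(
                n_features=config.n_features,
                genome_length=config.genome_length,
                ground_truth=truth,
                seed=config.seed + 1,
            )
            write_beta_matrix(beta, out / "beta.tsv")
            write_sample_sheet(sheet, out / "samples.tsv")
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            write_probe_annotation(annotation, out / "probe_annotation.tsv")
            (out / "tracks").mkdir(exist_ok=True)
            for name, track in tracks.items():
                track.to_bed(out / "tracks" / f"{name}.bed")
        else:
            beta = read_beta_matrix(config.beta_path)
            sheet = read_sample_sheet(config.sample_sheet_path)
            annotation = read_probe_annotation(config.probe_annotation_path)
            truth = None
            tracks = {}
            for key, name in (
                ("regulatory_bed", "regulatory"),
                ("cdmr_bed", "cdmr"),
                ("orc_bed", "orc"),
                ("transcripts_bed", "transcripts"),
            ):
                path = getattr(config, key)
                if path:
                    tracks[name] = read_bed(path, name=name)
        check_sample_agreement(beta, sheet)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: probe filtering
    stage = "filter"
    try:
        detection = (
            read_beta_matrix(config.detection_p_path) if config.detection_p_path else None
        )
        beta, filter_report = filter_probes(beta, annotation, detection_p=detection)
        filter_report.to_tsv(out / "filter_report.tsv")
        log.info("filtering: %d -> %d probes", filter_report.n_input, filter_report.n_retained)
        report["filter"] = {
            "n_input": filter_report.n_input,
            "n_retained": filter_report.n_retained,
            "removed": filter_report.removed,
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: variance decomposition
    stage = "pca"
    try:
        pca = run_pca(beta, n_components=config.n_components, impute_missing=True)
        assoc = associate_pcs(pca, sheet)
        pca.scree_frame().to_csv(out / "pca_scree.tsv", sep="\t", index=False)
        assoc.to_csv(out / "pca_associations.tsv", sep="\t", index=False, na_rep="NA")
        passage_rows = assoc[assoc["covariate"] == "passage"].sort_values("p")
        report["pca"] = {
            "variance_fraction_top": [round(float(v), 6) for v in pca.variance_fraction[: config.n_components]],
            "best_passage_pc": str(passage_rows.iloc[0]["pc"]) if len(passage_rows) else None,
            "best_passage_p": float(passage_rows.iloc[0]["p"]) if len(passage_rows) else None,
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: drift classification
    stage = "classify"
    try:
        model = PassageDriftModel(beta, sheet, design=config.design())
        results = model.fit()
        results.to_tsv(out / "classification.tsv")
        report["classification"] = {
            "counts": results.class_counts(),
            "proportions": {k: round(v, 6) for k, v in results.class_proportions().items()},
        }
        if truth is not None:
            report["classification"]["recovery"] = {
                k: (round(v, 6) if isinstance(v, float) else v)
                for k, v in results.score_against(truth).items()
            }
        log.info("classification: %s", results.class_counts())
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: genomic enrichment
    stage = "enrich"
    try:
        rng_enrich, rng_orc, *_ = _stage_seeds(config.seed)
        annotation = annotation[annotation["probe_id"].isin(beta.index)].reset_index(drop=True)
        baseline = _baseline_beta(beta, sheet)
        enrich_report: dict = {}
        if "regulatory" in tracks and len(tracks["regulatory"]):
            labels = annotate_probes(annotation, tracks["regulatory"])
            frames = []
            for cls, direction in (("hypo", "loss"), ("hyper", "gain"), ("hetero", None)):
                universe = results.frame.index
                if direction is None:
                    background = universe
                    n_excluded = 0
                else:
                    background, n_excluded = feasibility_background(
                        baseline, direction, config.delta_beta_threshold, universe=universe
                    )
                target = results.probes_in_class(cls).intersection(background)
                if len(target) == 0 or len(target) >= len(background):
                    continue
                res = sampling_enrichment(
                    target, background, labels,
                    n_samplings=config.n_samplings, seed=rng_enrich, keep_samples=False,
                )
                frame = res.frame.assign(**{"class": cls, "n_background_excluded": n_excluded})
                frames.append(frame)
                enrich_report[cls] = {
                    row["feature"]: round(float(row["fold"]), 4)
                    for _, row in res.frame.iterrows()
                    if row["fold"] == row["fold"]
                }
            if frames:
                pd.concat(frames).to_csv(out / "enrichment_regulatory.tsv", sep="\t", index=False, na_rep="NA")
        report["enrichment_folds"] = enrich_report

        if "cdmr" in tracks and len(tracks["cdmr"]):
            cdmr = cdmr_concordance(
                results, annotation, tracks["cdmr"], baseline,
                n_samplings=config.n_samplings, seed=rng_enrich,
            )
            cdmr.to_csv(out / "cdmr_concordance.tsv", sep="\t", index=False, na_rep="NA")

        if "orc" in tracks and len(tracks["orc"]):
            distances = min_distance_to_boundaries(annotation, tracks["orc"])
            dist_bg = distances.dropna().index
            dist_rows = []
            for cls in ("hypo", "hyper", "hetero"):
                target = results.probes_in_class(cls).intersection(dist_bg)
                if len(target) == 0 or len(target) >= len(dist_bg):
                    continue
                res = distance_permutation_test(
                    target, dist_bg, distances, n_samplings=config.n_samplings, seed=rng_orc
                )
                dist_rows.append(
                    {
                        "class": cls,
                        "observed_mean_bp": res.observed_mean,
                        "expected_mean_bp": float(np.mean(res.sampled_means)),
                        "direction": res.direction,
                        "p_farther": res.p_farther,
                        "p_nearer": res.p_nearer,
                    }
                )
            if dist_rows:
                dist_frame = pd.DataFrame(dist_rows)
                dist_frame.to_csv(out / "orc_distance.tsv", sep="\t", index=False)
                report["orc_distance"] = {
                    r["class"]: {"direction": r["direction"],
                                 "p": min(r["p_farther"], r["p_nearer"])}
                    for r in dist_rows
                }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: report
    stage = "report"
    try:
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = {
            "package": "methdrift",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report
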