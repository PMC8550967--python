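"""End-to-end orchestration: discovery fitting and cross-cohort application.

``run_discovery`` executes preprocessing -> association screen ->
PCA + CCA -> LDA biotyping on one cohort and returns (and optionally
persists) every fitted model.  ``run_apply`` projects a new cohort through
a persisted discovery fit without refitting anything, which is how
biotypes transfer to replication, follow-up or screening cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biotyping import BiotypeModel, assign_biotype, fit_lda_boundary
from .containers import RegionMatrix, validate_beta
from .correlates import (CorrelateModel, fit_cca, fit_pca, project_latent,
                         subject_feature_ratio_ok)
from .preprocessing import collapse_regions, filter_probes, recall_stability_filter
from .screen import ScreenResult, cv_frequency_ranking
from .synthetic import CLINICAL_FEATURES, CONFOUNDER_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DiscoveryResult", "run_discovery", "run_apply"]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the discovery pipeline.

    Defaults are the published operating points of the method: probe sd
    filter 0.05, mean bounds 0.01/0.99, region-collapse correlation 0.8,
    recall stability 0.65, clinical screen |r| > 0.2 with confounder
    exclusion at |r| <= 0.2, 5000 leave-five-out iterations keeping the
    top 100 regions, 4 gene PCs + 6 clinical PCs into a 2-pair CCA gated
    at Wilks p < 1e-4, and DMP calling at p < 0.01 with |delta beta| > 0.02.
    """

    sd_min: float = 0.05
    mean_lo: float = 0.01
    mean_hi: float = 0.99
    r_collapse: float = 0.8
    collapse_scope: str = "gene"
    r_recall: float = 0.65
    r_clin: float = 0.2
    r_conf: float = 0.2
    n_iter: int = 5000
    leave_out: int = 5
    top_k: int = 100
    n_pcs_gene: int = 4
    n_pcs_clin: int = 6
    n_cca_pairs: int = 2
    wilks_alpha: float = 1e-4
    dm_p_cut: float = 0.01
    dm_d_cut: float = 0.02
    feature_cols: list[str] = field(default_factory=lambda: list(CLINICAL_FEATURES))
    confounder_cols: list[str] = field(default_factory=lambda: list(CONFOUNDER_COLUMNS))
    orient_column: str = "caps_total"
    diagnosis_column: str = "diagnosis"
    control_label: str = "control"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class DiscoveryResult:
    regions: RegionMatrix
    screen: ScreenResult
    correlates: CorrelateModel
    biotype_model: BiotypeModel
    latent: pd.DataFrame
    assignments: pd.DataFrame
    manifest: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.regions.to_files(outdir / "regions.tsv", outdir / "membership.json")
        self.screen.to_tsv(outdir / "screen.tsv")
        self.correlates.to_json(outdir / "correlates.json")
        self.biotype_model.to_json(outdir / "biotype_model.json")
        self.latent.to_csv(outdir / "latent.csv")
        self.assignments.to_csv(outdir / "assignments.csv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def run_discovery(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    recall_beta: pd.DataFrame | None = None,
    stable_sample_ids: list[str] | None = None,
    outdir=None,
) -> DiscoveryResult:
    """Fit the full discovery pipeline on one cohort.

    Stages run in the fixed order probe filter -> region collapse ->
    (optional recall stability filter) -> resampled clinical screen ->
    block PCA -> CCA -> LDA biotyping.  Any stage failure raises with the
    stage name attached.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    stage = "validate inputs"
    try:
        validate_beta(beta)
        missing = beta.index.difference(clinical.index)
        if len(missing):
            raise ValueError(f"samples without clinical rows: {list(missing[:5])}")

        stage = "probe filter"
        t0 = time.perf_counter()
        filtered = filter_probes(beta, annot, sd_min=config.sd_min,
                                 mean_lo=config.mean_lo, mean_hi=config.mean_hi)
        timings[stage] = time.perf_counter() - t0

        stage = "region collapse"
        t0 = time.perf_counter()
        regions = collapse_regions(filtered, annot, r_thresh=config.r_collapse,
                                   scope=config.collapse_scope)
        timings[stage] = time.perf_counter() - t0

        if recall_beta is not None:
            stage = "recall stability filter"
            t0 = time.perf_counter()
            recall_filtered = recall_beta.loc[:, filtered.columns]
            recall_regions = RegionMatrix(
                values=pd.DataFrame(
                    {rid: recall_filtered[m].mean(axis=1)
                     for rid, m in regions.membership.items()},
                    index=recall_filtered.index),
                membership=regions.membership,
            )
            ids = (stable_sample_ids if stable_sample_ids is not None
                   else list(recall_beta.index.intersection(beta.index)))
            regions = recall_stability_filter(regions, recall_regions, ids,
                                              r_min=config.r_recall)
            timings[stage] = time.perf_counter() - t0

        stage = "clinical association screen"
        t0 = time.perf_counter()
        screen = cv_frequency_ranking(
            regions, clinical,
            feature_cols=config.feature_cols,
            confounder_cols=config.confounder_cols,
            n_iter=config.n_iter, leave_out=config.leave_out,
            top_k=config.top_k, seed=config.seed,
            r_clin=config.r_clin, r_conf=config.r_conf,
        )
        selected = regions.subset(screen.top_regions)
        if len(screen.top_regions) < config.top_k:
            logger.warning("screen yielded %d regions (< top_k=%d)",
                           len(screen.top_regions), config.top_k)
        timings[stage] = time.perf_counter() - t0

        stage = "PCA"
        t0 = time.perf_counter()
        subject_feature_ratio_ok(
            beta.shape[0], config.n_pcs_gene + config.n_pcs_clin)
        pca_gene = fit_pca(selected.values, n_pcs=config.n_pcs_gene,
                           standardize=False)
        pca_clin = fit_pca(clinical.loc[beta.index, config.feature_cols],
                           n_pcs=config.n_pcs_clin, standardize=True)
        timings[stage] = time.perf_counter() - t0

        stage = "CCA"
        t0 = time.perf_counter()
        orient = (clinical.loc[beta.index, config.orient_column].to_numpy()
                  if config.orient_column in clinical.columns else None)
        cca = fit_cca(
            pca_gene.transform(selected.values),
            pca_clin.transform(clinical.loc[beta.index, config.feature_cols]),
            n_pairs=config.n_cca_pairs, alpha=config.wilks_alpha, orient=orient,
        )
        correlates = CorrelateModel(pca_gene=pca_gene, pca_clinical=pca_clin,
                                    cca=cca)
        latent = project_latent(pca_gene, cca, selected)
        timings[stage] = time.perf_counter() - t0

        stage = "LDA biotyping"
        t0 = time.perf_counter()
        case_flags = (clinical.loc[beta.index, config.diagnosis_column]
                      != config.control_label)
        model = fit_lda_boundary(latent, case_flags, pca_gene, cca)
        assignments = assign_biotype(model, selected, case_flags=case_flags)
        assignments = assignments.join(latent)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"discovery stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_samples": int(beta.shape[0]),
        "n_probes_in": int(beta.shape[1]),
        "n_regions": int(regions.values.shape[1]),
        "n_selected": len(screen.top_regions),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    result = DiscoveryResult(
        regions=selected, screen=screen, correlates=correlates,
        biotype_model=model, latent=latent, assignments=assignments,
        manifest=manifest,
    )
    if outdir is not None:
        result.save(outdir)
        config.to_json(Path(outdir) / "config.json")
    return result


def region_values_from_membership(
    beta: pd.DataFrame,
    membership: dict[str, list[str]],
) -> RegionMatrix:
    """Recompute region means for a new cohort from a saved membership map."""
    missing: list[str] = []
    cols: dict[str, np.ndarray] = {}
    for rid, probes in membership.items():
        absent = [p for p in probes if p not in beta.columns]
        if absent:
            missing.extend(absent)
            continue
        cols[rid] = beta[probes].to_numpy(dtype=float).mean(axis=1)
    if missing:
        raise KeyError(f"probes required by the model are missing: "
                       f"{sorted(set(missing))[:10]}")
    return RegionMatrix(values=pd.DataFrame(cols, index=beta.index),
                        membership=dict(membership))


def run_apply(
    correlates: CorrelateModel,
    biotype_model: BiotypeModel,
    membership: dict[str, list[str]],
    beta: pd.DataFrame,
    case_flags: pd.Series | None = None,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Assign biotypes to a new cohort with a frozen discovery model."""
    if beta.shape[0] == 0:
        raise ValueError("empty cohort")
    validate_beta(beta)
    regions = region_values_from_membership(beta, membership)
    regions = regions.subset(biotype_model.region_ids)
    latent = project_latent(correlates.pca_gene, correlates.cca, regions)
    assignments = assign_biotype(biotype_model, regions, case_flags=case_flags,
                                 include_controls=include_controls)
    return assignments.join(latent)
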