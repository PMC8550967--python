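"""Seeded synthetic methylation cohorts with planted biotype structure.

The generator emulates the statistical features of an Illumina 450K-style
case/control study of a heterogeneous stress disorder:

* bounded beta values produced by a logit-normal noise model (values stay
  inside ``(0, 1)`` without probability mass at the bounds),
* probes grouped by gene, correlated within a gene through a shared
  per-(sample, gene) latent draw,
* covariate effects (age, blood cell composition, ancestry) injected into
  a subset of genes on the logit scale,
* two planted case biotypes with opposite-direction mean beta shifts on
  their signal genes: G2 is broadly control-distinct (its program is
  hypermethylated and severity-graded, and it also carries an
  opposite-direction shift on the G1 program), while G1 is control-like
  (flat hypomethylation of its own program, only a mild opposite trace on
  the G2 program).  Pooling all cases against controls therefore
  partially cancels the per-biotype differences -- the washout phenomenon
  that motivates biotype-resolved differential analysis,
* 34 clinical features organised around two latent factors, a
  "Psychological" severity factor and a "Physical and Dissociative"
  factor, with biotype membership shifting the psychological factor mean
  (control < G1 < G2) while the physical factor separates cases from
  controls but not the biotypes from each other,
* a physical-program gene set whose methylation tracks a biological
  correlate of the physical factor, supporting the second gene-clinical
  composite the way the severity-graded G2 program supports the first.

Everything is a deterministic function of the config and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_recall_pair",
    "PSYCHOLOGICAL_FEATURES",
    "PHYSICAL_DISSOCIATIVE_FEATURES",
    "CLINICAL_FEATURES",
    "CONFOUNDER_COLUMNS",
]

# The 34 symptom / function scores.  Names mirror the instruments commonly
# administered in combat-trauma cohorts (CAPS subscales, PCL, BDI, MSC,
# SCL-90 subscales, PSQI, PSS, SF-12 subscales, PDEQ, ETI) but the exact
# strings are only conventions; the pipeline treats them as opaque columns.
PSYCHOLOGICAL_FEATURES = [
    "caps_b", "caps_c", "caps_d", "pcl", "bdi", "msc", "psqi", "pss",
    "scl_somatization", "scl_obsessive", "scl_sensitivity", "scl_depression",
    "scl_anxiety", "scl_hostility", "scl_phobic", "scl_paranoid",
    "scl_psychoticism", "scl_gsi",
]
PHYSICAL_DISSOCIATIVE_FEATURES = [
    "pdeq", "sf12_pcs", "sf12_mcs", "sf12_pf", "sf12_rp", "sf12_bp",
    "sf12_gh", "sf12_vt", "sf12_sf", "sf12_re", "sf12_mh",
    "eti_general", "eti_physical", "eti_emotional", "eti_sexual", "whoqol",
]
CLINICAL_FEATURES = PSYCHOLOGICAL_FEATURES + PHYSICAL_DISSOCIATIVE_FEATURES

CELL_COLUMNS = ["neutrophils", "lymphocytes", "monocytes", "eosinophils", "basophils"]
CONFOUNDER_COLUMNS = (
    ["age", "bmi"]
    + ["ancestry_pc1", "ancestry_pc2", "ancestry_pc3"]
    + CELL_COLUMNS
    + ["smoking", "alcohol_audit", "n_deployments"]
)

# Mean blood cell fractions (neutrophils ... basophils) typical of adult
# whole blood; the Dirichlet concentration keeps per-sample spread at a
# few percentage points.
_CELL_MEANS = np.array([0.56, 0.33, 0.08, 0.025, 0.005])
_CELL_CONCENTRATION = 140.0


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic cohort.

    The defaults are desk-scale study conditions: 200 samples
    (100 control / 50 G1 / 50 G2), 1,500 genes giving roughly 4,000
    usable probes, and mean beta shifts of magnitude 0.06 on 40 signal
    genes per biotype in opposite directions.
    """

    n_control: int = 100
    n_g1: int = 50
    n_g2: int = 50
    n_genes: int = 1500
    probes_per_gene: tuple[int, int] = (1, 6)
    n_intergenic_probes: int = 150
    n_signal_genes_g1: int = 40
    n_signal_genes_g2: int = 40
    #: mean beta shift of G1 samples on G1 signal genes (typically negative)
    delta_g1: float = -0.06
    #: mean beta shift of G2 samples on G2 signal genes (typically positive)
    delta_g2: float = 0.06
    #: fraction of the G1 program's shift applied, with opposite sign, to
    #: G2 samples (the control-distinct biotype is broadly shifted, so its
    #: opposite-direction involvement in the other program is strong);
    #: makes the pooled case group partially cancel on G1 signal genes.
    cross_coupling_g2: float = 0.5
    #: fraction of the G2 program's shift applied, with opposite sign, to
    #: G1 samples; kept small so the control-like biotype stays close to
    #: controls on the clinically selected (G2-program) regions.
    cross_coupling_g1: float = 0.2
    #: how strongly the per-sample shift scales with the individual's
    #: latent severity factor (0 = uniform shift within a biotype).
    severity_coupling: float = 0.25
    #: genes whose methylation tracks the physical-dissociative factor
    #: (the DNAm correlate of the second clinical composite), drawn from
    #: the non-signal genes.
    n_phys_factor_genes: int = 60
    #: logit-scale methylation change per standard deviation of the
    #: physical program's biological factor on those genes.
    phys_methylation_loading: float = 0.25
    #: correlation between the physical program's biological factor and the
    #: reported physical-dissociative factor (methylation tracks biology,
    #: which only partially aligns with self-report).
    phys_methylation_fidelity: float = 0.55
    #: total probe-level noise standard deviation on the logit scale;
    #: 0.25 corresponds to a beta-scale sd of roughly 0.05-0.06 for
    #: mid-range probes, typical of variable 450K CpGs.
    probe_noise_sd: float = 0.25
    #: target Pearson correlation between probes of the same gene.
    within_gene_corr: float = 0.9
    #: global multiplier on the clinical factor loadings.
    clinical_loading: float = 1.0
    #: residual noise sd of each clinical feature around its factor model
    #: (instrument noise relative to unit within-group factor sd).
    feature_noise_sd: float = 0.6
    #: logit-scale effect (per covariate standard deviation) of age, cell
    #: composition, and ancestry on their affected gene subsets.
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.15, "cells": 0.4, "ancestry": 0.2}
    )
    #: latent "Psychological" factor means for (control, G1, G2).  Large
    #: case/control separation mirrors the by-design severity gap between
    #: diagnosed cases and screened controls.
    psych_means: tuple[float, float, float] = (0.0, 3.0, 4.5)
    #: latent "Physical and Dissociative" factor means for (control, G1, G2);
    #: cases report more physical burden than controls but the biotypes are
    #: mixed in this dimension (it separates cases from controls, not G1
    #: from G2).
    phys_means: tuple[float, float, float] = (0.0, 0.5, 0.5)
    #: target test-retest correlation for stable regions in a recall pair.
    recall_corr: float = 0.95
    #: fraction of genes whose recall values are uncorrelated with the
    #: original draw (assay-unstable regions).
    unstable_region_fraction: float = 0.0
    #: number of individuals with a recall measurement.
    n_recall: int = 41
    #: seed of the shared population structure (gene/probe layout, baselines,
    #: disease programs); cohorts with equal structure_seed but different
    #: `seed` are independent samples from the same population.
    structure_seed: int = 0
    seed: int = 0

    # ---- derived helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_g1 + self.n_g2

    def validate(self) -> None:
        counts = (self.n_control, self.n_g1, self.n_g2, self.n_genes,
                  self.n_intergenic_probes, self.n_signal_genes_g1,
                  self.n_signal_genes_g2)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_signal_genes_g1 + self.n_signal_genes_g2 > self.n_genes:
            raise ValueError(
                "n_genes must be at least the total number of signal genes"
            )
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene must satisfy 1 <= min <= max")
        if not 0.0 <= self.within_gene_corr <= 1.0:
            raise ValueError("within_gene_corr must lie in [0, 1]")
        if not 0.0 <= self.recall_corr <= 1.0:
            raise ValueError("recall_corr must lie in [0, 1]")
        if not 0.0 <= self.unstable_region_fraction <= 1.0:
            raise ValueError("unstable_region_fraction must lie in [0, 1]")
        # Signal baselines are drawn from [0.35, 0.65]; the worst-case
        # expected beta after the shift (including severity scaling at
        # 3 sd) must stay inside (0, 1) by more than the clipping margin.
        for delta in (self.delta_g1, self.delta_g2):
            worst = abs(delta) * (1.0 + 3.0 * abs(self.severity_coupling))
            if 0.65 + worst >= 0.999 or 0.35 - worst <= 0.001:
                raise ValueError(
                    f"shift {delta} pushes expected betas outside (0, 1) "
                    "beyond the clipping tolerance"
                )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("probes_per_gene", "psych_means", "phys_means"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for recovery tests."""

    #: per-sample label: "control", "G1" or "G2"
    labels: pd.Series
    signal_genes_g1: list[str]
    signal_genes_g2: list[str]
    #: expected sign of the case-minus-control beta difference per signal
    #: gene in the G1-vs-control contrast (and likewise for G2).
    direction_g1: dict[str, int]
    direction_g2: dict[str, int]
    #: per-sample latent factor scores (psychological, physical_dissociative)
    factors: pd.DataFrame
    #: genes carrying planted covariate effects
    confounded_genes: dict[str, list[str]]
    #: genes whose methylation tracks the physical-dissociative factor
    phys_factor_genes: list[str] = field(default_factory=list)

    @property
    def case_mask(self) -> pd.Series:
        return self.labels != "control"

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "signal_genes_g1": self.signal_genes_g1,
            "signal_genes_g2": self.signal_genes_g2,
            "direction_g1": self.direction_g1,
            "direction_g2": self.direction_g2,
            "factors": self.factors.to_dict(orient="index"),
            "confounded_genes": self.confounded_genes,
            "phys_factor_genes": self.phys_factor_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        factors = pd.DataFrame.from_dict(payload["factors"], orient="index")
        order = [c for c in ("psychological", "physical_dissociative")
                 if c in factors.columns]
        factors = factors[order + [c for c in factors.columns if c not in order]]
        labels = pd.Series(payload["labels"], name="label")
        labels = labels.loc[factors.index]
        return cls(
            labels=labels,
            signal_genes_g1=payload["signal_genes_g1"],
            signal_genes_g2=payload["signal_genes_g2"],
            direction_g1={k: int(v) for k, v in payload["direction_g1"].items()},
            direction_g2={k: int(v) for k, v in payload["direction_g2"].items()},
            factors=factors,
            confounded_genes=payload["confounded_genes"],
            phys_factor_genes=payload.get("phys_factor_genes", []),
        )


# ---------------------------------------------------------------------------
# internal simulation machinery


class _CohortDraw:
    """All random components of one cohort, kept separately so that a
    recall measurement can re-mix the noise at a chosen test-retest
    correlation while holding the fixed effects (baselines, covariates,
    biotype shifts) constant."""

    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.config = config
        # Two independent streams: the *structure* stream fixes the shared
        # biology (gene/probe layout, baseline methylation, which genes
        # carry disease, physical-program and covariate effects) and the
        # *cohort* stream draws the individuals.  Cohorts with different
        # `seed` but equal `structure_seed` are independent samples from
        # the same population, which is what cross-cohort model transfer
        # assumes.
        structure_root = np.random.SeedSequence(config.structure_seed)
        (ss_structure,) = structure_root.spawn(1)
        cohort_root = np.random.SeedSequence(config.seed)
        (ss_cov, ss_clinical, ss_noise,
         self.ss_recall) = cohort_root.spawn(4)
        rng_s = np.random.default_rng(ss_structure)
        rng_c = np.random.default_rng(ss_cov)
        rng_f = np.random.default_rng(ss_clinical)
        rng_n = np.random.default_rng(ss_noise)
        cfg = config
        n = cfg.n_samples

        # --- samples and labels
        self.sample_ids = [f"S{i + 1:04d}" for i in range(n)]
        labels = (["control"] * cfg.n_control + ["G1"] * cfg.n_g1
                  + ["G2"] * cfg.n_g2)
        self.labels = pd.Series(labels, index=self.sample_ids, name="label")

        # --- gene / probe layout
        self.genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
        lo, hi = cfg.probes_per_gene
        n_probes_per_gene = rng_s.integers(lo, hi + 1, size=cfg.n_genes)
        gene_of_probe: list[str] = []
        for g, k in zip(self.genes, n_probes_per_gene):
            gene_of_probe.extend([g] * int(k))
        gene_of_probe.extend([""] * cfg.n_intergenic_probes)
        self.gene_of_probe = np.array(gene_of_probe)
        n_probes = len(gene_of_probe)
        self.probe_ids = [f"cg{i + 1:07d}" for i in range(n_probes)]
        region_class = np.where(
            self.gene_of_probe == "", "intergenic",
            np.where(rng_s.random(n_probes) < 0.3, "promoter", "body"),
        )
        self.annotation = pd.DataFrame(
            {"gene": self.gene_of_probe, "region_class": region_class},
            index=pd.Index(self.probe_ids, name="probe_id"),
        )

        # --- signal gene sets (disjoint from each other and from nulls)
        perm = rng_s.permutation(cfg.n_genes)
        sig1_idx = perm[: cfg.n_signal_genes_g1]
        sig2_idx = perm[cfg.n_signal_genes_g1:
                        cfg.n_signal_genes_g1 + cfg.n_signal_genes_g2]
        self.signal_genes_g1 = sorted(self.genes[i] for i in sig1_idx)
        self.signal_genes_g2 = sorted(self.genes[i] for i in sig2_idx)
        n_sig = cfg.n_signal_genes_g1 + cfg.n_signal_genes_g2
        n_phys = min(cfg.n_phys_factor_genes, cfg.n_genes - n_sig)
        phys_idx = perm[n_sig: n_sig + n_phys]
        self.phys_factor_genes = sorted(self.genes[i] for i in phys_idx)
        signal_set = set(self.signal_genes_g1) | set(self.signal_genes_g2)
        clinical_set = signal_set | set(self.phys_factor_genes)

        # --- baseline methylation: clinically coupled genes mid-range
        # (where variable, clinically relevant CpGs live), null genes across
        # a wider span so the extreme-mean / low-sd probe filters have work
        # to do.
        base_mean = np.empty(cfg.n_genes)
        for i, g in enumerate(self.genes):
            if g in clinical_set:
                base_mean[i] = rng_s.uniform(0.35, 0.65)
            else:
                base_mean[i] = rng_s.uniform(0.10, 0.90)
        gene_index = {g: i for i, g in enumerate(self.genes)}
        probe_base_logit = np.empty(n_probes)
        for p in range(n_probes):
            g = self.gene_of_probe[p]
            if g == "":
                probe_base_logit[p] = logit(rng_s.uniform(0.10, 0.90))
            else:
                probe_base_logit[p] = (logit(base_mean[gene_index[g]])
                                       + rng_s.normal(0.0, 0.3))
        self.probe_base_logit = probe_base_logit

        # --- covariates
        age = rng_c.normal(33.0, 7.5, size=n).clip(19, 65)
        bmi = rng_c.normal(29.0, 5.0, size=n).clip(17, 50)
        cells = rng_c.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, size=n)
        ancestry = rng_c.normal(0.0, 1.0, size=(n, 3))
        smoking = (rng_c.random(n) < 0.2).astype(float)
        alcohol = rng_c.gamma(1.5, 2.0, size=n)
        deployments = 1.0 + rng_c.poisson(0.8, size=n)
        self.covariates = pd.DataFrame(
            {"age": age, "bmi": bmi,
             **{c: cells[:, j] for j, c in enumerate(CELL_COLUMNS)},
             "ancestry_pc1": ancestry[:, 0], "ancestry_pc2": ancestry[:, 1],
             "ancestry_pc3": ancestry[:, 2], "smoking": smoking,
             "alcohol_audit": alcohol, "n_deployments": deployments},
            index=self.sample_ids,
        )

        # genes carrying covariate effects are drawn from the null genes so
        # that confounder screening and signal screening are separable.
        null_genes = [g for g in self.genes if g not in clinical_set]
        null_perm = rng_s.permutation(len(null_genes))
        n_age = int(round(0.08 * cfg.n_genes))
        n_cell = int(round(0.10 * cfg.n_genes))
        n_anc = int(round(0.05 * cfg.n_genes))
        total = n_age + n_cell + n_anc
        if total > len(null_genes):
            scale = len(null_genes) / max(1, total)
            n_age = int(n_age * scale)
            n_cell = int(n_cell * scale)
            n_anc = int(n_anc * scale)
        take = iter(null_perm)
        age_genes = sorted(null_genes[next(take)] for _ in range(n_age))
        cell_genes = sorted(null_genes[next(take)] for _ in range(n_cell))
        anc_genes = sorted(null_genes[next(take)] for _ in range(n_anc))
        self.confounded_genes = {
            "age": age_genes, "cells": cell_genes, "ancestry": anc_genes,
        }

        def _z(x):
            s = np.std(x)
            return (x - np.mean(x)) / s if s > 0 else np.zeros_like(x)

        eff = cfg.covariate_effects
        cov_logit = np.zeros((n, n_probes))
        drivers = {
            "age": _z(age),
            "cells": _z(cells[:, 0]),          # neutrophil fraction
            "ancestry": _z(ancestry[:, 0]),
        }
        for key, genes_k in self.confounded_genes.items():
            coef = float(eff.get(key, 0.0))
            if coef == 0.0 or not genes_k:
                continue
            genes_k = set(genes_k)
            mask = np.array([g in genes_k for g in self.gene_of_probe])
            cov_logit[:, mask] += coef * drivers[key][:, None]
        self.cov_logit = cov_logit

        # --- latent clinical factors; biotype shifts the means.
        label_idx = self.labels.map({"control": 0, "G1": 1, "G2": 2}).to_numpy()
        psych = (np.asarray(cfg.psych_means)[label_idx]
                 + rng_f.normal(0.0, 1.0, size=n))
        phys = (np.asarray(cfg.phys_means)[label_idx]
                + rng_f.normal(0.0, 1.0, size=n))
        self.factors = pd.DataFrame(
            {"psychological": psych, "physical_dissociative": phys},
            index=self.sample_ids,
        )

        # methylation correlate of the physical-dissociative factor: a gene
        # program whose logit methylation tracks the factor score, giving
        # the second gene-clinical composite something genuine to find.
        if self.phys_factor_genes and cfg.phys_methylation_loading != 0.0:
            phys_set = set(self.phys_factor_genes)
            mask = np.array([g in phys_set for g in self.gene_of_probe])
            alpha = cfg.phys_methylation_fidelity
            bio = (alpha * (phys - phys.mean())
                   + np.sqrt(1.0 - alpha**2) * rng_f.normal(0.0, 1.0, size=n))
            self.cov_logit[:, mask] += cfg.phys_methylation_loading * bio[:, None]

        # --- clinical features: linear loadings on the two factors + noise.
        n_feat = len(CLINICAL_FEATURES)
        primary = cfg.clinical_loading * rng_f.uniform(0.6, 0.95, size=n_feat)
        cross = rng_f.uniform(0.0, 0.15, size=n_feat)
        # SF-12 style quality-of-life scores run opposite to symptom load.
        sign = np.array([-1.0 if f.startswith("sf12") or f == "whoqol" else 1.0
                         for f in CLINICAL_FEATURES])
        feat = np.empty((n, n_feat))
        for j, name in enumerate(CLINICAL_FEATURES):
            factor = psych if name in PSYCHOLOGICAL_FEATURES else phys
            other = phys if name in PSYCHOLOGICAL_FEATURES else psych
            feat[:, j] = sign[j] * (primary[j] * factor + cross[j] * other
                                    + rng_f.normal(0.0, cfg.feature_noise_sd, size=n))
        self.clinical_features = pd.DataFrame(
            feat, index=self.sample_ids, columns=CLINICAL_FEATURES
        )

        # --- biotype shifts on the beta scale.  Only the control-distinct
        # biotype's own program is severity-graded (dose-response with the
        # psychological factor); the control-like biotype's program and the
        # cross-biotype shifts are categorical.  This is what couples the
        # selected methylome to the clinical features while keeping the
        # control-like biotype clinically dark, mirroring the asymmetry the
        # method exploits.
        g1_mask = (self.labels == "G1").to_numpy()
        g2_mask = (self.labels == "G2").to_numpy()
        z2 = psych - cfg.psych_means[2]   # centred severity within G2
        sc = cfg.severity_coupling
        shift = np.zeros((n, n_probes))
        sig1_set = set(self.signal_genes_g1)
        sig2_set = set(self.signal_genes_g2)
        probe_sig1 = np.array([g in sig1_set for g in self.gene_of_probe])
        probe_sig2 = np.array([g in sig2_set for g in self.gene_of_probe])
        dose_g2 = np.where(g2_mask, 1.0 + sc * z2, 0.0)
        # own-biotype shifts
        shift[:, probe_sig1] += cfg.delta_g1 * g1_mask[:, None]
        shift[:, probe_sig2] += cfg.delta_g2 * dose_g2[:, None]
        # cross-biotype (opposite-direction) shifts
        shift[:, probe_sig1] += -cfg.cross_coupling_g2 * cfg.delta_g1 * g2_mask[:, None]
        shift[:, probe_sig2] += -cfg.cross_coupling_g1 * cfg.delta_g2 * g1_mask[:, None]
        self.shift = shift

        self.direction_g1 = {
            **{g: int(np.sign(cfg.delta_g1)) for g in self.signal_genes_g1},
            **{g: int(np.sign(-cfg.cross_coupling_g1 * cfg.delta_g2))
               for g in self.signal_genes_g2},
        }
        self.direction_g2 = {
            **{g: int(np.sign(cfg.delta_g2)) for g in self.signal_genes_g2},
            **{g: int(np.sign(-cfg.cross_coupling_g2 * cfg.delta_g1))
               for g in self.signal_genes_g1},
        }

        # --- probe noise split into a shared per-gene draw and independent
        # probe-level residual so that within-gene Pearson correlation on
        # the logit scale equals within_gene_corr.
        self.sd_gene = cfg.probe_noise_sd * np.sqrt(cfg.within_gene_corr)
        self.sd_probe = cfg.probe_noise_sd * np.sqrt(1.0 - cfg.within_gene_corr)
        self.gene_col_of_probe = np.array(
            [gene_index.get(g, -1) for g in self.gene_of_probe]
        )
        self._rng_noise = rng_n
        self.noise_original = self._draw_noise(rng_n)

    def _draw_noise(self, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        n = cfg.n_samples
        shared = rng.normal(0.0, 1.0, size=(n, cfg.n_genes))
        eps = rng.normal(0.0, 1.0, size=(n, len(self.probe_ids)))
        noise = self.sd_probe * eps
        genic = self.gene_col_of_probe >= 0
        noise[:, genic] += self.sd_gene * shared[:, self.gene_col_of_probe[genic]]
        # intergenic probes: all noise is probe-level at full sd
        noise[:, ~genic] = cfg.probe_noise_sd * eps[:, ~genic]
        return noise

    def beta_from_noise(self, noise: np.ndarray) -> pd.DataFrame:
        vals = expit(self.probe_base_logit[None, :] + self.cov_logit + noise)
        vals = np.clip(vals + self.shift, 0.001, 0.999)
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.probe_ids)


def _clinical_table(draw: _CohortDraw) -> pd.DataFrame:
    """Assemble features + covariates + diagnosis + severity totals."""
    cfg = draw.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[-1])
    psych = draw.factors["psychological"].to_numpy()
    caps_total = np.clip(4.0 + 16.0 * psych + rng.normal(0, 3, cfg.n_samples), 0, 136)
    pcl_total = np.clip(26.0 + 8.0 * psych + rng.normal(0, 3, cfg.n_samples), 17, 80)
    table = pd.concat([draw.clinical_features, draw.covariates], axis=1)
    table["diagnosis"] = np.where(draw.labels == "control", "control", "PTSD")
    table["caps_total"] = caps_total
    table["pcl_total"] = pcl_total
    table.index.name = "sample_id"
    return table


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort.

    Returns
    -------
    beta
        samples x probes beta matrix, values clipped to ``[0.001, 0.999]``.
    annotation
        probe annotation (gene symbol, region class).
    clinical
        clinical table: 34 features, covariates, diagnosis label and
        severity totals.
    truth
        planted labels, signal genes, expected contrast directions and
        latent factor scores.
    """
    draw = _CohortDraw(config)
    beta = draw.beta_from_noise(draw.noise_original)
    clinical = _clinical_table(draw)
    truth = GroundTruth(
        labels=draw.labels,
        signal_genes_g1=draw.signal_genes_g1,
        signal_genes_g2=draw.signal_genes_g2,
        direction_g1=draw.direction_g1,
        direction_g2=draw.direction_g2,
        factors=draw.factors,
        confounded_genes=draw.confounded_genes,
        phys_factor_genes=draw.phys_factor_genes,
    )
    return beta, draw.annotation, clinical, truth


def generate_recall_pair(
    config: SyntheticConfig,
    recall_noise_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Simulate an original beta matrix plus a recall (retest) matrix.

    The recall matrix covers ``config.n_recall`` individuals.  For stable
    genes the probe noise at recall is an AR(1)-style mix of the original
    noise and a fresh draw, so original-vs-recall correlation per region is
    close to ``config.recall_corr`` (slightly higher for regions carrying
    group structure, which is preserved between visits).  Genes selected as
    unstable (``unstable_region_fraction``) behave like junk measurements:
    their recall values are fresh logit-normal draws around the probe
    baseline carrying none of the planted biology, so their test-retest
    correlation is ~0.  ``recall_noise_sd = 0`` with ``recall_corr = 1``
    reproduces the original matrix exactly.

    Returns ``(original, recall, mapping)`` where mapping covers exactly
    the intersection of the two matrices' sample ids.
    """
    draw = _CohortDraw(config)
    cfg = config
    original = draw.beta_from_noise(draw.noise_original)

    rng = np.random.default_rng(draw.ss_recall)
    n_recall = min(cfg.n_recall, cfg.n_samples)
    recall_samples = sorted(
        rng.choice(cfg.n_samples, size=n_recall, replace=False).tolist()
    )
    n_unstable = int(round(cfg.unstable_region_fraction * cfg.n_genes))
    unstable_idx = set(
        rng.choice(cfg.n_genes, size=n_unstable, replace=False).tolist()
    )
    rho = np.array(
        [0.0 if draw.gene_col_of_probe[p] in unstable_idx else cfg.recall_corr
         for p in range(len(draw.probe_ids))]
    )
    fresh = draw._draw_noise(rng)
    if recall_noise_sd is not None and cfg.probe_noise_sd > 0:
        fresh = fresh * (recall_noise_sd / cfg.probe_noise_sd)
        if recall_noise_sd == 0:
            fresh = np.zeros_like(fresh)
    mixed = rho[None, :] * draw.noise_original + np.sqrt(1.0 - rho**2)[None, :] * fresh
    recall_full = draw.beta_from_noise(mixed)
    if unstable_idx:
        # unstable probes measure nothing reproducible: baseline plus fresh
        # noise, without covariate effects or planted shifts
        bad = np.array([c in unstable_idx for c in draw.gene_col_of_probe])
        junk = expit(draw.probe_base_logit[None, bad] + fresh[:, bad])
        recall_full.loc[:, recall_full.columns[bad]] = np.clip(junk, 0.001, 0.999)
    recall = recall_full.iloc[recall_samples]
    mapping = {sid: sid for sid in recall.index}
    return original, recall, mapping
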