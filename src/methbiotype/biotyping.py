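"""Biotype assignment from latent DNAm scores.

A two-class LDA separates the control cluster from the case cluster in
the latent (x, y) plane.  The discriminant is oriented so the control
mean scores positive; cases on the far (negative) side of the boundary
form the control-distinct biotype G2, cases on the control side form the
control-like biotype G1 (score of exactly 0 falls to G1).

Because the latent coordinates are themselves a linear function of the
gene-region vector, the whole chain collapses to a closed-form weight per
region:

    score(sample) = sum_i w_i * (region_i - trainmean_i) + b
    w = PCA_gene_loadings @ CCA_gene_coefficients @ lda_normal

which makes the biotype score of a new sample a single weighted sum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import RegionMatrix
from .correlates import CcaModel, PcaModel

logger = logging.getLogger(__name__)

__all__ = [
    "BiotypeModel", "fit_lda_boundary", "biotype_score", "assign_biotype",
    "compare_clinical_by_biotype", "ternary_coordinates",
]


@dataclass
class BiotypeModel:
    """LDA boundary in latent space plus its region-space closed form."""

    normal: np.ndarray                 # unit-norm coefficients on (x, y)
    #: latent-space constant: score = normal . (x, y) + latent_intercept
    latent_intercept: float
    region_ids: list[str]
    region_means: np.ndarray           # training means used for centering
    weights: np.ndarray                # per-region weights w_i
    #: region-space constant: score = (regions - region_means) @ weights
    #: + intercept.  Algebraically identical to the latent-space form.
    intercept: float = 0.0
    flip_sign: bool = False

    def latent_score(self, latent: pd.DataFrame) -> pd.Series:
        s = (latent[["x", "y"]].to_numpy(dtype=float) @ self.normal
             + self.latent_intercept)
        if self.flip_sign:
            s = -s
        return pd.Series(s, index=latent.index, name="biotype_score")

    def label_from_score(self, score: pd.Series) -> pd.Series:
        # "< 0 belongs to G2, otherwise G1" -- ties go to G1.
        return pd.Series(np.where(score < 0, "G2", "G1"),
                         index=score.index, name="biotype")

    def weights_table(self) -> pd.DataFrame:
        return pd.DataFrame({"weight": self.weights},
                            index=pd.Index(self.region_ids, name="region"))

    def to_json(self, path) -> None:
        payload = {
            "normal": self.normal.tolist(),
            "latent_intercept": self.latent_intercept,
            "intercept": self.intercept,
            "region_ids": self.region_ids,
            "region_means": self.region_means.tolist(),
            "weights": self.weights.tolist(),
            "flip_sign": self.flip_sign,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BiotypeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            normal=np.asarray(d["normal"], dtype=float),
            latent_intercept=float(d["latent_intercept"]),
            intercept=float(d["intercept"]),
            region_ids=list(d["region_ids"]),
            region_means=np.asarray(d["region_means"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            flip_sign=bool(d["flip_sign"]),
        )


def fit_lda_boundary(
    latent: pd.DataFrame,
    case_flags: pd.Series,
    pca_gene: PcaModel,
    cca: CcaModel,
    ridge: float = 0.0,
) -> BiotypeModel:
    """Fit the two-class LDA boundary and derive per-region weights.

    Equal priors are assumed, so the boundary passes through the midpoint
    of the class means along the discriminant.  The normal vector is
    ``pooled_covariance^-1 (mu_control - mu_case)`` scaled to unit norm,
    which makes the control mean score positive and the control-distinct
    case cluster score negative.
    """
    flags = case_flags.loc[latent.index].astype(bool)
    z = latent[["x", "y"]].to_numpy(dtype=float)
    cases = z[flags.to_numpy()]
    ctrls = z[~flags.to_numpy()]
    if len(cases) < 2 or len(ctrls) < 2:
        raise ValueError("need at least 2 samples in each class")

    mu1 = cases.mean(axis=0)
    mu0 = ctrls.mean(axis=0)
    s1 = np.cov(cases, rowvar=False) * (len(cases) - 1)
    s0 = np.cov(ctrls, rowvar=False) * (len(ctrls) - 1)
    pooled = (s1 + s0) / (len(cases) + len(ctrls) - 2)
    if ridge > 0:
        pooled = pooled + ridge * np.eye(2)
    try:
        normal = np.linalg.solve(pooled, mu0 - mu1)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(pooled) / 2
        logger.warning("singular pooled covariance; ridge-regularizing with %g", eps)
        normal = np.linalg.solve(pooled + eps * np.eye(2), mu0 - mu1)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ValueError("degenerate LDA: identical class means")
    normal = normal / norm
    latent_intercept = -float(normal @ (mu0 + mu1) / 2.0)

    # closed-form region weights: PCA loadings -> CCA gene coefficients ->
    # LDA normal, all linear maps.
    weights = pca_gene.components_ @ cca.x_coef[:, :2] @ normal
    # The CCA centering of PC scores folds into the region-space constant
    # (PC scores of the training data have mean zero by construction, so
    # the correction is ~0 on the discovery fit but kept for exactness).
    intercept = latent_intercept - float(cca.x_mean @ (cca.x_coef[:, :2] @ normal))
    return BiotypeModel(
        normal=normal,
        latent_intercept=latent_intercept,
        intercept=intercept,
        region_ids=list(pca_gene.feature_names),
        region_means=pca_gene.mean_.copy(),
        weights=weights,
    )


def biotype_score(
    model: BiotypeModel,
    regions: RegionMatrix | pd.DataFrame,
) -> pd.Series:
    """Closed-form biotype score: weighted sum of centered region values."""
    values = regions.values if isinstance(regions, RegionMatrix) else regions
    missing = [r for r in model.region_ids if r not in values.columns]
    if missing:
        raise KeyError(f"regions missing from input: {missing[:10]}")
    x = values[model.region_ids].to_numpy(dtype=float) - model.region_means
    s = x @ model.weights + model.intercept
    if model.flip_sign:
        s = -s
    return pd.Series(s, index=values.index, name="biotype_score")


def assign_biotype(
    model: BiotypeModel,
    regions: RegionMatrix | pd.DataFrame,
    case_flags: pd.Series | None = None,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Score every sample and label the cases G1/G2.

    Controls get a score but no label unless ``include_controls`` is set
    (biotyping diagnosis-negative individuals is meaningful when studying
    susceptibility).
    """
    values = regions.values if isinstance(regions, RegionMatrix) else regions
    score = biotype_score(model, values)
    labels = model.label_from_score(score)
    if case_flags is not None and not include_controls:
        flags = case_flags.loc[values.index].astype(bool)
        labels = labels.where(flags, other="")
    out = pd.DataFrame({"biotype_score": score, "biotype": labels})
    return out


def compare_clinical_by_biotype(
    assignment: pd.DataFrame,
    clinical: pd.DataFrame,
    features: list[str],
    covariates: tuple[str, ...] = ("bmi", "age"),
) -> pd.DataFrame:
    """Per-feature linear model ``feature ~ biotype + covariates``.

    The biotype coefficient is the adjusted G2-minus-G1 difference;
    p-values are two-sided and corrected across features by
    Benjamini-Hochberg.  Constant features are reported with effect 0 and
    p = 1, flagged ``degenerate``.
    """
    labeled = assignment[assignment["biotype"].isin(["G1", "G2"])]
    if (labeled["biotype"] == "G1").sum() < 3 or (labeled["biotype"] == "G2").sum() < 3:
        raise ValueError("need at least 3 samples per biotype")
    clin = clinical.loc[labeled.index]
    indicator = (labeled["biotype"] == "G2").astype(float).to_numpy()

    cov_cols = []
    x_parts = [np.ones_like(indicator), indicator]
    for c in covariates:
        col = clin[c].to_numpy(dtype=float)
        trial = np.column_stack(x_parts + [col])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            logger.warning("covariate %s is collinear; dropped", c)
            continue
        x_parts.append(col)
        cov_cols.append(c)
    design = np.column_stack(x_parts)
    df_resid = design.shape[0] - design.shape[1]

    xtx_inv = np.linalg.inv(design.T @ design)
    h = xtx_inv @ design.T
    rows = []
    for f in features:
        y = clin[f].to_numpy(dtype=float)
        if np.std(y) == 0:
            rows.append({"feature": f, "effect": 0.0, "p_value": 1.0,
                         "degenerate": True})
            continue
        coef = h @ y
        resid = y - design @ coef
        sigma2 = float(resid @ resid) / df_resid
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        tval = coef[1] / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(tval), df_resid) if se > 0 else 1.0
        rows.append({"feature": f, "effect": float(coef[1]),
                     "p_value": float(p), "degenerate": False})
    out = pd.DataFrame(rows).set_index("feature")
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def ternary_coordinates(
    clinical: pd.DataFrame,
    features: list[str],
    caps_b: str = "caps_b",
    caps_c: str = "caps_c",
    caps_d: str = "caps_d",
) -> pd.DataFrame:
    """Relative similarity of each feature to the three core subcategories.

    coordinate_k = |r(feature, subcategory_k)| / sum_k |r(...)|; rows sum
    to 1.  Features uncorrelated with all three subcategories get the
    uniform point (1/3, 1/3, 1/3) and are flagged.
    """
    for c in (caps_b, caps_c, caps_d):
        if c not in clinical.columns:
            raise KeyError(f"subcategory column {c!r} not present")
    subs = clinical[[caps_b, caps_c, caps_d]].to_numpy(dtype=float)
    rows = []
    for f in features:
        y = clinical[f].to_numpy(dtype=float)
        rs = []
        for k in range(3):
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(y, subs[:, k])[0, 1]
            rs.append(abs(r) if np.isfinite(r) else 0.0)
        total = sum(rs)
        if total == 0:
            logger.warning("feature %s uncorrelated with all subcategories", f)
            coords = [1 / 3, 1 / 3, 1 / 3]
            flagged = True
        else:
            coords = [r / total for r in rs]
            flagged = False
        rows.append({"feature": f, caps_b: coords[0], caps_c: coords[1],
                     caps_d: coords[2], "degenerate": flagged})
    return pd.DataFrame(rows).set_index("feature")
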