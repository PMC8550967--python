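"""Gene-clinical composite construction: block PCA followed by CCA.

Each block (selected gene regions; clinical features) is reduced by PCA
to keep the subject-to-feature ratio healthy, then canonical correlation
analysis on the PC scores extracts orthogonal gene-clinical composite
pairs.  The first two composites define the per-sample latent coordinates
used downstream: ``x`` (the DNAm "Psychological" score) and ``y``
(the DNAm "Physical and Dissociative" score).

Conventions:

* the gene-region block is centered but not scaled (shared beta units);
  the clinical block is typically z-scored (heterogeneous instruments);
* canonical coefficients are "unstandardized": applied to centered data
  they yield variates with unit training-set variance;
* CCA signs are arbitrary, so each pair is flipped to correlate
  positively with a severity anchor (e.g. the CAPS total) when one is
  provided;
* the sequential Wilks' lambda test (Bartlett's chi-square approximation)
  gates how many pairs are statistically supported; non-significant pairs
  are retained in the model but flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.decomposition import PCA

from .containers import RegionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PcaModel", "CcaModel", "CorrelateModel",
    "fit_pca", "fit_cca", "project_latent",
]


@dataclass
class PcaModel:
    feature_names: list[str]
    mean_: np.ndarray
    scale_: np.ndarray | None
    components_: np.ndarray            # features x n_pcs, orthonormal columns
    explained_variance_ratio_: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.components_.shape[1]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in data.columns]
        if missing:
            raise KeyError(f"features missing from input: {missing[:10]}")
        x = data[self.feature_names].to_numpy(dtype=float) - self.mean_
        if self.scale_ is not None:
            x = x / self.scale_
        return x @ self.components_


def fit_pca(
    matrix: pd.DataFrame,
    n_pcs: int,
    standardize: bool = False,
) -> PcaModel:
    """Centered (optionally unit-scaled) PCA of a samples x features frame."""
    n, p = matrix.shape
    if n_pcs > min(n - 1, p):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_samples - 1, n_features) = {min(n - 1, p)}"
        )
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = None
    if standardize:
        scale = x.std(axis=0, ddof=1)
        dead = matrix.columns[scale == 0]
        if len(dead):
            raise ValueError(f"zero-variance features cannot be standardized: "
                             f"{list(dead[:5])}")
        x = (x - mean) / scale
    pca = PCA(n_components=n_pcs, svd_solver="full").fit(x)
    return PcaModel(
        feature_names=list(matrix.columns),
        mean_=mean,
        scale_=scale,
        components_=pca.components_.T.copy(),
        explained_variance_ratio_=pca.explained_variance_ratio_.copy(),
    )


@dataclass
class CcaModel:
    x_coef: np.ndarray                 # n_x_pcs x n_pairs ("unstandardized")
    y_coef: np.ndarray                 # n_y_pcs x n_pairs
    cancorrs: np.ndarray               # all min(p, q) canonical correlations
    x_mean: np.ndarray
    y_mean: np.ndarray
    wilks: pd.DataFrame                # per dimension: lambda, chi2, df, p
    significant: np.ndarray            # per retained pair
    n_samples: int

    @property
    def n_pairs(self) -> int:
        return self.x_coef.shape[1]

    def transform_x(self, x_scores: np.ndarray) -> np.ndarray:
        return (x_scores - self.x_mean) @ self.x_coef

    def transform_y(self, y_scores: np.ndarray) -> np.ndarray:
        return (y_scores - self.y_mean) @ self.y_coef


def fit_cca(
    x_scores: np.ndarray,
    y_scores: np.ndarray,
    n_pairs: int = 2,
    alpha: float = 1e-4,
    orient: np.ndarray | None = None,
) -> CcaModel:
    """Classical CCA between two blocks of (PC) scores.

    Uses the QR decomposition of each centered block and the SVD of
    ``Qx' Qy``; coefficients are scaled so the canonical variates have unit
    variance on the training data.  The sequential Wilks' lambda statistic
    (Bartlett chi-square approximation) tests whether canonical dimension k
    and beyond carry association; pairs with p >= ``alpha`` are flagged,
    not removed.

    ``orient`` (a per-sample vector, e.g. a severity total) fixes the
    arbitrary signs: each retained pair is flipped so its y-side variate
    correlates positively with ``orient``.  Without an anchor the y
    coefficient with the largest magnitude is made positive.
    """
    x = np.asarray(x_scores, dtype=float)
    y = np.asarray(y_scores, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must cover the same samples")
    n, p = x.shape
    q = y.shape[1]
    m = min(p, q)
    if n_pairs > m:
        raise ValueError(f"n_pairs={n_pairs} exceeds min block width {m}")
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    if np.linalg.matrix_rank(xc) < p or np.linalg.matrix_rank(yc) < q:
        raise ValueError("rank-deficient block; use fewer PCs per block")

    qx, rx = np.linalg.qr(xc)
    qy, ry = np.linalg.qr(yc)
    u, s, vt = np.linalg.svd(qx.T @ qy)
    cancorrs = np.clip(s[:m], 0.0, 1.0)

    # coefficients giving unit-variance variates on the training data
    a = linalg.solve_triangular(rx, u[:, :n_pairs]) * np.sqrt(n - 1)
    b = linalg.solve_triangular(ry, vt.T[:, :n_pairs]) * np.sqrt(n - 1)

    # Bartlett's chi-square approximation of the sequential Wilks test
    rows = []
    for k in range(m):
        lam = float(np.prod(1.0 - cancorrs[k:] ** 2))
        chi2 = -(n - 1 - (p + q + 1) / 2.0) * np.log(max(lam, 1e-300))
        df = (p - k) * (q - k)
        pval = float(stats.chi2.sf(chi2, df))
        rows.append({"dimension": k + 1, "wilks_lambda": lam,
                     "chi2": chi2, "df": df, "p_value": pval})
    wilks = pd.DataFrame(rows).set_index("dimension")
    significant = wilks["p_value"].to_numpy()[:n_pairs] < alpha
    if not significant.all():
        logger.warning("canonical pairs %s fail the Wilks' lambda gate",
                       list(np.nonzero(~significant)[0] + 1))

    for j in range(n_pairs):
        yvar = yc @ b[:, j]
        if orient is not None:
            anchor = np.asarray(orient, dtype=float)
            flip = np.corrcoef(yvar, anchor)[0, 1] < 0
        else:
            flip = b[np.argmax(np.abs(b[:, j])), j] < 0
        if flip:
            a[:, j] *= -1.0
            b[:, j] *= -1.0

    return CcaModel(
        x_coef=a, y_coef=b, cancorrs=cancorrs, x_mean=x_mean, y_mean=y_mean,
        wilks=wilks, significant=significant, n_samples=n,
    )


@dataclass
class CorrelateModel:
    """PCA models for both blocks plus the CCA connecting them."""

    pca_gene: PcaModel
    pca_clinical: PcaModel
    cca: CcaModel
    latent_names: tuple[str, str] = ("psychological", "physical_dissociative")

    def to_json(self, path) -> None:
        def pca_payload(p: PcaModel):
            return {
                "feature_names": p.feature_names,
                "mean": p.mean_.tolist(),
                "scale": None if p.scale_ is None else p.scale_.tolist(),
                "components": p.components_.tolist(),
                "explained_variance_ratio": p.explained_variance_ratio_.tolist(),
            }

        payload = {
            "pca_gene": pca_payload(self.pca_gene),
            "pca_clinical": pca_payload(self.pca_clinical),
            "cca": {
                "x_coef": self.cca.x_coef.tolist(),
                "y_coef": self.cca.y_coef.tolist(),
                "cancorrs": self.cca.cancorrs.tolist(),
                "x_mean": self.cca.x_mean.tolist(),
                "y_mean": self.cca.y_mean.tolist(),
                "wilks": self.cca.wilks.reset_index().to_dict(orient="records"),
                "significant": self.cca.significant.tolist(),
                "n_samples": self.cca.n_samples,
            },
            "latent_names": list(self.latent_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CorrelateModel":
        with open(path) as fh:
            payload = json.load(fh)

        def pca_from(d) -> PcaModel:
            return PcaModel(
                feature_names=list(d["feature_names"]),
                mean_=np.asarray(d["mean"], dtype=float),
                scale_=None if d["scale"] is None else np.asarray(d["scale"], float),
                components_=np.asarray(d["components"], dtype=float),
                explained_variance_ratio_=np.asarray(
                    d["explained_variance_ratio"], dtype=float),
            )

        c = payload["cca"]
        cca = CcaModel(
            x_coef=np.asarray(c["x_coef"], dtype=float),
            y_coef=np.asarray(c["y_coef"], dtype=float),
            cancorrs=np.asarray(c["cancorrs"], dtype=float),
            x_mean=np.asarray(c["x_mean"], dtype=float),
            y_mean=np.asarray(c["y_mean"], dtype=float),
            wilks=pd.DataFrame(c["wilks"]).set_index("dimension"),
            significant=np.asarray(c["significant"], dtype=bool),
            n_samples=int(c["n_samples"]),
        )
        return cls(pca_gene=pca_from(payload["pca_gene"]),
                   pca_clinical=pca_from(payload["pca_clinical"]),
                   cca=cca,
                   latent_names=tuple(payload["latent_names"]))


def project_latent(
    pca_gene: PcaModel,
    cca: CcaModel,
    regions: RegionMatrix | pd.DataFrame,
) -> pd.DataFrame:
    """Project gene-region methylation into the latent (x, y) plane.

    Applies the training-set centering (and the CCA score centering) to
    any cohort, so new cases land in the coordinate system of the
    discovery fit.
    """
    values = regions.values if isinstance(regions, RegionMatrix) else regions
    scores = pca_gene.transform(values)
    latent = cca.transform_x(scores)
    return pd.DataFrame(latent[:, :2], index=values.index, columns=["x", "y"])


def subject_feature_ratio_ok(n_samples: int, n_pcs_total: int,
                             minimum: float = 20.0) -> bool:
    """Warn-level guard: canonical loadings destabilize when there are
    fewer than ~20 subjects per retained feature."""
    ratio = n_samples / max(n_pcs_total, 1)
    if ratio < minimum:
        logger.warning(
            "subject-to-feature ratio %.1f is below %g; CCA loadings may be "
            "unstable", ratio, minimum)
        return False
    return True
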