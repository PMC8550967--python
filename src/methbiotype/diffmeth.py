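"""Covariate-adjusted moderated t-tests, DMG calling and pathway grouping.

Per probe, beta values are regressed on a case/control indicator plus
covariates (cell-composition fractions, ancestry PCs, age).  Residual
variances are pooled across probes by empirical Bayes: the prior degrees
of freedom ``d0`` and prior variance ``s0^2`` are estimated by method of
moments on the log residual variances (the scaled-F model of limma-style
moderation), and each probe's posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

giving a moderated t with ``d0 + d`` degrees of freedom.  Differentially
methylated probes (DMPs) require both statistical and practical
significance: p below a cutoff and an absolute raw case-minus-control
beta difference above an effect cutoff.  A gene is differentially
methylated (DMG) when at least one member probe is a DMP; its direction
is that of the member DMP with the largest |delta beta|.

Pathway utilities: hypergeometric enrichment of DMGs in gene sets with a
direction score, the pairwise pathway dissimilarity
``1 - |Pi & Pj| / max(|Pi|, |Pj|)``, and complete-linkage grouping of the
dissimilarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import digamma, polygamma

logger = logging.getLogger(__name__)

__all__ = [
    "DmDesign", "DmResult", "moderated_ttest", "call_dmg",
    "enrich_gene_sets", "pathway_dissimilarity", "cluster_pathways",
    "read_gmt", "fit_f_dist",
]


@dataclass
class DmDesign:
    """One contrast: which samples are cases/controls and the adjusters."""

    contrast: str
    case_ids: list[str]
    control_ids: list[str]
    covariates: pd.DataFrame | None = None     # indexed by sample id

    def __post_init__(self):
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"contrast groups overlap: {sorted(overlap)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.case_ids) + list(self.control_ids)


@dataclass
class DmResult:
    table: pd.DataFrame                # per probe
    d0: float
    s0_sq: float
    contrast: str
    counts: dict = field(default_factory=dict)

    def gene_table(self) -> pd.DataFrame:
        if "dmg" not in self.table.columns:
            raise RuntimeError("run call_dmg first")
        probes = self.table[self.table["gene"] != ""]
        rows = []
        for gene, grp in probes.groupby("gene", sort=True):
            dmps = grp[grp["dmp"]]
            if len(dmps):
                top = dmps.loc[dmps["delta_beta"].abs().idxmax()]
                rows.append({"gene": gene, "dmg": True,
                             "direction": int(np.sign(top["delta_beta"]))})
            else:
                rows.append({"gene": gene, "dmg": False, "direction": 0})
        return pd.DataFrame(rows).set_index("gene")


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y (Newton iterations on 1/trigamma)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled F model to residual variances.

    Under the hierarchical model, ``log s^2`` is ``log s0^2`` plus the log
    of a ratio of scaled chi-squares; matching the mean and variance of
    ``log s^2`` gives ``(d0, s0^2)``.  When the observed spread of
    ``log s^2`` does not exceed what sampling alone explains, ``d0`` is
    infinite (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(
    beta: pd.DataFrame,
    design: DmDesign,
    gene_of: pd.Series | None = None,
    d0_override: float | None = None,
) -> DmResult:
    """Empirical-Bayes moderated t-test of every probe for one contrast.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t-test exactly; ``np.inf`` shrinks every variance to the
    common prior); by default ``(d0, s0^2)`` are estimated from the data.
    If estimation fails (no dispersion in the variances), the ordinary
    t-test is used with a warning.
    """
    ids = design.sample_ids
    missing = [s for s in ids if s not in beta.index]
    if missing:
        raise ValueError(f"samples missing from beta matrix: {missing[:5]}")
    y = beta.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    indicator = np.array([1.0] * len(design.case_ids)
                         + [0.0] * len(design.control_ids))
    cols = [np.ones(n), indicator]
    if design.covariates is not None:
        cov = design.covariates.loc[ids]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df_resid = n - rank
    if df_resid < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ y                      # p x probes
    resid = y - x @ coef
    s2 = (resid**2).sum(axis=0) / df_resid
    unscaled = float(np.sqrt(xtx_inv[1, 1]))      # se = unscaled * s

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = coef[1] / (unscaled * np.sqrt(s2))

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2)) if np.isfinite(d0) and d0 > 0 else float(
            np.exp(np.mean(np.log(s2[s2 > 0]))))
        if d0 == 0:
            s0_sq = 0.0
    else:
        try:
            d0, s0_sq = fit_f_dist(s2, df_resid)
        except ValueError:
            logger.warning("variance-prior estimation failed; using ordinary t")
            d0, s0_sq = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef[1] / (unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    # raw (unadjusted) group difference: the effect-size cutoff applies to
    # the plain beta difference even though the test is covariate adjusted.
    case_mean = y[: len(design.case_ids)].mean(axis=0)
    ctrl_mean = y[len(design.case_ids):].mean(axis=0)
    delta = case_mean - ctrl_mean
    med_delta = (np.median(y[: len(design.case_ids)], axis=0)
                 - np.median(y[len(design.case_ids):], axis=0))

    table = pd.DataFrame(
        {
            "gene": (gene_of.loc[beta.columns].fillna("").to_numpy()
                     if gene_of is not None else ""),
            "delta_beta": delta,
            "median_delta_beta": med_delta,
            "t": t_ord,
            "t_mod": t_mod,
            "p": p,
        },
        index=beta.columns,
    )
    return DmResult(table=table, d0=float(d0), s0_sq=float(s0_sq),
                    contrast=design.contrast)


def call_dmg(
    result: DmResult,
    p_cut: float = 0.01,
    d_cut: float = 0.02,
) -> DmResult:
    """Flag DMPs (p < p_cut and |delta beta| > d_cut) and derive DMGs."""
    t = result.table
    t["dmp"] = (t["p"] < p_cut) & (t["delta_beta"].abs() > d_cut)
    t["direction"] = np.where(t["dmp"], np.sign(t["delta_beta"]).astype(int), 0)
    t["dmg"] = False
    genes = t.loc[(t["gene"] != "") & t["dmp"], "gene"].unique()
    t.loc[t["gene"].isin(genes), "dmg"] = True
    gene_tab = result.gene_table()
    dmg = gene_tab[gene_tab["dmg"]]
    result.counts = {
        "n_dmp": int(t["dmp"].sum()),
        "n_dmg": int(len(dmg)),
        "n_hyper": int((dmg["direction"] > 0).sum()),
        "n_hypo": int((dmg["direction"] < 0).sum()),
    }
    assert result.counts["n_hyper"] + result.counts["n_hypo"] == result.counts["n_dmg"]
    return result


def enrich_gene_sets(
    dmgs: dict[str, int],
    universe: list[str],
    sets: dict[str, set[str]],
    p_cut: float = 0.01,
    z_cut: float = 2.0,
) -> pd.DataFrame:
    """Hypergeometric enrichment of directed DMGs in gene sets.

    ``dmgs`` maps gene -> direction (+1 hyper / -1 hypo).  The direction
    score ``(n_hyper - n_hypo) / sqrt(n_overlap)`` plays the role of an
    activation z-score; a set is enriched when its one-sided
    hypergeometric p is below ``p_cut`` and |direction score| >= ``z_cut``.
    """
    uni = set(universe)
    missing = set(dmgs) - uni
    if missing:
        raise ValueError(f"DMGs outside the universe: {sorted(missing)[:5]}")
    n_uni = len(uni)
    n_dmg = len(dmgs)
    rows = []
    for name, members in sets.items():
        members = set(members) & uni
        overlap = {g: dmgs[g] for g in members if g in dmgs}
        k = len(overlap)
        if k == 0 or not members:
            p = 1.0
            score = 0.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_uni, len(members), n_dmg))
            n_hyper = sum(1 for v in overlap.values() if v > 0)
            n_hypo = sum(1 for v in overlap.values() if v < 0)
            score = (n_hyper - n_hypo) / np.sqrt(k)
        rows.append({
            "pathway": name, "set_size": len(members), "overlap": k,
            "p_value": p, "direction_score": score,
            "enriched": bool(p < p_cut and abs(score) >= z_cut),
        })
    return pd.DataFrame(rows).set_index("pathway")


def pathway_dissimilarity(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise pathway dissimilarity ``1 - |Pi & Pj| / max(|Pi|, |Pj|)``."""
    names = list(sets)
    for n in names:
        if not sets[n]:
            raise ValueError(f"pathway {n!r} is empty")
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = set(sets[names[i]]), set(sets[names[j]])
            d[i, j] = d[j, i] = 1.0 - len(si & sj) / max(len(si), len(sj))
    return pd.DataFrame(d, index=names, columns=names)


def cluster_pathways(
    dissimilarity: pd.DataFrame,
    n_groups: int | None = None,
    height: float | None = None,
) -> pd.Series:
    """Complete-linkage grouping of a pathway dissimilarity matrix.

    Cut either at a number of groups or at a merge height.  The linkage is
    deterministic for a fixed input order; exact ties between merge
    candidates are resolved by scipy's nearest-neighbor chain order.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("input is not a dissimilarity matrix")
    n = d.shape[0]
    if n_groups is not None and n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds {n} pathways")
    z = linkage(squareform(d, checks=False), method="complete")
    if n_groups is not None:
        labels = fcluster(z, t=n_groups, criterion="maxclust")
    elif height is not None:
        labels = fcluster(z, t=height, criterion="distance")
    else:
        raise ValueError("specify n_groups or height")
    return pd.Series(labels, index=dissimilarity.index, name="group")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")
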