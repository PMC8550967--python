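"""Resampling-based diagnostic marker panel selection and evaluation.

The search mirrors a conventional random-sampling feature selection:

1. **candidates** -- relaxed-threshold DMPs on the training cohort
   (moderated t p < 0.1, |median beta difference| > 0.02, covariate
   adjusted) whose median beta difference has a consistent sign in every
   validation cohort;
2. **random subset search** -- many runs of drawing a small probe subset,
   training a linear SVM on the training cohort and testing on the
   validation cohorts; subsets whose across-cohort mean AUC clears a bar
   (default 0.8) are retained, and probes are ranked by their frequency
   in the retained subsets;
3. **forward AUC trajectory** -- mean validation AUC of the top-k panel
   as k grows; the default cutoff is the smallest k within a tolerance of
   the trajectory maximum;
4. **collinearity pruning** -- greedily drop the lower-ranked probe of
   any pair correlated above a threshold;
5. **biotype-aware refinement** -- greedy forward selection maximizing
   the mean of the per-biotype validation AUCs (G1 vs control and G2 vs
   control), since a control-like biotype otherwise drags the panel's
   sensitivity down.

Classifiers are soft-margin linear SVMs (C = 1, hinge loss) on
z-scored features; evaluation reports trapezoidal ROC AUC plus the
sensitivity/specificity at the Youden-optimal operating point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .diffmeth import DmDesign, moderated_ttest

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort", "PanelSearchConfig", "PanelModel",
    "candidate_dmps", "random_subset_search", "forward_auc_cutoff",
    "collinearity_prune", "biotype_refine", "evaluate_panel",
]


@dataclass
class Cohort:
    """A beta matrix with case/control labels (and optional biotypes)."""

    beta: pd.DataFrame
    case: pd.Series                    # bool per sample
    biotype: pd.Series | None = None   # "G1"/"G2" for cases, "" otherwise
    covariates: pd.DataFrame | None = None
    name: str = "cohort"

    def __post_init__(self):
        self.case = self.case.loc[self.beta.index].astype(bool)
        if self.biotype is not None:
            self.biotype = self.biotype.reindex(self.beta.index).fillna("")


@dataclass
class PanelSearchConfig:
    n_runs: int = 100_000
    subset_size: int = 10
    auc_keep: float = 0.8
    p_cut: float = 0.1
    effect_cut: float = 0.02
    prune_r: float = 0.8
    forward_tol: float = 0.005
    seed: int = 0

    def validate(self, n_candidates: int | None = None) -> None:
        if self.n_runs < 1 or self.subset_size < 1:
            raise ValueError("n_runs and subset_size must be positive")
        if not 0.0 <= self.auc_keep <= 1.0:
            raise ValueError("auc_keep must lie in [0, 1]")
        if n_candidates is not None and self.subset_size > n_candidates:
            raise ValueError("subset_size exceeds the number of candidates")


@dataclass
class PanelModel:
    probes: list[str]
    frequencies: pd.Series
    cutoff_k: int
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svm_coef: np.ndarray
    svm_intercept: float
    metrics: dict = field(default_factory=dict)

    def decision_scores(self, beta: pd.DataFrame) -> pd.Series:
        x = beta[self.probes].to_numpy(dtype=float)
        x = (x - self.scaler_mean) / self.scaler_scale
        return pd.Series(x @ self.svm_coef + self.svm_intercept,
                         index=beta.index, name="score")

    def to_json(self, path) -> None:
        payload = {
            "probes": self.probes,
            "frequencies": self.frequencies.to_dict(),
            "cutoff_k": self.cutoff_k,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "svm_coef": self.svm_coef.tolist(),
            "svm_intercept": self.svm_intercept,
            "metrics": self.metrics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PanelModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            probes=list(d["probes"]),
            frequencies=pd.Series(d["frequencies"]),
            cutoff_k=int(d["cutoff_k"]),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            svm_coef=np.asarray(d["svm_coef"], dtype=float),
            svm_intercept=float(d["svm_intercept"]),
            metrics=dict(d["metrics"]),
        )


# ---------------------------------------------------------------------------
# linear SVM plumbing


def _zscore_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def _fit_lsvm(x: np.ndarray, y: np.ndarray):
    mean, scale = _zscore_params(x)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((x - mean) / scale, y)
    coef = clf.coef_.ravel() / scale
    intercept = float(clf.intercept_[0] - (clf.coef_.ravel() * mean / scale).sum())
    return coef, intercept, mean, scale


def _scores(coef: np.ndarray, intercept: float, x: np.ndarray) -> np.ndarray:
    return x @ coef + intercept


def _subset_auc(probes: list[str], train: Cohort, cohort: Cohort,
                case_mask: np.ndarray | None = None) -> float:
    xt = train.beta[probes].to_numpy(dtype=float)
    coef, intercept, _, _ = _fit_lsvm(xt, train.case.to_numpy())
    xv = cohort.beta[probes].to_numpy(dtype=float)
    scores = _scores(coef, intercept, xv)
    labels = cohort.case.to_numpy()
    if case_mask is not None:
        keep = ~labels | case_mask
        labels, scores = labels[keep], scores[keep]
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# selection pipeline


def candidate_dmps(
    train: Cohort,
    validations: list[Cohort],
    config: PanelSearchConfig,
) -> list[str]:
    """Relaxed-threshold DMPs on training, sign-consistent in validation.

    A probe survives when its moderated-t p-value is below ``config.p_cut``
    and |median case-minus-control beta difference| exceeds
    ``config.effect_cut`` on the training cohort, and its median beta
    difference has the same (non-zero) sign in every validation cohort.
    """
    shared = train.beta.columns
    for v in validations:
        shared = shared.intersection(v.beta.columns)
    if len(shared) == 0:
        raise ValueError("no probes shared across cohorts")

    design = DmDesign(
        contrast="case vs control",
        case_ids=list(train.beta.index[train.case]),
        control_ids=list(train.beta.index[~train.case]),
        covariates=train.covariates,
    )
    res = moderated_ttest(train.beta[shared], design)
    t = res.table
    keep = (t["p"] < config.p_cut) & (t["median_delta_beta"].abs()
                                      > config.effect_cut)
    cands = t.index[keep]
    sign = np.sign(t.loc[cands, "median_delta_beta"].to_numpy())

    for v in validations:
        case = v.beta.loc[v.case.to_numpy(), cands].median(axis=0)
        ctrl = v.beta.loc[~v.case.to_numpy(), cands].median(axis=0)
        vsign = np.sign((case - ctrl).to_numpy())
        ok = (vsign == sign) & (vsign != 0)
        cands, sign = cands[ok], sign[ok]
    return list(cands)


def _univariate_auc(train: Cohort, probes: list[str]) -> pd.Series:
    y = train.case.to_numpy()
    vals = {}
    for p in probes:
        a = roc_auc_score(y, train.beta[p].to_numpy(dtype=float))
        vals[p] = max(a, 1.0 - a)
    return pd.Series(vals)


def random_subset_search(
    candidates: list[str],
    train: Cohort,
    validations: list[Cohort],
    config: PanelSearchConfig,
) -> pd.DataFrame:
    """Frequency-rank candidate probes over retained random subsets.

    Each run draws ``subset_size`` probes uniformly without replacement,
    trains the linear SVM on the training cohort and scores the validation
    cohorts; the subset is retained when the unweighted mean of the
    per-cohort AUCs exceeds ``auc_keep``.  Ties in frequency are broken by
    the probe's univariate training AUC, then by id.
    """
    config.validate(n_candidates=len(candidates))
    counts = pd.Series(0, index=pd.Index(candidates, name="probe"), dtype=float)
    n_retained = 0
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    cand = np.asarray(candidates)
    for child in children:
        rng = np.random.default_rng(child)
        subset = list(cand[rng.choice(len(cand), size=config.subset_size,
                                      replace=False)])
        aucs = [_subset_auc(subset, train, v) for v in validations]
        if float(np.mean(aucs)) > config.auc_keep:
            counts[subset] += 1
            n_retained += 1
    if n_retained == 0:
        raise RuntimeError(
            "no subset cleared the AUC bar; lower auc_keep or enlarge runs")
    freq = counts / n_retained
    uni = _univariate_auc(train, candidates)
    table = pd.DataFrame({"frequency": freq, "univariate_auc": uni})
    order = sorted(candidates, key=lambda p: (-freq[p], -uni[p], p))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(order) + 1)
    table.attrs["n_retained"] = n_retained
    return table


def forward_auc_cutoff(
    ranked_probes: list[str],
    train: Cohort,
    validations: list[Cohort],
    tol: float = 0.005,
    k_max: int | None = None,
) -> tuple[int, np.ndarray]:
    """Mean validation AUC of the top-k panel for k = 1..K.

    Returns the default cutoff (smallest k whose AUC is within ``tol`` of
    the trajectory maximum; ``tol = 0`` picks the exact argmax) and the
    full trajectory.  The cutoff is deliberately overridable: panel size
    is ultimately a judgment call.
    """
    k_top = len(ranked_probes) if k_max is None else min(k_max, len(ranked_probes))
    traj = np.empty(k_top)
    for k in range(1, k_top + 1):
        probes = ranked_probes[:k]
        traj[k - 1] = float(np.mean(
            [_subset_auc(probes, train, v) for v in validations]))
    best = traj.max()
    cutoff = int(np.argmax(traj >= best - tol)) + 1
    return cutoff, traj


def collinearity_prune(
    probes: list[str],
    train: Cohort,
    prune_r: float = 0.8,
) -> list[str]:
    """Greedily drop the lower-ranked probe of any |r| > prune_r pair."""
    if not probes:
        raise ValueError("panel is empty")
    x = train.beta[probes].to_numpy(dtype=float)
    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    kept: list[int] = []
    for i in range(len(probes)):
        if all(abs(corr[i, j]) <= prune_r for j in kept):
            kept.append(i)
    return [probes[i] for i in kept]


def biotype_refine(
    panel: list[str],
    train: Cohort,
    validations: list[Cohort],
    tol: float = 0.005,
) -> list[str]:
    """Greedy forward selection on the mean of per-biotype validation AUCs.

    The objective of a candidate sub-panel is the mean over validation
    cohorts and biotypes of AUC(biotype cases vs all controls).  Probes
    are added greedily; the returned sub-panel is the smallest prefix of
    the greedy ordering whose objective is within ``tol`` of the best
    prefix objective (which also guarantees it is within ``tol`` of the
    full panel's objective).
    """
    for v in validations:
        if v.biotype is None:
            raise ValueError(f"validation cohort {v.name} lacks biotype labels")
        present = set(v.biotype[v.case])
        for b in ("G1", "G2"):
            if b not in present:
                raise ValueError(f"biotype {b} absent in validation {v.name}")

    def objective(subset: list[str]) -> float:
        aucs = []
        for v in validations:
            for b in ("G1", "G2"):
                mask = (v.biotype == b).to_numpy()
                aucs.append(_subset_auc(subset, train, v, case_mask=mask))
        return float(np.mean(aucs))

    remaining = list(panel)
    chosen: list[str] = []
    traj: list[float] = []
    while remaining:
        scored = [(objective(chosen + [p]), p) for p in remaining]
        best_obj, best_p = max(scored, key=lambda t: (t[0], t[1]))
        chosen.append(best_p)
        remaining.remove(best_p)
        traj.append(best_obj)
    best = max(traj)
    k = int(np.argmax(np.asarray(traj) >= best - tol)) + 1
    return chosen[:k]


def evaluate_panel(
    panel: list[str],
    train: Cohort,
    test: Cohort,
    case_filter: str | None = None,
) -> dict[str, float]:
    """Train on the training cohort, report AUC + Youden point on test.

    ``case_filter`` restricts the test cases to one biotype ("G1"/"G2")
    while keeping all controls, matching per-biotype contrasts.
    """
    xt = train.beta[panel].to_numpy(dtype=float)
    coef, intercept, mean, scale = _fit_lsvm(xt, train.case.to_numpy())
    labels = test.case.to_numpy()
    scores = _scores(coef, intercept, test.beta[panel].to_numpy(dtype=float))
    if case_filter is not None:
        if test.biotype is None:
            raise ValueError("test cohort lacks biotype labels")
        keep = ~labels | (test.biotype == case_filter).to_numpy()
        labels, scores = labels[keep], scores[keep]
    if labels.all() or not labels.any():
        raise ValueError("test set has a single class")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    youden = tpr - fpr
    i = int(np.argmax(youden))
    return {"auc": auc, "sensitivity": float(tpr[i]),
            "specificity": float(1.0 - fpr[i]),
            "n_cases": int(labels.sum()), "n_controls": int((~labels).sum())}


def build_panel_model(
    panel: list[str],
    ranked: pd.DataFrame,
    train: Cohort,
) -> PanelModel:
    """Freeze the final panel and its trained linear SVM."""
    xt = train.beta[panel].to_numpy(dtype=float)
    coef, intercept, mean, scale = _fit_lsvm(xt, train.case.to_numpy())
    # store the z-scored-space parameters explicitly
    mean_, scale_ = _zscore_params(xt)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((xt - mean_) / scale_, train.case.to_numpy())
    return PanelModel(
        probes=list(panel),
        frequencies=ranked.loc[ranked.index.intersection(panel), "frequency"],
        cutoff_k=len(panel),
        scaler_mean=mean_,
        scaler_scale=scale_,
        svm_coef=clf.coef_.ravel().copy(),
        svm_intercept=float(clf.intercept_[0]),
    )
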