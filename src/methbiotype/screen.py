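"""Clinical association screening and resampled frequency ranking.

A gene region is clinically informative when it correlates modestly
(|r| > 0.2 by default) with at least one of the declared symptom/function
features, while staying unassociated (|r| <= 0.2) with every declared
confounder (age, ancestry PCs, BMI, blood cell composition, smoking,
alcohol use, number of deployments).  The choice is then stabilized by a
leave-few-out resampling: the scan is repeated on random subsets of the
cohort and regions are ranked by how frequently they pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import RegionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "clinical_association_scan", "cv_frequency_ranking"]


@dataclass
class ScreenResult:
    """Outcome of the resampled screen.

    ``table`` has one row per region with columns ``frequency`` (fraction
    of iterations the region passed both correlation screens), ``rank``
    (1-based, by descending frequency with ties broken by descending
    full-sample max clinical |r| then region id), ``max_r_clin`` and
    ``max_r_conf`` (full-sample values), and ``passed_full`` (whether the
    region passes the single full-sample scan).
    """

    table: pd.DataFrame
    top_regions: list[str]
    n_iter: int
    leave_out: int
    seed: int

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "region"
        out.to_csv(path, sep="\t")


def _max_abs_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column-of-x maximum |Pearson r| against all columns of y.

    Constant columns (in either block) contribute correlation 0.
    """
    n = x.shape[0]
    xm = x - x.mean(axis=0)
    ym = y - y.mean(axis=0)
    xs = xm.std(axis=0)
    ys = ym.std(axis=0)
    xz = np.divide(xm, xs, out=np.zeros_like(xm), where=xs > 0)
    yz = np.divide(ym, ys, out=np.zeros_like(ym), where=ys > 0)
    r = np.clip(xz.T @ yz / n, -1.0, 1.0)
    return np.abs(r).max(axis=1) if y.shape[1] else np.zeros(x.shape[1])


def clinical_association_scan(
    regions: RegionMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    feature_cols: list[str],
    confounder_cols: list[str],
    r_clin: float = 0.2,
    r_conf: float = 0.2,
) -> tuple[list[str], pd.DataFrame]:
    """Single-pass correlation screen.

    Returns the passing region ids plus a per-region table with
    ``max_r_clin``, ``max_r_conf`` and the pass flag.  A region passes when
    its maximum |Pearson r| over the features strictly exceeds ``r_clin``
    and its maximum |Pearson r| over the confounders does not exceed
    ``r_conf``.
    """
    values = regions.values if isinstance(regions, RegionMatrix) else regions
    clin = clinical.loc[values.index]
    x = values.to_numpy(dtype=float)
    feats = clin[feature_cols].to_numpy(dtype=float)
    confs = clin[confounder_cols].to_numpy(dtype=float)

    max_clin = _max_abs_corr(x, feats)
    max_conf = _max_abs_corr(x, confs)
    passed = (max_clin > r_clin) & (max_conf <= r_conf)
    table = pd.DataFrame(
        {"max_r_clin": max_clin, "max_r_conf": max_conf, "passed": passed},
        index=values.columns,
    )
    n_const = int((x.std(axis=0) == 0).sum())
    if n_const:
        logger.info("%d constant regions treated as correlation 0", n_const)
    return list(values.columns[passed]), table


def cv_frequency_ranking(
    regions: RegionMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    feature_cols: list[str],
    confounder_cols: list[str],
    n_iter: int = 5000,
    leave_out: int = 5,
    top_k: int = 100,
    seed: int = 0,
    r_clin: float = 0.2,
    r_conf: float = 0.2,
) -> ScreenResult:
    """Leave-``leave_out``-out resampled screen with frequency ranking.

    Each iteration removes ``leave_out`` samples uniformly at random
    without replacement, reruns :func:`clinical_association_scan` on the
    remainder (confounder exclusion included) and records the pass set.
    Regions are ranked by descending pass frequency, ties broken by
    descending full-sample max clinical |r| then lexicographic region id.
    One master seed spawns a substream per iteration, so changing
    ``n_iter`` does not reshuffle earlier iterations.
    """
    values = regions.values if isinstance(regions, RegionMatrix) else regions
    n_samples, n_regions = values.shape
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if leave_out >= n_samples:
        raise ValueError("leave_out must be smaller than the number of samples")

    clin = clinical.loc[values.index]
    x = values.to_numpy(dtype=float)
    feats = clin[feature_cols].to_numpy(dtype=float)
    confs = clin[confounder_cols].to_numpy(dtype=float)

    counts = np.zeros(n_regions, dtype=int)
    children = np.random.SeedSequence(seed).spawn(n_iter)
    for child in children:
        rng = np.random.default_rng(child)
        drop = rng.choice(n_samples, size=leave_out, replace=False)
        mask = np.ones(n_samples, dtype=bool)
        mask[drop] = False
        max_clin = _max_abs_corr(x[mask], feats[mask])
        max_conf = _max_abs_corr(x[mask], confs[mask])
        counts += (max_clin > r_clin) & (max_conf <= r_conf)

    freq = counts / n_iter
    full_clin = _max_abs_corr(x, feats)
    full_conf = _max_abs_corr(x, confs)
    table = pd.DataFrame(
        {
            "frequency": freq,
            "max_r_clin": full_clin,
            "max_r_conf": full_conf,
            "passed_full": (full_clin > r_clin) & (full_conf <= r_conf),
        },
        index=values.columns,
    )
    order = sorted(
        range(n_regions),
        key=lambda i: (-freq[i], -full_clin[i], values.columns[i]),
    )
    table = table.iloc[order]
    table["rank"] = np.arange(1, n_regions + 1)

    if top_k > n_regions:
        logger.warning("top_k=%d exceeds %d regions; returning all", top_k, n_regions)
        top_k = n_regions
    top = list(table.index[:top_k])
    return ScreenResult(table=table, top_regions=top, n_iter=n_iter,
                        leave_out=leave_out, seed=seed)
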