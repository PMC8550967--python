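"""Probe filtering and correlation-graph region collapsing.

The reduction from a normalized probe-level beta matrix to gene-region
methylation values proceeds in a fixed order:

1. drop probes with low variability (sd < 0.05), extreme mean methylation
   (mean beta < 0.01 or > 0.99) or no gene annotation (intergenic);
2. keep only "confident" genes that retain at least two probes;
3. within each confident gene, build a graph over the remaining probes
   with edges where pairwise Pearson correlation exceeds a threshold
   (default 0.8) and average the member probes of each connected
   component into one region;
4. optionally drop regions whose values are not reproducible between an
   original and a recall (retest) measurement of the same individuals
   (Pearson r < 0.65).

Input betas are assumed already normalized (e.g. BMIQ); missing values
are not allowed.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .containers import RegionMatrix

logger = logging.getLogger(__name__)

__all__ = ["filter_probes", "collapse_regions", "recall_stability_filter"]


def _check_annotation(beta: pd.DataFrame, annot: pd.DataFrame) -> None:
    missing = beta.columns.difference(annot.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} probes lack annotation rows, e.g. "
            f"{list(missing[:5])}"
        )


def filter_probes(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    sd_min: float = 0.05,
    mean_lo: float = 0.01,
    mean_hi: float = 0.99,
) -> pd.DataFrame:
    """Drop uninformative probes and non-confident genes.

    Retains exactly the probes with ``sd >= sd_min``, mean beta inside
    ``[mean_lo, mean_hi]``, a non-empty gene symbol, and whose gene keeps
    at least two probes after those per-probe filters.  Column order is
    preserved.
    """
    for name, t in (("sd_min", sd_min), ("mean_lo", mean_lo), ("mean_hi", mean_hi)):
        if not 0.0 < t < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {t}")
    _check_annotation(beta, annot)

    vals = beta.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    mean = vals.mean(axis=0)
    gene = annot.loc[beta.columns, "gene"].fillna("").to_numpy()
    keep = (sd >= sd_min) & (mean >= mean_lo) & (mean <= mean_hi) & (gene != "")

    # confident-gene rule: at least two surviving probes per gene
    surviving = pd.Series(gene[keep])
    counts = surviving.value_counts()
    confident = set(counts.index[counts >= 2])
    keep &= np.array([g in confident for g in gene])

    out = beta.loc[:, beta.columns[keep]]
    if out.shape[1] == 0:
        logger.warning("probe filtering removed every probe")
    return out


def collapse_regions(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    r_thresh: float = 0.8,
    scope: str = "gene",
) -> RegionMatrix:
    """Average highly correlated probes into gene regions.

    Within each gene (the default scope), probes are nodes of a graph with
    an edge wherever pairwise Pearson correlation is strictly greater than
    ``r_thresh``; every connected component becomes a region whose value is
    the per-sample mean of its member probes.  Singleton components pass
    through as single-probe regions so no confident gene silently vanishes.
    Probe pairs with zero variance get a correlation of 0 (no edge).

    ``scope="global"`` builds one graph over all probes instead; regions
    are then named after the gene of their first member probe.
    """
    if scope not in ("gene", "global"):
        raise ValueError("scope must be 'gene' or 'global'")
    _check_annotation(beta, annot)
    gene = annot.loc[beta.columns, "gene"].fillna("").to_numpy()

    values: dict[str, np.ndarray] = {}
    membership: dict[str, list[str]] = {}
    vals = beta.to_numpy(dtype=float)

    def _components(cols: np.ndarray) -> list[list[int]]:
        sub = vals[:, cols]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
        graph = nx.Graph()
        graph.add_nodes_from(range(len(cols)))
        edges = np.argwhere(np.triu(corr > r_thresh, k=1))
        graph.add_edges_from(map(tuple, edges))
        comps = [sorted(c) for c in nx.connected_components(graph)]
        return sorted(comps, key=lambda c: c[0])

    if scope == "gene":
        order = pd.unique(gene)
        col_idx = pd.Series(np.arange(len(gene))).groupby(gene, sort=False).groups
        for g in order:
            cols = np.asarray(col_idx[g], dtype=int)
            if (vals[:, cols].std(axis=0) == 0).any() or beta.shape[0] < 2:
                logger.info("gene %s has zero-variance probes; treating as no edge", g)
            for k, comp in enumerate(_components(cols), start=1):
                members = [beta.columns[cols[j]] for j in comp]
                rid = f"{g}@{k}"
                values[rid] = vals[:, cols[comp]].mean(axis=1)
                membership[rid] = members
    else:
        cols = np.arange(len(gene))
        for k, comp in enumerate(_components(cols), start=1):
            members = [beta.columns[j] for j in comp]
            rid = f"{gene[comp[0]] or 'intergenic'}@{k}"
            values[rid] = vals[:, comp].mean(axis=1)
            membership[rid] = members

    frame = pd.DataFrame(values, index=beta.index)
    return RegionMatrix(values=frame, membership=membership)


def recall_stability_filter(
    regions: RegionMatrix,
    recall_regions: RegionMatrix,
    stable_sample_ids: list[str],
    r_min: float = 0.65,
) -> RegionMatrix:
    """Keep regions reproducible between original and recall measurements.

    Pearson correlation is computed per region between the original and
    recall values over ``stable_sample_ids`` (individuals whose diagnostic
    status did not change).  Regions with ``r >= r_min`` are retained;
    regions with undefined correlation (zero variance at either timepoint)
    are dropped.
    """
    stable = [s for s in stable_sample_ids]
    if len(stable) < 3:
        raise ValueError("need at least 3 stable samples for a meaningful correlation")
    missing_o = [s for s in stable if s not in regions.values.index]
    missing_r = [s for s in stable if s not in recall_regions.values.index]
    if missing_o or missing_r:
        raise ValueError(
            f"stable samples missing from original {missing_o[:5]} "
            f"or recall {missing_r[:5]}"
        )
    if list(regions.values.columns) != list(recall_regions.values.columns):
        raise ValueError("original and recall matrices must share the same regions")

    a = regions.values.loc[stable].to_numpy(dtype=float)
    b = recall_regions.values.loc[stable].to_numpy(dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=0) / denom, np.nan)
    keep = [rid for rid, ri in zip(regions.values.columns, r)
            if np.isfinite(ri) and ri >= r_min]
    dropped = regions.values.shape[1] - len(keep)
    if dropped:
        logger.info("recall stability filter removed %d regions", dropped)
    return regions.subset(keep)
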