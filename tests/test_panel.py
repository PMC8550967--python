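"""Random-subset panel search, pruning, refinement, and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest

from methbiotype.panel import (Cohort, PanelSearchConfig, biotype_refine,
                               candidate_dmps, collinearity_prune,
                               evaluate_panel, forward_auc_cutoff,
                               random_subset_search)


def _cohort(rng, n_cases=30, n_ctrl=30, n_probes=30, separators=(),
            effect=0.25, name="cohort", biotype_split=False):
    """Cases/controls with selected probes separating the groups."""
    n = n_cases + n_ctrl
    ids = [f"{name}S{i}" for i in range(n)]
    case = pd.Series([True] * n_cases + [False] * n_ctrl, index=ids)
    x = rng.normal(0.5, 0.05, size=(n, n_probes))
    for j in separators:
        x[:n_cases, j] += effect
    beta = pd.DataFrame(np.clip(x, 0.001, 0.999), index=ids,
                        columns=[f"cg{j:03d}" for j in range(n_probes)])
    biotype = None
    if biotype_split:
        half = n_cases // 2
        biotype = pd.Series([""] * n, index=ids)
        biotype.iloc[:half] = "G1"
        biotype.iloc[half:n_cases] = "G2"
    return Cohort(beta=beta, case=case, biotype=biotype, name=name)


def test_candidate_rules_match_brute_force(rng):
    train = _cohort(rng, separators=(0, 1, 2), name="tr")
    v1 = _cohort(rng, separators=(0, 1), name="v1")
    # probe 2 flips sign in the second validation cohort
    v2 = _cohort(rng, separators=(0, 1, 2), name="v2")
    v2.beta["cg002"] = np.clip(
        v2.beta["cg002"] + np.where(v2.case, -0.5, 0.0), 0.001, 0.999)
    cfg = PanelSearchConfig(p_cut=0.1, effect_cut=0.02)
    cands = candidate_dmps(train, [v1, v2], cfg)

    # brute-force oracle over the three rules
    from methbiotype.diffmeth import DmDesign, moderated_ttest
    design = DmDesign(contrast="c",
                      case_ids=list(train.beta.index[train.case]),
                      control_ids=list(train.beta.index[~train.case]))
    res = moderated_ttest(train.beta, design)
    expected = []
    for probe in train.beta.columns:
        med = (train.beta.loc[train.case.to_numpy(), probe].median()
               - train.beta.loc[~train.case.to_numpy(), probe].median())
        if not (res.table.loc[probe, "p"] < 0.1 and abs(med) > 0.02):
            continue
        sign_ok = True
        for v in (v1, v2):
            vmed = (v.beta.loc[v.case.to_numpy(), probe].median()
                    - v.beta.loc[~v.case.to_numpy(), probe].median())
            sign_ok &= np.sign(vmed) == np.sign(med) and vmed != 0
        if sign_ok:
            expected.append(probe)
    assert cands == expected
    assert "cg000" in cands and "cg001" in cands
    assert "cg002" not in cands          # sign flip in validation


def test_subset_search_ranks_planted_separator_first(rng):
    train = _cohort(rng, separators=(5,), effect=0.4, name="tr")
    vals = [_cohort(rng, separators=(5,), effect=0.4, name=f"v{i}")
            for i in range(2)]
    cfg = PanelSearchConfig(n_runs=300, subset_size=5, auc_keep=0.75, seed=3)
    ranked = random_subset_search(list(train.beta.columns), train, vals, cfg)
    assert ranked.index[0] == "cg005"
    assert ranked["frequency"].iloc[0] > ranked["frequency"].iloc[1]
    # determinism
    ranked2 = random_subset_search(list(train.beta.columns), train, vals, cfg)
    pd.testing.assert_frame_equal(ranked, ranked2)


def test_subset_search_uniform_when_bar_is_zero(rng):
    train = _cohort(rng, name="tr")
    vals = [_cohort(rng, name="v0")]
    cfg = PanelSearchConfig(n_runs=400, subset_size=6, auc_keep=0.0, seed=1)
    cands = list(train.beta.columns)
    ranked = random_subset_search(cands, train, vals, cfg)
    assert ranked.attrs["n_retained"] == 400
    expect = cfg.subset_size / len(cands)
    se = np.sqrt(expect * (1 - expect) / cfg.n_runs)
    assert np.abs(ranked["frequency"] - expect).max() < 5 * se

    bad = PanelSearchConfig(n_runs=5, subset_size=6, auc_keep=1.0, seed=1)
    with pytest.raises(RuntimeError, match="AUC bar"):
        random_subset_search(cands, train, vals, bad)
    with pytest.raises(ValueError):
        PanelSearchConfig(subset_size=99).validate(n_candidates=30)


def test_forward_trajectory_and_cutoff(rng):
    train = _cohort(rng, separators=(0, 1, 2), effect=0.35, name="tr")
    vals = [_cohort(rng, separators=(0, 1, 2), effect=0.35, name="v0")]
    ranked = [f"cg{j:03d}" for j in range(12)]   # separators ranked first
    k, traj = forward_auc_cutoff(ranked, train, vals, tol=0.005)
    assert len(traj) == 12
    assert k <= 8
    k0, traj0 = forward_auc_cutoff(ranked, train, vals, tol=0.0)
    assert k0 == int(np.argmax(traj0)) + 1


def test_collinearity_pruning(rng):
    train = _cohort(rng, name="tr", n_probes=8)
    b = train.beta
    b["cg001"] = b["cg000"] * 0.9 + 0.05           # near-duplicate of cg000
    b["cg004"] = b["cg003"] * 0.95 + 0.02
    b["cg005"] = np.clip(b["cg003"] + rng.normal(0, 0.005, len(b)), 0, 1)
    panel = [f"cg{j:03d}" for j in range(8)]
    pruned = collinearity_prune(panel, train, prune_r=0.8)

    # hand-worked greedy: walk ranks, keep a probe only if |r| <= 0.8
    # against every kept probe
    corr = np.corrcoef(b[panel].to_numpy(), rowvar=False)
    kept = []
    for i in range(len(panel)):
        if all(abs(corr[i, j]) <= 0.8 for j in kept):
            kept.append(i)
    assert pruned == [panel[i] for i in kept]
    assert "cg001" not in pruned and "cg000" in pruned

    # nothing correlated -> unchanged
    train2 = _cohort(rng, name="t2", n_probes=6)
    panel2 = list(train2.beta.columns)
    assert collinearity_prune(panel2, train2, prune_r=0.95) == panel2
    with pytest.raises(ValueError):
        collinearity_prune([], train2)


def test_biotype_refine_selects_per_biotype_separators():
    """Three complementary probes separate G1 and three separate G2 (each
    covers a different third of its biotype's cases); all six survive the
    refinement in at least 90% of seeded draws."""

    def cohort(r, name):
        n_cases, n_ctrl, n_probes = 42, 40, 18
        n = n_cases + n_ctrl
        ids = [f"{name}S{i}" for i in range(n)]
        case = pd.Series([True] * n_cases + [False] * n_ctrl, index=ids)
        x = r.normal(0.5, 0.05, size=(n, n_probes))
        biotype = pd.Series([""] * n, index=ids)
        biotype.iloc[:21] = "G1"
        biotype.iloc[21:42] = "G2"
        for k in range(3):
            x[np.arange(7 * k, 7 * (k + 1)), k] += 0.35
            x[np.arange(21 + 7 * k, 21 + 7 * (k + 1)), 3 + k] += 0.35
        beta = pd.DataFrame(np.clip(x, 0.001, 0.999), index=ids,
                            columns=[f"cg{j:03d}" for j in range(n_probes)])
        return Cohort(beta=beta, case=case, biotype=biotype, name=name)

    hits = 0
    n_rep = 20
    for s in range(n_rep):
        r = np.random.default_rng(1000 + s)
        train = cohort(r, "tr")
        val = cohort(r, "v")
        refined = biotype_refine(list(train.beta.columns), train, [val],
                                 tol=0.005)
        hits += set(f"cg{j:03d}" for j in range(6)) <= set(refined)
    assert hits / n_rep >= 0.9


def test_biotype_refine_single_perfect_probe(rng):
    train = _cohort(rng, n_cases=30, n_ctrl=30, n_probes=10,
                    name="tr", biotype_split=True)
    val = _cohort(rng, n_cases=30, n_ctrl=30, n_probes=10,
                  name="v", biotype_split=True)
    for c in (train, val):
        c.beta["cg000"] = np.where(c.case, 0.9, 0.1)
    refined = biotype_refine(list(train.beta.columns), train, [val])
    assert refined == ["cg000"]

    # stopping-rule guarantee: refined objective within tol of full panel
    def objective(subset):
        return np.mean([evaluate_panel(subset, train, val, case_filter=b)["auc"]
                        for b in ("G1", "G2")])
    assert objective(refined) >= objective(list(train.beta.columns)) - 0.005

    naked = _cohort(rng, name="x", biotype_split=False)
    with pytest.raises(ValueError, match="biotype"):
        biotype_refine(["cg000"], train, [naked])


def test_evaluate_panel_metrics(rng):
    train = _cohort(rng, n_probes=5, name="tr")
    test = _cohort(rng, n_probes=5, name="te")
    for c in (train, test):
        c.beta["cg000"] = np.where(c.case, 0.9, 0.1)
    out = evaluate_panel(["cg000"], train, test)
    assert out["auc"] == 1.0
    assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    # biotype-filtered contrast keeps all controls
    test_b = _cohort(rng, n_cases=30, n_ctrl=30, n_probes=5, name="tb",
                     biotype_split=True)
    test_b.beta["cg000"] = np.where(test_b.case, 0.9, 0.1)
    out = evaluate_panel(["cg000"], train, test_b, case_filter="G2")
    assert out["n_cases"] == 15 and out["n_controls"] == 30

    single = _cohort(rng, n_cases=0, n_ctrl=20, n_probes=5, name="sc")
    with pytest.raises(ValueError, match="single class"):
        evaluate_panel(["cg000"], train, single)


def test_auc_equals_mann_whitney_concordance(rng):
    """Trapezoidal ROC AUC equals pairwise concordance (ties count 1/2)."""
    train = _cohort(rng, n_cases=15, n_ctrl=15, n_probes=4,
                    separators=(0,), effect=0.15, name="tr")
    test = _cohort(rng, n_cases=15, n_ctrl=15, n_probes=4,
                   separators=(0,), effect=0.15, name="te")
    # introduce ties in the decision scores through duplicated rows
    test.beta.iloc[1] = test.beta.iloc[0]
    out = evaluate_panel(["cg000", "cg001"], train, test)

    from methbiotype.panel import _fit_lsvm, _scores
    coef, intercept, _, _ = _fit_lsvm(
        train.beta[["cg000", "cg001"]].to_numpy(), train.case.to_numpy())
    scores = _scores(coef, intercept, test.beta[["cg000", "cg001"]].to_numpy())
    labels = test.case.to_numpy()
    conc = 0.0
    pairs = 0
    for sc in scores[labels]:
        for sn in scores[~labels]:
            pairs += 1
            conc += 1.0 if sc > sn else (0.5 if sc == sn else 0.0)
    assert out["auc"] == pytest.approx(conc / pairs, abs=1e-12)

    # AUC is invariant to monotone transforms of the scores
    from sklearn.metrics import roc_auc_score
    assert roc_auc_score(labels, scores) == pytest.approx(
        roc_auc_score(labels, np.tanh(scores / 5.0)), abs=1e-12)


def test_null_scores_give_chance_auc(rng):
    aucs = []
    for s in range(30):
        r = np.random.default_rng(s)
        train = _cohort(r, n_cases=40, n_ctrl=40, n_probes=6, name="tr")
        test = _cohort(r, n_cases=40, n_ctrl=40, n_probes=6, name="te")
        aucs.append(evaluate_panel(list(train.beta.columns), train, test)["auc"])
    se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.02
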