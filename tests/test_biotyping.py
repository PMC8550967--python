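"""LDA boundary, closed-form biotype score, and clinical comparisons."""

import numpy as np
import pandas as pd
import pytest

from methbiotype.biotyping import (BiotypeModel, assign_biotype, biotype_score,
                                   compare_clinical_by_biotype,
                                   fit_lda_boundary, ternary_coordinates)
from methbiotype.correlates import fit_cca, fit_pca


def _latent(rng, mu0, mu1, n0=60, n1=60, cov=None):
    cov = np.eye(2) if cov is None else cov
    z0 = rng.multivariate_normal(mu0, cov, size=n0)
    z1 = rng.multivariate_normal(mu1, cov, size=n1)
    lat = pd.DataFrame(np.vstack([z0, z1]), columns=["x", "y"],
                       index=[f"S{i}" for i in range(n0 + n1)])
    flags = pd.Series([False] * n0 + [True] * n1, index=lat.index)
    return lat, flags


def _dummy_chain(rng, n_regions=12, n=120):
    regions = pd.DataFrame(
        rng.normal(0.5, 0.05, size=(n, n_regions)),
        columns=[f"R{i}" for i in range(n_regions)],
        index=[f"S{i}" for i in range(n)],
    )
    pca = fit_pca(regions, n_pcs=4)
    clin = pd.DataFrame(rng.normal(size=(n, 6)),
                        columns=[f"c{i}" for i in range(6)], index=regions.index)
    pca_c = fit_pca(clin, n_pcs=3, standardize=True)
    cca = fit_cca(pca.transform(regions), pca_c.transform(clin), n_pairs=2)
    return regions, pca, cca


def test_lda_normal_matches_closed_form(rng):
    cov = np.array([[1.0, 0.3], [0.3, 2.0]])
    lat, flags = _latent(rng, [0.0, 0.0], [2.0, 1.0], cov=cov)
    regions, pca, cca = _dummy_chain(rng)
    model = fit_lda_boundary(lat, flags, pca, cca)

    z = lat.to_numpy()
    mu0 = z[~flags].mean(axis=0)
    mu1 = z[flags].mean(axis=0)
    s0 = np.cov(z[~flags], rowvar=False) * (len(z[~flags]) - 1)
    s1 = np.cov(z[flags], rowvar=False) * (len(z[flags]) - 1)
    pooled = (s0 + s1) / (len(z) - 2)
    oracle = np.linalg.solve(pooled, mu0 - mu1)
    oracle /= np.linalg.norm(oracle)
    assert np.allclose(model.normal, oracle, atol=1e-10)
    # control mean scores positive; case-distinct side negative
    assert model.latent_score(lat)[~flags].mean() > 0
    assert model.latent_score(lat)[flags].mean() < 0


def test_lda_isotropic_boundary_is_perpendicular_bisector(rng):
    lat, flags = _latent(rng, [-1.0, 0.0], [1.0, 0.0], n0=4000, n1=4000)
    regions, pca, cca = _dummy_chain(rng)
    model = fit_lda_boundary(lat, flags, pca, cca)
    # normal parallel to the mean difference for (near-)isotropic clusters
    mu_diff = lat[flags].mean() - lat[~flags].mean()
    cosine = abs(model.normal @ mu_diff / np.linalg.norm(mu_diff))
    assert cosine > 0.99


def test_label_swap_flips_normal_and_preserves_magnitude(rng):
    lat, flags = _latent(rng, [0.0, 0.0], [1.5, 0.5])
    regions, pca, cca = _dummy_chain(rng)
    m1 = fit_lda_boundary(lat, flags, pca, cca)
    m2 = fit_lda_boundary(lat, ~flags, pca, cca)
    assert np.allclose(m1.normal, -m2.normal, atol=1e-10)
    s1 = m1.latent_score(lat)
    s2 = m2.latent_score(lat)
    assert np.allclose(np.abs(s1), np.abs(s2), atol=1e-10)


def test_score_sign_rule_and_tie():
    model = BiotypeModel(normal=np.array([1.0, 0.0]), latent_intercept=0.0,
                         region_ids=["R0", "R1"],
                         region_means=np.array([0.5, 0.5]),
                         weights=np.array([1.0, 0.0]), intercept=0.0)
    regions = pd.DataFrame({"R0": [0.2, 0.8, 0.5], "R1": [0.5, 0.5, 0.5]},
                           index=["a", "b", "c"])
    out = assign_biotype(model, regions)
    assert out.loc["a", "biotype"] == "G2"       # score -0.3
    assert out.loc["b", "biotype"] == "G1"       # score +0.3
    assert out.loc["c", "biotype"] == "G1"       # score 0 is "otherwise"
    # doubling the centered region vector doubles the score
    doubled = 0.5 + 2 * (regions - 0.5)
    assert np.allclose(biotype_score(model, doubled), 2 * out["biotype_score"])


def test_weighted_sum_equals_staged_projection(rng, small_cohort):
    """Closed-form weights reproduce the explicit PCA -> CCA -> LDA path."""
    cfg, beta, annot, clinical, truth = small_cohort
    from methbiotype.preprocessing import collapse_regions, filter_probes
    from methbiotype.correlates import project_latent

    regions = collapse_regions(filter_probes(beta, annot), annot)
    sub = regions.values.iloc[:, :40]
    pca = fit_pca(sub, n_pcs=4)
    clin = clinical[["caps_b", "caps_c", "bdi", "pcl", "msc", "psqi"]]
    pca_c = fit_pca(clin, n_pcs=3, standardize=True)
    cca = fit_cca(pca.transform(sub), pca_c.transform(clin), n_pairs=2)
    latent = project_latent(pca, cca, sub)
    flags = clinical["diagnosis"] != "control"
    model = fit_lda_boundary(latent, flags, pca, cca)

    direct = biotype_score(model, sub)
    staged = model.latent_score(latent)
    assert np.abs(direct - staged).max() < 1e-10

    # scoring 50 perturbed region vectors agrees as well
    noise = rng.normal(0, 0.02, size=(50, sub.shape[1]))
    pert = pd.DataFrame(sub.to_numpy()[:50] + noise, columns=sub.columns,
                        index=[f"P{i}" for i in range(50)])
    lat_p = project_latent(pca, cca, pert)
    assert np.abs(biotype_score(model, pert)
                  - model.latent_score(lat_p)).max() < 1e-10


def test_missing_region_raises():
    model = BiotypeModel(normal=np.array([1.0, 0.0]), latent_intercept=0.0,
                         region_ids=["R0", "R1"],
                         region_means=np.zeros(2),
                         weights=np.ones(2), intercept=0.0)
    regions = pd.DataFrame({"R0": [0.5]})
    with pytest.raises(KeyError, match="R1"):
        biotype_score(model, regions)


def test_controls_unlabeled_unless_requested():
    model = BiotypeModel(normal=np.array([1.0, 0.0]), latent_intercept=0.0,
                         region_ids=["R0"], region_means=np.array([0.5]),
                         weights=np.array([1.0]), intercept=0.0)
    regions = pd.DataFrame({"R0": [0.2, 0.8]}, index=["case", "ctrl"])
    flags = pd.Series([True, False], index=regions.index)
    out = assign_biotype(model, regions, case_flags=flags)
    assert out.loc["case", "biotype"] == "G2"
    assert out.loc["ctrl", "biotype"] == ""
    out2 = assign_biotype(model, regions, case_flags=flags, include_controls=True)
    assert out2.loc["ctrl", "biotype"] == "G1"


def test_model_json_roundtrip(tmp_path):
    model = BiotypeModel(normal=np.array([-0.9, 0.2]), latent_intercept=0.3,
                         region_ids=["R0", "R1"],
                         region_means=np.array([0.4, 0.6]),
                         weights=np.array([1.5, -2.0]), intercept=0.25)
    model.to_json(tmp_path / "m.json")
    back = BiotypeModel.from_json(tmp_path / "m.json")
    regions = pd.DataFrame({"R0": [0.3, 0.7], "R1": [0.5, 0.9]})
    assert np.allclose(biotype_score(model, regions),
                       biotype_score(back, regions))


# ---------------------------------------------------------------------------
# clinical comparisons


def _assignment(rng, n=60):
    idx = [f"S{i}" for i in range(n)]
    labels = ["G1"] * (n // 2) + ["G2"] * (n - n // 2)
    return pd.DataFrame({"biotype_score": rng.normal(size=n),
                         "biotype": labels}, index=idx)


def test_orthogonal_covariates_recover_raw_difference(rng):
    assignment = _assignment(rng)
    n = len(assignment)
    g2 = (assignment["biotype"] == "G2").to_numpy().astype(float)
    # covariates exactly orthogonal to the (centered) biotype indicator
    raw = rng.normal(size=(n, 2))
    ind = g2 - g2.mean()
    cov = raw - np.outer(ind, ind @ raw / (ind @ ind))
    cov = cov - cov.mean(axis=0)
    clinical = pd.DataFrame({"bmi": cov[:, 0], "age": cov[:, 1],
                             "feat": 2.0 * g2 + rng.normal(size=n)},
                            index=assignment.index)
    out = compare_clinical_by_biotype(assignment, clinical, ["feat"])
    raw_diff = (clinical.loc[assignment["biotype"] == "G2", "feat"].mean()
                - clinical.loc[assignment["biotype"] == "G1", "feat"].mean())
    assert out.loc["feat", "effect"] == pytest.approx(raw_diff, abs=1e-10)


def test_bh_adjustment_matches_hand_computation(rng):
    assignment = _assignment(rng, n=40)
    n = len(assignment)
    g2 = (assignment["biotype"] == "G2").astype(float).to_numpy()
    clinical = pd.DataFrame(rng.normal(size=(n, 2)), columns=["bmi", "age"],
                            index=assignment.index)
    # four features engineered to give a known p-value *ordering*; the BH
    # identity itself is checked on the exact p-values the model produced
    for j, strength in enumerate((2.0, 0.9, 0.6, 0.0)):
        clinical[f"feat{j}"] = strength * g2 + rng.normal(size=n)
    out = compare_clinical_by_biotype(assignment, clinical,
                                      [f"feat{j}" for j in range(4)])
    p = out["p_value"].to_numpy()
    m = len(p)
    order = np.argsort(p)
    hand = np.empty(m)
    running = 1.0
    for rank_from_last, i in enumerate(order[::-1]):
        k = m - rank_from_last
        running = min(running, p[i] * m / k)
        hand[i] = running
    assert np.allclose(out["fdr"].to_numpy(), hand, atol=1e-12)

    # the documented worked example
    ps = np.array([0.001, 0.02, 0.04, 0.9])
    from statsmodels.stats.multitest import multipletests
    fdr = multipletests(ps, method="fdr_bh")[1]
    assert np.allclose(fdr, [0.004, 0.04, 0.04 * 4 / 3, 0.9])


def test_constant_feature_flagged_degenerate(rng):
    assignment = _assignment(rng, n=30)
    clinical = pd.DataFrame({
        "bmi": rng.normal(size=30), "age": rng.normal(size=30),
        "flat": np.ones(30)}, index=assignment.index)
    out = compare_clinical_by_biotype(assignment, clinical, ["flat"])
    assert bool(out.loc["flat", "degenerate"]) is True
    assert out.loc["flat", "p_value"] == 1.0
    assert out.loc["flat", "effect"] == 0.0


def test_ternary_coordinates(rng):
    n = 200
    # columns exactly uncorrelated (orthogonal to each other and to the
    # intercept) via QR with a leading ones column
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 4))]))
    q = q[:, 1:]
    clinical = pd.DataFrame({
        "caps_b": q[:, 0], "caps_c": q[:, 1], "caps_d": q[:, 2],
        "copy_d": q[:, 2],                 # exact copy of CAPS-D
        "mix": q[:, 0] + q[:, 1],
        "noise": q[:, 3],
    })
    out = ternary_coordinates(clinical, ["copy_d", "mix", "noise"])
    assert out.loc["copy_d", "caps_d"] == pytest.approx(1.0, abs=1e-10)
    assert out.loc["copy_d", "caps_b"] == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(out[["caps_b", "caps_c", "caps_d"]].sum(axis=1), 1.0)

    # brute-force oracle on every feature
    for f in ("copy_d", "mix", "noise"):
        rs = [abs(np.corrcoef(clinical[f], clinical[c])[0, 1])
              for c in ("caps_b", "caps_c", "caps_d")]
        expected = np.array(rs) / sum(rs)
        assert np.allclose(out.loc[f, ["caps_b", "caps_c", "caps_d"]].to_numpy(),
                           expected)


def test_score_severity_association_is_negative(discovery_cohort,
                                                discovery_fit):
    """Planted severity raises the G2-ward displacement, and G2 scores are
    negative under the score<0 convention, so among cases the biotype score
    anti-correlates with the severity total."""
    cfg, beta, annot, clinical, truth = discovery_cohort
    _, result = discovery_fit
    cases = truth.labels.index[truth.labels != "control"]
    r = np.corrcoef(result.assignments.loc[cases, "biotype_score"],
                    clinical.loc[cases, "caps_total"])[0, 1]
    assert r < -0.3
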