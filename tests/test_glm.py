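"""GLM normalization: closed forms, likelihood oracles, Z contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphostat as ms
from morphostat.glm import GLMError, fit_parameter_glm, gaussian_design_batch

from conftest import small_gaussian_specs


def test_identical_groups_coefficient_and_z_zero():
    fit = fit_parameter_glm([1, 1, 1, 1, 1, 1], ["A"] * 3 + ["B"] * 3,
                            "gaussian", reference="A")
    assert fit.coefficients["strain[B]"] == 0.0
    assert fit.degenerate
    assert fit.wald_z("B", "A") == 0.0


def test_gaussian_closed_form():
    """The gaussian path reduces to OLS: coefficient = mean(B) - mean(A)."""
    fit = fit_parameter_glm([1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3,
                            "gaussian", reference="A")
    assert fit.coefficients["Intercept"] == pytest.approx(2.0, abs=1e-12)
    assert fit.coefficients["strain[B]"] == pytest.approx(3.0, abs=1e-12)
    # OLS covariance: sigma2 * (1/3 + 1/3) for the contrast
    sigma2 = fit.scale
    assert fit.covariance.loc["strain[B]", "strain[B]"] == pytest.approx(
        sigma2 * (2 / 3), abs=1e-12
    )


def test_gaussian_matches_lstsq_oracle(rng):
    """Multi-strain gaussian fits agree with a hand-rolled least-squares
    oracle to 1e-10."""
    labels = np.repeat(["A", "B", "C", "D"], 7)
    y = rng.normal(size=labels.size) + np.repeat([0.0, 1.0, -2.0, 0.5], 7)
    fit = fit_parameter_glm(y, labels, "gaussian", reference="A")
    X = np.column_stack(
        [np.ones(labels.size)] + [(labels == s).astype(float)
                                  for s in ("B", "C", "D")]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, atol=1e-10)


def test_gamma_grid_search_likelihood_oracle(rng):
    """Gamma/log-link coefficient matches a brute-force likelihood grid.

    For a one-way gamma GLM the mean-structure score equations do not
    involve the shape, so the grid fixes shape at its simulation value and
    maximizes the exact log-likelihood over (intercept, shift)."""
    shape = 10.0
    b0, b1 = 0.2, 0.7
    n = 200
    y = np.concatenate([
        rng.gamma(shape, np.exp(b0) / shape, size=n),
        rng.gamma(shape, np.exp(b0 + b1) / shape, size=n),
    ])
    labels = np.array(["A"] * n + ["B"] * n)
    fit = fit_parameter_glm(y, labels, "gamma", reference="A")

    g0 = np.linspace(b0 - 0.5, b0 + 0.5, 201)
    g1 = np.linspace(b1 - 0.5, b1 + 0.5, 201)
    G0, G1 = np.meshgrid(g0, g1, indexing="ij")
    mu_a = np.exp(G0)[..., None]
    mu_b = np.exp(G0 + G1)[..., None]
    ll = (
        stats.gamma.logpdf(y[:n], a=shape, scale=mu_a / shape).sum(axis=-1)
        + stats.gamma.logpdf(y[n:], a=shape, scale=mu_b / shape).sum(axis=-1)
    )
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    step = g0[1] - g0[0]
    assert fit.coefficients["Intercept"] == pytest.approx(g0[i], abs=2 * step)
    assert fit.coefficients["strain[B]"] == pytest.approx(g1[j], abs=2 * step)
    assert fit.coefficients["strain[B]"] == pytest.approx(b1, abs=0.05)


def test_support_violation_named():
    with pytest.raises(GLMError, match="support"):
        fit_parameter_glm([1.0, -0.5, 2.0, 1.0], ["A", "A", "B", "B"],
                          "gamma", reference="A")


def _two_strain_data(d=1.0, n=50, seed=0):
    design = ms.study_design(backgrounds=("A", "B"), steps=(),
                             reference="A")
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(2 * n)], name="sample")
    vals = pd.DataFrame(
        {"C101_A": np.concatenate([rng.normal(0, 1, n),
                                   rng.normal(d, 1, n)])}, index=idx)
    strains = pd.Series(["A"] * n + ["B"] * n, index=idx, name="strain")
    return ms.MorphologyMatrix(vals, strains), design


def test_per_strain_z_two_sample_closed_form():
    """Per-strain Wald Z equals the pooled two-sample Z computed by hand,
    and approximates d / (sigma sqrt(2/n)) for a planted shift."""
    data, design = _two_strain_data(d=1.0, n=50, seed=42)
    z = ms.compute_z_matrix(data, design, {"C101_A": "gaussian"},
                            mode="per_strain")
    y = data.values["C101_A"]
    g = data.strains
    ya, yb = y[g == "A"], y[g == "B"]
    sp2 = ((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()
    sp2 /= len(y) - 2
    oracle = (yb.mean() - ya.mean()) / np.sqrt(sp2 * (2 / 50))
    assert z.values.loc["B", "C101_A"] == pytest.approx(oracle, abs=1e-10)
    assert z.values.loc["A", "C101_A"] == 0.0
    # planted d=1, sigma=1, n=50 -> Z ~ 5 up to sampling noise
    assert abs(z.values.loc["B", "C101_A"] - 5.0) < 3.0


def test_z_scale_equivariance():
    """Scaling a gaussian parameter by c > 0 leaves Z unchanged."""
    data, design = _two_strain_data(seed=7)
    scaled = ms.MorphologyMatrix(data.values * 3.7, data.strains)
    for mode in ("per_strain", "per_replicate"):
        z1 = ms.compute_z_matrix(data, design, {"C101_A": "gaussian"},
                                 mode=mode)
        z2 = ms.compute_z_matrix(scaled, design, {"C101_A": "gaussian"},
                                 mode=mode)
        np.testing.assert_allclose(z1.values.to_numpy(),
                                   z2.values.to_numpy(), atol=1e-10)


def test_per_strain_shape_and_reference_column(two_bg_design):
    specs = small_gaussian_specs(3)
    data = ms.generate_morphology(
        specs, two_bg_design, {s: 5 for s in two_bg_design.strains}, seed=3)
    z = ms.compute_z_matrix(data, two_bg_design, ms.family_map(specs),
                            mode="per_strain")
    assert list(z.values.index) == list(two_bg_design.strains)
    assert (z.values.loc["K7"] == 0).all()


def test_per_replicate_reference_rows_centered(two_bg_design):
    """In global-reference mode the reference strain's per-replicate Z
    averages to exactly 0 for gaussian parameters (intercept definition)."""
    specs = small_gaussian_specs(2)
    data = ms.generate_morphology(
        specs, two_bg_design, {s: 6 for s in two_bg_design.strains}, seed=9)
    z = ms.compute_z_matrix(data, two_bg_design, ms.family_map(specs))
    ref_rows = z.values.loc[(z.strains == "K7").to_numpy()]
    assert np.abs(ref_rows.mean()).max() < 1e-12


def test_parent_baseline_mode(two_bg_design):
    """Parent-mode per-strain Z contrasts each strain with its parent;
    originals are their own baseline (Z = 0)."""
    specs = small_gaussian_specs(1)
    eff = ms.PlantedEffects([("K6GE01", "C101_A", 5.0)])
    data = ms.generate_morphology(
        specs, two_bg_design, {s: 30 for s in two_bg_design.strains},
        eff, seed=11)
    z = ms.compute_z_matrix(data, two_bg_design, ms.family_map(specs),
                            mode="per_strain", baseline="parent_strain")
    col = z.values["C101_A"]
    assert col["K6"] == 0.0 and col["K7"] == 0.0
    assert col["K6GE01"] > 5.0          # strong planted shift
    assert abs(col["K6GE21"]) < 4.0     # inherited, so no parent contrast


def test_degenerate_parameter_excluded(two_bg_design):
    specs = small_gaussian_specs(2)
    data = ms.generate_morphology(
        specs, two_bg_design, {s: 4 for s in two_bg_design.strains}, seed=2)
    data.values["C102_A"] = 1.0
    z = ms.compute_z_matrix(data, two_bg_design, ms.family_map(specs))
    assert z.excluded == ("C102_A",)
    assert z.values["C102_A"].isna().all()
    assert "C102_A" not in z.usable().columns


def test_null_per_strain_z_standard_normal():
    """Under the null, per-strain Wald Z across many independent gaussian
    parameters follows N(0,1) (Kolmogorov-Smirnov)."""
    design = ms.study_design(backgrounds=("A", "B"), steps=(),
                             reference="A")
    specs = small_gaussian_specs(500)
    data = ms.generate_morphology(
        specs, design, {"A": 50, "B": 50}, seed=20)
    z = ms.compute_z_matrix(data, design, ms.family_map(specs),
                            mode="per_strain")
    zs = z.values.loc["B"].to_numpy()
    assert stats.kstest(zs, "norm").pvalue > 0.01


def test_gaussian_design_batch_matches_per_parameter(full_design, rng):
    """The vectorized gaussian design fit equals fit_design_glm per column."""
    labels = np.repeat(list(full_design.strains), 3)
    X = full_design.design_matrix(labels)
    Y = pd.DataFrame(rng.normal(size=(len(labels), 4)),
                     columns=list("abcd"))
    coefs, zdf, lrt, lrt_p = gaussian_design_batch(Y, X)
    for c in Y.columns:
        fit = ms.fit_design_glm(Y[c].to_numpy(), X, "gaussian")
        np.testing.assert_allclose(coefs.loc[c].to_numpy(),
                                   fit.params.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(zdf.loc[c].to_numpy(),
                                   fit.z.to_numpy(), atol=1e-8)
        assert lrt[c] == pytest.approx(fit.lrt_stat, abs=1e-8)


def test_binomial_trials_tighten_inference():
    """With known trial counts the Wald SE reflects p(1-p)/m sampling."""
    rng = np.random.default_rng(3)
    m = 200
    pa, pb = 0.3, 0.45
    y = np.concatenate([rng.binomial(m, pa, 40) / m,
                        rng.binomial(m, pb, 40) / m])
    labels = np.array(["A"] * 40 + ["B"] * 40)
    fit = fit_parameter_glm(y, labels, "binomial", reference="A", trials=m)
    true_shift = np.log(pb / (1 - pb)) - np.log(pa / (1 - pa))
    est, se = fit.contrast("B", "A")
    assert est == pytest.approx(true_shift, abs=3 * se)
    assert se < 0.2


def test_beta_fit_recovers_logit_shift():
    rng = np.random.default_rng(8)
    phi = 50.0
    mu_a, mu_b = 0.3, 0.45
    ya = rng.beta(mu_a * phi, (1 - mu_a) * phi, 150)
    yb = rng.beta(mu_b * phi, (1 - mu_b) * phi, 150)
    fit = fit_parameter_glm(np.concatenate([ya, yb]),
                            np.array(["A"] * 150 + ["B"] * 150),
                            "beta", reference="A")
    truth = np.log(mu_b / (1 - mu_b)) - np.log(mu_a / (1 - mu_a))
    est, se = fit.contrast("B", "A")
    assert fit.converged
    assert est == pytest.approx(truth, abs=3 * se)
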