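"""Synthetic-data generator: determinism, family support, planted effects."""

import io as _io

import numpy as np
import pytest

import morphostat as ms
from morphostat.simulate import EffectError

from conftest import small_gaussian_specs


def _mixed_specs():
    return [
        ms.ParameterSpec("C101_A", "gaussian", 0.0, 1.0, 0),
        ms.ParameterSpec("C102_A", "gaussian", 2.0, 4.0, 0),
        ms.ParameterSpec("D101_A", "gamma", 1.5, 10.0, 1),
        ms.ParameterSpec("D102_A", "gamma", 0.5, 30.0, None),
        ms.ParameterSpec("A101_A", "beta", 0.3, 40.0, None),
        ms.ParameterSpec("A201_C", "binomial", 0.4, 50.0, None),
    ]


def test_parameter_spec_invariants():
    with pytest.raises(ValueError):
        ms.ParameterSpec("x", "beta", 1.2, 10.0)
    with pytest.raises(ValueError):
        ms.ParameterSpec("x", "gamma", -1.0, 10.0)
    with pytest.raises(ValueError):
        ms.ParameterSpec("x", "gaussian", 0.0, 0.0)
    with pytest.raises(ValueError):
        ms.ParameterSpec("x", "binomial", 0.4, 0.5)  # trials < 1
    with pytest.raises(ValueError):
        ms.ParameterSpec("x", "weibull", 1.0, 1.0)


def test_determinism_byte_identical(two_bg_design):
    reps = {s: 3 for s in two_bg_design.strains}
    out = []
    for _ in range(2):
        data = ms.generate_morphology(
            _mixed_specs(), two_bg_design, reps,
            ms.PlantedEffects([("K6GE01", "C101_A", 1.0)]),
            block_correlation=0.4, seed=77,
        )
        buf = _io.StringIO()
        ms.write_morphology(data, buf)
        out.append(buf.getvalue())
    assert out[0] == out[1]


def test_family_support(two_bg_design):
    reps = {s: 20 for s in two_bg_design.strains}
    data = ms.generate_morphology(_mixed_specs(), two_bg_design, reps, seed=3)
    v = data.values
    assert (v["D101_A"] > 0).all() and (v["D102_A"] > 0).all()
    assert ((v["A101_A"] > 0) & (v["A101_A"] < 1)).all()
    # binomial proportions are multiples of 1/trials inside [0, 1]
    counts = v["A201_C"] * 50
    assert np.allclose(counts, np.round(counts))
    assert ((v["A201_C"] >= 0) & (v["A201_C"] <= 1)).all()


def test_null_case_column_mean(two_bg_design):
    reps = {s: 1000 for s in two_bg_design.strains}
    data = ms.generate_morphology(small_gaussian_specs(1), two_bg_design,
                                  reps, seed=9)
    assert abs(data.values["C101_A"].mean()) < 0.05


def test_planted_shift_sample_mean_oracle():
    """A +2.0 identity-link shift on strain B is recovered by the group
    sample-mean difference within Monte-Carlo error at n = 1000."""
    d = ms.study_design(backgrounds=("A", "B"), steps=("GE01",),
                        reference="A")
    reps = {s: 1000 for s in d.strains}
    eff = ms.PlantedEffects([("B", "C101_A", 2.0)])
    data = ms.generate_morphology(small_gaussian_specs(1), d, reps, eff,
                                  seed=21)
    means = data.values["C101_A"].groupby(data.strains).mean()
    # MC error of a mean difference: sqrt(2/1000) ~ 0.045; use 4 sigma
    assert means["B"] - means["A"] == pytest.approx(2.0, abs=0.18)


def test_effect_inheritance(full_design):
    """A shift planted at GE21 appears in GE21/GE31/GE41 of the same
    background and nowhere else."""
    reps = {s: 200 for s in full_design.strains}
    eff = ms.PlantedEffects([("K6GE21", "C101_A", 3.0)])
    data = ms.generate_morphology(small_gaussian_specs(1), full_design,
                                  reps, eff, seed=5)
    means = data.values["C101_A"].groupby(data.strains).mean()
    shifted = {"K6GE21", "K6GE31", "K6GE41"}
    for s in full_design.strains:
        target = 3.0 if s in shifted else 0.0
        assert means[s] == pytest.approx(target, abs=0.35), s


def test_block_correlation(two_bg_design):
    reps = {s: 400 for s in two_bg_design.strains}
    specs = small_gaussian_specs(4, block_id=7)
    data = ms.generate_morphology(specs, two_bg_design, reps,
                                  block_correlation=0.5, seed=13)
    corr = data.values.corr().to_numpy()
    off = corr[np.triu_indices_from(corr, k=1)]
    assert np.all(np.abs(off - 0.5) < 0.07)


def test_blocks_preserve_marginals_nonblocked_independent(two_bg_design):
    reps = {s: 400 for s in two_bg_design.strains}
    specs = small_gaussian_specs(2) + [
        ms.ParameterSpec("C901_A", "gaussian", 0.0, 1.0, 1)
    ]
    data = ms.generate_morphology(specs, two_bg_design, reps,
                                  block_correlation=0.6, seed=13)
    r = data.values.corr().iloc[0, 1]
    assert abs(r) < 0.08


def test_adding_parameter_does_not_perturb_existing(two_bg_design):
    reps = {s: 5 for s in two_bg_design.strains}
    a = ms.generate_morphology(small_gaussian_specs(2), two_bg_design,
                               reps, seed=4)
    b = ms.generate_morphology(small_gaussian_specs(3), two_bg_design,
                               reps, seed=4)
    assert a.values.equals(b.values[a.values.columns])


def test_effect_validation_errors(two_bg_design):
    reps = {s: 3 for s in two_bg_design.strains}
    with pytest.raises(EffectError):
        ms.generate_morphology(
            small_gaussian_specs(1), two_bg_design, reps,
            ms.PlantedEffects([("ghost", "C101_A", 1.0)]), seed=0,
        )
    with pytest.raises(EffectError):
        ms.generate_morphology(
            small_gaussian_specs(1), two_bg_design, reps,
            ms.PlantedEffects([("K6", "nope", 1.0)]), seed=0,
        )
    with pytest.raises(EffectError):
        ms.PlantedEffects([("K6", "C101_A", 1.0), ("K6", "C101_A", 2.0)])


def test_beta_mean_outside_unit_interval_rejected(two_bg_design):
    reps = {s: 3 for s in two_bg_design.strains}
    specs = [ms.ParameterSpec("A101_A", "beta", 0.5, 10.0)]
    eff = ms.PlantedEffects([("K6", "A101_A", 60.0)])  # expit saturates to 1.0
    with pytest.raises(EffectError):
        ms.generate_morphology(specs, two_bg_design, reps, eff, seed=0)


def test_replicate_minimum_enforced(two_bg_design):
    reps = {s: 2 for s in two_bg_design.strains}
    reps["K6"] = 1
    with pytest.raises(ValueError):
        ms.generate_morphology(small_gaussian_specs(1), two_bg_design,
                               reps, seed=0)


def test_default_census_counts():
    specs = ms.default_parameter_specs()
    assert len(specs) == 501
    fams = [sp.family for sp in specs]
    assert fams.count("gaussian") == 254
    assert fams.count("gamma") == 123
    assert fams.count("beta") == 93
    assert fams.count("binomial") == 31
    assert len({sp.name for sp in specs}) == 501


# -- component tables -------------------------------------------------------


def test_components_study_shape(full_design):
    strains = full_design.originals() + [
        full_design.strain_at(bg, "GE41") for bg in full_design.backgrounds()
    ]
    table = ms.generate_components(full_design, strains=strains, seed=2)
    assert table.values.shape == (24, 21)  # 8 strains x 3 samples
    assert table.strains.nunique() == 8


def test_components_zero_noise_identical_rows(two_bg_design):
    table = ms.generate_components(two_bg_design, n_components=3,
                                   noise_sd=0.0, seed=1)
    per_strain = table.values.groupby(table.strains, sort=False).nunique()
    assert (per_strain == 1).all().all()


def test_components_planted_shift_recovered(two_bg_design):
    eff = ms.PlantedEffects([("K6", "comp01", 4.0)])
    table = ms.generate_components(two_bg_design, replicates=200,
                                   effects=eff, noise_sd=1.0, seed=8)
    means = table.values["comp01"].groupby(table.strains).mean()
    assert means["K6"] - means["K7"] == pytest.approx(4.0, abs=0.4)


def test_components_deterministic(two_bg_design):
    a = ms.generate_components(two_bg_design, seed=5)
    b = ms.generate_components(two_bg_design, seed=5)
    assert a.values.equals(b.values)
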