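"""Animal-model design construction and Gibbs-sampler correctness."""
import numpy as np
import pandas as pd
import pytest

import ssgblup as s
from ssgblup.animal_model import (
    Design,
    DesignBuilder,
    McmcConfig,
    ModelSpec,
    Priors,
    build_design,
    fit_animal_model,
    fit_gibbs,
)


def make_records(n, cg_labels, animals=None, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "animal": animals if animals is not None else np.arange(1, n + 1),
            "value": rng.normal(10, 2, n),
            "herd": 1,
            "birth_date": pd.Timestamp("2005-05-01"),
            "dam_age": rng.normal(1500, 100, n),
            "sex": rng.choice(["F", "M"], n),
            "cg": cg_labels,
        }
    )


# --------------------------- design ----------------------------------- #
def test_z1_incidence_structure():
    rec = make_records(3, ["g1", "g2", "g1"])
    design = build_design(rec, ModelSpec("BW"), delta_ids=[1, 2, 3])
    assert design.Z1.shape == (3, 2)
    assert np.all(design.Z1.sum(axis=1) == 1)
    assert design.X.shape[1] == len(design.builder.x_names)


def test_gblup_rejects_ungenotyped_phenotyped_animal():
    rec = make_records(3, ["g1", "g1", "g2"])
    with pytest.raises(s.DataError, match="absent"):
        build_design(rec, ModelSpec("BW", method="GBLUP"), delta_ids=[1, 2])


def test_z2_dimension_contract():
    rec = make_records(30, ["g1", "g2"] * 15)
    design = build_design(rec, ModelSpec("BW"), delta_ids=np.arange(1, 101))
    assert design.Z2.shape == (30, 100)
    assert np.all(design.Z2.sum(axis=1) == 1)


def test_unseen_cg_level_maps_to_zero_row():
    train = make_records(4, ["g1", "g1", "g2", "g2"])
    builder = DesignBuilder(("sex", "dam_age")).fit(train)
    test = make_records(2, ["g1", "g9"])
    _, z1 = builder.transform(test)
    assert z1[0].sum() == 1 and z1[1].sum() == 0


# --------------------------- sampler ---------------------------------- #
def test_toy_posterior_matches_closed_form():
    """One record, no fixed effects, fixed variances: the genetic value's
    posterior is N(y·k, v) with k = prec_e/(prec_e+prec_a)."""
    y = np.array([2.0])
    fit = fit_gibbs(
        y,
        np.zeros((1, 0)),
        np.zeros((1, 0)),
        np.ones((1, 1)),
        np.array([[1.0]]),
        McmcConfig(n_iterations=40_000, burn_in=500, thin=1, seed=3),
        Priors(fixed_variances=(2.0, None, 1.0)),
    )
    expect_mean = 2.0 * (1 / 1.0) / (1 / 1.0 + 1 / 2.0)
    assert fit.ebv.iloc[0] == pytest.approx(expect_mean, abs=0.02)


def test_chains_are_deterministic_in_the_seed():
    rng = np.random.default_rng(1)
    n = 40
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    Z1 = np.zeros((n, 2))
    Z1[np.arange(n), rng.integers(0, 2, n)] = 1
    delta = np.eye(n)
    args = (y, X, Z1, np.eye(n), delta)
    f1 = fit_gibbs(*args, McmcConfig(200, 100, 2, seed=9))
    f2 = fit_gibbs(*args, McmcConfig(200, 100, 2, seed=9))
    assert np.array_equal(f1.var_samples, f2.var_samples)
    assert np.array_equal(f1.ebv.to_numpy(), f2.ebv.to_numpy())
    f3 = fit_gibbs(*args, McmcConfig(200, 100, 2, seed=10))
    assert not np.array_equal(f1.var_samples, f3.var_samples)


def test_sample_count_contract():
    rng = np.random.default_rng(2)
    n = 10
    fit = fit_gibbs(
        rng.normal(size=n),
        np.ones((n, 1)),
        np.zeros((n, 0)),
        np.eye(n),
        np.eye(n),
        McmcConfig(n_iterations=1000, burn_in=100, thin=10, seed=0),
    )
    assert fit.n_samples == 100
    assert np.all(fit.var_samples > 0)


def test_no_signal_limit_shrinks_ebvs():
    """Data simulated with zero additive and CG variance: with real family
    structure the posterior pushes sigma_a well below the residual variance
    and EBVs shrink hard toward zero."""
    config = s.SimulationConfig(
        n_founders=150,
        n_generations=3,
        offspring_per_mating=2.2,
        sire_fraction=0.08,
        n_herds=3,
        year_range=(2000, 2004),
        n_markers=10,
        genotyped_fraction=0.2,
        variance_components=(0.0, 0.0, 1.0),
        fixed_effect_sizes={"intercept": 5.0},
        seed=7,
    )
    ped = s.simulate_pedigree(config)
    drop = s.gene_drop_genotypes(ped, config)
    rec = s.simulate_phenotypes(ped, config, drop.true_values)
    qc, _ = s.run_phenotype_qc(rec, ped, drop.genotyped_ids)
    a = s.tabular_a(ped)
    fit = fit_animal_model(
        build_design(qc, ModelSpec("BW"), a.ids),
        a,
        ModelSpec("BW"),
        McmcConfig(2000, 2000, 2, seed=0),
    )
    var_y = qc["value"].var(ddof=1)
    assert fit.var_mean["sigma_a"] < 0.2 * var_y
    assert fit.var_mean["sigma_a"] < fit.var_mean["sigma_e"] / 4
    max_dev = np.abs(qc["value"] - qc["value"].mean()).max()
    assert np.abs(fit.ebv.to_numpy()).max() < 0.25 * max_dev


def test_repeated_records_rejected():
    y = np.zeros(2)
    z2 = np.array([[1.0], [1.0]])
    with pytest.raises(s.DataError, match="repeated"):
        fit_gibbs(
            y, np.ones((2, 1)), np.zeros((2, 0)), z2, np.eye(1), McmcConfig(10, 0, 1)
        )


def test_method_delta_kind_consistency(small_sim):
    cfg, ped, drop, records = small_sim
    qc, _ = s.run_phenotype_qc(records, ped, drop.genotyped_ids)
    a = s.tabular_a(ped)
    spec = ModelSpec("BW", method="ssGBLUP")
    design = build_design(qc, spec, a.ids)
    with pytest.raises(s.ConfigError, match="requires"):
        fit_animal_model(design, a, spec, McmcConfig(10, 0, 1))


def test_ssgblup_equals_blup_without_genotyped_animals(small_sim):
    cfg, ped, drop, records = small_sim
    qc, _ = s.run_phenotype_qc(records, ped, drop.genotyped_ids)
    a = s.tabular_a(ped)
    ainv = s.a_inverse(ped)
    empty = s.extract_agg(a, [])
    h = s.h_from_h_inverse(s.assemble_h_inverse(ainv, empty, empty, []))
    # the single-step precision collapses to the pedigree precision exactly
    ainv_again = s.assemble_h_inverse(ainv, empty, empty, [])
    assert np.array_equal(ainv_again.values, ainv.values)
    # posterior agreement: H differs from the tabular A only by double-
    # precision inversion noise, which the chains amplify into Monte-Carlo
    # level (not bitwise) differences
    mcmc = McmcConfig(3000, 2000, 2, seed=21)
    fit_b = fit_animal_model(
        build_design(qc, ModelSpec("BW"), a.ids), a, ModelSpec("BW"), mcmc
    )
    fit_h = fit_animal_model(
        build_design(qc, ModelSpec("BW", method="ssGBLUP"), h.ids),
        h,
        ModelSpec("BW", method="ssGBLUP"),
        mcmc,
    )
    assert np.abs(h.values - a.values).max() < 1e-8
    eb, eh = fit_b.ebv.to_numpy(), fit_h.ebv.to_numpy()
    assert np.corrcoef(eb, eh)[0, 1] > 0.995
    # the EBV level rides on the slowly mixing intercept/genetic-mean
    # trade-off, so compare rankings after centring
    assert np.abs((eb - eb.mean()) - (eh - eh.mean())).max() < 0.3
    for key in ("sigma_a", "sigma_cg", "sigma_e"):
        assert fit_b.var_mean[key] == pytest.approx(fit_h.var_mean[key], rel=0.15)


# --------------------------- derived quantities ----------------------- #
def test_h2_and_share_identities():
    assert s.h2_from_components(0.0, 1.0, 1.0) == 0.0
    assert s.h2_from_components(2.0, 0.0, 0.0) == 1.0
    shares = s.shares_from_components(1.0, 1.0, 1.0)
    assert shares["sigma_a"] == pytest.approx(100 / 3)
    assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)
    assert s.h2_from_components(1.0, 1.0, 1.0) == pytest.approx(
        shares["sigma_a"] / 100.0
    )
    with pytest.raises(ZeroDivisionError):
        s.h2_from_components(0.0, 0.0, 0.0)


def test_single_replicate_parameter_recovery_smoke():
    """One mid-sized synthetic replicate lands in a loose band around the
    simulation truths (the full multi-replicate study is part of the
    acceptance suite)."""
    config = s.SimulationConfig(
        n_founders=120,
        n_generations=3,
        offspring_per_mating=2.2,
        sire_fraction=0.1,
        n_herds=4,
        year_range=(2000, 2003),
        n_markers=60,
        genotyped_fraction=0.2,
        variance_components=(2.5, 4.5, 3.0),
        seed=3,
    )
    ped = s.simulate_pedigree(config)
    drop = s.gene_drop_genotypes(ped, config)
    records = s.simulate_phenotypes(ped, config, drop.true_values)
    qc, _ = s.run_phenotype_qc(records, ped, drop.genotyped_ids)
    a = s.tabular_a(ped)
    fit = fit_animal_model(
        build_design(qc, ModelSpec("BW"), a.ids),
        a,
        ModelSpec("BW"),
        McmcConfig(2000, 2000, 2, seed=5),
    )
    assert 0.1 < s.heritability(fit) < 0.45
    total = sum(fit.var_mean.values())
    assert total == pytest.approx(10.0, rel=0.35)
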