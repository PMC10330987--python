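"""Cross-validation partitioning, adjusted phenotypes and leakage safety."""
import numpy as np
import pandas as pd
import pytest

import ssgblup as s
from ssgblup.animal_model import DesignBuilder, McmcConfig, ModelSpec, build_design
from ssgblup.validation import CvResult, MethodSetup, _pearson


# --------------------------- partitions ------------------------------- #
def test_partition_sizes():
    parts = s.make_partitions(range(1, 11), n_partitions=3, test_fraction=0.2, seed=0)
    for p in parts:
        assert len(p.testing_ids) == 2
        assert len(p.training_ids["GBLUP"]) == 8


def test_partitions_deterministic_in_seed():
    a = s.make_partitions(range(50), n_partitions=5, seed=3)
    b = s.make_partitions(range(50), n_partitions=5, seed=3)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.testing_ids, pb.testing_ids)


def test_every_id_tested_binomially_often():
    ids = range(1, 201)
    parts = s.make_partitions(ids, n_partitions=100, test_fraction=0.2, seed=1)
    counts = pd.Series(
        np.concatenate([p.testing_ids for p in parts])
    ).value_counts()
    # each id is tested ~Binomial(100, 0.2): mean 20, SD 4
    assert counts.max() <= 20 + 3 * 4
    assert counts.reindex(ids, fill_value=0).min() >= 20 - 3 * 4


def test_matched_testing_sets_and_method_training_pools():
    geno = list(range(1, 51))
    everyone = list(range(1, 101))
    parts = s.make_partitions(
        geno, n_partitions=10, seed=2, all_phenotyped_ids=everyone
    )
    for p in parts:
        test = set(p.testing_ids)
        assert test <= set(geno)
        # matched: same testing animals for the three methods by construction
        assert set(p.training_ids["GBLUP"]) == set(geno) - test
        assert set(p.training_ids["BLUP"]) == set(everyone) - test
        assert set(p.training_ids["ssGBLUP"]) == set(everyone) - test


def test_bad_fraction_rejected():
    with pytest.raises(s.ConfigError):
        s.make_partitions(range(10), test_fraction=1.5)
    with pytest.raises(s.ConfigError):
        s.make_partitions(range(3))


# --------------------------- adjusted phenotypes ---------------------- #
def fake_fit(train, beta, cg_effects):
    """A PosteriorFit carrying exact coefficients, for arithmetic checks."""
    builder = DesignBuilder(("sex", "dam_age")).fit(train)
    design = build_design(train, ModelSpec("BW"), train["animal"].to_numpy())
    p = len(builder.x_names)
    fit = s.PosteriorFit(
        var_samples=np.ones((2, 3)),
        beta_samples=np.tile(beta, (2, 1)),
        beta_names=builder.x_names,
        cg_mean=pd.Series(cg_effects, index=builder.cg_levels),
        cg_sd=pd.Series(0.0, index=builder.cg_levels),
        ebv=pd.Series(0.0, index=train["animal"]),
        h2_samples=np.zeros(2),
        design=design,
    )
    return fit


def records(n, values, cg, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    return pd.DataFrame(
        {
            "animal": np.arange(1, n + 1),
            "value": values,
            "herd": 1,
            "birth_date": pd.Timestamp("2004-04-01"),
            "dam_age": np.full(n, 1500.0),
            "sex": ["F"] * n,
            "cg": cg,
        }
    )


def test_zero_coefficients_leave_phenotypes_unchanged():
    rec = records(4, [1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])
    fit = fake_fit(rec, beta=np.zeros(2), cg_effects=[0.0, 0.0])
    adj = s.adjust_phenotypes(rec, fit)
    assert np.allclose(adj.to_numpy(), rec["value"])


def test_intercept_subtraction():
    rec = records(4, [12.0, 12.0, 12.0, 12.0], ["a", "a", "b", "b"])
    fit = fake_fit(rec, beta=np.array([5.0, 0.0]), cg_effects=[0.0, 0.0])
    adj = s.adjust_phenotypes(rec, fit)
    assert np.allclose(adj.to_numpy(), 7.0)


def test_adjustment_removes_nuisance_variance(small_sim):
    """Adjusted phenotypes track the genetic-plus-residual signal better
    than raw phenotypes do."""
    config, ped, drop, rec = small_sim
    qc, _ = s.run_phenotype_qc(rec, ped, drop.genotyped_ids)
    a = s.tabular_a(ped)
    spec = ModelSpec("BW")
    fit = s.fit_animal_model(
        build_design(qc, spec, a.ids), a, spec, McmcConfig(1500, 1500, 3, seed=2)
    )
    adj = s.adjust_phenotypes(qc, fit)
    truth = drop.true_values
    signal = (
        truth.true_breeding_values.loc[qc["animal"]].to_numpy()
        + (qc["value"].to_numpy() - qc["value"].mean()) * 0.0
    )
    # target: a + e = y - Xb - Z1c with the TRUE coefficients
    cg_true = np.array([truth.true_cg_effects[g] for g in qc["cg"]])
    beta = truth.true_fixed_effects
    fixed = (
        beta.get("intercept", 0.0)
        + np.where(qc["sex"] == "M", beta.get("sex_M", 0.0), 0.0)
        + beta.get("dam_age", 0.0) * qc["dam_age"].to_numpy()
    )
    target = qc["value"].to_numpy() - fixed - cg_true
    r_adj = np.corrcoef(adj.to_numpy(), target)[0, 1]
    r_raw = np.corrcoef(qc["value"].to_numpy(), target)[0, 1]
    assert r_adj > r_raw


# --------------------------- correlations ----------------------------- #
def test_perfect_and_null_correlations():
    rng = np.random.default_rng(0)
    x = rng.normal(size=400)
    assert _pearson(x, x.copy(), 0, "BLUP") == pytest.approx(1.0)
    noise = rng.normal(size=400)
    assert abs(_pearson(x, noise, 0, "BLUP")) < 3 / np.sqrt(400)
    assert np.isnan(_pearson(x[:5], np.ones(5), 0, "BLUP"))


def test_summaries_and_se_rule():
    r = CvResult(correlations=np.array([0.4, 0.4, 0.4]))
    assert r.mean == pytest.approx(0.4)
    assert r.sd == pytest.approx(0.0)
    rng = np.random.default_rng(1)
    vals = rng.normal(0.3, 0.18, 100)
    r = CvResult(correlations=vals)
    assert r.se == pytest.approx(r.sd / 10.0)
    # missing partitions drop out of the divisor
    vals_with_nan = np.concatenate([vals, [np.nan] * 10])
    r2 = CvResult(correlations=vals_with_nan)
    assert r2.n_valid == 100
    assert r2.se == pytest.approx(r.sd / np.sqrt(100))


# --------------------------- leakage and monotonicity ----------------- #
@pytest.fixture(scope="module")
def cv_setup(small_sim):
    config, ped, drop, rec = small_sim
    qc, _ = s.run_phenotype_qc(rec, ped, drop.genotyped_ids)
    a = s.tabular_a(ped)
    return config, ped, drop, qc, a


def test_training_fit_ignores_poisoned_testing_phenotype(cv_setup):
    config, ped, drop, qc, a = cv_setup
    geno_pheno = sorted(set(drop.genotyped_ids) & set(qc["animal"]))
    parts = s.make_partitions(
        geno_pheno,
        n_partitions=1,
        seed=0,
        all_phenotyped_ids=sorted(qc["animal"]),
        methods=("BLUP",),
    )
    victim = parts[0].testing_ids[0]
    poisoned = qc.copy()
    poisoned.loc[poisoned["animal"] == victim, "value"] += 1e4
    spec = ModelSpec("BW")
    mcmc = McmcConfig(300, 200, 2, seed=4)
    fits = []
    for frame in (qc, poisoned):
        train = frame[frame["animal"].isin(parts[0].training_ids["BLUP"])]
        fits.append(
            s.fit_animal_model(
                build_design(train.reset_index(drop=True), spec, a.ids),
                a,
                spec,
                mcmc,
            )
        )
    assert np.array_equal(fits[0].var_samples, fits[1].var_samples)
    assert np.array_equal(fits[0].ebv.to_numpy(), fits[1].ebv.to_numpy())


def test_ssgblup_matches_blup_partitionwise_without_genotypes(cv_setup):
    config, ped, drop, qc, a = cv_setup
    ainv = s.a_inverse(ped)
    empty = s.extract_agg(a, [])
    h = s.h_from_h_inverse(s.assemble_h_inverse(ainv, empty, empty, []))
    setups = {
        "BLUP": MethodSetup(spec=ModelSpec("BW"), delta=a),
        "ssGBLUP": MethodSetup(spec=ModelSpec("BW", method="ssGBLUP"), delta=h),
    }
    geno_pheno = sorted(set(drop.genotyped_ids) & set(qc["animal"]))
    parts = s.make_partitions(
        geno_pheno,
        n_partitions=2,
        seed=5,
        all_phenotyped_ids=sorted(qc["animal"]),
        methods=("BLUP", "ssGBLUP"),
    )
    mcmc = McmcConfig(1500, 1000, 2, seed=6)
    for p in parts:
        corr = s.evaluate_partition(p, qc, setups, mcmc)
        # H = inv(A⁻¹) equals the tabular A only to double precision, so the
        # chains agree to Monte-Carlo accuracy rather than bitwise
        assert corr["BLUP"] == pytest.approx(corr["ssGBLUP"], abs=0.03)


def test_mean_correlation_increases_with_heritability():
    """Predictive correlations respond to the simulated signal: h² = 0.5
    beats h² = 0.05 on the same pipeline over 20 partitions."""
    means = {}
    for h2, (sa, scg, se) in {"low": (0.5, 4.5, 5.0), "high": (5.0, 4.5, 0.5)}.items():
        config = s.SimulationConfig(
            n_founders=40,
            n_generations=3,
            offspring_per_mating=2.2,
            sire_fraction=0.2,
            n_herds=3,
            year_range=(2000, 2004),
            n_markers=40,
            genotyped_fraction=0.5,
            variance_components=(sa, scg, se),
            seed=9,
        )
        ped = s.simulate_pedigree(config)
        drop = s.gene_drop_genotypes(ped, config)
        rec = s.simulate_phenotypes(ped, config, drop.true_values)
        qc, _ = s.run_phenotype_qc(rec, ped, drop.genotyped_ids)
        a = s.tabular_a(ped)
        setups = {"BLUP": MethodSetup(spec=ModelSpec("BW"), delta=a)}
        results, _ = s.run_cross_validation(
            qc,
            setups,
            drop.genotyped_ids,
            n_partitions=20,
            mcmc=McmcConfig(800, 800, 4, seed=1),
            seed=12,
        )
        means[h2] = results["BLUP"].mean
    assert means["high"] > means["low"]
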