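"""Relationship matrices against dense-algebra and hand-computed oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssgblup as s
from conftest import random_pedigree


def founders_only(n):
    return s.PedigreeTable.from_frame(
        pd.DataFrame({"animal": range(1, n + 1), "sire": 0, "dam": 0})
    )


# --------------------------- tabular A -------------------------------- #
def test_founders_give_identity():
    a = s.tabular_a(founders_only(4))
    assert np.array_equal(a.values, np.eye(4))


def test_hand_tabular_recursion(five_animal_pedigree):
    a = s.tabular_a(five_animal_pedigree)
    pos = a.positions
    assert a.values[pos[3], pos[4]] == pytest.approx(0.5)  # full sibs
    assert a.values[pos[5], pos[5]] == pytest.approx(1.25)  # F = 0.25
    assert a.values[pos[1], pos[3]] == pytest.approx(0.5)  # parent-offspring


def test_inbreeding_matches_tabular_diagonal():
    rng = np.random.default_rng(7)
    ped = random_pedigree(120, rng)
    f = s.inbreeding(ped)
    a = s.tabular_a(ped)
    assert np.allclose(1.0 + f, np.diag(a.values), atol=1e-12)


# --------------------------- A inverse -------------------------------- #
def test_a_inverse_founders_identity():
    ainv = s.a_inverse(founders_only(3))
    assert np.array_equal(ainv.values, np.eye(3))


def test_a_inverse_times_a_is_identity(five_animal_pedigree):
    a = s.tabular_a(five_animal_pedigree)
    ainv = s.a_inverse(five_animal_pedigree)
    assert np.abs(ainv.values @ a.values - np.eye(5)).max() < 1e-8


def test_a_inverse_dense_oracle_on_random_pedigree():
    rng = np.random.default_rng(123)
    ped = random_pedigree(200, rng)
    err = np.abs(
        s.a_inverse(ped).values @ s.tabular_a(ped).values - np.eye(200)
    ).max()
    assert err < 1e-6


# --------------------------- genomic G -------------------------------- #
def make_geno(data):
    data = np.asarray(data, dtype=float)
    return s.GenotypeMatrix(
        ids=np.arange(1, data.shape[0] + 1),
        markers=[f"m{j}" for j in range(data.shape[1])],
        data=data,
    )


def test_single_marker_hand_computation():
    g = s.genomic_relationship(make_geno([[0], [1], [2]]))
    expect = np.array([[1, 0, -1], [0, 0, 0], [-1, 0, 1]], dtype=float)
    assert np.allclose(g.values, expect)


def test_trace_identity_forced_by_standardization():
    rng = np.random.default_rng(5)
    data = rng.integers(0, 3, size=(37, 250)).astype(float)
    keep = data.std(axis=0) > 0
    g = s.genomic_relationship(make_geno(data[:, keep]))
    assert np.trace(g.values) == pytest.approx(37 - 1, abs=1e-10)


def test_duplicated_genotype_rows_share_entries():
    rng = np.random.default_rng(8)
    data = rng.integers(0, 3, size=(10, 100)).astype(float)
    data[1] = data[0]
    keep = data.std(axis=0) > 0
    g = s.genomic_relationship(make_geno(data[:, keep]))
    assert g.values[0, 0] == pytest.approx(g.values[1, 1])
    assert g.values[0, 1] == pytest.approx(g.values[0, 0])


def test_zero_variance_column_is_a_pipeline_order_error():
    data = np.array([[0.0, 1], [0.0, 2], [0.0, 0]])
    with pytest.raises(s.PipelineOrderError):
        s.genomic_relationship(make_geno(data))


# --------------------------- A_gg ------------------------------------- #
def test_extract_agg(five_animal_pedigree):
    a = s.tabular_a(five_animal_pedigree)
    assert np.array_equal(s.extract_agg(a, a.ids).values, a.values)
    assert np.allclose(s.extract_agg(a, [1]).values, [[1.0]])
    sub = s.extract_agg(a, [3, 4])
    assert np.allclose(sub.values, [[1, 0.5], [0.5, 1]])
    with pytest.raises(s.DataError):
        s.extract_agg(a, [99])


# --------------------------- blending --------------------------------- #
def rel(kind, values):
    values = np.asarray(values, dtype=float)
    return s.RelationshipMatrix(kind, np.arange(len(values)), values)


def test_blend_identity_when_moments_already_match():
    g = rel("G", [[1.0, 0.3], [0.3, 1.0]])
    agg = rel("A_gg", [[1.0, 0.3], [0.3, 1.0]])
    coeffs = s.solve_blend(g, agg)
    assert coeffs.beta == pytest.approx(1.0)
    assert coeffs.alpha == pytest.approx(0.0)
    assert np.allclose(s.blend_ga(g, coeffs).values, g.values)


def test_blend_hand_solved_2x2():
    coeffs = s.solve_blend(
        rel("G", [[1.2, 0.2], [0.2, 0.8]]), rel("A_gg", [[1.05, 0.5], [0.5, 1.0]])
    )
    assert coeffs.beta == pytest.approx(0.65625)
    assert coeffs.alpha == pytest.approx(0.36875)
    ga = s.blend_ga(rel("G", [[1.2, 0.2], [0.2, 0.8]]), coeffs)
    assert np.diag(ga.values).mean() == pytest.approx(1.025, abs=1e-12)
    assert ga.values.mean() == pytest.approx(0.7625, abs=1e-12)


def test_blend_identity_g_case():
    coeffs = s.solve_blend(
        rel("G", np.eye(2)), rel("A_gg", [[1.0, 0.25], [0.25, 1.0]])
    )
    assert coeffs.beta == pytest.approx(0.75)
    assert coeffs.alpha == pytest.approx(0.25)


def test_degenerate_blend_system_raises():
    g = rel("G", np.full((3, 3), 0.7) + 0.0)  # Avg(diag) == Avg
    with pytest.raises(s.SingularSystemError):
        s.solve_blend(g, rel("A_gg", np.eye(3)))


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_blend_conservation_property(seed):
    """βG + α reproduces both A_gg moments to near machine precision."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    w = rng.normal(size=(n, n + 3))
    g = rel("G", w @ w.T / (n + 3))
    b = rng.normal(size=(n, n + 3))
    agg = rel("A_gg", b @ b.T / (n + 3) + np.eye(n) * 0.1)
    try:
        coeffs = s.solve_blend(g, agg)
    except s.SingularSystemError:
        return
    ga = s.blend_ga(g, coeffs)
    assert np.diag(ga.values).mean() == pytest.approx(
        np.diag(agg.values).mean(), abs=1e-10
    )
    assert ga.values.mean() == pytest.approx(agg.values.mean(), abs=1e-10)


# --------------------------- H inverse -------------------------------- #
def h_dense_oracle(a, agg_ids, ga_values):
    """Brute-force H⁻¹ via generic dense inverses of the defining formula."""
    n = len(a.ids)
    pos = a.positions
    idx = [pos[int(i)] for i in agg_ids]
    a_inv = np.linalg.inv(a.values)
    agg = a.values[np.ix_(idx, idx)]
    h = a_inv.copy()
    h[np.ix_(idx, idx)] += np.linalg.inv(ga_values) - np.linalg.inv(agg)
    return h


def test_h_inverse_without_genotyped_animals_is_a_inverse(five_animal_pedigree):
    ainv = s.a_inverse(five_animal_pedigree)
    a = s.tabular_a(five_animal_pedigree)
    h = s.assemble_h_inverse(ainv, s.extract_agg(a, []), s.extract_agg(a, []), [])
    assert np.array_equal(h.values, ainv.values)


def test_h_inverse_cancels_when_ga_equals_agg(five_animal_pedigree):
    a = s.tabular_a(five_animal_pedigree)
    ainv = s.a_inverse(five_animal_pedigree)
    agg = s.extract_agg(a, [3, 4, 5])
    ga = s.RelationshipMatrix("G_a", agg.ids, agg.values.copy())
    h = s.assemble_h_inverse(ainv, agg, ga, [3, 4, 5])
    assert np.abs(h.values - ainv.values).max() < 1e-8


def test_h_inverse_matches_dense_formula_on_simulated_pedigree():
    rng = np.random.default_rng(17)
    ped = random_pedigree(20, rng)
    a = s.tabular_a(ped)
    geno_ids = sorted(rng.choice(ped.ids, size=8, replace=False).tolist())
    agg = s.extract_agg(a, geno_ids)
    w = rng.normal(size=(8, 40))
    g = s.RelationshipMatrix("G", np.asarray(geno_ids), w @ w.T / 40)
    ga = s.blend_ga(g, s.solve_blend(g, agg))
    h = s.assemble_h_inverse(s.a_inverse(ped), agg, ga, geno_ids)
    oracle = h_dense_oracle(a, geno_ids, ga.values)
    assert np.abs(h.values - oracle).max() < 1e-8


def test_all_kinds_are_symmetric(small_sim):
    cfg, ped, drop, _ = small_sim
    a = s.tabular_a(ped)
    ainv = s.a_inverse(ped)
    pa, pb = s.split_panels(drop)
    qc, _, _ = s.run_genotype_qc(pa, pb)
    g = s.genomic_relationship(qc)
    agg = s.extract_agg(a, g.ids)
    ga = s.blend_ga(g, s.solve_blend(g, agg))
    hinv = s.assemble_h_inverse(ainv, agg, ga, g.ids)
    for m in (a, ainv, g, agg, ga, hinv):
        assert np.abs(m.values - m.values.T).max() < 1e-12


# --------------------------- summaries -------------------------------- #
def test_matrix_summary_identity():
    out = s.matrix_summary(rel("G", np.eye(3)))
    assert out["diag_min"] == out["diag_max"] == out["diag_mean"] == 1.0
    assert out["offdiag_min"] == out["offdiag_max"] == 0.0


def test_matrix_summary_inbred_diagonal(five_animal_pedigree):
    out = s.matrix_summary(s.tabular_a(five_animal_pedigree))
    assert out["diag_max"] == pytest.approx(1.25)


def test_g_mean_diagonal_tracks_trace_identity(small_sim):
    cfg, ped, drop, _ = small_sim
    pa, pb = s.split_panels(drop)
    qc, _, _ = s.run_genotype_qc(pa, pb)
    g = s.genomic_relationship(qc)
    out = s.matrix_summary(g)
    n = len(g)
    assert out["diag_mean"] == pytest.approx((n - 1) / n, abs=1e-10)
    assert 0.9 < out["diag_mean"] < 1.0
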