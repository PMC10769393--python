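"""Design encoding and per-gene OLS against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from nanoconcord import EffectTable, build_design, fit_effects
from nanoconcord.exceptions import SingularDesignError, ValidationError

from conftest import SMALL_STRAINS, balanced_annotations

ROLES = dict(SMALL_STRAINS)


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------

def test_nested_encoding_rows():
    annot = balanced_annotations(["B6J", "LOAD1", "5xFAD", "Abca7"], n_per_group=1)
    X = build_design(annot, ROLES)
    # baseline female: intercept only
    row = X.loc["B6J_F_0"]
    assert row["intercept"] == 1 and row.drop("intercept").sum() == 0
    # variant male: male + comparator + own indicator
    row = X.loc["Abca7_M_0"]
    assert row["male"] == 1 and row["LOAD1"] == 1 and row["Abca7"] == 1
    assert row["5xFAD"] == 0
    # transgenic female: only its own indicator
    row = X.loc["5xFAD_F_0"]
    assert row["5xFAD"] == 1 and row["male"] == 0 and row["LOAD1"] == 0
    # comparator sets only itself
    row = X.loc["LOAD1_F_0"]
    assert row["LOAD1"] == 1 and row["Abca7"] == 0


def test_flat_encoding_drops_nesting():
    annot = balanced_annotations(["B6J", "LOAD1", "Abca7"], n_per_group=1)
    X = build_design(annot, ROLES, encoding="flat")
    assert X.loc["Abca7_M_0", "LOAD1"] == 0
    assert X.loc["Abca7_M_0", "Abca7"] == 1


def test_unknown_strain_is_named():
    annot = balanced_annotations(["B6J", "Mystery"], n_per_group=1)
    with pytest.raises(ValidationError, match="Mystery"):
        build_design(annot, ROLES)


def test_variant_without_any_control_strain_is_singular():
    annot = balanced_annotations(["Abca7"], n_per_group=2)
    with pytest.raises(SingularDesignError):
        build_design(annot, ROLES)


# ---------------------------------------------------------------------------
# OLS estimates
# ---------------------------------------------------------------------------

def _expr_from_means(annot, means: dict[str, float], noise=0.0, seed=0, n_genes=1):
    rng = np.random.default_rng(seed)
    Y = np.empty((n_genes, len(annot)))
    for j, strain in enumerate(annot["strain"]):
        Y[:, j] = means[strain] + rng.normal(0, noise, n_genes)
    return pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)], columns=annot.index)


def test_balanced_two_group_beta_is_mean_difference():
    annot = balanced_annotations(["B6J", "LOAD1"], n_per_group=3)
    annot = annot[annot["sex"] == "F"]
    expr = _expr_from_means(annot, {"B6J": 4.0, "LOAD1": 5.0})
    X = build_design(annot, ROLES)
    assert "male" not in X.columns  # single-sex cohort has no sex contrast
    eff = fit_effects(expr, X, age=12)
    assert eff.betas("LOAD1")["g0"] == pytest.approx(1.0, abs=1e-12)


def test_nested_three_group_betas_match_normal_equations():
    annot = balanced_annotations(["B6J", "LOAD1", "Abca7"], n_per_group=3)
    annot = annot[annot["sex"] == "F"]
    expr = _expr_from_means(annot, {"B6J": 4.0, "LOAD1": 5.0, "Abca7": 5.5})
    X = build_design(annot, ROLES)
    eff = fit_effects(expr, X, age=12)
    # nested encoding: variant beta is the LOAD1-relative effect
    assert eff.betas("LOAD1")["g0"] == pytest.approx(1.0, abs=1e-12)
    assert eff.betas("Abca7")["g0"] == pytest.approx(0.5, abs=1e-12)
    # explicit normal-equations oracle on the same design
    Xm = X.to_numpy()
    y = expr.to_numpy()[0]
    beta_oracle = np.linalg.inv(Xm.T @ Xm) @ Xm.T @ y
    got = eff.table[eff.table["gene"] == "g0"].set_index("factor")["beta"]
    assert np.allclose(got[X.columns].to_numpy(), beta_oracle, atol=1e-12)


def test_inference_matches_statsmodels():
    import statsmodels.api as sm

    annot = balanced_annotations(["B6J", "LOAD1", "Abca7"], n_per_group=4)
    expr = _expr_from_means(annot, {"B6J": 4.0, "LOAD1": 4.6, "Abca7": 5.1},
                            noise=0.5, seed=3, n_genes=5)
    X = build_design(annot, ROLES)
    eff = fit_effects(expr, X, age=12)
    for gene in expr.index:
        fit = sm.OLS(expr.loc[gene].to_numpy(), X.to_numpy()).fit()
        sub = eff.table[eff.table["gene"] == gene].set_index("factor").loc[X.columns]
        assert np.allclose(sub["beta"], fit.params, atol=1e-10)
        assert np.allclose(sub["se"], fit.bse, atol=1e-10)
        assert np.allclose(sub["p"], fit.pvalues, atol=1e-10)
        assert (sub["df"] == fit.df_resid).all()


def test_adding_constant_shifts_only_intercept():
    annot = balanced_annotations(["B6J", "LOAD1"], n_per_group=4)
    expr = _expr_from_means(annot, {"B6J": 4.0, "LOAD1": 5.0}, noise=0.3, seed=1, n_genes=3)
    X = build_design(annot, ROLES)
    base = fit_effects(expr, X, age=12)
    shifted = expr.copy()
    shifted.loc["g1"] += 7.0
    moved = fit_effects(shifted, X, age=12)
    b0 = base.table.set_index(["factor", "gene"])["beta"]
    b1 = moved.table.set_index(["factor", "gene"])["beta"]
    assert b1[("intercept", "g1")] - b0[("intercept", "g1")] == pytest.approx(7.0, abs=1e-10)
    for factor in ("male", "LOAD1"):
        assert b1[(factor, "g1")] == pytest.approx(b0[(factor, "g1")], abs=1e-10)


def test_sex_balanced_design_makes_sex_column_orthogonal():
    annot = balanced_annotations(["B6J", "LOAD1"], n_per_group=5)
    rng = np.random.default_rng(9)
    expr = pd.DataFrame(
        rng.normal(4, 1, (6, len(annot))), columns=annot.index,
        index=[f"g{i}" for i in range(6)],
    )
    X = build_design(annot, ROLES)
    with_sex = fit_effects(expr, X, age=12)
    without = fit_effects(expr, X.drop(columns="male"), age=12)
    delta = np.abs(with_sex.betas("LOAD1") - without.betas("LOAD1")).max()
    se = with_sex.table.query("factor == 'LOAD1'")["se"].min()
    assert delta < se / 10


def test_zero_residual_variance_flags_na():
    annot = balanced_annotations(["B6J", "LOAD1"], n_per_group=3)
    expr = _expr_from_means(annot, {"B6J": 4.0, "LOAD1": 5.0})  # deterministic
    X = build_design(annot, ROLES)
    eff = fit_effects(expr, X, age=12)
    assert eff.table["p"].isna().all()
    assert (eff.table["se"] == 0).all()


def test_singular_design_raises_not_pseudoinverse():
    annot = balanced_annotations(["B6J", "LOAD1"], n_per_group=3)
    X = build_design(annot, ROLES)
    X["dup"] = X["LOAD1"]
    expr = _expr_from_means(annot, {"B6J": 4.0, "LOAD1": 5.0}, noise=0.1, seed=2)
    with pytest.raises(SingularDesignError):
        fit_effects(expr, X, age=12)


def test_ols_matches_oracle_on_random_designs():
    """Property: solver equals (X'X)^-1 X'y on random full-rank designs."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(10, 40))
        p = int(rng.integers(2, 7))
        X = np.column_stack([np.ones(n), rng.integers(0, 2, size=(n, p - 1))])
        if np.linalg.matrix_rank(X) < p:
            continue
        Y = rng.normal(size=(3, n))
        design = pd.DataFrame(
            X, columns=["intercept"] + [f"f{j}" for j in range(p - 1)],
            index=[f"s{i}" for i in range(n)],
        )
        expr = pd.DataFrame(Y, index=["a", "b", "c"], columns=design.index)
        eff = fit_effects(expr, design, age=0)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y.T
        got = eff.beta_matrix(include_intercept=True).loc[design.columns].to_numpy()
        rel = np.abs(got - oracle) / np.maximum(np.abs(oracle), 1e-12)
        assert rel.max() < 1e-10


def test_effect_table_round_trips_through_tsv(tmp_path, effects):
    path = tmp_path / "eff.tsv"
    effects.to_tsv(path)
    back = EffectTable.from_tsv(path)
    assert back.age == effects.age
    assert back.factors == effects.factors
    assert np.allclose(back.table["beta"], effects.table["beta"])
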