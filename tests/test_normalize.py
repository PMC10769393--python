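"""Normalization stages: housekeeping scaling, log transform, batch correction."""

import numpy as np
import pandas as pd
import pytest

from nanoconcord import (
    SimulationConfig,
    combat_correct,
    generate_counts,
    housekeeping_normalize,
    log_transform,
)
from nanoconcord.exceptions import (
    AlignmentError,
    FormatError,
    ProvenanceError,
    SingularDesignError,
    ValidationError,
)
from nanoconcord.io import read_counts
from nanoconcord.normalize import ExpressionMatrix


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def test_read_counts_well_formed(toy_counts):
    cpath, apath, counts, annot = toy_counts
    got_counts, got_annot = read_counts(cpath, apath)
    assert got_counts.shape == (3, 2)
    pd.testing.assert_frame_equal(got_counts, counts, check_names=False)
    assert list(got_annot.index) == list(counts.columns)


def test_read_counts_missing_annotation_names_sample(toy_counts, tmp_path):
    cpath, _, _, annot = toy_counts
    apath = tmp_path / "short.tsv"
    annot.iloc[:1].to_csv(apath, sep="\t")
    with pytest.raises(AlignmentError, match="s2"):
        read_counts(cpath, apath)


def test_read_counts_negative_cell_cites_coordinates(toy_counts, tmp_path):
    _, apath, counts, _ = toy_counts
    bad = counts.copy()
    bad.loc["g2", "s1"] = -4
    cpath = tmp_path / "bad.tsv"
    bad.to_csv(cpath, sep="\t", index_label="gene")
    with pytest.raises(FormatError, match=r"g2.*s1"):
        read_counts(cpath, apath)


def test_read_counts_non_integer_rejected(toy_counts, tmp_path):
    _, apath, counts, _ = toy_counts
    bad = counts.astype(float)
    bad.loc["g3", "s2"] = 1.5
    cpath = tmp_path / "bad.tsv"
    bad.to_csv(cpath, sep="\t", index_label="gene")
    with pytest.raises(FormatError, match=r"g3.*s2"):
        read_counts(cpath, apath)


# ---------------------------------------------------------------------------
# housekeeping normalization
# ---------------------------------------------------------------------------

def hk_matrix():
    return pd.DataFrame(
        {"s1": [2, 8, 12], "s2": [1, 1, 7]}, index=["hk1", "hk2", "g1"]
    )


def test_geometric_mean_scaling_hand_example():
    out = housekeeping_normalize(hk_matrix(), ["hk1", "hk2"])
    # geomean(2, 8) = 4, so gene count 12 -> 3.0
    assert out.loc["g1", "s1"] == pytest.approx(3.0)
    # housekeeping counts of 1 leave the sample untouched
    assert out.loc["g1", "s2"] == pytest.approx(7.0)
    # output housekeeping geomean is 1 in every sample
    geomean = np.exp(np.log(out.loc[["hk1", "hk2"]]).mean(axis=0))
    assert np.allclose(geomean, 1.0)


def test_per_sample_scale_invariance():
    m = hk_matrix()
    scaled = m.copy()
    scaled["s1"] = scaled["s1"] * 10
    out = housekeeping_normalize(m, ["hk1", "hk2"])
    out_scaled = housekeeping_normalize(scaled, ["hk1", "hk2"])
    pd.testing.assert_frame_equal(out, out_scaled)


def test_idempotence_second_pass_divides_by_one():
    once = housekeeping_normalize(hk_matrix(), ["hk1", "hk2"])
    twice = housekeeping_normalize(once, ["hk1", "hk2"])
    pd.testing.assert_frame_equal(once, twice)


def test_zero_housekeeping_count_is_an_error():
    m = hk_matrix()
    m.loc["hk2", "s2"] = 0
    with pytest.raises(ValidationError, match=r"hk2.*s2"):
        housekeeping_normalize(m, ["hk1", "hk2"])


def test_missing_housekeeping_gene_is_an_error():
    with pytest.raises(ValidationError, match="hk9"):
        housekeeping_normalize(hk_matrix(), ["hk1", "hk9"])


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def test_log_transform_hand_values():
    m = pd.DataFrame({"s1": [3.0, 0.0]}, index=["g1", "g2"])
    expr = log_transform(m, base=2, pseudocount=1)
    assert expr.values.loc["g1", "s1"] == pytest.approx(2.0)
    assert expr.values.loc["g2", "s1"] == pytest.approx(0.0)
    assert expr.provenance["log_base"] == 2.0
    assert expr.provenance["pseudocount"] == 1.0


def test_change_of_base_rescales_exactly():
    m = pd.DataFrame({"s1": [3.0, 9.0], "s2": [0.5, 4.0]}, index=["g1", "g2"])
    base2 = log_transform(m, base=2, pseudocount=1).values
    basee = log_transform(m, base=np.e, pseudocount=1).values
    assert np.allclose(basee.to_numpy(), base2.to_numpy() * np.log(2), rtol=1e-14)


def test_zero_value_requires_pseudocount():
    m = pd.DataFrame({"s1": [0.0]}, index=["g1"])
    with pytest.raises(ValidationError, match="pseudocount"):
        log_transform(m, base=2, pseudocount=0)


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def _expr(Y, samples=None):
    samples = samples or [f"s{i}" for i in range(Y.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(Y, columns=samples),
        provenance={"normalized": True, "log_base": 2.0, "pseudocount": 1.0,
                    "batch_corrected": False},
    )


def test_single_batch_is_identity():
    rng = np.random.default_rng(0)
    expr = _expr(rng.normal(size=(10, 6)))
    batch = pd.Series(["a"] * 6, index=expr.samples)
    out = combat_correct(expr, batch)
    pd.testing.assert_frame_equal(out.values, expr.values)
    assert out.provenance["batch_corrected"]


def test_planted_additive_shift_removed_without_shrinkage():
    rng = np.random.default_rng(1)
    G, half = 60, 50
    Y = rng.normal(5, 1, (G, 1)) + rng.normal(0, 0.5, (G, 2 * half))
    delta = 1.7
    Y[:, half:] += delta
    expr = _expr(Y)
    batch = pd.Series(["a"] * half + ["b"] * half, index=expr.samples)
    out = combat_correct(expr, batch, shrink=False)
    diff = out.values.iloc[:, half:].mean(axis=1) - out.values.iloc[:, :half].mean(axis=1)
    assert np.abs(diff).max() < 1e-2 * delta


def test_random_batch_labels_perturb_less_than_group_noise():
    cfg = SimulationConfig(
        n_genes=120, n_housekeeping=6,
        strains={"B6J": "baseline", "LOAD1": "comparator"},
        n_per_group=10, ages=(12,), n_batches=3,
        batch_shift_sd=0.0, batch_scale_sd=0.0, seed=4,
    )
    counts, annot, _ = generate_counts(cfg)
    expr = log_transform(housekeeping_normalize(counts, cfg.housekeeping_genes()))
    out = combat_correct(expr, annot["batch"], covariates=annot[["strain", "sex"]])
    rms_change = np.sqrt(((out.values - expr.values) ** 2).mean(axis=1))
    group_sd = expr.values.T.groupby([annot["strain"], annot["sex"]]).std().mean(axis=0)
    assert (rms_change.to_numpy() <= group_sd.to_numpy()).all()


def test_grand_mean_preserved():
    rng = np.random.default_rng(2)
    Y = rng.normal(3, 1, (30, 40))
    Y[:, 20:] += rng.normal(0.5, 0.2, (30, 1))
    expr = _expr(Y)
    batch = pd.Series(["a"] * 20 + ["b"] * 20, index=expr.samples)
    exact = combat_correct(expr, batch, shrink=False)
    drift = (exact.values.mean(axis=1) - expr.values.mean(axis=1)).abs().max()
    assert drift < 1e-8
    shrunk = combat_correct(expr, batch, shrink=True)
    drift_eb = (shrunk.values.mean(axis=1) - expr.values.mean(axis=1)).abs().max()
    assert drift_eb < 0.05


def test_matches_scanpy_combat():
    """Independent cross-check against scanpy's parametric ComBat."""
    sc = pytest.importorskip("scanpy")
    anndata = pytest.importorskip("anndata")
    rng = np.random.default_rng(3)
    G, n = 40, 60
    Y = rng.normal(5, 1, (G, 1)) + rng.normal(0, 0.6, (G, n))
    Y[:, 30:] += rng.normal(0.8, 0.3, (G, 1))
    expr = _expr(Y)
    batch = pd.Series(["a"] * 30 + ["b"] * 30, index=expr.samples)
    mine = combat_correct(expr, batch, shrink=True)
    adata = anndata.AnnData(
        Y.T.astype(np.float64),
        obs=pd.DataFrame({"batch": batch.to_numpy()}, index=list(expr.samples)),
    )
    sc.pp.combat(adata, key="batch")
    assert np.abs(mine.values.to_numpy() - adata.X.T).max() < 0.01


def test_confounded_batch_and_covariate_is_singular():
    rng = np.random.default_rng(5)
    expr = _expr(rng.normal(size=(10, 8)))
    batch = pd.Series(["a"] * 4 + ["b"] * 4, index=expr.samples)
    cov = pd.DataFrame({"strain": ["x"] * 4 + ["y"] * 4}, index=expr.samples)
    with pytest.raises(SingularDesignError, match="confounded"):
        combat_correct(expr, batch, covariates=cov)


def test_double_correction_refused():
    rng = np.random.default_rng(6)
    expr = _expr(rng.normal(size=(5, 8)))
    batch = pd.Series(["a"] * 4 + ["b"] * 4, index=expr.samples)
    once = combat_correct(expr, batch)
    with pytest.raises(ProvenanceError):
        combat_correct(once, batch)


def test_stage_chain_is_permutation_equivariant():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(100, (12, 10)), index=[f"g{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(10)],
    )
    hk = ["g0", "g1"]
    batch = pd.Series(["a"] * 5 + ["b"] * 5, index=counts.columns)
    out = combat_correct(log_transform(housekeeping_normalize(counts, hk)), batch)
    perm = list(rng.permutation(counts.columns))
    out_perm = combat_correct(
        log_transform(housekeeping_normalize(counts[perm], hk)), batch[perm]
    )
    pd.testing.assert_frame_equal(out.values[perm], out_perm.values, atol=1e-10)
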