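"""Enrichment engines against brute-force and combinatorial oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoconcord import bh_adjust, gsea_preranked, ora_hypergeometric, rank_genes
from nanoconcord.enrichment import RankedList, enrichment_score
from nanoconcord.exceptions import ValidationError


def naive_es(scores, member, weight=1.0):
    """Loop-based running-sum oracle, independent of the vectorized path."""
    n = len(scores)
    n_hit = sum(member)
    hit_total = sum(abs(s) ** weight for s, m in zip(scores, member) if m)
    run, best = 0.0, 0.0
    for s, m in zip(scores, member):
        if m:
            run += (abs(s) ** weight / hit_total) if hit_total > 0 else 1.0 / n_hit
        else:
            run -= 1.0 / (n - n_hit)
        if abs(run) > abs(best):
            best = run
    return best


def ranked(scores: dict[str, float]) -> RankedList:
    return rank_genes(pd.Series(scores))


def test_rank_genes_orders_and_breaks_ties_by_identifier():
    rl = ranked({"b": 1.0, "a": 1.0, "c": 2.0, "d": -1.0})
    assert rl.genes == ("c", "a", "b", "d")
    assert "identifier" in rl.tie_break


def test_top_block_hand_example():
    rl = ranked({f"g{i}": 6 - i for i in range(6)})
    es, _ = enrichment_score(rl, {"g0", "g1"})
    # hits contribute 6/11 then 5/11; the running sum peaks at 1.0
    assert es == pytest.approx(1.0, abs=1e-12)


def test_bottom_block_is_negative():
    rl = ranked({f"g{i}": 6 - i for i in range(6)})
    es, _ = enrichment_score(rl, {"g4", "g5"})
    assert es < 0


def test_es_matches_bruteforce_on_random_small_lists():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(3, 13))
        scores = rng.normal(size=n)
        genes = [f"g{i:02d}" for i in range(n)]
        rl = rank_genes(pd.Series(scores, index=genes))
        k = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=k, replace=False))
        es, _ = enrichment_score(rl, members)
        oracle = naive_es(rl.scores, [g in members for g in rl.genes])
        assert es == pytest.approx(oracle, abs=1e-12)


def test_sign_reversal_flips_es_antisymmetrically():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=10)
    genes = [f"g{i}" for i in range(10)]
    members = {"g2", "g5", "g7"}
    es_fwd, _ = enrichment_score(rank_genes(pd.Series(scores, index=genes)), members)
    es_rev, _ = enrichment_score(rank_genes(pd.Series(-scores, index=genes)), members)
    assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


def test_set_equal_to_universe_is_an_error():
    rl = ranked({"a": 3.0, "b": 2.0, "c": 1.0})
    with pytest.raises(ValidationError, match="proper"):
        enrichment_score(rl, {"a", "b", "c"})


def test_size_filters_skip_terms():
    rl = ranked({f"g{i}": 10 - i for i in range(10)})
    sets = {"small": {"g0"}, "ok": {"g0", "g1", "g2"}, "big": {f"g{i}" for i in range(8)}}
    res = gsea_preranked(rl, sets, min_size=2, max_size=5, n_perm=200, seed=0)
    assert set(res["term"]) == {"ok"}


def test_permutation_p_matches_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    n, k = 7, 3
    scores = rng.normal(size=n)
    genes = [f"g{i}" for i in range(n)]
    series = pd.Series(scores, index=genes)
    rl = rank_genes(series)
    members = set(rng.choice(genes, size=k, replace=False))
    res = gsea_preranked(rl, {"t": members}, min_size=1, max_size=n - 1,
                         n_perm=10_000, seed=3)
    es_obs = res["es"].iloc[0]
    # exhaustive oracle over all C(7,3) = 35 memberships
    all_es = [
        naive_es(rl.scores, [g in set(combo) for g in rl.genes])
        for combo in itertools.combinations(genes, k)
    ]
    same_sign = [e for e in all_es if (e >= 0) == (es_obs >= 0)]
    exact = sum(abs(e) >= abs(es_obs) for e in same_sign) / len(same_sign)
    p_hat = res["p"].iloc[0]
    se = np.sqrt(max(exact * (1 - exact), 1e-4) / 10_000)
    assert abs(p_hat - exact) < 3 * se + 2.0 / 10_000


def test_gsea_null_calibration():
    """Under random scores, ~5% of terms reach nominal p < 0.05."""
    rng = np.random.default_rng(4)
    n = 60
    genes = [f"g{i:02d}" for i in range(n)]
    hits = 0
    trials = 400
    for i in range(trials):
        scores = pd.Series(rng.normal(size=n), index=genes)
        members = set(rng.choice(genes, size=10, replace=False))
        res = gsea_preranked(rank_genes(scores), {"t": members}, min_size=5,
                             max_size=50, n_perm=400, seed=100 + i)
        hits += res["p"].iloc[0] < 0.05
    rate = hits / trials
    se = np.sqrt(0.05 * 0.95 / trials)
    assert abs(rate - 0.05) < 3 * se + 1e-3


def test_leading_edge_is_subset_of_term_and_direction_consistent():
    rng = np.random.default_rng(5)
    n = 40
    genes = [f"g{i:02d}" for i in range(n)]
    scores = pd.Series(rng.normal(size=n), index=genes)
    sets = {f"t{j}": set(rng.choice(genes, size=12, replace=False)) for j in range(5)}
    res = gsea_preranked(rank_genes(scores), sets, min_size=5, max_size=30,
                         n_perm=300, seed=6)
    for _, row in res.iterrows():
        leading = set(row["genes"].split(";"))
        assert leading <= sets[row["term"]]
        assert row["direction"] == ("up" if row["es"] >= 0 else "down")
        assert row["padj"] >= row["p"] - 1e-15


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def test_ora_exact_combinatorial_value():
    universe = set("abcdefghij")
    res = ora_hypergeometric({"a", "b", "c", "d", "e"}, {"T": {"a", "b", "c", "d", "e"}}, universe)
    assert res["p"].iloc[0] == pytest.approx(1 / 252, rel=1e-12)


def test_ora_zero_overlap_gives_p_one():
    res = ora_hypergeometric({"a"}, {"T": {"b", "c"}}, set("abc"))
    assert res["p"].iloc[0] == pytest.approx(1.0)
    assert res["k"].iloc[0] == 0


def test_ora_query_equal_universe_saturates():
    universe = set("abcdef")
    res = ora_hypergeometric(universe, {"T": {"a", "b"}}, universe)
    assert res["k"].iloc[0] == res["K"].iloc[0]
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_ora_matches_enumeration_over_all_draws():
    universe = list("abcdefgh")  # N = 8
    term = {"a", "b", "c"}
    n_draw = 4
    rng = np.random.default_rng(7)
    query = set(rng.choice(universe, size=n_draw, replace=False))
    k_obs = len(query & term)
    res = ora_hypergeometric(query, {"T": term}, set(universe))
    total = hits = 0
    for combo in itertools.combinations(universe, n_draw):
        total += 1
        hits += len(set(combo) & term) >= k_obs
    assert res["p"].iloc[0] == pytest.approx(hits / total, rel=1e-12)


@pytest.mark.parametrize(
    "query, universe", [(set(), {"a"}), ({"a"}, set()), ({"z"}, {"a"})]
)
def test_ora_invalid_inputs_rejected(query, universe):
    with pytest.raises(ValidationError):
        ora_hypergeometric(query, {"T": {"a"}}, universe)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_step_up_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_trivial_cases():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_na_excluded_from_m():
    q = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    # m = 2: q = (0.02, 0.04)
    assert np.allclose(q[[0, 2]], [0.02, 0.04])


def test_bh_matches_statsmodels_and_is_monotone():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        mine = bh_adjust(p)
        _, ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(mine, ref, atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(mine[order]) >= -1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
)
def test_bh_properties_hold_for_arbitrary_p_vectors(p):
    """q >= p everywhere, q <= 1, and q is monotone in the sorted order."""
    q = bh_adjust(p)
    p = np.asarray(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.data())
def test_es_oracle_agreement_for_arbitrary_small_lists(data):
    """Vectorized ES equals the loop oracle for any scores and membership."""
    n = data.draw(st.integers(min_value=3, max_value=12))
    scores = data.draw(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    k = data.draw(st.integers(min_value=1, max_value=n - 1))
    genes = [f"g{i:02d}" for i in range(n)]
    rl = rank_genes(pd.Series(scores, index=genes))
    members = set(genes[:k])
    es, _ = enrichment_score(rl, members)
    oracle = naive_es(rl.scores, [g in members for g in rl.genes])
    assert es == pytest.approx(oracle, abs=1e-12)
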