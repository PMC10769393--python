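"""Simulation studies validating the pipeline's statistical behavior.

Each routine generates its own inputs from a seed, runs the relevant
pipeline stages, and returns the measured quantities (oracle agreement,
coverage, recovery error, calibration rates). They are consumed by the test
suite and by ``scripts/acceptance.py``; problem sizes are chosen so the full
battery runs in a few minutes on one core.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import flag_significant, module_concordance
from .effects import EffectTable, fit_all_ages, fit_effects
from .enrichment import enrichment_score, gsea_preranked, rank_genes
from .normalize import ExpressionMatrix, combat_correct, housekeeping_normalize, log_transform
from .simulate import SimulationConfig, generate_counts, generate_human_reference

__all__ = [
    "ols_oracle_error",
    "ci_coverage",
    "concordance_recovery",
    "gsea_oracle_agreement",
    "gsea_permutation_vs_exhaustive",
    "ora_exact_agreement",
    "batch_correction_metrics",
    "normalization_invariances",
    "end_to_end_separation",
]

FIVE_STRAINS = {
    "B6J": "baseline",
    "LOAD1": "comparator",
    "5xFAD": "transgenic",
    "Abca7": "variant",
    "Sorl1": "variant",
}


def _subseed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def naive_running_sum_es(scores: np.ndarray, member: list[bool], weight: float = 1.0) -> float:
    """Loop-based enrichment-score oracle (independent of the vectorized path)."""
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


def ols_oracle_error(seed: int, n_designs: int = 100) -> dict:
    """Max relative deviation of the per-gene OLS from (X'X)^-1 X'y.

    Random balanced-ish 0/1 designs with up to 8 factors and 60 samples.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_designs:
        n = int(rng.integers(12, 61))
        p = int(rng.integers(2, 9))
        X = np.column_stack([np.ones(n), rng.integers(0, 2, size=(n, p - 1))])
        if np.linalg.matrix_rank(X) < p:
            continue
        Y = rng.normal(size=(4, n))
        design = pd.DataFrame(
            X, columns=["intercept"] + [f"f{j}" for j in range(p - 1)],
            index=[f"s{i}" for i in range(n)],
        )
        expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(4)], columns=design.index)
        eff = fit_effects(expr, design, age=0)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y.T  # p x genes
        got = eff.beta_matrix(include_intercept=True).loc[design.columns].to_numpy()
        rel = np.abs(got - oracle) / np.maximum(np.abs(oracle), 1e-12)
        worst = max(worst, float(rel.max()))
        done += 1
    return {"max_rel_err": worst, "n": n_designs}


def ci_coverage(seed: int, n_genes: int = 300) -> dict:
    """Empirical 95% CI coverage of planted effects at 6 animals/sex/group."""
    cfg = SimulationConfig(
        n_genes=n_genes,
        n_housekeeping=8,
        strains=dict(FIVE_STRAINS),
        n_per_group=6,
        ages=(12,),
        n_batches=1,
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        seed=_subseed(seed, 1),
    )
    counts, annot, truth = generate_counts(cfg)
    # rescale the per-lane ratios by the reference housekeeping geometric
    # mean (count scale restored) so the +1 pseudocount stays negligible,
    # and use natural log so fitted betas share the planted effects' scale
    hk = cfg.housekeeping_genes()
    normed = housekeeping_normalize(counts, hk)
    reference = np.exp(np.log(counts.loc[hk].to_numpy(dtype=float)).mean())
    expr = log_transform(normed * reference, base=np.e)
    eff = fit_all_ages(expr, annot, dict(cfg.strains))[12]
    tcrit = stats.t.ppf(0.975, eff.table["df"].iloc[0])
    covered = total = 0
    for factor in eff.factors:
        sub = eff.table[eff.table["factor"] == factor].set_index("gene")
        truth_vec = truth.beta_true.loc[factor]
        lo = sub["beta"] - tcrit * sub["se"]
        hi = sub["beta"] + tcrit * sub["se"]
        ok = (truth_vec.loc[sub.index] >= lo) & (truth_vec.loc[sub.index] <= hi)
        covered += int(ok.sum())
        total += len(ok)
    return {"coverage": covered / total, "n": total}


def concordance_recovery(
    seed: int,
    rhos: tuple[float, ...] = (0.0, 0.3, 0.6),
    module_size: int = 100,
    reps: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Recovery of planted factor-module correlations over many replicates.

    Each replicate draws fresh planted mouse effects and a fresh human
    contrast with the target rho; the concordance stage runs on the exact
    planted effect vectors. Reports, per rho, the mean Fisher-z deviation
    from the expectation (in units of the z standard error of the mean),
    plus the rate at which null (rho = 0) cells are flagged at ``alpha``.
    """
    out: dict = {"module_size": module_size, "reps": reps}
    null_flags = 0
    null_cells = 0
    for ridx, rho in enumerate(rhos):
        zs = []
        for rep in range(reps):
            cfg = SimulationConfig(
                n_genes=150,
                n_housekeeping=10,
                strains={"B6J": "baseline", "LOAD1": "comparator", "Sorl1": "variant"},
                n_per_group=1,
                sexes=("F",),
                ages=(12,),
                n_batches=1,
                frac_affected=0.5,
                seed=_subseed(seed, 100 + 1000 * ridx + rep),
            )
            _, _, truth = generate_counts(cfg)
            catalog, contrasts, _, homologs = generate_human_reference(
                cfg,
                truth,
                [module_size, module_size],
                planted={"M01": ("Sorl1", rho), "M02": ("Sorl1", 0.0)},
                seed=_subseed(seed, 500_000 + 1000 * ridx + rep),
            )
            eff = EffectTable.from_betas(truth.beta_true, age=12)
            res = flag_significant(
                module_concordance(
                    eff, contrasts, catalog, homologs, list(truth.beta_true.columns)
                ),
                alpha=alpha,
            )
            cell = res.query("factor == 'Sorl1' and target == 'M01'").iloc[0]
            zs.append(np.arctanh(cell["r"]))
            null = res[~((res["factor"] == "Sorl1") & (res["target"] == "M01"))]
            null_flags += int((null["sig"] != "none").sum())
            null_cells += len(null)
        zs = np.asarray(zs)
        expected = np.arctanh(rho) + rho / (2 * (module_size - 1))
        se_mean = (1.0 / np.sqrt(module_size - 3)) / np.sqrt(reps)
        out[f"rho_{rho}"] = {
            "mean_r": float(np.tanh(zs.mean())),
            "z_deviation_sigmas": float(abs(zs.mean() - expected) / se_mean),
        }
    out["null_flag_rate"] = null_flags / null_cells
    out["null_cells"] = null_cells
    return out


def gsea_oracle_agreement(seed: int, cases: int = 1000, max_genes: int = 12) -> dict:
    """Exact agreement of the ES with the loop oracle on small random lists."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(cases):
        n = int(rng.integers(3, max_genes + 1))
        genes = [f"g{i:02d}" for i in range(n)]
        rl = rank_genes(pd.Series(rng.normal(size=n), index=genes))
        k = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=k, replace=False))
        es, _ = enrichment_score(rl, members)
        oracle = naive_running_sum_es(rl.scores, [g in members for g in rl.genes])
        worst = max(worst, abs(es - oracle))
    return {"max_abs_diff": worst, "n": cases}


def gsea_permutation_vs_exhaustive(
    seed: int, universe_size: int = 8, set_size: int = 3, n_perm: int = 10_000,
    instances: int = 5,
) -> dict:
    """Sampled permutation p against exhaustive membership enumeration."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(universe_size)]
    max_sigmas = 0.0
    for i in range(instances):
        rl = rank_genes(pd.Series(rng.normal(size=universe_size), index=genes))
        members = set(rng.choice(genes, size=set_size, replace=False))
        res = gsea_preranked(
            rl, {"t": members}, min_size=1, max_size=universe_size - 1,
            n_perm=n_perm, seed=_subseed(seed, 900 + i),
        )
        es_obs, p_hat = res["es"].iloc[0], res["p"].iloc[0]
        all_es = [
            naive_running_sum_es(rl.scores, [g in set(c) for g in rl.genes])
            for c in itertools.combinations(genes, set_size)
        ]
        same = [e for e in all_es if (e >= 0) == (es_obs >= 0)]
        exact = sum(abs(e) >= abs(es_obs) for e in same) / len(same)
        se = np.sqrt(max(exact * (1 - exact), 1.0 / n_perm) / n_perm)
        max_sigmas = max(max_sigmas, abs(p_hat - exact) / se)
    return {"max_deviation_sigmas": max_sigmas, "n_perm": n_perm, "instances": instances}


def ora_exact_agreement(seed: int) -> dict:
    """Hypergeometric p against exhaustive enumeration for small universes."""
    from .enrichment import ora_hypergeometric

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(20):
        N = int(rng.integers(6, 13))
        universe = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N))
        term = set(rng.choice(universe, size=K, replace=False))
        n = int(rng.integers(1, N + 1))
        query = set(rng.choice(universe, size=n, replace=False))
        res = ora_hypergeometric(query, {"T": term}, set(universe))
        k_obs = len(query & term)
        total = hits = 0
        for combo in itertools.combinations(universe, n):
            total += 1
            hits += len(set(combo) & term) >= k_obs
        worst = max(worst, abs(res["p"].iloc[0] - hits / total))
    canonical = ora_hypergeometric(
        {"a", "b", "c", "d", "e"},
        {"T": {"a", "b", "c", "d", "e"}},
        set("abcdefghij"),
    )["p"].iloc[0]
    return {"max_abs_diff": worst, "p_n10_k5": float(canonical)}


def batch_correction_metrics(
    seed: int, n_genes: int = 200, per_batch: int = 40, delta: float = 1.5,
    alpha: float = 0.05,
) -> dict:
    """Shift removal and residual batch signal after correction.

    Two batches of ``per_batch`` samples with a planted additive shift
    ``delta``; in the exact (unshrunk) regime the shift must vanish, and a
    per-gene one-way F-test across batches should flag at most chance level.
    """
    rng = np.random.default_rng(seed)
    n = 2 * per_batch
    Y = rng.normal(5, 1, (n_genes, 1)) + rng.normal(0, 0.5, (n_genes, n))
    Y[:, per_batch:] += delta
    samples = [f"s{i}" for i in range(n)]
    prov = {"normalized": True, "log_base": 2.0, "pseudocount": 1.0, "batch_corrected": False}
    expr = ExpressionMatrix(pd.DataFrame(Y, columns=samples), dict(prov))
    batch = pd.Series(["a"] * per_batch + ["b"] * per_batch, index=samples)
    corrected = combat_correct(expr, batch, shrink=False)
    diff = (
        corrected.values.iloc[:, per_batch:].mean(axis=1)
        - corrected.values.iloc[:, :per_batch].mean(axis=1)
    )
    shift_residual = float(np.abs(diff).max() / delta)
    pf = np.array(
        [
            stats.f_oneway(row[:per_batch], row[per_batch:]).pvalue
            for row in corrected.values.to_numpy()
        ]
    )
    f_rate = float((pf < alpha).mean())

    single = ExpressionMatrix(pd.DataFrame(Y, columns=samples), dict(prov))
    out_single = combat_correct(single, pd.Series(["a"] * n, index=samples))
    identity_dev = float((out_single.values - single.values).abs().to_numpy().max())
    return {
        "shift_residual_frac": shift_residual,
        "f_test_sig_rate": f_rate,
        "single_batch_max_change": identity_dev,
        "n_genes": n_genes,
        "per_batch": per_batch,
    }


def normalization_invariances(seed: int) -> dict:
    """Scale invariance of housekeeping normalization; log-base neutrality."""
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(200, (30, 12)) + 1,
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(12)],
    )
    hk = ["g0", "g1", "g2"]
    scaled = counts.copy()
    scaled.iloc[:, 0] *= 10
    a = housekeeping_normalize(counts, hk)
    b = housekeeping_normalize(scaled, hk)
    scale_dev = float((a - b).abs().to_numpy().max())

    cfg = SimulationConfig(
        n_genes=200, n_housekeeping=8, strains=dict(FIVE_STRAINS), n_per_group=4,
        ages=(12,), n_batches=1, seed=_subseed(seed, 11),
    )
    counts2, annot, truth = generate_counts(cfg)
    catalog, contrasts, _, homologs = generate_human_reference(
        cfg, truth, [60] * 4, seed=_subseed(seed, 12)
    )
    normed = housekeeping_normalize(counts2, cfg.housekeeping_genes())
    rs = {}
    rankings = {}
    for base in (2.0, np.e):
        eff = fit_all_ages(log_transform(normed, base=base), annot, dict(cfg.strains))[12]
        res = module_concordance(eff, contrasts, catalog, homologs, list(counts2.index))
        rs[base] = res["r"].to_numpy()
        rankings[base] = rank_genes(eff.betas("Sorl1")).genes
    return {
        "scale_invariance_max_diff": scale_dev,
        "log_base_max_r_delta": float(np.nanmax(np.abs(rs[2.0] - rs[np.e]))),
        "log_base_ranking_identical": float(rankings[2.0] == rankings[np.e]),
    }


def end_to_end_separation(
    seed: int, n_runs: int = 20, module_size: int = 100, rho: float = 0.6,
    alpha: float = 0.05,
) -> dict:
    """Planted-truth separation through the full count-to-flag chain.

    Each run simulates a full study (counts with batch effects, human
    references with three rho-planted and three null modules), normalizes,
    batch-corrects, fits the nested regression, and flags the concordance
    matrix. Reports the fraction of planted cells flagged
    significant-positive and the flag rate among null cells.
    """
    drivers = ["LOAD1", "Abca7", "Sorl1"]
    hits = planted_cells = 0
    null_flags = null_cells = 0
    for run in range(n_runs):
        cfg = SimulationConfig(
            n_genes=250,
            n_housekeeping=8,
            strains=dict(FIVE_STRAINS),
            n_per_group=6,
            ages=(12,),
            n_batches=2,
            seed=_subseed(seed, 2000 + run),
        )
        counts, annot, truth = generate_counts(cfg)
        planted = {
            "M01": ("LOAD1", rho),
            "M02": ("Abca7", rho),
            "M03": ("Sorl1", rho),
            "M04": ("LOAD1", 0.0),
            "M05": ("Abca7", 0.0),
            "M06": ("Sorl1", 0.0),
        }
        catalog, contrasts, _, homologs = generate_human_reference(
            cfg, truth, [module_size] * 6, planted=planted,
            seed=_subseed(seed, 600_000 + run),
        )
        expr = log_transform(housekeeping_normalize(counts, cfg.housekeeping_genes()))
        expr = combat_correct(expr, annot["batch"], covariates=annot[["strain", "sex"]])
        eff = fit_all_ages(expr, annot, dict(cfg.strains))[12]
        res = flag_significant(
            module_concordance(eff, contrasts, catalog, homologs, list(counts.index)),
            alpha=alpha,
        )
        planted_pairs = {(f, m) for m, (f, r) in planted.items() if r > 0}
        for _, row in res.iterrows():
            if (row["factor"], row["target"]) in planted_pairs:
                planted_cells += 1
                hits += row["sig"] == "pos"
            else:
                null_cells += 1
                null_flags += row["sig"] != "none"
    return {
        "sensitivity": hits / planted_cells,
        "null_flag_rate": null_flags / null_cells,
        "planted_cells": planted_cells,
        "null_cells": null_cells,
        "runs": n_runs,
    }
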