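"""Housekeeping normalization, log transform and empirical-Bayes batch correction.

The normalization model is the standard one for probe-count panels: within
each lane (sample), every count is divided by the geometric mean of the
designated housekeeping genes of that same lane, the ratios are
log-transformed, and residual lane/batch structure on the log scale is
removed with the parametric empirical-Bayes location/scale adjustment of
Johnson et al. (ComBat): per gene, standardize by the covariate-adjusted
grand mean and pooled variance, estimate per-batch additive (gamma) and
multiplicative (delta^2) effects, shrink them toward a normal and an
inverse-gamma prior with moment-matched hyperparameters, then adjust and
restore the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ProvenanceError, SingularDesignError, ValidationError

__all__ = ["ExpressionMatrix", "housekeeping_normalize", "log_transform", "combat_correct"]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Log-scale gene x sample expression with stage provenance.

    ``provenance`` records whether housekeeping normalization was applied,
    the log base and pseudocount, and whether batch correction has run; each
    stage refuses to run twice on the same object.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), dict(self.provenance))

    def to_tsv(self, path, provenance_path=None) -> None:
        import yaml

        self.values.to_csv(path, sep="\t", index_label="gene")
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                yaml.safe_dump(self.provenance, fh)


def housekeeping_normalize(counts: pd.DataFrame, housekeeping: list[str]) -> pd.DataFrame:
    """Divide each sample's counts by its housekeeping geometric mean.

    After this step the geometric mean of the housekeeping genes equals 1 in
    every sample; the operation is invariant to per-sample scaling and
    idempotent (a second pass divides by 1).
    """
    if not housekeeping:
        raise ValidationError("housekeeping gene list is empty")
    missing = [g for g in housekeeping if g not in counts.index]
    if missing:
        raise ValidationError(f"housekeeping genes absent from matrix: {missing}")
    hk = counts.loc[housekeeping].to_numpy(dtype=float)
    zero = np.argwhere(hk <= 0)
    if len(zero):
        g, s = zero[0]
        raise ValidationError(
            f"housekeeping gene {housekeeping[g]!r} has non-positive count "
            f"in sample {counts.columns[s]!r}"
        )
    geomean = np.exp(np.mean(np.log(hk), axis=0))
    return counts.astype(float) / geomean


def log_transform(
    normalized: pd.DataFrame, base: float = 2.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """``log_base(value + pseudocount)`` with provenance recording.

    A positive pseudocount is required whenever any value is zero. The base
    only rescales the output; Pearson correlations and rank-based statistics
    downstream are unaffected by it.
    """
    arr = normalized.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("normalized values must be >= 0")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (arr == 0).any():
        raise ValidationError("zero values require a positive pseudocount")
    if base <= 0 or base == 1:
        raise ValidationError("log base must be positive and != 1")
    vals = np.log(arr + pseudocount) / np.log(base)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=normalized.index, columns=normalized.columns),
        provenance={
            "normalized": True,
            "log_base": float(base),
            "pseudocount": float(pseudocount),
            "batch_corrected": False,
        },
    )


def combat_correct(
    expr: ExpressionMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    shrink: bool = True,
    conv: float = 1e-6,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch correction.

    Parameters
    ----------
    batch
        Sample -> batch label, aligned to ``expr.samples``.
    covariates
        Biological covariates to protect (e.g. strain and sex); categorical
        columns are dummy-coded. ``None`` corrects without protection.
    shrink
        Apply the empirical-Bayes shrinkage of the per-batch location and
        scale estimates. With ``shrink=False`` the exact per-batch estimates
        are removed (the large-sample limit of the EB adjustment).
    """
    if expr.provenance.get("batch_corrected"):
        raise ProvenanceError("expression matrix is already batch-corrected")
    batch = batch.reindex(expr.samples)
    if batch.isna().any():
        missing = batch.index[batch.isna()].tolist()
        raise ValidationError(f"samples without batch label: {missing}")

    levels = pd.unique(batch)
    if len(levels) < 2:
        log.info("single batch (%s): batch correction is the identity", levels[0])
        out = expr.copy()
        out.provenance["batch_corrected"] = True
        out.provenance["batch_method"] = "identity (single batch)"
        return out
    sizes = batch.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValidationError(f"batches with < 2 samples: {small.index.tolist()}")

    Y = expr.values.to_numpy(dtype=float)  # genes x samples
    n_genes, n = Y.shape
    onehot = pd.get_dummies(batch).astype(float)
    onehot = onehot[[lev for lev in levels]]  # declared batch order
    B = onehot.shape[1]

    if covariates is not None:
        cov = pd.get_dummies(covariates.reindex(expr.samples), drop_first=True).astype(float)
        # drop constant columns (e.g. a single-level factor)
        cov = cov.loc[:, cov.nunique() > 1]
    else:
        cov = pd.DataFrame(index=expr.samples)

    X = np.hstack([onehot.to_numpy(), cov.to_numpy()]) if cov.shape[1] else onehot.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"batch is confounded with covariates {list(cov.columns)}: design is rank deficient"
        )

    beta_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (B + q) x genes
    n_b = onehot.to_numpy().sum(axis=0)  # samples per batch
    grand = (n_b / n) @ beta_hat[:B]  # gene-wise covariate-adjusted grand mean
    resid = Y.T - X @ beta_hat
    var_pooled = np.mean(resid**2, axis=0)  # per gene, 1/n convention
    var_pooled = np.where(var_pooled <= 0, np.finfo(float).tiny, var_pooled)

    stand_mean = np.tile(grand[:, None], (1, n))
    if cov.shape[1]:
        stand_mean = stand_mean + (cov.to_numpy() @ beta_hat[B:]).T
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    batch_idx = [np.flatnonzero((batch == lev).to_numpy()) for lev in levels]
    gamma_hat = np.vstack([Z[:, idx].mean(axis=1) for idx in batch_idx])  # B x genes
    delta_hat = np.vstack([Z[:, idx].var(axis=1, ddof=1) for idx in batch_idx])

    if shrink:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for b, idx in enumerate(batch_idx):
            gamma_star[b], delta_star[b] = _eb_shrink(
                Z[:, idx], gamma_hat[b], delta_hat[b], conv=conv
            )
    else:
        gamma_star, delta_star = gamma_hat, delta_hat
    delta_star = np.maximum(delta_star, np.finfo(float).tiny)

    adj = np.empty_like(Z)
    for b, idx in enumerate(batch_idx):
        adj[:, idx] = (Z[:, idx] - gamma_star[b][:, None]) / np.sqrt(delta_star[b])[:, None]
    corrected = adj * sd + stand_mean

    out = ExpressionMatrix(
        pd.DataFrame(corrected, index=expr.genes, columns=expr.samples),
        dict(expr.provenance),
    )
    out.provenance["batch_corrected"] = True
    out.provenance["batch_method"] = (
        f"parametric EB location/scale ({'shrunk' if shrink else 'exact'}), {B} batches"
    )
    return out


def _eb_shrink(
    Zb: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray, conv: float
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative joint posterior for one batch's location/scale effects.

    Hyperparameters are moment-matched across genes: gamma ~ N(gamma_bar,
    tau^2), delta^2 ~ InvGamma(a, b) with (a, b) from the mean and variance
    of the per-gene scale estimates.
    """
    n_b = Zb.shape[1]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if s2 <= 0 or tau2 <= 0:
        # degenerate across-gene spread: nothing to shrink toward
        return gamma_hat.copy(), delta_hat.copy()
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(500):
        g_new = (tau2 * n_b * gamma_hat + d_old * gamma_bar) / (tau2 * n_b + d_old)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old
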