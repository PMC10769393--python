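"""Per-gene effect estimation with the nested-control multiple regression.

One joint ordinary-least-squares model per age cohort and gene:

    log(expr) = beta0 + sum_i beta_i * x_i + eps

where the indicators x_i cover sex (male) and every non-baseline strain. The
encoding is nested: the baseline strain (B6J) is the all-zero reference, the
transgenic (5xFAD) and comparator (LOAD1) strains set only their own
indicator, and each variant strain sets the comparator indicator *and* its
own, so a variant's beta is its effect relative to the comparator
background. A ``flat`` encoding (every strain its own sole indicator,
relative to baseline) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SingularDesignError, ValidationError
from .normalize import ExpressionMatrix
from .simulate import VALID_ROLES

__all__ = ["build_design", "fit_effects", "fit_all_ages", "EffectTable"]

INTERCEPT = "intercept"


def build_design(
    annotations: pd.DataFrame,
    strain_roles: Mapping[str, str],
    encoding: str = "nested",
) -> pd.DataFrame:
    """Build the samples x factors 0/1 design matrix (with intercept).

    Factor order: intercept, male, then the non-baseline strains in the
    order of ``strain_roles``.
    """
    if encoding not in ("nested", "flat"):
        raise ValidationError(f"unknown encoding {encoding!r}")
    bad_roles = {r for r in strain_roles.values()} - VALID_ROLES
    if bad_roles:
        raise ValidationError(f"unknown strain roles: {sorted(bad_roles)}")
    unknown = sorted(set(annotations["strain"]) - set(strain_roles))
    if unknown:
        raise ValidationError(f"strains without a declared role: {unknown}")
    bad_sex = sorted(set(annotations["sex"]) - {"F", "M"})
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {bad_sex}")

    present = set(annotations["strain"])
    comparator = next((s for s, r in strain_roles.items() if r == "comparator"), None)
    strain_cols = [
        s for s, r in strain_roles.items() if r != "baseline" and (s in present or s == comparator)
    ]
    # drop an absent comparator column unless a variant needs it
    if comparator is not None and comparator not in present:
        needs = any(
            strain_roles[s] == "variant" and s in present for s in strain_roles
        ) and encoding == "nested"
        if not needs:
            strain_cols = [s for s in strain_cols if s != comparator]

    # a single-sex cohort carries no sex contrast
    sex_cols = ["male"] if annotations["sex"].nunique() > 1 else []
    X = pd.DataFrame(0.0, index=annotations.index, columns=[INTERCEPT, *sex_cols, *strain_cols])
    X[INTERCEPT] = 1.0
    if sex_cols:
        X.loc[annotations["sex"] == "M", "male"] = 1.0
    for sid, strain in annotations["strain"].items():
        role = strain_roles[strain]
        if role == "baseline":
            continue
        X.loc[sid, strain] = 1.0
        if encoding == "nested" and role == "variant" and comparator is not None:
            X.loc[sid, comparator] = 1.0

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank deficient; check that reference strains "
            f"are present (columns: {list(X.columns)})"
        )
    return X


@dataclass
class EffectTable:
    """Long-format per-gene effect estimates for one age cohort.

    Columns: age, factor, gene, beta, se, t, p, df. The intercept row is
    kept under factor ``intercept``; :attr:`factors` excludes it.
    """

    table: pd.DataFrame
    age: int | str
    n_samples: int

    @property
    def factors(self) -> list[str]:
        return [f for f in self.table["factor"].unique() if f != INTERCEPT]

    def beta_matrix(self, include_intercept: bool = False) -> pd.DataFrame:
        wide = self.table.pivot(index="factor", columns="gene", values="beta")
        order = [f for f in self.table["factor"].unique()]
        wide = wide.loc[order]
        if not include_intercept:
            wide = wide.drop(index=INTERCEPT, errors="ignore")
        return wide

    def betas(self, factor: str) -> pd.Series:
        sub = self.table[self.table["factor"] == factor]
        if sub.empty:
            raise KeyError(f"unknown factor {factor!r}")
        return pd.Series(sub["beta"].to_numpy(), index=sub["gene"].tolist(), name=factor)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_betas(cls, beta: pd.DataFrame, age: int | str = 0) -> "EffectTable":
        """Wrap a factor x gene coefficient matrix (no inference columns).

        Useful for feeding externally obtained or exactly known effect
        vectors into the concordance and enrichment stages.
        """
        rows = []
        for factor in beta.index:
            rows.append(
                pd.DataFrame(
                    {
                        "age": age,
                        "factor": factor,
                        "gene": beta.columns,
                        "beta": beta.loc[factor].to_numpy(dtype=float),
                        "se": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                        "df": 0,
                    }
                )
            )
        return cls(table=pd.concat(rows, ignore_index=True), age=age, n_samples=0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EffectTable":
        df = pd.read_csv(path, sep="\t")
        ages = df["age"].unique()
        if len(ages) != 1:
            raise ValidationError(f"effect table mixes ages {ages.tolist()}")
        n = int(df["df"].iloc[0] + df["factor"].nunique())
        return cls(table=df, age=ages[0], n_samples=n)


def fit_effects(
    expr: ExpressionMatrix | pd.DataFrame,
    design: pd.DataFrame,
    age: int | str,
) -> EffectTable:
    """Per-gene OLS of log expression on the design matrix.

    Standard errors use the unbiased residual variance on ``n - p`` degrees
    of freedom; two-sided p-values come from the t distribution. Genes with
    zero residual variance are flagged with ``p = NA``.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [s for s in design.index if s not in values.columns]
    if missing:
        raise ValidationError(f"design samples absent from expression matrix: {missing}")
    Y = values[design.index].to_numpy(dtype=float)  # genes x n
    X = design.to_numpy(dtype=float)  # n x p
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need more samples ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = Y @ X @ XtX_inv  # genes x p
    resid = Y - beta @ X.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))  # genes x p

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate fit: residual variance at rounding level relative to the data
    scale = np.maximum((Y**2).mean(axis=1), np.finfo(float).tiny)
    zero_var = sigma2 <= (1e3 * np.finfo(float).eps) ** 2 * scale
    t[zero_var] = np.nan
    pvals[zero_var] = np.nan
    se[zero_var] = 0.0

    genes = values.index
    rows = []
    for j, factor in enumerate(design.columns):
        rows.append(
            pd.DataFrame(
                {
                    "age": age,
                    "factor": factor,
                    "gene": genes,
                    "beta": beta[:, j],
                    "se": se[:, j],
                    "t": t[:, j],
                    "p": pvals[:, j],
                    "df": df,
                }
            )
        )
    return EffectTable(table=pd.concat(rows, ignore_index=True), age=age, n_samples=n)


def fit_all_ages(
    expr: ExpressionMatrix | pd.DataFrame,
    annotations: pd.DataFrame,
    strain_roles: Mapping[str, str],
    ages: Sequence[int] | None = None,
    encoding: str = "nested",
) -> dict[int, EffectTable]:
    """Fit one joint model per age cohort (separate models per age)."""
    if ages is None:
        ages = sorted(annotations["age_months"].unique())
    out: dict[int, EffectTable] = {}
    for age in ages:
        sub = annotations[annotations["age_months"] == age]
        if sub.empty:
            raise ValidationError(f"no samples at age {age}")
        design = build_design(sub, strain_roles, encoding=encoding)
        out[age] = fit_effects(expr, design, age)
    return out
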