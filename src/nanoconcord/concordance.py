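"""Mouse-human concordance: Pearson correlations with significance flags.

The headline statistic: for each mouse factor (sex or strain effect) and
each human contrast (co-expression module AD/control, or disease subtype vs
control), the Pearson correlation between the factor's per-gene regression
coefficients and the human log2 fold changes over the homologous genes, with
the two-sided p-value of ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2``
degrees of freedom. Module correlations span the module genes on the panel;
subtype correlations span all homologous panel genes. Cells are flagged
significant-positive/negative at unadjusted ``p < alpha`` (strict), which is
the display rule used for the dot-matrix plots.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectTable
from .exceptions import ValidationError
from .homology import ModuleCatalog, map_homologs

__all__ = [
    "module_concordance",
    "subtype_concordance",
    "factor_factor_correlation",
    "flag_significant",
    "pearson_cell",
]

N_MIN_DEFAULT = 5

RESULT_COLUMNS = ["age", "factor", "target", "cluster", "r", "p", "n", "note"]


def pearson_cell(x: np.ndarray, y: np.ndarray, n_min: int = N_MIN_DEFAULT):
    """Pearson r and two-sided p for one cell, with the NA policy applied.

    Pairs with a non-finite value on either side are dropped; cells with
    fewer than ``n_min`` complete pairs (never fewer than 3) or a constant
    vector are reported as NA with the attained n and a reason.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < max(n_min, 3):
        return np.nan, np.nan, n, f"n={n} below minimum {max(n_min, 3)}"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n, "constant input vector"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return float(r), float(p), n, ""


def _effect_betas(effects: EffectTable, factors: Sequence[str] | None) -> dict[str, pd.Series]:
    names = list(factors) if factors is not None else effects.factors
    return {f: effects.betas(f) for f in names}


def module_concordance(
    effects: EffectTable,
    contrasts: Mapping[str, pd.Series],
    catalog: ModuleCatalog,
    homolog_map: pd.DataFrame,
    panel: Iterable[str] | None = None,
    n_min: int = N_MIN_DEFAULT,
    factors: Sequence[str] | None = None,
    policy: str = "1:1",
) -> pd.DataFrame:
    """Factor x module Pearson correlations over module-panel homolog pairs.

    For each module, the gene universe is the module's human genes mapped
    1:1 onto the panel; the mouse side is the factor's beta vector, the
    human side the module's log2FC contrast.
    """
    missing = [m for m in contrasts if m not in catalog.members]
    if missing:
        raise ValidationError(f"contrasts for unknown modules: {missing}")
    betas = _effect_betas(effects, factors)
    if panel is None:
        panel = effects.table["gene"].unique()
    rows = []
    for module, fc in contrasts.items():
        pairs = map_homologs(catalog.members[module], homolog_map, panel, policy=policy)
        pairs = [(h, m) for h, m in pairs if h in fc.index]
        for factor, beta in betas.items():
            usable = [(h, m) for h, m in pairs if m in beta.index]
            x = beta.loc[[m for _, m in usable]].to_numpy() if usable else np.array([])
            y = fc.loc[[h for h, _ in usable]].to_numpy() if usable else np.array([])
            r, p, n, note = pearson_cell(x, y, n_min=n_min)
            rows.append(
                {
                    "age": effects.age,
                    "factor": factor,
                    "target": module,
                    "cluster": catalog.cluster.get(module, ""),
                    "r": r,
                    "p": p,
                    "n": n,
                    "note": note,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def subtype_concordance(
    effects: EffectTable,
    subtype_contrasts: Mapping[str, pd.Series],
    homolog_map: pd.DataFrame,
    panel: Iterable[str] | None = None,
    n_min: int = N_MIN_DEFAULT,
    factors: Sequence[str] | None = None,
    policy: str = "1:1",
) -> pd.DataFrame:
    """Factor x (subtype x cohort) correlations over all homologous panel genes."""
    betas = _effect_betas(effects, factors)
    if panel is None:
        panel = effects.table["gene"].unique()
    rows = []
    for sid, fc in subtype_contrasts.items():
        pairs = map_homologs(fc.index, homolog_map, panel, policy=policy)
        for factor, beta in betas.items():
            usable = [(h, m) for h, m in pairs if m in beta.index]
            x = beta.loc[[m for _, m in usable]].to_numpy() if usable else np.array([])
            y = fc.loc[[h for h, _ in usable]].to_numpy() if usable else np.array([])
            r, p, n, note = pearson_cell(x, y, n_min=n_min)
            rows.append(
                {
                    "age": effects.age,
                    "factor": factor,
                    "target": sid,
                    "cluster": "",
                    "r": r,
                    "p": p,
                    "n": n,
                    "note": note,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def factor_factor_correlation(
    effects: EffectTable,
    factors: Sequence[str] | None = None,
    n_min: int = N_MIN_DEFAULT,
) -> pd.DataFrame:
    """Symmetric factor x factor correlation of beta vectors over panel genes.

    Each unordered pair is computed once and mirrored, so the matrix equals
    its transpose exactly; the diagonal is r = 1, p = 0.
    """
    betas = _effect_betas(effects, factors)
    names = list(betas)
    cells: dict[tuple[str, str], tuple] = {}
    for f in names:
        cells[(f, f)] = (1.0, 0.0, int(betas[f].notna().sum()), "")
    for f1, f2 in itertools.combinations(names, 2):
        b1, b2 = betas[f1].align(betas[f2], join="inner")
        r, p, n, note = pearson_cell(b1.to_numpy(), b2.to_numpy(), n_min=max(n_min, 3))
        cells[(f1, f2)] = cells[(f2, f1)] = (r, p, n, note)
    rows = [
        {
            "age": effects.age,
            "factor": f1,
            "target": f2,
            "cluster": "",
            "r": cells[(f1, f2)][0],
            "p": cells[(f1, f2)][1],
            "n": cells[(f1, f2)][2],
            "note": cells[(f1, f2)][3],
        }
        for f1 in names
        for f2 in names
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def flag_significant(
    matrix: pd.DataFrame, alpha: float = 0.05, adjust: str | None = None
) -> pd.DataFrame:
    """Annotate each cell with ``sig in {pos, neg, none}``.

    A cell is flagged when ``p < alpha`` strictly (a cell with p exactly
    equal to alpha is not flagged) and takes the sign of r. ``adjust="bh"``
    applies Benjamini-Hochberg across the cells first; the default matches
    the unadjusted display rule.
    """
    out = matrix.copy()
    p = out["p"].to_numpy(dtype=float)
    if adjust == "bh":
        from .enrichment import bh_adjust

        p = bh_adjust(p)
        out["p_adj"] = p
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    sig = np.where(
        np.isfinite(p) & (p < alpha),
        np.where(out["r"].to_numpy(dtype=float) > 0, "pos", "neg"),
        "none",
    )
    out["sig"] = sig
    return out


def pivot_matrix(result: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Reshape a long result table into a factor x target matrix."""
    return result.pivot(index="factor", columns="target", values=value)
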