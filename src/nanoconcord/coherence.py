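"""Directional-coherence driver analysis.

For a chosen factor and human module, isolate the homologous genes whose
mouse effect (beta) and human log2FC strictly agree in sign; these coherent
genes are the candidate drivers of a factor-module correlation. Their
over-representation among GO-style terms, intersected with the factor's
ranked-list enrichment, annotates shared terms back to the modules (and
consensus clusters) in which they appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import EffectTable
from .exceptions import LibraryMismatchError, ValidationError
from .homology import ModuleCatalog, map_homologs

__all__ = ["CoherentGeneSet", "directional_coherence", "shared_terms_to_modules"]


@dataclass
class CoherentGeneSet:
    """Genes of one (factor, module) pair with same-sign mouse/human change.

    ``pairs`` has one row per coherent gene: mouse_gene, human_gene, beta,
    log2fc. ``universe`` is the set of panel mouse genes that were mappable
    to the module's contrast (the ORA universe for this set).
    """

    factor: str
    module: str
    pairs: pd.DataFrame
    universe: tuple[str, ...]

    @property
    def mouse_genes(self) -> list[str]:
        return self.pairs["mouse_gene"].tolist()

    def __len__(self) -> int:
        return len(self.pairs)


def directional_coherence(
    effects: EffectTable,
    factor: str,
    contrasts: Mapping[str, pd.Series],
    module: str,
    catalog: ModuleCatalog,
    homolog_map: pd.DataFrame,
    panel: Iterable[str] | None = None,
    policy: str = "1:1",
) -> CoherentGeneSet:
    """Select module-panel homolog pairs with strictly same-sign changes.

    A gene with beta = 0 or log2FC = 0 carries no direction and is excluded.
    """
    if module not in catalog.members:
        raise ValidationError(f"unknown module {module!r}")
    if module not in contrasts:
        raise ValidationError(f"no contrast table for module {module!r}")
    beta = effects.betas(factor)  # raises KeyError for unknown factor
    if panel is None:
        panel = effects.table["gene"].unique()
    fc = contrasts[module]
    pairs = map_homologs(catalog.members[module], homolog_map, panel, policy=policy)
    pairs = [(h, m) for h, m in pairs if h in fc.index and m in beta.index]

    rows = []
    universe = []
    for h, m in pairs:
        b, f = float(beta[m]), float(fc[h])
        if not (np.isfinite(b) and np.isfinite(f)):
            continue
        universe.append(m)
        if b * f > 0:
            rows.append({"mouse_gene": m, "human_gene": h, "beta": b, "log2fc": f})
    return CoherentGeneSet(
        factor=factor,
        module=module,
        pairs=pd.DataFrame(rows, columns=["mouse_gene", "human_gene", "beta", "log2fc"]),
        universe=tuple(universe),
    )


def shared_terms_to_modules(
    gsea_terms: pd.DataFrame,
    coherent_ora_terms: Mapping[str, pd.DataFrame],
    catalog: ModuleCatalog,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotate terms significant in both enrichment runs to their modules.

    A term qualifies when its BH-adjusted p is below ``alpha`` in the
    factor's ranked-list GSEA *and* in at least one module's coherent-gene
    ORA; it is annotated to every qualifying module with that module's
    consensus cluster. Both runs must use the same term library.
    """
    gsea_libs = set(gsea_terms["library"].unique()) if len(gsea_terms) else set()
    for module, ora in coherent_ora_terms.items():
        ora_libs = set(ora["library"].unique()) if len(ora) else set()
        if gsea_libs and ora_libs and gsea_libs != ora_libs:
            raise LibraryMismatchError(
                f"GSEA library {sorted(gsea_libs)} != ORA library {sorted(ora_libs)} "
                f"for module {module!r}"
            )

    sig_gsea = gsea_terms[gsea_terms["padj"] < alpha] if len(gsea_terms) else gsea_terms
    rows = []
    for module, ora in coherent_ora_terms.items():
        if not len(ora):
            continue
        sig_ora = set(ora.loc[ora["padj"] < alpha, "term"])
        for _, grow in sig_gsea.iterrows():
            if grow["term"] in sig_ora:
                rows.append(
                    {
                        "term": grow["term"],
                        "module": module,
                        "cluster": catalog.cluster.get(module, ""),
                        "direction": grow["direction"],
                        "gsea_padj": grow["padj"],
                        "ora_padj": float(
                            ora.loc[ora["term"] == grow["term"], "padj"].iloc[0]
                        ),
                    }
                )
    return pd.DataFrame(
        rows, columns=["term", "module", "cluster", "direction", "gsea_padj", "ora_padj"]
    )
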