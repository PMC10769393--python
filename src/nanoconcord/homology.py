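"""Human-side reference loading: module catalogs, clusters, homolog mapping.

The module catalog mirrors the 30-module human brain co-expression set:
every module carries a consensus-cluster label (A-E) and a brain-region tag.
Homolog mapping is case-sensitive and, by default, restricted to
unambiguous 1:1 pairs after intersection with the mouse panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import FormatError, ValidationError
from .io import read_gmt

__all__ = ["ModuleCatalog", "read_modules", "map_homologs"]

log = logging.getLogger(__name__)

CONSENSUS_CLUSTERS = ("A", "B", "C", "D", "E")


@dataclass
class ModuleCatalog:
    """Module id -> member human genes, with cluster and region labels."""

    members: dict[str, list[str]]
    cluster: dict[str, str]
    region: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, genes in self.members.items():
            if not genes:
                raise ValidationError(f"module {m!r} is empty")
            if m not in self.cluster:
                raise ValidationError(f"module {m!r} has no consensus-cluster label")

    def __len__(self) -> int:
        return len(self.members)

    def modules(self) -> list[str]:
        return list(self.members)


def read_modules(gmt_path: str | Path, cluster_map_path: str | Path) -> ModuleCatalog:
    """Read a GMT module catalog and join consensus-cluster labels.

    The cluster map is a TSV with columns ``module``, ``cluster`` and
    optionally ``region``; every GMT module must appear in it.
    """
    members = read_gmt(gmt_path)
    cmap = pd.read_csv(cluster_map_path, sep="\t")
    for col in ("module", "cluster"):
        if col not in cmap.columns:
            raise FormatError(f"{cluster_map_path}: missing column {col!r}")
    cluster = dict(zip(cmap["module"].astype(str), cmap["cluster"].astype(str)))
    missing = [m for m in members if m not in cluster]
    if missing:
        raise ValidationError(f"modules missing from cluster map: {missing}")
    region = (
        dict(zip(cmap["module"].astype(str), cmap["region"].astype(str)))
        if "region" in cmap.columns
        else {}
    )
    return ModuleCatalog(members=members, cluster=cluster, region=region)


def map_homologs(
    human_genes: Iterable[str],
    homolog_map: pd.DataFrame,
    panel: Iterable[str],
    policy: str = "1:1",
) -> list[tuple[str, str]]:
    """Pair query human genes with panel mouse genes through the homolog map.

    Only pairs whose mouse gene is on the panel are considered. Under the
    default ``1:1`` policy, any human or mouse gene that is ambiguous after
    the panel restriction (maps to more than one partner) is dropped
    entirely; ``"all"`` keeps every pair. Output is sorted by mouse gene.
    """
    if policy not in ("1:1", "all"):
        raise ValidationError(f"unknown homolog policy {policy!r}")
    panel = set(panel)
    query = set(human_genes)
    sub = homolog_map[homolog_map["mouse_gene"].isin(panel)].drop_duplicates()
    if policy == "1:1":
        n_before = len(sub)
        sub = sub[~sub["human_gene"].duplicated(keep=False)]
        sub = sub[~sub["mouse_gene"].duplicated(keep=False)]
        dropped = n_before - len(sub)
        if dropped:
            log.info("dropped %d ambiguous homolog pairs under 1:1 policy", dropped)
    pairs = [
        (h, m)
        for h, m in zip(sub["human_gene"], sub["mouse_gene"])
        if h in query
    ]
    return sorted(pairs, key=lambda hm: hm[1])
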