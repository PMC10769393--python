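"""End-to-end orchestration: normalize -> fit per age -> correlate -> enrich.

A single YAML config names every input file and parameter; the run emits
per-age effect tables, the three concordance matrices, enrichment and
coherence tables, a provenance manifest (parameters, seeds, input
checksums) and a human-readable summary. Given the same config and seed the
output tables are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coherence import directional_coherence, shared_terms_to_modules
from .concordance import (
    factor_factor_correlation,
    flag_significant,
    module_concordance,
    subtype_concordance,
)
from .effects import fit_all_ages
from .enrichment import gsea_preranked, ora_hypergeometric, rank_genes
from .exceptions import NanoconcordError, ValidationError
from .homology import read_modules
from .io import read_contrasts, read_counts, read_gene_list, read_gmt, read_homolog_map
from .normalize import combat_correct, housekeeping_normalize, log_transform

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

log = logging.getLogger(__name__)

_PATH_FIELDS = (
    "counts",
    "annotations",
    "housekeeping",
    "roles",
    "modules_gmt",
    "cluster_map",
    "module_contrasts",
    "subtype_contrasts",
    "homolog_map",
    "term_gmt",
)


@dataclass
class PipelineConfig:
    """Paths and parameters of one orchestrated run."""

    counts: Path
    annotations: Path
    housekeeping: Path
    roles: Path
    modules_gmt: Path
    cluster_map: Path
    module_contrasts: Path
    subtype_contrasts: Path
    homolog_map: Path
    term_gmt: Path
    outdir: Path
    ages: tuple[int, ...] = (4, 12)
    alpha: float = 0.05
    n_min: int = 5
    log_base: float = 2.0
    pseudocount: float = 1.0
    batch_covariates: tuple[str, ...] = ("strain", "sex")
    homolog_policy: str = "1:1"
    gsea_weight: float = 1.0
    gsea_n_perm: int = 10_000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    encoding: str = "nested"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (*_PATH_FIELDS, "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        self.ages = tuple(self.ages)
        self.batch_covariates = tuple(self.batch_covariates)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        for name in (*_PATH_FIELDS, "outdir"):
            if name in raw and not Path(raw[name]).is_absolute():
                raw[name] = base / raw[name]
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        missing = {f.name for f in dataclasses.fields(cls) if f.default is dataclasses.MISSING} - set(raw)
        if missing:
            raise ValidationError(f"missing config keys: {sorted(missing)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
            elif isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check file existence, parseability and gene/sample universe overlaps."""
    report = ValidationReport()
    for name in _PATH_FIELDS:
        path = getattr(config, name)
        if not Path(path).exists():
            report.errors.append(f"{name}: file not found: {path}")
    if not config.ages:
        report.errors.append("ages: must be non-empty")
    if report.errors:
        return report

    try:
        counts, annot = read_counts(config.counts, config.annotations)
    except NanoconcordError as exc:
        report.errors.append(f"counts/annotations: {exc}")
        return report
    panel = set(counts.index)

    hk = read_gene_list(config.housekeeping)
    missing_hk = [g for g in hk if g not in panel]
    if missing_hk:
        report.errors.append(f"housekeeping genes absent from panel: {missing_hk}")

    with open(config.roles) as fh:
        roles = yaml.safe_load(fh)
    undeclared = sorted(set(annot["strain"]) - set(roles))
    if undeclared:
        report.errors.append(f"strains without declared role: {undeclared}")

    for age in config.ages:
        if not (annot["age_months"] == age).any():
            report.warnings.append(f"no samples at age {age}")

    try:
        catalog = read_modules(config.modules_gmt, config.cluster_map)
        contrasts = read_contrasts(config.module_contrasts)
        hmap = read_homolog_map(config.homolog_map)
    except NanoconcordError as exc:
        report.errors.append(str(exc))
        return report
    mouse_of = dict(zip(hmap["human_gene"], hmap["mouse_gene"]))
    for module, genes in catalog.members.items():
        mappable = [g for g in genes if mouse_of.get(g) in panel]
        if not mappable:
            report.warnings.append(f"module {module}: no panel-mappable genes")
    missing_contrast = [m for m in catalog.members if m not in contrasts]
    if missing_contrast:
        report.warnings.append(f"modules without contrast table: {missing_contrast}")

    terms = read_gmt(config.term_gmt)
    if not terms:
        report.errors.append("term library is empty")
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _save(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write all result tables under ``outdir``.

    Stage order: housekeeping normalization, log transform, batch
    correction, per-age regression, module/subtype/factor-factor
    concordance, per-factor ranked-list GSEA, directional-coherence ORA and
    shared-term annotation. Any stage error is re-raised with the stage name
    after a FAILED marker is written; partial outputs are retained.
    """
    report = validate_inputs(config)
    if not report.ok:
        raise ValidationError("input validation failed:\n" + "\n".join(report.errors))

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "read"
        counts, annot = read_counts(config.counts, config.annotations)
        hk = read_gene_list(config.housekeeping)
        with open(config.roles) as fh:
            roles = yaml.safe_load(fh)
        catalog = read_modules(config.modules_gmt, config.cluster_map)
        contrasts = read_contrasts(config.module_contrasts)
        subtype_contrasts = read_contrasts(config.subtype_contrasts)
        hmap = read_homolog_map(config.homolog_map)
        terms = {t: set(g) for t, g in read_gmt(config.term_gmt).items()}
        panel = list(counts.index)

        stage = "normalize"
        normed = housekeeping_normalize(counts, hk)
        expr = log_transform(normed, base=config.log_base, pseudocount=config.pseudocount)
        covariates = (
            annot[list(config.batch_covariates)] if config.batch_covariates else None
        )
        expr = combat_correct(expr, annot["batch"], covariates=covariates)
        expr.to_tsv(out / "expression.tsv", out / "expression_provenance.yaml")

        stage = "fit"
        effects_by_age = fit_all_ages(
            expr, annot, roles, ages=config.ages, encoding=config.encoding
        )
        for age, eff in effects_by_age.items():
            eff.to_tsv(out / f"effects_{age}mo.tsv")

        summary_lines = [f"nanoconcord {__version__} pipeline run", ""]
        for age, eff in effects_by_age.items():
            stage = f"concordance (age {age})"
            mod = flag_significant(
                module_concordance(
                    eff, contrasts, catalog, hmap, panel,
                    n_min=config.n_min, policy=config.homolog_policy,
                ),
                alpha=config.alpha,
            )
            _save(mod, out / f"module_concordance_{age}mo.tsv")
            sub = flag_significant(
                subtype_concordance(
                    eff, subtype_contrasts, hmap, panel,
                    n_min=config.n_min, policy=config.homolog_policy,
                ),
                alpha=config.alpha,
            )
            _save(sub, out / f"subtype_concordance_{age}mo.tsv")
            ff = flag_significant(factor_factor_correlation(eff), alpha=config.alpha)
            _save(ff, out / f"factor_factor_{age}mo.tsv")

            stage = f"enrichment (age {age})"
            gsea_by_factor = {}
            gsea_frames = []
            for i, factor in enumerate(eff.factors):
                res = gsea_preranked(
                    rank_genes(eff.betas(factor)),
                    terms,
                    weight_exponent=config.gsea_weight,
                    n_perm=config.gsea_n_perm,
                    min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                    seed=config.seed + 7919 * i,
                    library=Path(config.term_gmt).stem,
                )
                res.insert(0, "factor", factor)
                res.insert(0, "age", age)
                gsea_by_factor[factor] = res
                gsea_frames.append(res)
            gsea_all = pd.concat(gsea_frames, ignore_index=True)
            _save(gsea_all, out / f"gsea_{age}mo.tsv")

            stage = f"coherence (age {age})"
            coherent_rows = []
            shared_frames = []
            sig_pos = mod[mod["sig"] == "pos"]
            for factor in sig_pos["factor"].unique():
                modules = sig_pos.loc[sig_pos["factor"] == factor, "target"].tolist()
                ora_by_module = {}
                for module in modules:
                    cset = directional_coherence(
                        eff, factor, contrasts, module, catalog, hmap, panel,
                        policy=config.homolog_policy,
                    )
                    for _, row in cset.pairs.iterrows():
                        coherent_rows.append(
                            {"age": age, "factor": factor, "module": module, **row.to_dict()}
                        )
                    if len(cset) and len(cset.universe) > len(cset):
                        ora_by_module[module] = ora_hypergeometric(
                            cset.mouse_genes, terms, cset.universe,
                            library=Path(config.term_gmt).stem,
                        )
                if ora_by_module:
                    shared = shared_terms_to_modules(
                        gsea_by_factor[factor], ora_by_module, catalog, alpha=config.alpha
                    )
                    shared.insert(0, "factor", factor)
                    shared.insert(0, "age", age)
                    shared_frames.append(shared)
            _save(
                pd.DataFrame(
                    coherent_rows,
                    columns=["age", "factor", "module", "mouse_gene", "human_gene", "beta", "log2fc"],
                ),
                out / f"coherent_genes_{age}mo.tsv",
            )
            shared_all = (
                pd.concat(shared_frames, ignore_index=True)
                if shared_frames
                else pd.DataFrame(
                    columns=["age", "factor", "term", "module", "cluster", "direction", "gsea_padj", "ora_padj"]
                )
            )
            _save(shared_all, out / f"shared_terms_{age}mo.tsv")

            n_pos = int((mod["sig"] == "pos").sum())
            n_neg = int((mod["sig"] == "neg").sum())
            summary_lines += [
                f"age {age} months: {eff.n_samples} samples, {len(eff.factors)} factors",
                f"  module cells flagged: {n_pos} positive, {n_neg} negative "
                f"of {len(mod)} (alpha={config.alpha})",
                f"  subtype cells flagged: {int((sub['sig'] != 'none').sum())} of {len(sub)}",
                f"  GSEA terms FDR<{config.alpha}: "
                f"{int((gsea_all['padj'] < config.alpha).sum())} of {len(gsea_all)}",
                f"  coherent driver genes recorded: {len(coherent_rows)}",
            ]

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "input_sha256": {name: _sha256(getattr(config, name)) for name in _PATH_FIELDS},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise NanoconcordError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
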