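"""Synthetic panel-count and human-reference generator with planted truth.

Emulates a targeted expression panel experiment across mouse strains: a
baseline strain (B6J), a sensitized comparator background (LOAD1), a
transgenic amyloidosis model (5xFAD) and a set of variant strains carried on
the comparator background. Counts are negative binomial on a log-normal
per-gene baseline, with additive per-batch (lane) location shifts and a
multiplicative batch dispersion scale, so that the location/scale batch model
assumed by the correction stage is exactly the generating model and its
removal is verifiable.

Human-side references (co-expression module catalog, per-module and
per-subtype log2 fold-change contrast tables, homolog map) are generated with
a *planted* gene-level concordance: for a module driven by factor ``f`` with
target correlation ``rho``, the human log2FC over the module genes is

    rho * standardize(beta_true[f, genes]) + sqrt(1 - rho^2) * noise

so the population Pearson correlation against the planted mouse effect equals
``rho`` by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticBundle",
    "generate_counts",
    "generate_human_reference",
    "generate_term_library",
    "generate_bundle",
    "write_bundle",
]

#: strain -> control-role table mirroring the study design: the baseline is
#: the reference for the transgenic and comparator strains, and the comparator
#: is the reference background for every variant strain.
DEFAULT_STRAINS: dict[str, str] = {
    "B6J": "baseline",
    "LOAD1": "comparator",
    "5xFAD": "transgenic",
    "Abca7": "variant",
    "Ceacam1": "variant",
    "Mthfr": "variant",
    "Shc2": "variant",
    "Slc6a17": "variant",
    "Clasp2": "variant",
    "Sorl1": "variant",
    "Meox2": "variant",
    "Snx1": "variant",
    "Plcg2": "variant",
    "Mtmr4": "variant",
}

VALID_ROLES = {"baseline", "comparator", "transgenic", "variant"}

#: subtype layout per human cohort (two inflammatory-vs-not strata in ROSMAP
#: and MSBB, three in Mayo).
DEFAULT_COHORT_SUBTYPES: dict[str, tuple[str, ...]] = {
    "ROSMAP": ("A", "B"),
    "Mayo": ("A", "B", "C"),
    "MSBB": ("A", "B"),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the scale of the mouse AD panel study: a ~760-gene
    panel with 10 housekeeping genes, the full strain table, six animals per
    strain/sex/age, and two age cohorts (4 and 12 months).
    """

    n_genes: int = 760
    n_housekeeping: int = 10
    strains: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STRAINS))
    n_per_group: int = 6
    sexes: tuple[str, ...] = ("F", "M")
    ages: tuple[int, ...] = (4, 12)
    n_batches: int = 4
    batch_shift_sd: float = 0.2
    batch_scale_sd: float = 0.05
    effect_sd: float = 0.5
    frac_affected: float = 0.3
    dispersion: float = 0.1
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not (0 <= self.n_housekeeping < self.n_genes):
            raise ValidationError("n_housekeeping must be in [0, n_genes)")
        if not self.strains:
            raise ValidationError("strains must be non-empty")
        roles = set(self.strains.values())
        bad = roles - VALID_ROLES
        if bad:
            raise ValidationError(f"unknown strain roles: {sorted(bad)}")
        n_baseline = sum(r == "baseline" for r in self.strains.values())
        if n_baseline != 1:
            raise ValidationError("exactly one baseline strain is required")
        if len(self.strains) < 2:
            raise ValidationError("at least one non-baseline strain is required")
        if "variant" in roles and "comparator" not in roles:
            raise ValidationError("variant strains require a comparator strain")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if not self.sexes:
            raise ValidationError("sexes must be non-empty")
        if not self.ages:
            raise ValidationError("ages must be non-empty")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")
        if not (0.0 <= self.frac_affected <= 1.0):
            raise ValidationError("frac_affected must be in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        for name in ("batch_shift_sd", "batch_scale_sd", "effect_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    # -- derived helpers -------------------------------------------------
    @property
    def baseline_strain(self) -> str:
        return next(s for s, r in self.strains.items() if r == "baseline")

    @property
    def comparator_strain(self) -> str | None:
        return next((s for s, r in self.strains.items() if r == "comparator"), None)

    @property
    def factors(self) -> list[str]:
        """Model factors: sex (male) plus every non-baseline strain."""
        return ["male"] + [s for s, r in self.strains.items() if r != "baseline"]

    def gene_names(self) -> list[str]:
        hk = [f"Hk{i + 1:02d}" for i in range(self.n_housekeeping)]
        n_reg = self.n_genes - self.n_housekeeping
        return hk + [f"Gene{i + 1:04d}" for i in range(n_reg)]

    def housekeeping_genes(self) -> list[str]:
        return self.gene_names()[: self.n_housekeeping]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strains"] = dict(self.strains)
        return d


@dataclass
class PlantedTruth:
    """Ground truth as used by the generator.

    ``beta_true`` is the factor x gene matrix of planted log-scale effects
    (natural log); housekeeping rows are exactly zero. ``batch_shift`` /
    ``batch_scale`` hold the additive log-scale lane shifts and dispersion
    scale factors. ``rho_modules`` / ``rho_subtypes`` record, per factor and
    human contrast, the planted population concordance.
    """

    beta_true: pd.DataFrame
    batch_shift: pd.DataFrame
    batch_scale: pd.DataFrame
    rho_modules: pd.DataFrame | None = None
    rho_subtypes: pd.DataFrame | None = None


def generate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Draw a gene x sample count matrix with annotations and planted truth.

    The log-mean of a sample is the gene baseline plus the male effect (if
    male) plus its strain contributions plus the lane shift. A variant-strain
    sample receives *both* the comparator (LOAD1) effect and its own variant
    effect, matching the nested control structure of the design.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = config.gene_names()
    hk = set(config.housekeeping_genes())
    free_genes = [g for g in genes if g not in hk]
    factors = config.factors

    # planted effects: exactly round(frac_affected * n_free) genes per factor
    beta = pd.DataFrame(0.0, index=factors, columns=genes)
    n_hit = int(round(config.frac_affected * len(free_genes)))
    for f in factors:
        hit = rng.choice(len(free_genes), size=n_hit, replace=False)
        vals = rng.normal(0.0, config.effect_sd, size=n_hit)
        beta.loc[f, [free_genes[i] for i in hit]] = vals

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=len(genes))
    # housekeeping genes are chosen for high, stable expression: shift them
    # up and tighten their spread so lane geometric means are well-defined
    if config.n_housekeeping:
        nh = config.n_housekeeping
        baseline[:nh] = config.baseline_log_mean + 1.5 + 0.25 * config.baseline_log_sd * (
            (baseline[:nh] - config.baseline_log_mean)
            / max(config.baseline_log_sd, np.finfo(float).tiny)
        )

    # batch structure
    batches = [f"lane{b + 1}" for b in range(config.n_batches)]
    shift = pd.DataFrame(
        rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, len(genes))),
        index=batches,
        columns=genes,
    )
    scale = pd.DataFrame(
        np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, len(genes)))),
        index=batches,
        columns=genes,
    )

    # sample table
    rows = []
    for age in config.ages:
        for strain in config.strains:
            for sex in config.sexes:
                for i in range(config.n_per_group):
                    rows.append(
                        {
                            "sample_id": f"{strain}_{sex}_{age}m_{i + 1}",
                            "strain": strain,
                            "sex": sex,
                            "age_months": age,
                            "batch": "",
                        }
                    )
    annot = pd.DataFrame(rows).set_index("sample_id")
    # balanced random lane assignment, independent of strain/sex/age
    order = rng.permutation(len(annot))
    lane_of = np.empty(len(annot), dtype=object)
    for pos, idx in enumerate(order):
        lane_of[idx] = batches[pos % config.n_batches]
    annot["batch"] = lane_of

    comparator = config.comparator_strain
    beta_arr = beta.to_numpy()
    factor_index = {f: i for i, f in enumerate(factors)}

    counts = np.empty((len(genes), len(annot)), dtype=np.int64)
    for j, (sid, row) in enumerate(annot.iterrows()):
        mu = baseline.copy()
        if row["sex"] == "M":
            mu = mu + beta_arr[factor_index["male"]]
        strain = row["strain"]
        role = config.strains[strain]
        if role != "baseline":
            mu = mu + beta_arr[factor_index[strain]]
        if role == "variant" and comparator is not None:
            mu = mu + beta_arr[factor_index[comparator]]
        mu = mu + shift.loc[row["batch"]].to_numpy()
        mean = np.exp(mu)
        disp = config.dispersion * scale.loc[row["batch"]].to_numpy()
        counts[:, j] = _nb_draw(rng, mean, disp)

    count_df = pd.DataFrame(counts, index=genes, columns=annot.index)
    truth = PlantedTruth(beta_true=beta, batch_shift=shift, batch_scale=scale)
    return count_df, annot, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Negative binomial with mean ``mean`` and var mean + disp*mean^2.

    Zero dispersion degenerates to Poisson.
    """
    out = np.empty_like(mean, dtype=np.int64)
    pois = disp <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / disp[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


# --------------------------------------------------------------------------
# human reference generation
# --------------------------------------------------------------------------

def _default_planting(
    modules: Sequence[str], factors: Sequence[str], rho_cycle: Sequence[float]
) -> dict[str, tuple[str, float]]:
    """Round-robin assignment of a driver factor and a rho to each contrast."""
    out = {}
    usable = [f for f in factors if f != "male"]
    for i, m in enumerate(modules):
        out[m] = (usable[i % len(usable)], rho_cycle[i % len(rho_cycle)])
    return out


def generate_human_reference(
    config: SimulationConfig,
    truth: PlantedTruth,
    module_sizes: Sequence[int],
    planted: Mapping[str, tuple[str, float]] | None = None,
    subtype_planted: Mapping[str, tuple[str, float]] | None = None,
    cohort_subtypes: Mapping[str, Sequence[str]] | None = None,
    rho_cycle: Sequence[float] = (0.6, 0.0, 0.3),
    seed: int | None = None,
):
    """Generate module catalog, contrast tables and homolog map.

    Parameters
    ----------
    module_sizes
        Gene count per module; each must be >= 10 and fit in the
        non-housekeeping panel.
    planted
        Optional ``module -> (driver_factor, rho)`` map; by default drivers
        and rho values from ``rho_cycle`` are assigned round-robin. Only the
        driver factor has nonzero planted concordance with a module; all
        other factors are independent of its contrast.
    seed
        RNG seed for the human side; defaults to ``config.seed + 1_000_003``
        so the mouse and human draws are decoupled but jointly reproducible.

    Returns
    -------
    (catalog, module_contrasts, subtype_contrasts, homologs)
        ``catalog`` is a :class:`~nanoconcord.homology.ModuleCatalog`;
        contrasts are ``dict[str, pandas.Series]`` keyed by module id or
        ``"cohort.subtype"``, each Series indexed by human gene symbol;
        ``homologs`` is a two-column DataFrame (human_gene, mouse_gene).
    """
    from .homology import ModuleCatalog

    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)

    genes = config.gene_names()
    hk = set(config.housekeeping_genes())
    free_genes = [g for g in genes if g not in hk]
    for size in module_sizes:
        if size < 10:
            raise ValidationError(f"module size {size} < 10")
        if size > len(free_genes):
            raise ValidationError(
                f"module size {size} exceeds available non-housekeeping genes ({len(free_genes)})"
            )

    homologs = pd.DataFrame(
        {"human_gene": [g.upper() for g in genes], "mouse_gene": genes}
    )
    to_human = dict(zip(homologs["mouse_gene"], homologs["human_gene"]))

    module_names = [f"M{i + 1:02d}" for i in range(len(module_sizes))]
    clusters = {m: "ABCDE"[i % 5] for i, m in enumerate(module_names)}
    if planted is None:
        planted = _default_planting(module_names, config.factors, rho_cycle)

    members: dict[str, list[str]] = {}
    contrasts: dict[str, pd.Series] = {}
    rho_mod = pd.DataFrame(0.0, index=config.factors, columns=module_names)
    for m, size in zip(module_names, module_sizes):
        idx = rng.choice(len(free_genes), size=size, replace=False)
        mouse_members = sorted(free_genes[i] for i in idx)
        members[m] = [to_human[g] for g in mouse_members]
        driver, rho = planted[m]
        contrasts[m] = _planted_contrast(rng, truth.beta_true, driver, rho, mouse_members, to_human)
        rho_mod.loc[driver, m] = rho

    if cohort_subtypes is None:
        cohort_subtypes = DEFAULT_COHORT_SUBTYPES
    subtype_ids = [f"{c}.{s}" for c, subs in cohort_subtypes.items() for s in subs]
    if subtype_planted is None:
        subtype_planted = _default_planting(subtype_ids, config.factors, rho_cycle)
    subtype_contrasts: dict[str, pd.Series] = {}
    rho_sub = pd.DataFrame(0.0, index=config.factors, columns=subtype_ids)
    panel_free = sorted(free_genes)
    for sid in subtype_ids:
        driver, rho = subtype_planted[sid]
        subtype_contrasts[sid] = _planted_contrast(
            rng, truth.beta_true, driver, rho, panel_free, to_human
        )
        rho_sub.loc[driver, sid] = rho

    truth.rho_modules = rho_mod
    truth.rho_subtypes = rho_sub

    catalog = ModuleCatalog(
        members=members,
        cluster=clusters,
        region={m: "synthetic" for m in module_names},
    )
    return catalog, contrasts, subtype_contrasts, homologs


def _planted_contrast(
    rng: np.random.Generator,
    beta_true: pd.DataFrame,
    driver: str,
    rho: float,
    mouse_genes: Sequence[str],
    to_human: Mapping[str, str],
) -> pd.Series:
    if not (-1.0 <= rho <= 1.0):
        raise ValidationError(f"planted rho {rho} outside [-1, 1]")
    if driver not in beta_true.index:
        raise ValidationError(f"unknown driver factor {driver!r}")
    b = beta_true.loc[driver, list(mouse_genes)].to_numpy(dtype=float)
    noise = rng.normal(0.0, 1.0, size=len(mouse_genes))
    if rho != 0.0:
        sd = b.std()
        if sd == 0:
            raise ValidationError(
                f"driver factor {driver!r} has constant planted effect over the module genes"
            )
        z = (b - b.mean()) / sd
        fc = rho * z + np.sqrt(1.0 - rho * rho) * noise
    else:
        fc = noise
    return pd.Series(fc, index=[to_human[g] for g in mouse_genes], name="log2FC")


def generate_term_library(
    config: SimulationConfig,
    n_terms: int = 25,
    size_range: tuple[int, int] = (15, 60),
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Random mouse-gene term sets over the panel, for enrichment stages."""
    config.validate()
    rng = np.random.default_rng(config.seed + 2_000_003 if seed is None else seed)
    genes = config.gene_names()
    lo, hi = size_range
    if lo < 1 or hi > len(genes) or lo > hi:
        raise ValidationError("invalid term size range")
    out = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        out[f"T{i + 1:03d}"] = {genes[j] for j in idx}
    return out


# --------------------------------------------------------------------------
# bundle assembly and on-disk layout
# --------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """In-memory collection of everything one simulated study comprises."""

    config: SimulationConfig
    counts: pd.DataFrame
    annotations: pd.DataFrame
    truth: PlantedTruth
    catalog: "ModuleCatalog"  # noqa: F821
    module_contrasts: dict[str, pd.Series]
    subtype_contrasts: dict[str, pd.Series]
    homologs: pd.DataFrame
    term_library: dict[str, set[str]]


def generate_bundle(
    config: SimulationConfig,
    module_sizes: Sequence[int] | None = None,
    planted: Mapping[str, tuple[str, float]] | None = None,
    subtype_planted: Mapping[str, tuple[str, float]] | None = None,
    n_terms: int = 25,
) -> SyntheticBundle:
    """One-call generation of counts, truth, human references and term sets."""
    if module_sizes is None:
        module_sizes = [100] * 10
    counts, annot, truth = generate_counts(config)
    catalog, mod_con, sub_con, homologs = generate_human_reference(
        config, truth, module_sizes, planted=planted, subtype_planted=subtype_planted
    )
    library = generate_term_library(config, n_terms=n_terms)
    return SyntheticBundle(
        config=config,
        counts=counts,
        annotations=annot,
        truth=truth,
        catalog=catalog,
        module_contrasts=mod_con,
        subtype_contrasts=sub_con,
        homologs=homologs,
        term_library=library,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Path:
    """Write every bundle component as plain-text TSV/GMT under ``outdir``."""
    from .io import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    bundle.annotations.to_csv(out / "annotations.tsv", sep="\t", index_label="sample_id")
    (out / "housekeeping.txt").write_text(
        "\n".join(bundle.config.housekeeping_genes()) + "\n"
    )
    write_gmt({m: bundle.catalog.members[m] for m in bundle.catalog.members}, out / "modules.gmt")
    pd.DataFrame(
        {
            "module": list(bundle.catalog.members),
            "cluster": [bundle.catalog.cluster[m] for m in bundle.catalog.members],
            "region": [bundle.catalog.region.get(m, "") for m in bundle.catalog.members],
        }
    ).to_csv(out / "module_clusters.tsv", sep="\t", index=False)
    _write_contrasts(bundle.module_contrasts, out / "module_contrasts.tsv", "module")
    _write_contrasts(bundle.subtype_contrasts, out / "subtype_contrasts.tsv", "subtype")
    bundle.homologs.to_csv(out / "homologs.tsv", sep="\t", index=False)
    write_gmt(bundle.term_library, out / "terms.gmt")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    bundle.truth.beta_true.to_csv(truth_dir / "beta_true.tsv", sep="\t", index_label="factor")
    bundle.truth.batch_shift.to_csv(truth_dir / "batch_shift.tsv", sep="\t", index_label="batch")
    bundle.truth.batch_scale.to_csv(truth_dir / "batch_scale.tsv", sep="\t", index_label="batch")
    if bundle.truth.rho_modules is not None:
        bundle.truth.rho_modules.to_csv(truth_dir / "rho_modules.tsv", sep="\t", index_label="factor")
    if bundle.truth.rho_subtypes is not None:
        bundle.truth.rho_subtypes.to_csv(truth_dir / "rho_subtypes.tsv", sep="\t", index_label="factor")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh)
    return out


def _write_contrasts(contrasts: Mapping[str, pd.Series], path: Path, key: str) -> None:
    rows = []
    for cid, series in contrasts.items():
        for gene, fc in series.items():
            rows.append({key: cid, "human_gene": gene, "log2FC": fc})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
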