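import numpy as np
import pandas as pd
import pytest

from nanoconcord import (
    SimulationConfig,
    combat_correct,
    fit_all_ages,
    generate_bundle,
    housekeeping_normalize,
    log_transform,
)

SMALL_STRAINS = {
    "B6J": "baseline",
    "LOAD1": "comparator",
    "5xFAD": "transgenic",
    "Abca7": "variant",
    "Sorl1": "variant",
}


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=300,
        n_housekeeping=8,
        strains=dict(SMALL_STRAINS),
        ages=(12,),
        n_batches=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    return generate_bundle(small_config, module_sizes=[80] * 5, n_terms=12)


@pytest.fixture(scope="session")
def expression(bundle):
    expr = log_transform(
        housekeeping_normalize(bundle.counts, bundle.config.housekeeping_genes())
    )
    return combat_correct(
        expr, bundle.annotations["batch"], covariates=bundle.annotations[["strain", "sex"]]
    )


@pytest.fixture(scope="session")
def effects(bundle, expression):
    return fit_all_ages(expression, bundle.annotations, dict(bundle.config.strains))[12]


@pytest.fixture
def toy_counts(tmp_path):
    """A 3-gene x 2-sample count TSV with matching annotations on disk."""
    counts = pd.DataFrame(
        {"s1": [10, 20, 5], "s2": [12, 18, 7]}, index=["g1", "g2", "g3"]
    )
    annot = pd.DataFrame(
        {
            "strain": ["B6J", "LOAD1"],
            "sex": ["F", "M"],
            "age_months": [12, 12],
            "batch": ["lane1", "lane1"],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    cpath = tmp_path / "counts.tsv"
    apath = tmp_path / "annot.tsv"
    counts.to_csv(cpath, sep="\t", index_label="gene")
    annot.to_csv(apath, sep="\t")
    return cpath, apath, counts, annot


def balanced_annotations(strains, n_per_group=4, age=12, n_batches=1, seed=0):
    """Small balanced annotation table for design/OLS tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for strain in strains:
        for sex in ("F", "M"):
            for i in range(n_per_group):
                rows.append(
                    {
                        "sample_id": f"{strain}_{sex}_{i}",
                        "strain": strain,
                        "sex": sex,
                        "age_months": age,
                        "batch": f"lane{rng.integers(n_batches) + 1}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
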