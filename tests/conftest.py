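import dataclasses

import numpy as np
import pandas as pd
import pytest

from crcmicro import prep
from crcmicro.simulate import SimulationConfig, generate_cohort

SMALL_GROUPS = {"BP": 12, "T1": 6, "T2": 6, "T3": 6, "T4": 5}


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-size cohort config for unit tests."""
    base = dict(
        n_per_group=dict(SMALL_GROUPS),
        n_taxa=80,
        n_age_taxa=4,
        n_stage_taxa=6,
        n_driver_taxa=5,
        rarefy_depth=1500,
        depth_mean=5000.0,
        depth_sd=1000.0,
        seed=11,
    )
    base.update(overrides)
    return dataclasses.replace(SimulationConfig(), **base)


@pytest.fixture(scope="session")
def small_cohort():
    counts, meta, tax, truth = generate_cohort(small_config())
    return counts, meta, tax, truth


@pytest.fixture(scope="session")
def small_rarefied(small_cohort):
    counts, meta, tax, truth = small_cohort
    filtered = prep.filter_taxa(counts, tax)
    rarefied = prep.rarefy(filtered, depth=1500, seed=0)
    return rarefied, meta.loc[rarefied.index], tax, truth


@pytest.fixture()
def toy_tables(tmp_path):
    """Three-sample TSV trio on disk for reader round-trips."""
    counts = pd.DataFrame(
        {"S1": [5, 0, 3], "S2": [2, 4, 0], "S3": [1, 1, 1]},
        index=["ASV1", "ASV2", "ASV3"],
    )
    meta = pd.DataFrame(
        {
            "group": ["BP", "T1", "T2"],
            "age": [40, 55, 60],
            "gender": ["male", "female", "male"],
        },
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )
    tax = pd.DataFrame(
        {
            "lineage": [
                "d__Bacteria;p__Firmicutes;c__Cl;o__Or;f__Fa;g__Ge;s__Sp",
                "d__Bacteria;p__Bacteroidota;c__Cl;o__Or;f__Fa;g__Ge2;s__",
                "d__Bacteria;p__Firmicutes;c__Cl;o__Or;f__Fa;g__;s__",
            ]
        },
        index=pd.Index(["ASV1", "ASV2", "ASV3"], name="taxon_id"),
    )
    cp, mp, tp = tmp_path / "counts.tsv", tmp_path / "meta.tsv", tmp_path / "tax.tsv"
    counts.to_csv(cp, sep="\t", index_label="taxon_id")
    meta.to_csv(mp, sep="\t")
    tax.to_csv(tp, sep="\t")
    return cp, mp, tp
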