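"""Shared fixtures: tiny hand-written MAF files and scaled synthetic data."""

import pandas as pd
import pytest

from abtslc.gene_catalog import builtin_abt_catalog
from abtslc.maf_io import MutationTable, SampleRegistry
from abtslc.synthetic_data import SimConfig, simulate_maf

TOY_MAF = """\
#version gdc-1.0
Hugo_Symbol\tTumor_Sample_Barcode\tCohort\tVariant_Classification\tProtein_position\tSIFT\tPolyPhen
SLC4A3\tTCGA-AA-0001-01\tTCGA-UCEC\tMissense_Mutation\t328/1232\tdeleterious(0.01)\tprobably_damaging(0.98)
SLC9A1\tTCGA-AA-0002-01\tTCGA-UCEC\tSilent\t-\t\t
SLC16A1\tTCGA-AA-0003-01\tTCGA-COAD\tNonsense_Mutation\tp.R328*\t\t
"""


@pytest.fixture
def toy_maf_path(tmp_path):
    path = tmp_path / "toy.maf"
    path.write_text(TOY_MAF)
    return path


def make_table(rows):
    """Build a MutationTable from (gene, sample, cohort, classification,
    protein_pos, sift, polyphen) tuples; trailing fields optional."""
    full = [tuple(r) + (None,) * (7 - len(r)) for r in rows]
    df = pd.DataFrame(full, columns=[
        "gene", "sample", "cohort", "classification",
        "protein_pos", "sift", "polyphen"])
    df["protein_pos"] = df["protein_pos"].astype("Int64")
    for col in ("gene", "sample", "cohort", "classification",
                "sift", "polyphen"):
        df[col] = df[col].astype("string")
    return MutationTable(df)


def make_registry(pairs):
    """Registry from (sample, cohort) pairs."""
    s = pd.Series({sample: cohort for sample, cohort in pairs}, name="cohort")
    s.index.name = "sample"
    return SampleRegistry(s.sort_index())


@pytest.fixture(scope="session")
def catalog():
    return builtin_abt_catalog()


@pytest.fixture(scope="session")
def sim_small():
    """A small deterministic synthetic dataset shared by read-only tests."""
    config = SimConfig(seed=11, n_cohorts=4, samples_per_cohort=150)
    table, registry, truth = simulate_maf(config)
    return config, table, registry, truth
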