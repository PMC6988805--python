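import numpy as np
import pandas as pd
import pytest

from methsponge.synthetic_data import SimulationConfig, simulate_all
from methsponge.types import ExpressionMatrix, MethylationProfile, ProbeAnnotation


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (60 tumor / 30 normal, 5 planted pairs)."""
    return simulate_all(SimulationConfig(rng_seed=7))


@pytest.fixture()
def tiny_groups():
    return pd.Series(
        ["tumor", "tumor", "tumor", "normal", "normal", "normal"],
        index=[f"S{i}" for i in range(6)], name="group",
    )


@pytest.fixture()
def tiny_expression(tiny_groups):
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.uniform(1, 10, size=(4, 6)),
        index=[f"f{i}" for i in range(4)],
        columns=tiny_groups.index,
    )
    return ExpressionMatrix(values, tiny_groups).validate()


@pytest.fixture()
def six_probe_fixture(tiny_groups):
    """Six probes: NA-carrying, two-gene, chrX, SNP-flagged, and two clean."""
    samples = list(tiny_groups.index)
    values = pd.DataFrame(
        0.5, index=[f"cg{i}" for i in range(6)], columns=samples
    )
    values.iloc[0, 0] = np.nan  # cg0: missing value
    profile = MethylationProfile(values, "probe", tiny_groups).validate()
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr2", "chrX", "chr3", "chr4", "chr5"],
                "pos": [100, 200, 300, 400, 500, 600],
                "genes": [("gA",), ("gA", "gB"), ("gA",), ("gB",), ("gA",), ("gB",)],
                "snp_overlap": [False, False, False, True, False, False],
            },
            index=values.index,
        )
    ).validate()
    # cg0 NA, cg1 two-gene, cg2 chrX, cg3 SNP -> cg4 and cg5 survive
    return profile, ann
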