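import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hetprofile.genome_partition import ChromosomeArm, FeatureSet
from hetprofile.synthetic_data import (
    ArmSpec,
    ClusterGroupSpec,
    SimConfig,
    TeFamilySpec,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("hetprofile").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A small, fast synthetic genome: two arms plus a chr4-like arm."""
    return SimConfig(
        arm_specs=(
            ArmSpec("armA", 200_000, True, 150_000),
            ArmSpec("armB", 120_000, False, 30_000),
            ArmSpec("chr4", 40_000, True, 40_000, is_chr4=True),
        ),
        te_family_specs=(
            TeFamilySpec("roo", 4, (800, 1500), 0.05),
            TeFamilySpec("gypsy5", 4, (800, 1500), 2.4),
            TeFamilySpec("blood", 4, (800, 1500), 1.2),
        ),
        cluster_specs=(ClusterGroupSpec("cluster", 2, (5_000, 10_000), 1.3),),
        probe_spacing=200,
        subtelomere_window=20_000,
        seed=7,
    )


@pytest.fixture
def simple_features():
    """Hand-built annotation with known coordinates for rule checks."""
    arms = {
        "armA": ChromosomeArm("armA", 1_000_000, True, 600_000),
        "armB": ChromosomeArm("armB", 1_000_000, False, 400_000),
        "chr4": ChromosomeArm("chr4", 100_000, True, 100_000, is_chr4=True),
    }
    te = pd.DataFrame(
        [
            {"chrom": "armA", "start": 200, "end": 800, "family": "roo"},
            {"chrom": "armA", "start": 700_000, "end": 702_000, "family": "gypsy5"},
            {"chrom": "armB", "start": 100_000, "end": 101_000, "family": "blood"},
        ]
    )
    clusters = pd.DataFrame(
        [{"chrom": "armB", "start": 200_000, "end": 230_000, "cluster": "c1"}]
    )
    return FeatureSet(arms=arms, te_instances=te, pirna_clusters=clusters)
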