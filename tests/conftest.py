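import numpy as np
import pandas as pd
import pytest

from riboplate import simdata
from riboplate.plateio import GeneAnno, PairedCounts, PlateMeta
from riboplate.simdata import EffectSpec, SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small two-condition plate with a TOP-gene knockdown under 'mTORi'."""
    return SimConfig(
        n_coding=300,
        n_ncrna=40,
        n_spikein=24,
        n_wells_per_condition=4,
        conditions=("DMSO", "mTORi"),
        depth_mean=5e4,
        n_top_canonical=30,
        n_top_candidate=40,
        effect_map={"mTORi": EffectSpec("TOP_canonical", -1.0, 1.0)},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simdata.simulate_experiment(small_config)


@pytest.fixture()
def tiny_pc() -> PairedCounts:
    """Hand-sized paired counts: 4 genes x 3 wells, ribo == total."""
    mat = np.array([[10, 20, 30], [5, 10, 15], [8, 16, 24], [2, 4, 6]])
    return PairedCounts(
        genes=["g1", "g2", "g3", "g4"],
        wells=["A01", "A02", "A03"],
        ribo=mat.copy(),
        total=mat.copy(),
    )


@pytest.fixture()
def tiny_meta() -> PlateMeta:
    return PlateMeta(
        pd.DataFrame(
            {
                "condition": ["DMSO", "DMSO", "drug"],
                "spikein": [True, True, True],
                "input_fraction_ribo": [0.5, 0.5, 0.5],
                "input_fraction_total": [0.5, 0.5, 0.5],
            },
            index=pd.Index(["A01", "A02", "A03"], name="well"),
        )
    )


@pytest.fixture()
def tiny_anno() -> GeneAnno:
    return GeneAnno(
        pd.DataFrame(
            {
                "biotype": ["coding", "coding", "ncRNA", "spikein"],
                "top_status": ["canonical", "none", "none", "none"],
                "blacklisted": [False, False, False, False],
            },
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
        )
    )
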