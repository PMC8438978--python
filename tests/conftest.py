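import numpy as np
import pandas as pd
import pytest

from coexpnet import preprocess
from coexpnet.data import CountMatrix, SampleSheet
from coexpnet.simulate import SimConfig, generate_compendium


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic compendium: 300 genes, 2x8 class treatments + 8 other."""
    return generate_compendium(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """Fast compendium for pipeline-level tests."""
    cfg = SimConfig(
        n_genes=120,
        module_sizes=(25, 25),
        treatments_per_class=6,
        n_other_treatments=4,
        replicates_per_treatment=3,
        seed=5,
    )
    return generate_compendium(cfg)


@pytest.fixture(scope="session")
def default_de(default_sim):
    cm, sheet, _ = default_sim
    return preprocess.differential_expression(cm, sheet)


@pytest.fixture()
def toy_counts():
    """3 genes x 4 samples, two treatment groups with matched controls."""
    df = pd.DataFrame(
        [[10, 12, 5, 6], [0, 1, 2, 0], [100, 90, 80, 70]],
        index=["gA", "gB", "gC"],
        columns=["t_r1", "t_r2", "c_r1", "c_r2"],
    )
    return CountMatrix(df)


@pytest.fixture()
def toy_sheet():
    rows = [
        {"sample": "t_r1", "treatment": "T1", "control_for": "C1", "class": "FRC", "replicate": 1},
        {"sample": "t_r2", "treatment": "T1", "control_for": "C1", "class": "FRC", "replicate": 2},
        {"sample": "c_r1", "treatment": "C1", "control_for": "", "class": "control", "replicate": 1},
        {"sample": "c_r2", "treatment": "C1", "control_for": "", "class": "control", "replicate": 2},
    ]
    return SampleSheet(pd.DataFrame(rows))


def make_two_group_experiment(counts_treated, counts_control, gene_ids=None):
    """Build (CountMatrix, SampleSheet) for a single treatment/control pair
    from (genes x reps) arrays."""
    counts_treated = np.asarray(counts_treated)
    counts_control = np.asarray(counts_control)
    n_genes = counts_treated.shape[0]
    genes = gene_ids or [f"g{i}" for i in range(n_genes)]
    t_names = [f"t_r{i}" for i in range(counts_treated.shape[1])]
    c_names = [f"c_r{i}" for i in range(counts_control.shape[1])]
    cm = CountMatrix(
        pd.DataFrame(
            np.hstack([counts_treated, counts_control]),
            index=genes,
            columns=t_names + c_names,
        )
    )
    rows = [
        {"sample": s, "treatment": "T", "control_for": "C", "class": "other", "replicate": i}
        for i, s in enumerate(t_names)
    ] + [
        {"sample": s, "treatment": "C", "control_for": "", "class": "control", "replicate": i}
        for i, s in enumerate(c_names)
    ]
    return cm, SampleSheet(pd.DataFrame(rows))
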