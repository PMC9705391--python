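import numpy as np
import pandas as pd
import pytest

from organovasc.simulate import SimulationSpec, simulate_counts

EC_CLASSES = ("EC-1", "EC-2", "EC-3", "EC-4", "EC-5")


def small_spec(**overrides) -> SimulationSpec:
    """A scaled-down simulation used for fast unit tests."""
    kwargs = dict(
        n_conditions=3,
        ec_count_range=(60, 120),
        osc_count_range=(200, 400),
        n_genes=600,
        marker_baseline=0.012,  # keeps panel dropout realistic at this gene-space size
        seed=1,
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    """Shared small simulated dataset (counts AnnData, ground truth)."""
    return simulate_counts(small_spec())


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    """QC-filtered version of the small dataset plus its truth subset."""
    from organovasc import qc

    adata, truth = small_sim
    filtered, _ = qc.qc_filter(adata, qc.compute_qc_metrics(adata))
    return filtered, truth.cells.loc[filtered.obs_names]
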