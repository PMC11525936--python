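import numpy as np
import pandas as pd
import pytest

from pulmoplex import presets, synthetic


@pytest.fixture(scope="session")
def study_scene():
    """Mid-size per-week table scene shared by read-only tests."""
    cfg = presets.study_table_config(week=6.0, n_cells=3000)
    gt = synthetic.generate_ground_truth(cfg, seed=11)
    table = synthetic.emit_cell_table(gt, cfg, seed=12)
    table["cell_type"] = gt.cells["cell_type"].to_numpy()
    table["tag"] = gt.cells["tag"].to_numpy()
    return cfg, gt, table


@pytest.fixture(scope="session")
def vessel_scene():
    """Vessel scene with planted artery-close marker shifts."""
    cfg = presets.vessel_scene_config()
    gt = synthetic.generate_ground_truth(cfg, seed=21)
    table = synthetic.emit_cell_table(gt, cfg, seed=22)
    table["cell_type"] = gt.cells["cell_type"].to_numpy()
    table["tag"] = gt.cells["tag"].to_numpy()
    return cfg, gt, table


@pytest.fixture()
def two_type_table():
    """Two cell types with disjoint marker support, 500 cells each."""
    rng = np.random.default_rng(0)
    n = 500
    a = pd.DataFrame({
        "m1": rng.lognormal(3.5, 0.2, n), "m2": rng.lognormal(0.3, 0.2, n),
        "m3": rng.lognormal(0.3, 0.2, n),
    })
    b = pd.DataFrame({
        "m1": rng.lognormal(0.3, 0.2, n), "m2": rng.lognormal(3.5, 0.2, n),
        "m3": rng.lognormal(0.3, 0.2, n),
    })
    t = pd.concat([a, b], ignore_index=True)
    t["truth"] = ["A"] * n + ["B"] * n
    return t
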