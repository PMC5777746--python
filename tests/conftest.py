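"""Shared fixtures: a small synthetic study preprocessed once per session."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncarray import preprocess as pre_mod
from lncarray import simulate as sim_mod


SMALL_CFG = dict(
    n_probesets=120,
    probes_per_set=5,
    n_case=6,
    n_control=4,
    n_de=8,
    n_trans_pairs=3,
    n_outlier_arrays=1,
)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One small simulated experiment, preprocessed with QC."""
    d = tmp_path_factory.mktemp("small_study")
    cfg = sim_mod.SimulationConfig(seed=7, **SMALL_CFG)
    truth = sim_mod.simulate_experiment(cfg, d / "probes.tsv", d / "design.tsv")
    matrix = pre_mod.read_probe_tsv(d / "probes.tsv", d / "design.tsv")
    expr, report = pre_mod.preprocess_and_qc(matrix)
    return {"dir": d, "cfg": cfg, "truth": truth, "matrix": matrix,
            "expr": expr, "report": report}
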