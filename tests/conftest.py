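import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # _datasets helpers

from wildshift import io
from wildshift.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def sim_study():
    """A moderate synthetic study shared across tests (fixed seed)."""
    cfg = SimConfig(seed=42, n_projects=6, species_pool_size=14,
                    stations_per_project=8, period_length_days=45)
    tables, truth = simulate_study(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def sim_study_dir(sim_study, tmp_path_factory):
    """The same study written out in the documented CSV schemas."""
    _, tables, truth = sim_study
    out = tmp_path_factory.mktemp("study")
    io.write_detections(tables["detections"], out / "detections.csv")
    io.write_deployments(tables["deployments"], out / "deployments.csv")
    io.write_periods(tables["periods"], out / "periods.csv")
    tables["traits"].to_csv(out / "traits.csv", index=False)
    tables["project_covariates"].to_csv(out / "project_covariates.csv", index=False)
    tables["hunting"].to_csv(out / "hunting.csv", index=False)
    return out
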