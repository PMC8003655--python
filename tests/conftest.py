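import numpy as np
import pytest

from gliomaft.workflow import degradation_recovery, recovery_config, run_experiment, smoke_config


@pytest.fixture(scope="session")
def recovery_results():
    """The 5-seed two-facility degradation/recovery experiment.

    This is the package's headline computation (minutes of CPU); shared
    across every test that asserts on its outcome.
    """
    summary, per_seed, records = degradation_recovery(recovery_config(), seeds=range(5))
    return {"summary": summary, "per_seed": per_seed, "records": records}


@pytest.fixture(scope="session")
def smoke_runs(tmp_path_factory):
    """Two runs of the built-in smoke experiment with the same seed."""
    outs = []
    for tag in ("one", "two"):
        out = tmp_path_factory.mktemp(f"smoke_{tag}")
        report, records = run_experiment(smoke_config(seed=3), out_dir=out)
        outs.append({"report": report, "records": records,
                     "csv": (out / "eval_records.csv").read_bytes()})
    return outs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
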