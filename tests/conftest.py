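import numpy as np
import pandas as pd
import pytest

import inflammclock as ic


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged synthetic study cohort (560 samples, 2000 CpGs)."""
    return ic.default_fixture()


@pytest.fixture(scope="session")
def pipeline_replicates():
    """Full two-level pipeline runs for replicate seeds 0..9.

    Each entry records the gate decision, the clock's test metrics and the
    cohort's analytic irreducible error; used by the recovery tests."""
    out = []
    for seed in range(10):
        cohort = ic.generate(ic.SynthConfig(seed=seed))
        panel = ic.SurrogatePanelModel(cohort.beta, cohort.markers)
        pres = panel.fit(seed=seed)
        est = pres.predict(cohort.beta)
        cres = ic.InflammAgeModel(est, cohort.meta).fit(seed=seed)
        out.append({
            "seed": seed,
            "cohort": cohort,
            "panel": pres,
            "clock": cres,
            "retained": set(pres.retained),
            "test_mae": cres.clock.metrics["test"]["mae"],
            "test_r": cres.clock.metrics["test"]["pearson_r"],
            "irreducible_mae": cohort.truth.irreducible_mae_years,
        })
    return out


@pytest.fixture(scope="session")
def cli_workspace(tmp_path_factory):
    """Simulated cohort + one CLI train/predict run, shared across tests."""
    from inflammclock.cli import main

    root = tmp_path_factory.mktemp("cli")
    data = root / "data"
    assert main(["simulate", "--out", str(data), "--seed", "123"]) == 0
    bundle = root / "bundle"
    assert main(["train", "--beta", str(data / "beta.csv"),
                 "--meta", str(data / "meta.csv"),
                 "--markers", str(data / "markers.csv"),
                 "--out", str(bundle), "--seed", "7"]) == 0
    pred = root / "pred"
    assert main(["predict", "--bundle", str(bundle),
                 "--beta", str(data / "beta.csv"),
                 "--meta", str(data / "meta.csv"),
                 "--out", str(pred)]) == 0
    return {"root": root, "data": data, "bundle": bundle, "pred": pred}


@pytest.fixture
def small_beta():
    """A tiny hand-checkable beta matrix."""
    return ic.BetaMatrix(pd.DataFrame(
        [[0.1, 0.5, 0.9], [0.2, 0.4, 0.8], [0.3, 0.6, 0.7]],
        index=["A", "B", "C"], columns=["cg1", "cg2", "cg3"]))


@pytest.fixture
def small_meta():
    return pd.DataFrame({
        "Age": [30.0, 40.0, 50.0],
        "Sex": ["F", "M", "F"],
        "DatasetID": ["D1", "D1", "D1"],
        "Status": ["control", "control", "case"],
        "ICDChapter": [np.nan, np.nan, 1],
        "ICDCode": [None, None, "1A00"],
    }, index=pd.Index(["A", "B", "C"], name="SampleID"))
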