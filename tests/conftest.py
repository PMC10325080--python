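import numpy as np
import pandas as pd
import pytest

from ctasca import (
    TimeBasis,
    LongDataset,
    build_design,
    decompose,
    encode_ground_truth,
    fit_all,
    reference_scenario,
    simulate_dataset,
)


def make_long_df(I=2, treatments=("A", "B"), times=(0.0, 1.0, 2.0), responses=("y1",), fill=0.0):
    rows = []
    for i in range(I):
        for h in treatments:
            for t in times:
                row = {"subject": f"s{i + 1}", "treatment": h, "time": t}
                for r in responses:
                    row[r] = fill
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_data():
    rng = np.random.default_rng(42)
    df = make_long_df(I=3, times=(0.0, 1.0, 2.0, 3.0), responses=("y1", "y2"))
    df[["y1", "y2"]] = rng.normal(5.0, 1.0, size=(len(df), 2))
    return LongDataset(df, ["y1", "y2"])


@pytest.fixture(scope="session")
def ref_sim():
    """Reference-scale simulation, fitted once and shared across tests."""
    spec = reference_scenario(seed=11)
    data, gamma = simulate_dataset(spec)
    truth = encode_ground_truth(spec, gamma)
    design = build_design(data, TimeBasis("polynomial", 2), "mirror_fixed")
    fit = fit_all(data, design)
    em = decompose(fit, data)
    return {"spec": spec, "data": data, "gamma": gamma, "truth": truth,
            "design": design, "fit": fit, "em": em}


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulation for mechanical checks (I=8, K=5, J=3)."""
    from ctasca import SimulationSpec

    beta = np.array(
        [
            [5.0, 0.4, -0.03, 0.1, -0.01],
            [6.0, -0.2, 0.02, -0.15, 0.012],
            [4.0, 0.1, 0.00, 0.05, 0.00],
        ]
    )
    sd = np.array([0.3, 0.05, 0.01, 0.04, 0.008])
    corr = 0.25 * np.ones((5, 5)) + 0.75 * np.eye(5)
    spec = SimulationSpec(
        beta_tilde=beta,
        D_tilde=corr * np.outer(sd, sd),
        sigma_eps=0.2,
        t=np.arange(5.0),
        n_subjects=8,
        seed=5,
    )
    data, gamma = simulate_dataset(spec)
    design = build_design(data, TimeBasis("polynomial", 2), "mirror_fixed")
    fit = fit_all(data, design)
    return {"spec": spec, "data": data, "gamma": gamma, "design": design, "fit": fit}
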