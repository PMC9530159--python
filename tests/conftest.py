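import numpy as np
import pandas as pd
import pytest

import ratdetect as rd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """10 rats x 3 devices x 20 nights at the reference parameter values."""
    pop = rd.PopulationSpec(n_rats=10)
    return rd.generate_dataset(
        pop,
        rd.DeviceLayoutSpec(),
        20,
        rd.EncounterParams(),
        rd.InteractionParams(),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_tables():
    """3 rats x 3 devices x 5 nights with every pair well inside candidate range."""
    rng = np.random.default_rng(7)
    centres = np.array([[0.0, 0.0], [60.0, 10.0], [25.0, 55.0]])
    sigmas = np.array([22.0, 28.0, 25.0])
    tel = rd.simulate_telemetry(centres, sigmas, 30, rng, sexes=[0, 1, 0])
    recs, avail = [], {}
    dev_pos = [(5.0, 8.0), (40.0, 20.0), (30.0, 40.0)]
    for k, (t, (x, y)) in enumerate(zip(("baitstation", "chewcard", "waxtag"), dev_pos)):
        did = f"dev{k}"
        recs.append((did, t, x, y))
        avail[did] = frozenset(range(5)) if k < 2 else frozenset(range(1, 5))
    devices = rd.DeviceTable(
        pd.DataFrame(recs, columns=["device_id", "device_type", "x", "y"]), avail
    )
    rats = pd.DataFrame(
        {
            "rat_id": [f"r{i:03d}" for i in range(3)],
            "sex": [0, 1, 0],
            "x": centres[:, 0],
            "y": centres[:, 1],
            "sigma": sigmas,
            "delta": [0.3, -0.2, 0.0],
            "rho": [-0.1, 0.4, 0.2],
        }
    )
    enc_log, _ = rd.simulate_encounter_history(
        rats, devices, 5, rd.EncounterParams(), rng
    )
    int_log, _ = rd.simulate_interaction_history(
        enc_log, rats, devices, rd.InteractionParams(), rng
    )
    tel.df["rat_id"] = tel.df["rat_id"].astype(str)
    return tel, devices, enc_log, int_log


@pytest.fixture(scope="session")
def surrogate_post():
    return rd.synthetic_reference_posterior(n_draws=500, seed=99)
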