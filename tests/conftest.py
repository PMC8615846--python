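import numpy as np
import pandas as pd
import pytest

import pitgimme as pg


@pytest.fixture(scope="session")
def task_config():
    return pg.TaskConfig()


@pytest.fixture(scope="session")
def short_config():
    """Shorter scan for fast estimation tests."""
    return pg.TaskConfig(n_trs=200)


@pytest.fixture(scope="session")
def benchmark_truth():
    return pg.benchmark_network(10)


@pytest.fixture(scope="session")
def benchmark_matrices(short_config, benchmark_truth):
    """One simulated 10-subject sample from the benchmark truth."""
    schedules = [
        pg.gen_transfer_schedule(short_config, seed=100 + i) for i in range(10)
    ]
    return pg.simulate_bold(benchmark_truth, schedules, short_config, seed=42)


def simulate_subject(truth, config, seed):
    """One subject matrix from an arbitrary truth (helper used across test modules)."""
    schedule = pg.gen_transfer_schedule(config, seed=seed)
    return pg.simulate_bold(
        truth, [schedule] * truth.n_subjects, config, seed=seed
    )[0]


@pytest.fixture(scope="session")
def null_rates_table():
    """Transfer rate table from 6 null-agent subjects (no transfer effect)."""
    from pitgimme.behavior import transfer_rates

    frames = []
    cfg = pg.TaskConfig()
    agent = pg.null_agent()
    for i in range(6):
        sched = pg.gen_transfer_schedule(cfg, seed=700 + i)
        rec = pg.gen_transfer_behavior(sched, agent, seed=700 + i)
        frames.append(transfer_rates(rec, sched, subject_id=f"s{i}"))
    return pd.concat(frames, ignore_index=True)
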