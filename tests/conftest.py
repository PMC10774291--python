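import numpy as np
import pytest

import kelpflux as kf


@pytest.fixture(scope="session")
def default_config() -> kf.ShelfScenarioConfig:
    return kf.ShelfScenarioConfig()


@pytest.fixture(scope="session")
def may_scenario() -> kf.Scenario:
    """One cold-season month of the default shelf, for classifier tests."""
    cfg = kf.ShelfScenarioConfig(start_date="2017-05-01", n_days=31)
    return kf.make_scenario(cfg)


@pytest.fixture(scope="session")
def january_scenario() -> kf.Scenario:
    """One warm-season month of the default shelf."""
    cfg = kf.ShelfScenarioConfig(start_date="2017-01-01", n_days=31)
    return kf.make_scenario(cfg)


@pytest.fixture(scope="session")
def year_run() -> kf.PipelineResult:
    """Full-year default scenario at 10^4 particles, shared by the
    end-to-end checks.  Problem size: 2 km grid, 3-hourly forcing
    snapshots, 30-minute tracking steps, 6-hourly trajectory records."""
    cfg = kf.RunConfig(
        total_particles=10_000,
        seed=7,
        tracker=kf.TrackerOptions(dt=1800.0, record_hours=6.0,
                                  periodic_y=True),
    )
    return kf.run_pipeline(cfg)


def make_trajectories(record_times, release_times, release_xy, xy, depth,
                      state=None) -> kf.TrajectorySet:
    """Hand-built trajectory sets for accounting tests."""
    xy = np.asarray(xy, dtype=np.float32)
    n = xy.shape[0]
    return kf.TrajectorySet(
        release_times=np.asarray(release_times, dtype="datetime64[s]"),
        release_xy=np.asarray(release_xy, dtype=float),
        record_times=np.asarray(record_times, dtype="datetime64[s]"),
        xy=xy,
        depth=np.asarray(depth, dtype=np.float32),
        state=(np.zeros(n, dtype=np.int8) if state is None
               else np.asarray(state, dtype=np.int8)),
    )
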