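import numpy as np
import pytest

from mdsync.preprocess import GroupRecord, IBISeries
from mdsync.synthetic import SimConfig, generate_triad


@pytest.fixture
def toy_series() -> np.ndarray:
    """The three 4-point series of the worked example, as columns."""
    return np.column_stack([[1, 1, 2, 25], [1, 1, 3, 40], [1, 1, 1, 99]])


def make_group(
    gid: str = "g1",
    lengths: dict | None = None,
    rng: np.random.Generator | None = None,
    base: float = 0.85,
) -> GroupRecord:
    """Small hand-built triad with controllable per-series lengths."""
    if rng is None:
        rng = np.random.default_rng(0)
    lengths = lengths or {}
    series = {}
    for mid in (1, 2, 3):
        for phase in ("baseline", "task"):
            n = lengths.get((mid, phase), 50)
            series[(mid, phase)] = IBISeries(
                values=base + 0.1 * rng.standard_normal(n),
                group_id=gid,
                member_id=mid,
                phase=phase,
                study="1",
                condition="A",
            )
    return GroupRecord(group_id=gid, study="1", condition="A", series=series)


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        n_groups=6,
        condition_layout=(("1", "A", 2), ("1", "B", 2), ("2", "C", 1), ("2", "D", 1)),
        length_range=(150, 180),
        seed=11,
    )


@pytest.fixture
def coupled_groups(small_config):
    cfg = SimConfig(
        n_groups=small_config.n_groups,
        condition_layout=small_config.condition_layout,
        length_range=(150, 180),
        coupling_task=0.15,
        seed=5,
    )
    return [generate_triad(cfg, i) for i in range(cfg.n_groups)]
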