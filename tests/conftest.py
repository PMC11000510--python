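import numpy as np
import pytest

from multidfc import AtlasTable, ParcellatedTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_atlas():
    return AtlasTable(
        [f"r{i}" for i in range(6)],
        ["dmn", "dmn", "vis", "vis", "dmn", "vis"],
        ["L", "R", "L", "R", "L", "R"],
    )


def make_ts(values, tr=0.72, subject_id="sub-000", rsn=None):
    values = np.asarray(values, dtype=float)
    r = values.shape[1]
    if rsn is None:
        rsn = ["net0"] * r
    return ParcellatedTimeSeries(
        subject_id, tr, values,
        [f"r{i}" for i in range(r)], rsn,
        ["L" if i % 2 == 0 else "R" for i in range(r)],
    )


@pytest.fixture
def random_ts(rng):
    return make_ts(rng.standard_normal((200, 6)))


def gordon_like_atlas(n_total=333, n_unassigned=47, n_rsns=12, seed=0):
    """Synthetic atlas emulating a whole-brain parcellation: ``n_total``
    ROIs, ``n_unassigned`` outside every network, the rest split over
    ``n_rsns`` RSNs with hemisphere-balanced membership."""
    rng = np.random.default_rng(seed)
    n_assigned = n_total - n_unassigned
    # uneven but deterministic RSN sizes, forced even for L/R balance
    raw = rng.dirichlet(np.arange(2, 2 + n_rsns)) * n_assigned
    sizes = np.maximum(2, 2 * np.round(raw / 2).astype(int))
    while sizes.sum() > n_assigned:
        sizes[np.argmax(sizes)] -= 2
    while sizes.sum() < n_assigned - 1:
        sizes[np.argmin(sizes)] += 2
    rows = []
    for k, size in enumerate(sizes):
        for i in range(size):
            rows.append((f"net{k:02d}", "L" if i < size // 2 else "R"))
    while len(rows) < n_assigned:
        rows.append(("net00", "L"))
    for _ in range(n_unassigned):
        rows.append(("None", "L"))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    return AtlasTable(
        [f"roi{i:03d}" for i in range(n_total)],
        [r[0] for r in rows],
        [r[1] for r in rows],
    )
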