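import numpy as np
import pytest

from assocpat.scan_data import Individual, ScanDataset, SeasonRoster


def make_roster(n=5, season="2014/5", start_year=2014, sexes=None):
    """Small attributed roster for unit tests."""
    members = []
    for i in range(n):
        sex = sexes[i] if sexes else ("female" if i % 2 == 0 else "male")
        members.append(
            Individual(
                id=f"A{i}",
                sex=sex,
                birth_year=start_year - (10 if i % 3 else 5),
                mother_id=None,
            )
        )
    return SeasonRoster(season=season, members=tuple(members), start_year=start_year)


def make_dataset(roster, compositions, focals=None, start="2014-10-01T08:00"):
    """Build a ScanDataset from a list of member-index lists."""
    n = len(roster)
    s = len(compositions)
    presence = np.zeros((s, n), dtype=bool)
    for i, comp in enumerate(compositions):
        presence[i, list(comp)] = True
    focal = np.array([c[0] for c in compositions] if focals is None else focals, dtype=np.intp)
    presence[np.arange(s), focal] = True
    ts = np.datetime64(start, "s") + np.arange(s) * np.timedelta64(900, "s")
    return ScanDataset(roster, np.arange(s), ts, focal, presence)


def random_dataset(rng, n=6, n_scans=20, roster=None):
    """Random small dataset for oracle comparisons."""
    roster = roster or make_roster(n)
    comps = []
    for _ in range(n_scans):
        size = int(rng.integers(1, n + 1))
        members = rng.choice(n, size=size, replace=False).tolist()
        comps.append(members)
    return make_dataset(roster, comps)


@pytest.fixture
def roster5():
    return make_roster(5)


@pytest.fixture
def rng():
    return np.random.default_rng(20140)
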