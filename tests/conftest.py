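import datetime as dt

import numpy as np
import pandas as pd
import pytest

from socpod.sightings import SIGHTING_COLUMNS, SamplingPeriods


def make_sightings(rows):
    """Build a canonical sightings frame from (id, date, group) tuples or dicts."""
    records = []
    for r in rows:
        if isinstance(r, dict):
            rec = r
        else:
            rec = {"individual_id": r[0], "date": r[1], "group_id": r[2]}
        rec = {
            "session": pd.NA,
            "habitat": "estuary",
            "stratum": "SNCESS",
            "mark_type": "LTM",
            "photo_quality": "good",
            "distinctiveness": "distinctive",
            **rec,
        }
        rec["date"] = pd.Timestamp(rec["date"]).date()
        records.append(rec)
    return pd.DataFrame(records, columns=SIGHTING_COLUMNS)


def periods_from_sets(period_groups, n=None, ids=None, times=None):
    """SamplingPeriods from a list (per period) of lists of member-index sets."""
    if ids is None:
        if n is None:
            n = max((max(g) for gs in period_groups for g in gs if g), default=-1) + 1
        ids = [f"I{k}" for k in range(n)]
    keys = (
        [dt.date(2000, 1, 1) + dt.timedelta(days=int(t)) for t in times]
        if times is not None
        else [dt.date(2000, 1, 1) + dt.timedelta(days=p) for p in range(len(period_groups))]
    )
    groups = [
        [np.array(sorted(g), dtype=int) for g in gs if len(g)] for gs in period_groups
    ]
    return SamplingPeriods(ids=list(ids), period_keys=keys, groups=groups)


@pytest.fixture(scope="session")
def table7_boundary():
    """Capture histories reconstructed from the three-session boundary counts."""
    from socpod.sightings import histories_from_session_counts

    return histories_from_session_counts((269, 141, 174), (41, 42, 46), 21)


@pytest.fixture(scope="session")
def small_clustered_catalog():
    """Two well-separated social clusters, generously resighted."""
    from socpod.simulate import SimulationConfig, simulate_population

    cfg = SimulationConfig(
        n_clusters=2,
        cluster_sizes=(8, 8),
        between_propensity=0.0,
        n_days=40,
        groups_per_day=2,
        mean_group_size=5,
        detection_prob=0.8,
        seed=101,
    )
    return simulate_population(cfg)
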