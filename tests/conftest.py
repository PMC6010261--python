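"""Shared fixtures: hand-built networks and brute-force traversal oracles.

The oracle helpers recompute every network metric by explicit set
enumeration (materialize each reach's upstream set, then sum/filter), fully
independent of the package's single-pass accumulation implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riverscape.core import StreamNetwork


def make_network(rows) -> StreamNetwork:
    """Build a network from (reach_id, downstream_id, length, area, slope)
    tuples plus optional per-reach extra dicts."""
    recs = []
    for row in rows:
        rid, down, length, area, slope, *rest = row
        rec = {
            "reach_id": rid,
            "downstream_id": down,
            "length_km": length,
            "local_area_km2": area,
            "slope": slope,
        }
        if rest:
            rec.update(rest[0])
        recs.append(rec)
    return StreamNetwork(pd.DataFrame(recs))


@pytest.fixture
def chain3() -> StreamNetwork:
    """a -> b -> c with local areas 1, 2, 3 km^2 and lengths 1, 2, 3 km."""
    return make_network(
        [
            ("a", "b", 1.0, 1.0, 0.01),
            ("b", "c", 2.0, 2.0, 0.01),
            ("c", "", 3.0, 3.0, 0.01, {"terminus_type": "ocean"}),
        ]
    )


@pytest.fixture
def dci_fixture():
    """Focal reach with 10 km of upstream network; a dam on u1 bounds a
    4 km subtree (u1 + u2 + u3), leaving 6 km functional."""
    net = make_network(
        [
            ("u2", "u1", 1.0, 1.0, 0.01),
            ("u3", "u1", 1.0, 1.0, 0.01),
            ("u1", "f", 2.0, 1.0, 0.01),
            ("v2", "v1", 2.0, 1.0, 0.01),
            ("v3", "v1", 1.0, 1.0, 0.01),
            ("v1", "f", 3.0, 1.0, 0.01),
            ("f", "", 1.0, 1.0, 0.01, {"terminus_type": "ocean"}),
        ]
    )
    dams = pd.DataFrame([{"dam_id": "d0", "reach_id": "u1", "storage_m3": 1e6}])
    return net, dams


def random_tree(rng: np.random.Generator, n: int, extra_columns=()) -> StreamNetwork:
    """Uniform random attachment tree with randomized attributes."""
    downstream = [-1]
    for i in range(1, n):
        downstream.append(int(rng.integers(i)))
    ids = [f"n{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "reach_id": ids,
            "downstream_id": ["" if d < 0 else ids[d] for d in downstream],
            "length_km": rng.uniform(0.2, 3.0, n),
            "local_area_km2": rng.uniform(0.1, 10.0, n),
            "slope": rng.uniform(0.0, 0.2, n),
            "terminus_type": ["ocean"] + ["interior"] * (n - 1),
        }
    )
    for col, (lo, hi) in extra_columns:
        df[col] = rng.uniform(lo, hi, n)
    return StreamNetwork(df)


def random_dams(rng: np.random.Generator, net: StreamNetwork, p: float = 0.1) -> pd.DataFrame:
    picks = [rid for rid in net.ids if rng.random() < p]
    return pd.DataFrame(
        [
            {"dam_id": f"d{k}", "reach_id": rid, "storage_m3": float(rng.uniform(1e4, 1e7))}
            for k, rid in enumerate(picks)
        ],
        columns=["dam_id", "reach_id", "storage_m3"],
    )


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def upstream_sets(net: StreamNetwork) -> dict[int, set[int]]:
    """Exhaustive upstream reach sets (excluding the focal reach), by DFS
    from each reach over the children lists."""
    out = {}
    for i in range(len(net)):
        seen = set()
        stack = list(net.children[i])
        while stack:
            j = stack.pop()
            seen.add(j)
            stack.extend(net.children[j])
        out[i] = seen
    return out


def oracle_sum_inclusive(net: StreamNetwork, values) -> np.ndarray:
    ups = upstream_sets(net)
    values = np.asarray(values, float)
    return np.array([values[i] + sum(values[j] for j in ups[i]) for i in range(len(net))])


def oracle_area_weighted_mean(net: StreamNetwork, values) -> np.ndarray:
    ups = upstream_sets(net)
    values = np.asarray(values, float)
    areas = net.local_areas_km2
    out = np.empty(len(net))
    for i in range(len(net)):
        members = [i, *ups[i]]
        w = areas[members]
        out[i] = np.average(values[members], weights=w) if w.sum() > 0 else values[i]
    return out


def oracle_upstream_length(net: StreamNetwork) -> np.ndarray:
    ups = upstream_sets(net)
    lengths = net.lengths_km
    return np.array([sum(lengths[j] for j in ups[i]) for i in range(len(net))])


def oracle_functional_length(net: StreamNetwork, dams: pd.DataFrame) -> np.ndarray:
    """Functional upstream length by explicit blocked-subtree enumeration:
    walk upstream from each focal reach, stopping at (and excluding) dammed
    reaches."""
    dammed = {net.index_of(r) for r in dams["reach_id"].astype(str)}
    lengths = net.lengths_km
    out = np.zeros(len(net))
    for i in range(len(net)):
        total = 0.0
        stack = [j for j in net.children[i] if j not in dammed]
        while stack:
            j = stack.pop()
            total += lengths[j]
            stack.extend(c for c in net.children[j] if c not in dammed)
        out[i] = total
    return out
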