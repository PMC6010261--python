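"""Accumulation, connectivity, DCI and DOR against hand sums and
brute-force traversal oracles."""

import numpy as np
import pandas as pd
import pytest

from riverscape.netops import (
    accumulate,
    connected_to_terminus,
    cumulative_area,
    dci,
    dor,
    functional_upstream_length,
    topological_order,
    upstream_length,
)

from conftest import (
    make_network,
    oracle_area_weighted_mean,
    oracle_functional_length,
    oracle_sum_inclusive,
    oracle_upstream_length,
    random_dams,
    random_tree,
    upstream_sets,
)


class TestTopologicalOrder:
    def test_chain_order(self, chain3):
        order = [chain3.ids[i] for i in topological_order(chain3)]
        assert order.index("a") < order.index("b") < order.index("c")

    def test_star_outlet_last(self):
        net = make_network(
            [("h1", "o", 1, 1, 0), ("h2", "o", 1, 1, 0), ("h3", "o", 1, 1, 0), ("o", "", 1, 1, 0)]
        )
        assert topological_order(net)[-1] == net.index_of("o")

    def test_random_tree_respects_ancestry(self):
        net = random_tree(np.random.default_rng(7), 200)
        order = topological_order(net)
        pos = {int(i): p for p, i in enumerate(order)}
        ups = upstream_sets(net)
        for i, members in ups.items():
            assert all(pos[j] < pos[i] for j in members)


class TestAccumulate:
    def test_chain_hand_sum(self, chain3):
        np.testing.assert_allclose(cumulative_area(chain3), [1.0, 3.0, 6.0])

    def test_headwater_identity(self, chain3):
        acc = accumulate(chain3, [5.0, 1.0, 1.0], "sum_inclusive")
        assert acc[chain3.index_of("a")] == 5.0

    def test_matches_oracle_on_random_tree(self):
        rng = np.random.default_rng(11)
        net = random_tree(rng, 200)
        x = rng.uniform(0, 5, 200)
        np.testing.assert_allclose(accumulate(net, x, "sum_inclusive"), oracle_sum_inclusive(net, x), rtol=1e-12)
        np.testing.assert_allclose(
            accumulate(net, x, "area_weighted_mean"), oracle_area_weighted_mean(net, x), rtol=1e-12
        )

    def test_linearity(self):
        rng = np.random.default_rng(5)
        net = random_tree(rng, 80)
        x, y = rng.uniform(0, 1, 80), rng.uniform(0, 1, 80)
        lhs = accumulate(net, 2.0 * x + 3.0 * y, "sum_inclusive")
        rhs = 2.0 * accumulate(net, x, "sum_inclusive") + 3.0 * accumulate(net, y, "sum_inclusive")
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_missing_values_rejected(self, chain3):
        with pytest.raises(ValueError, match="missing"):
            accumulate(chain3, [1.0, np.nan, 1.0])


class TestUpstreamLength:
    def test_headwater_zero(self, chain3):
        assert upstream_length(chain3)[chain3.index_of("a")] == 0.0

    def test_chain_hand_sum(self, chain3):
        # downstream end: 1 + 2 = 3 km upstream, own 3 km excluded
        assert upstream_length(chain3)[chain3.index_of("c")] == pytest.approx(3.0)

    def test_matches_oracle(self):
        net = random_tree(np.random.default_rng(13), 150)
        np.testing.assert_allclose(upstream_length(net), oracle_upstream_length(net), rtol=1e-12)


class TestDCI:
    def test_no_dams_all_100(self):
        net = random_tree(np.random.default_rng(1), 60)
        empty = pd.DataFrame(columns=["dam_id", "reach_id", "storage_m3"])
        np.testing.assert_allclose(dci(net, empty), 100.0)

    def test_blocked_subtree_fixture(self, dci_fixture):
        net, dams = dci_fixture
        assert dci(net, dams)[net.index_of("f")] == pytest.approx(60.0)
        assert functional_upstream_length(net, dams)[net.index_of("f")] == pytest.approx(6.0)

    def test_dam_on_only_upstream_reach_gives_zero(self):
        net = make_network([("u", "f", 2, 1, 0), ("f", "", 1, 1, 0)])
        dams = pd.DataFrame([{"dam_id": "d", "reach_id": "u", "storage_m3": 1.0}])
        assert dci(net, dams)[net.index_of("f")] == 0.0

    def test_monotone_nonincreasing_as_dams_added(self):
        rng = np.random.default_rng(17)
        net = random_tree(rng, 120)
        dams = random_dams(rng, net, 0.15)
        prev = dci(net, dams.iloc[:0])
        for k in range(1, len(dams) + 1):
            cur = dci(net, dams.iloc[:k])
            assert (cur <= prev + 1e-9).all()
            prev = cur

    def test_functional_bounded_by_total(self):
        rng = np.random.default_rng(19)
        net = random_tree(rng, 150)
        dams = random_dams(rng, net, 0.1)
        func = functional_upstream_length(net, dams)
        total = upstream_length(net)
        assert (func <= total + 1e-9).all()

    def test_matches_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(5, 120))
            net = random_tree(rng, n)
            dams = random_dams(rng, net, 0.15)
            np.testing.assert_allclose(
                functional_upstream_length(net, dams), oracle_functional_length(net, dams), rtol=1e-12
            )

    def test_dam_on_unknown_reach_errors(self, chain3):
        dams = pd.DataFrame([{"dam_id": "d", "reach_id": "ghost", "storage_m3": 1.0}])
        with pytest.raises(ValueError, match="unknown reach"):
            dci(chain3, dams)


class TestDOR:
    def _net(self):
        return make_network(
            [
                ("a", "b", 1, 7.884, 0, {"runoff_mm_yr": 1000.0}),
                ("b", "", 1, 7.884, 0, {"runoff_mm_yr": 1000.0}),
            ]
        )

    def test_zero_storage_zero_dor(self):
        net = self._net()
        empty = pd.DataFrame(columns=["dam_id", "reach_id", "storage_m3"])
        np.testing.assert_allclose(dor(net, empty), 0.0)

    def test_hand_ratio(self):
        # annual runoff volume at b: (7.884 + 7.884) km^2 * 1000 mm * 1000
        # = 1.5768e7 m^3; storage 2e6 m^3 upstream -> 12.68%
        net = self._net()
        dams = pd.DataFrame([{"dam_id": "d", "reach_id": "a", "storage_m3": 2.0e6}])
        assert dor(net, dams)[net.index_of("b")] == pytest.approx(12.68, abs=0.005)

    def test_storage_homogeneity(self):
        rng = np.random.default_rng(29)
        net = random_tree(rng, 80, extra_columns=[("runoff_mm_yr", (200, 800))])
        dams = random_dams(rng, net, 0.2)
        base = dor(net, dams)
        doubled = dams.assign(storage_m3=dams["storage_m3"] * 2)
        np.testing.assert_allclose(dor(net, doubled), 2 * base, rtol=1e-12)

    def test_focal_storage_toggle(self):
        net = self._net()
        dams = pd.DataFrame([{"dam_id": "d", "reach_id": "b", "storage_m3": 1e6}])
        inclusive = dor(net, dams)[net.index_of("b")]
        exclusive = dor(net, dams, include_focal_storage=False)[net.index_of("b")]
        assert inclusive > 0 and exclusive == 0.0


class TestConnectivity:
    def test_dam_free_path_to_ocean(self, chain3):
        empty = pd.DataFrame(columns=["dam_id", "reach_id", "storage_m3"])
        connected, terminus = connected_to_terminus(chain3, empty)
        assert connected.all() and (terminus == "ocean").all()

    def test_downstream_dam_blocks(self, chain3):
        dams = pd.DataFrame([{"dam_id": "d", "reach_id": "b", "storage_m3": 1.0}])
        connected, _ = connected_to_terminus(chain3, dams)
        assert not connected[chain3.index_of("a")]
        # dam on b itself does not disconnect b
        assert connected[chain3.index_of("b")]
        assert connected[chain3.index_of("c")]

    def test_interior_terminus_disconnected(self):
        net = make_network([("a", "b", 1, 1, 0), ("b", "", 1, 1, 0, {"terminus_type": "interior"})])
        empty = pd.DataFrame(columns=["dam_id", "reach_id", "storage_m3"])
        connected, terminus = connected_to_terminus(net, empty)
        assert not connected.any() and (terminus == "interior").all()
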