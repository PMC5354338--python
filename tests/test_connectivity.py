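"""Structural wiring: area graphs, Gaussian link profile, twin pairs."""

import numpy as np
import pytest

from perisylvian.connectivity import (
    AREAS,
    JUMPING_PAIRS,
    AreaGraph,
    build_synapses,
    connection_probability,
    inhibitory_links,
    instantiate_pair,
)


class TestAreaGraph:
    def test_monkey_chain_and_human_superset(self):
        ma, ha = AreaGraph.monkey(), AreaGraph.human()
        assert len(ma.projections) == 10          # 5 reciprocal pairs
        assert len(ha.projections) == 18          # + 4 reciprocal jumping pairs
        assert ma.projections < ha.projections    # strict subset
        assert ha.jumping_links() == {(a, b) for a, b in JUMPING_PAIRS} \
            | {(b, a) for a, b in JUMPING_PAIRS}

    def test_sensorimotor_path_shortens(self):
        assert AreaGraph.monkey().path_length("A1", "M1") == 5
        assert AreaGraph.human().path_length("A1", "M1") == 3

    def test_middle_areas_gain_degree(self):
        ma, ha = AreaGraph.monkey(), AreaGraph.human()
        for area in ("PB", "PF"):
            assert ma.degree(area) == 2
            assert ha.degree(area) == 4


class TestConnectionProbability:
    def test_peak_window_and_radial_symmetry(self):
        assert connection_probability(0, 0, 4.5, 0.4) == pytest.approx(0.4)
        assert connection_probability(10, 0, 4.5, 0.4) == 0.0   # outside 19x19
        assert connection_probability(0, 23, 4.5, 0.4) == 0.0
        assert connection_probability(3, 4, 4.5, 0.4) == pytest.approx(
            connection_probability(5, 0, 4.5, 0.4))

    def test_validation(self):
        with pytest.raises(ValueError):
            connection_probability(0, 0, sigma=-1)
        with pytest.raises(ValueError):
            connection_probability(0, 0, p0=1.5)
        with pytest.raises(ValueError):
            connection_probability(0, 0, n=10)


class TestBuildSynapses:
    def test_window_discipline_weights_and_no_self_links(self):
        syn = build_synapses(AreaGraph.human(), rng=np.random.default_rng(0))
        side = syn.side
        pre_local = np.asarray(syn.pre) % syn.area_cells
        post_local = np.asarray(syn.post) % syn.area_cells
        dr = np.abs(pre_local // side - post_local // side)
        dc = np.abs(pre_local % side - post_local % side)
        assert dr.max() <= 9 and dc.max() <= 9
        same_area = syn.area_of(syn.pre) == syn.area_of(syn.post)
        assert not np.any(same_area & (syn.pre == syn.post))
        assert syn.w.min() >= 0.0 and syn.w.max() <= 0.1

    def test_between_area_links_follow_graph(self):
        syn = build_synapses(AreaGraph.monkey(), rng=np.random.default_rng(1))
        counts = syn.links_by_projection()
        between = {k for k in counts if k[0] != k[1]}
        assert between == AreaGraph.monkey().directed_links

    def test_determinism_and_p0_zero(self):
        g = AreaGraph.human()
        a = build_synapses(g, rng=np.random.default_rng(5))
        b = build_synapses(g, rng=np.random.default_rng(5))
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.w, b.w)
        empty = build_synapses(g, p0=0.0, rng=np.random.default_rng(5))
        assert empty.n_links == 0

    def test_empirical_acceptance_matches_profile(self):
        # Monte-Carlo: realised fraction at a given offset ~ the Gaussian
        # profile, within 3 binomial SE (single area keeps offsets unique).
        sigma, p0 = 4.5, 0.457
        graph = AreaGraph.chain(["A"])
        syn = build_synapses(graph, sigma=sigma, p0=p0,
                             rng=np.random.default_rng(7), side=25)
        side = 25
        pre_rc = np.stack([np.asarray(syn.pre) // side,
                           np.asarray(syn.pre) % side], 1)
        post_rc = np.stack([np.asarray(syn.post) // side,
                            np.asarray(syn.post) % side], 1)
        diff = pre_rc - post_rc
        for dx, dy in [(0, 1), (3, 0), (2, 2), (6, 0), (0, 8)]:
            # candidate count: posts for which (r+dx, c+dy) is on the grid
            n_cand = (25 - abs(dx)) * (25 - abs(dy))
            hits = int(np.sum((diff[:, 0] == dx) & (diff[:, 1] == dy)))
            p = float(connection_probability(dx, dy, sigma, p0))
            se = np.sqrt(p * (1 - p) / n_cand)
            assert abs(hits / n_cand - p) < 3 * se + 1e-12, (dx, dy)


class TestInhibitoryWiring:
    def test_pooling_window_and_own_column_feedback(self):
        side = 7
        pool, feedback = inhibitory_links(side, window=5)
        assert feedback == [(i, i) for i in range(side * side)]
        counts = {}
        for e_cell, i_cell in pool:
            er, ec = divmod(e_cell, side)
            ir, ic = divmod(i_cell, side)
            assert abs(er - ir) <= 2 and abs(ec - ic) <= 2
            counts[i_cell] = counts.get(i_cell, 0) + 1
        # interior inhibitory cells pool the full 5x5 patch
        assert counts[3 * side + 3] == 25
        assert counts[0] == 9  # corner clipped


class TestInstantiatePair:
    def test_twins_share_everything_but_jumping_links(self):
        ha, ma = instantiate_pair(seed=11)
        assert ha.patterns == ma.patterns
        ha_set = {(int(p), int(q)): float(w) for p, q, w in
                  zip(ha.synapses.pre, ha.synapses.post, ha.synapses.w)}
        ma_set = {(int(p), int(q)): float(w) for p, q, w in
                  zip(ma.synapses.pre, ma.synapses.post, ma.synapses.w)}
        # every MA link exists in HA with equal weight
        for k, w in ma_set.items():
            assert ha_set[k] == w
        # HA minus MA contains only links of the jumping projections
        area = lambda c: AREAS[c // 625]
        jumping = ha.graph.jumping_links()
        extra = set(ha_set) - set(ma_set)
        assert extra
        for p, q in extra:
            assert (area(p), area(q)) in jumping

    def test_between_area_count_ratio(self):
        # 9 vs 5 reciprocal between-area pairs of identical statistics
        ratios = []
        for seed in range(10):
            ha, ma = instantiate_pair(seed=seed, side=15)
            n_between = lambda syn: int(np.sum(
                syn.area_of(syn.pre) != syn.area_of(syn.post)))
            ratios.append(n_between(ha.synapses) / n_between(ma.synapses))
        assert np.mean(ratios) == pytest.approx(9 / 5, rel=0.05)

    def test_pb_pf_degree_rises_in_realised_wiring(self):
        ha, ma = instantiate_pair(seed=3, side=15)
        for area in ("PB", "PF"):
            n_pairs = lambda inst: len({k for k in
                                        inst.synapses.links_by_projection()
                                        if k[0] != k[1] and area in k})
            assert n_pairs(ma) == 4    # 2 reciprocal pairs -> 4 directed
            assert n_pairs(ha) == 8    # 4 reciprocal pairs


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        syn = build_synapses(AreaGraph.monkey(),
                             rng=np.random.default_rng(2), side=9)
        path = tmp_path / "syn.npz"
        syn.save(path)
        from perisylvian.connectivity import SynapseSet
        back = SynapseSet.load(path)
        assert np.array_equal(back.pre, syn.pre)
        assert np.array_equal(back.w, syn.w)
        assert back.areas == syn.areas
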