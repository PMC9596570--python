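"""Dual-puncta construction, edge distances, mitochondria association, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitoflux as mf
from mitoflux.associate import (
    associate_with_mito,
    build_dual_puncta,
    min_edge_distance,
    restrict_to_cell,
    summarize_cell,
)
from mitoflux.detect import DetectionParams, detect_puncta


class Obj:
    """Minimal pixel-set object for association inputs."""

    def __init__(self, oid, pixels):
        self.id = oid
        self.pixels = np.asarray(pixels, dtype=int)


class TestBuildDualPuncta:
    def test_disjoint_objects_no_duals(self):
        g = [Obj(1, [[0, 0], [0, 1]])]
        r = [Obj(1, [[5, 5]])]
        assert build_dual_puncta(g, r) == []

    def test_single_shared_pixel_union_area(self):
        g = [Obj(1, [[0, 0], [0, 1], [0, 2]])]
        r = [Obj(7, [[0, 2], [0, 3]])]
        (dual,) = build_dual_puncta(g, r)
        assert dual.area_px == 3 + 2 - 1
        assert dual.gfp_ids == [1] and dual.rfp_ids == [7]

    def test_one_to_many_overlap_single_component(self):
        """One mRFP object bridging two GFP objects forms one dual punctum."""
        g = [Obj(1, [[0, 0]]), Obj(2, [[0, 4]])]
        r = [Obj(1, [[0, 0], [0, 1], [0, 2], [0, 3], [0, 4]])]
        duals = build_dual_puncta(g, r)
        assert len(duals) == 1
        assert sorted(duals[0].gfp_ids) == [1, 2]
        assert duals[0].area_px == 5

    def test_matches_bruteforce_components_on_random_objects(self):
        """Grouping equals brute-force connected components of the overlap graph."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            g = [
                Obj(i, rng.integers(0, 12, size=(rng.integers(1, 5), 2)))
                for i in range(rng.integers(1, 6))
            ]
            r = [
                Obj(i, rng.integers(0, 12, size=(rng.integers(1, 5), 2)))
                for i in range(rng.integers(1, 6))
            ]
            duals = build_dual_puncta(g, r)

            # brute force: adjacency over all object pairs, DFS components
            nodes = [("g", i) for i in range(len(g))] + [("r", i) for i in range(len(r))]
            pix = {("g", i): {tuple(p) for p in o.pixels} for i, o in enumerate(g)}
            pix.update({("r", i): {tuple(p) for p in o.pixels} for i, o in enumerate(r)})
            adj = {n: set() for n in nodes}
            for i in range(len(g)):
                for j in range(len(r)):
                    if pix[("g", i)] & pix[("r", j)]:
                        adj[("g", i)].add(("r", j))
                        adj[("r", j)].add(("g", i))
            seen, comps = set(), []
            for n in nodes:
                if n in seen or not adj[n]:
                    continue
                comp, stack = set(), [n]
                while stack:
                    cur = stack.pop()
                    if cur in comp:
                        continue
                    comp.add(cur)
                    stack.extend(adj[cur] - comp)
                seen |= comp
                comps.append(frozenset().union(*(pix[m] for m in comp)))
            assert sorted(len(c) for c in comps) == sorted(d.area_px for d in duals)


class TestMinEdgeDistance:
    def test_identical_sets_zero(self):
        p = np.array([[1, 1], [1, 2]])
        assert min_edge_distance(p, p) == 0.0

    def test_three_four_five(self):
        assert min_edge_distance([[0, 0]], [[3, 4]]) == 5.0

    def test_matches_allpairs_oracle_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.integers(0, 40, size=(rng.integers(1, 20), 2))
            b = rng.integers(0, 40, size=(rng.integers(1, 20), 2))
            brute = min(
                float(np.hypot(pa[0] - pb[0], pa[1] - pb[1])) for pa in a for pb in b
            )
            assert min_edge_distance(a, b) == brute

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            min_edge_distance(np.empty((0, 2)), [[0, 0]])

    @given(
        a=st.tuples(st.integers(0, 30), st.integers(0, 30)),
        b=st.tuples(st.integers(0, 30), st.integers(0, 30)),
        c=st.tuples(st.integers(0, 30), st.integers(0, 30)),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_triangle_on_singletons(self, a, b, c):
        d_ab = min_edge_distance([a], [b])
        d_ba = min_edge_distance([b], [a])
        d_ac = min_edge_distance([a], [c])
        d_cb = min_edge_distance([c], [b])
        assert d_ab == d_ba
        assert d_ab <= d_ac + d_cb + 1e-9


class TestAssociateWithMito:
    def test_overlapping_distance_zero(self):
        duals = build_dual_puncta([Obj(1, [[2, 2], [2, 3]])], [Obj(1, [[2, 3]])])
        (rec,) = associate_with_mito(duals, [Obj(0, [[2, 2]])])
        assert rec.edge_distance_px == 0.0 and rec.associated

    def test_exactly_at_cutoff_counts_as_associated(self):
        """Distance exactly 5 px is within the resolution limit: associated."""
        duals = build_dual_puncta([Obj(1, [[0, 0]])], [Obj(1, [[0, 0]])])
        (rec,) = associate_with_mito(duals, [Obj(0, [[0, 5]])], cutoff_px=5)
        assert rec.edge_distance_px == 5.0 and rec.associated
        (rec6,) = associate_with_mito(duals, [Obj(0, [[0, 6]])], cutoff_px=5)
        assert not rec6.associated

    def test_no_mito_objects(self):
        duals = build_dual_puncta([Obj(1, [[0, 0]])], [Obj(1, [[0, 0]])])
        (rec,) = associate_with_mito(duals, [])
        assert rec.nearest_mito_id is None and not rec.associated

    def test_all_duals_associated_when_placed_on_mito(self):
        """frac_near_mito = 1: every detected-and-matched dual is associated."""
        spec = mf.SceneSpec(seed=9, n_dual=6, n_gfp_only=2, n_rfp_only=2,
                            puncta_min_sep_px=12.0, frac_near_mito=1.0)
        truth, scene = mf.simulate_scene(spec)
        sup = truth.cell_mask
        gfp = detect_puncta(scene["gfp"], DetectionParams(support=sup), "gfp")
        rfp = detect_puncta(scene["rfp"], DetectionParams(support=sup), "rfp")
        mito = detect_puncta(scene["mito"], DetectionParams(min_area_px=0, support=sup), "mito")
        duals = build_dual_puncta(gfp, rfp)
        records = associate_with_mito(duals, mito)
        assert len(duals) == truth.expected_n_dual
        assert all(r.associated for r in records)


class TestSummaries:
    def test_empty_counts(self):
        s = summarize_cell("c1", [], [], [], [])
        assert (s.n_gfp, s.n_rfp, s.n_dual, s.n_dual_near_mito) == (0, 0, 0, 0)
        assert s.fraction_near_mito is None

    def test_fraction_arithmetic(self):
        duals = build_dual_puncta(
            [Obj(i, [[i, 0]]) for i in range(10)], [Obj(i, [[i, 0]]) for i in range(10)]
        )
        mito = [Obj(0, [[k, 0]] ) for k in range(5)]
        records = associate_with_mito(duals, [Obj(0, [[i, 0] for i in range(5)])])
        s = summarize_cell("c", [], [], duals, records)
        assert s.n_dual == 10
        assert s.n_dual_near_mito == sum(r.associated for r in records)

    def test_counts_equal_bruteforce_recount(self, default_scene):
        truth, scene = default_scene
        sup = truth.cell_mask
        gfp = detect_puncta(scene["gfp"], DetectionParams(support=sup), "gfp")
        rfp = detect_puncta(scene["rfp"], DetectionParams(support=sup), "rfp")
        mito = detect_puncta(scene["mito"], DetectionParams(min_area_px=0, support=sup), "mito")
        duals = build_dual_puncta(gfp, rfp)
        records = associate_with_mito(duals, mito)
        s = summarize_cell("c", gfp, rfp, duals, records)
        assert s.n_dual == len(duals)
        assert s.n_dual_near_mito == len([r for r in records if r.associated])
        assert s.n_dual_near_mito <= s.n_dual

    def test_restrict_to_cell_majority_rule(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :5] = True
        inside = Obj(1, [[0, 0], [0, 1], [0, 2]])
        straddle_in = Obj(2, [[0, 3], [0, 4], [0, 5]])  # 2/3 inside
        outside = Obj(3, [[0, 6], [0, 7], [0, 8]])
        kept = restrict_to_cell([inside, straddle_in, outside], mask)
        assert [o.id for o in kept] == [1, 2]


class TestEndToEndRecovery:
    def test_dual_counts_and_flags_match_ground_truth(self):
        """At SNR >= 5 the measured dual count is within 10% of truth and
        association flags agree with construction for matched puncta."""
        for seed in (21, 22, 23):
            spec = mf.SceneSpec(seed=seed, n_dual=10, n_gfp_only=3, n_rfp_only=3,
                                puncta_peak_snr=5.0, frac_near_mito=0.5)
            truth, scene = mf.simulate_scene(spec)
            sup = truth.cell_mask
            gfp = detect_puncta(scene["gfp"], DetectionParams(support=sup), "gfp")
            rfp = detect_puncta(scene["rfp"], DetectionParams(support=sup), "rfp")
            mito = detect_puncta(scene["mito"], DetectionParams(min_area_px=0, support=sup), "mito")
            duals = build_dual_puncta(gfp, rfp)
            records = associate_with_mito(duals, mito)
            assert abs(len(duals) - truth.expected_n_dual) <= 0.1 * truth.expected_n_dual
            flags = {r.dual_id: r.associated for r in records}
            true_near = {p.near_mito for p in truth.dual_puncta()}
            # per-dual comparison via nearest true punctum
            for d in duals:
                nearest = min(
                    truth.dual_puncta(),
                    key=lambda p: (p.center[0] - d.centroid[0]) ** 2
                    + (p.center[1] - d.centroid[1]) ** 2,
                )
                dist = np.hypot(
                    nearest.center[0] - d.centroid[0], nearest.center[1] - d.centroid[1]
                )
                if dist <= 3:
                    assert flags[d.id] == nearest.near_mito
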