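import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midzone.errors import UndefinedAngleError
from midzone.filaments import BoundingBox, Filament, FilamentNetwork
from midzone.geometry import (Interaction, detect_interactions,
                              filament_pair_distance, interaction_angle,
                              nearest_neighbor_distances, network_stats,
                              segment_min_distance)
from midzone.synth import make_overlap_pairs, make_random_network
from .conftest import straight


# -------------------------------------------------------------------------
# Independent oracles (plain formulas, no reuse of library internals)
# -------------------------------------------------------------------------

def _oracle_point_seg(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


def _oracle_polyline_distance(pts, poly):
    """Min distance from each query point to a polyline (projection formula,
    broadcast over all point-segment combinations)."""
    a = poly[:-1][None, :, :]            # (1, S, 3)
    ab = poly[1:][None, :, :] - a        # (1, S, 3)
    ap = pts[:, None, :] - a             # (P, S, 3)
    denom = (ab * ab).sum(-1)
    t = np.clip((ap * ab).sum(-1) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(pts[:, None, :] - closest, axis=-1).min(axis=1)


def _oracle_resample(poly, step):
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    arcs = np.arange(0.0, u[-1], step)
    if u[-1] - arcs[-1] > 1e-9:
        arcs = np.append(arcs, u[-1])
    pts = np.column_stack([np.interp(arcs, u, poly[:, k]) for k in range(3)])
    return arcs, pts


def dense_interaction_oracle(net, d_max=100.0, l_min=100.0, step=1.0):
    """Brute-force interaction scan: dense sampling, all ordered pairs."""
    found = []
    for src, tgt in itertools.permutations(net.filaments, 2):
        arcs, pts = _oracle_resample(src.points, step)
        d = _oracle_polyline_distance(pts, tgt.points)
        inside = d <= d_max
        i = 0
        while i < len(arcs):
            if not inside[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(arcs) and inside[j + 1]:
                j += 1
            start = arcs[i] if i == 0 else arcs[i - 1] + (
                (d[i - 1] - d_max) / (d[i - 1] - d[i])) * (arcs[i] - arcs[i - 1])
            end = arcs[j] if j == len(arcs) - 1 else arcs[j + 1] - (
                (d[j + 1] - d_max) / (d[j + 1] - d[j])) * (arcs[j + 1] - arcs[j])
            if end - start >= l_min - 1e-9:
                found.append((src.id, tgt.id, start, end, d[i:j + 1].min()))
            i = j + 1
    return found


def _pair_total_lengths(records):
    out = {}
    for r in records:
        if isinstance(r, Interaction):
            key, length = (r.source_id, r.target_id), r.length
        else:
            key, length = (r[0], r[1]), r[3] - r[2]
        out[key] = out.get(key, 0.0) + length
    return out


# -------------------------------------------------------------------------
# Elementary distances and angles
# -------------------------------------------------------------------------

class TestSegmentDistance:
    @pytest.mark.parametrize("a,b,expected", [
        (((0, 0, 0), (100, 0, 0)), ((0, 50, 0), (100, 50, 0)), 50.0),
        (((0, 0, 0), (100, 0, 0)), ((50, -50, 0), (50, 50, 0)), 0.0),
        (((0, 0, 0), (100, 0, 0)), ((200, 30, 40), (300, 30, 40)),
         np.sqrt(100 ** 2 + 30 ** 2 + 40 ** 2)),
    ])
    def test_known_configurations(self, a, b, expected):
        d = segment_min_distance(np.array(a[0], float), np.array(a[1], float),
                                 np.array(b[0], float), np.array(b[1], float))
        assert d == pytest.approx(expected, abs=1e-9)

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(30):
            a0, a1, b0, b1 = rng.uniform(-100, 100, (4, 3))
            d = segment_min_distance(a0, a1, b0, b1)
            ts = np.linspace(0, 1, 400)
            pa = a0 + ts[:, None] * (a1 - a0)
            oracle = min(_oracle_point_seg(p, b0, b1) for p in pa)
            assert d <= oracle + 1e-9
            assert d == pytest.approx(oracle, abs=0.2)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-500, 500, allow_nan=False), min_size=12,
                    max_size=12))
    def test_symmetry_and_endpoint_bound(self, coords):
        """d(a, b) == d(b, a), and never exceeds any endpoint-to-segment
        distance; translation leaves the distance unchanged."""
        c = np.array(coords).reshape(4, 3)
        a0, a1, b0, b1 = c
        if np.allclose(a0, a1) or np.allclose(b0, b1):
            return
        d = segment_min_distance(a0, a1, b0, b1)
        assert d == pytest.approx(segment_min_distance(b0, b1, a0, a1), abs=1e-9)
        for p in (a0, a1):
            assert d <= _oracle_point_seg(p, b0, b1) + 1e-9
        shift = np.array([17.0, -3.0, 42.0])
        assert d == pytest.approx(
            segment_min_distance(a0 + shift, a1 + shift, b0 + shift, b1 + shift),
            abs=1e-6)

    def test_degenerate_point_segments(self):
        p = np.array([0.0, 0, 0])
        q = np.array([3.0, 4, 0])
        assert segment_min_distance(p, p, q, q) == pytest.approx(5.0)


class TestPairDistanceAndAngle:
    def test_identical_filaments_distance_zero(self, parallel_pair):
        f = parallel_pair.filaments[0]
        assert filament_pair_distance(f, f) == 0.0

    def test_parallel_offset(self, parallel_pair):
        f, g = parallel_pair.filaments
        assert filament_pair_distance(f, g) == pytest.approx(50.0)

    def test_matches_brute_force_on_random_polylines(self, rng):
        for _ in range(10):
            a = Filament(id=0, points=np.cumsum(rng.uniform(1, 50, (10, 3)), axis=0))
            b = Filament(id=1, points=np.cumsum(rng.uniform(1, 50, (10, 3)), axis=0)
                         + rng.uniform(-200, 200, 3))
            brute = min(
                segment_min_distance(a.points[i], a.points[i + 1],
                                     b.points[j], b.points[j + 1])
                for i in range(9) for j in range(9))
            assert filament_pair_distance(a, b) == pytest.approx(brute, abs=1e-9)

    @pytest.mark.parametrize("end_g,expected", [
        ((1, 0, 0), 0.0), ((0, 1, 0), 90.0),
    ])
    def test_angle_conventions(self, end_g, expected):
        f = straight(0, (0, 0, 0), (1, 0, 0))
        g = straight(1, (0, 0, 0), end_g)
        assert interaction_angle(f, g) == pytest.approx(expected, abs=1e-9)

    def test_antiparallel_is_180(self):
        f = straight(0, (0, 0, 0), (1, 0, 0))
        g = Filament(id=1, points=np.array([[1.0, 0, 0], [0.0, 0, 0]]))
        assert interaction_angle(f, g) == pytest.approx(180.0)

    def test_closed_loop_raises(self):
        loop = Filament(id=0, points=np.array(
            [[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]]))
        f = straight(1, (0, 0, 0), (1, 0, 0))
        with pytest.raises(UndefinedAngleError):
            interaction_angle(loop, f)

    def test_fold_option(self):
        f = straight(0, (0, 0, 0), (1, 0, 0))
        g = Filament(id=1, points=np.array([[1.0, 0, 0], [0.0, 0, 0]]))
        assert interaction_angle(f, g, fold=True) == pytest.approx(0.0)


# -------------------------------------------------------------------------
# Interaction detection
# -------------------------------------------------------------------------

class TestDetectInteractions:
    def test_full_overlap_pair(self, parallel_pair):
        its = detect_interactions(parallel_pair, resample_step=20.0)
        assert len(its) == 2  # one per ordered pair
        for it in its:
            assert it.length == pytest.approx(500.0, abs=40.0)
            assert it.min_distance == pytest.approx(50.0, abs=1e-6)
            assert it.angle == pytest.approx(0.0, abs=1e-9)

    def test_pair_beyond_threshold(self):
        net = FilamentNetwork(filaments=(
            straight(0, (0, 0, 0), (500, 0, 0)),
            straight(1, (0, 150, 0), (500, 150, 0)),
        ))
        assert detect_interactions(net) == []

    def test_diverging_target_boundary_matches_dense_oracle(self):
        # target runs parallel at 80 nm, then bends away beyond threshold
        tgt_pts = np.array([[0, 80, 0], [400, 80, 0], [700, 380, 0.0]])
        net = FilamentNetwork(filaments=(
            straight(0, (0, 0, 0), (700, 0, 0), n=8),
            Filament(id=1, points=tgt_pts),
        ))
        fast = [i for i in detect_interactions(net, resample_step=20.0)
                if i.source_id == 0]
        oracle = [r for r in dense_interaction_oracle(net, step=1.0)
                  if r[0] == 0]
        assert len(fast) == len(oracle) == 1
        assert fast[0].start_arc == pytest.approx(oracle[0][2], abs=40.0)
        assert fast[0].end_arc == pytest.approx(oracle[0][3], abs=40.0)

    def test_fewer_than_two_filaments(self):
        net = FilamentNetwork(filaments=(straight(0, (0, 0, 0), (500, 0, 0)),))
        assert detect_interactions(net) == []

    def test_monotone_in_dmax_and_lmin(self):
        net, _ = make_random_network(n=8, seed=5)
        base = _pair_total_lengths(detect_interactions(net, d_max=100))
        wider = _pair_total_lengths(detect_interactions(net, d_max=120))
        assert set(base) <= set(wider)
        for k in base:
            assert wider[k] >= base[k] - 1e-6
        loose = detect_interactions(net, l_min=50)
        strict = detect_interactions(net, l_min=100)
        assert set(_pair_total_lengths(strict)) <= set(_pair_total_lengths(loose))

    def test_symmetry_of_existence(self):
        net, _ = make_random_network(n=10, seed=7)
        pairs = {(i.source_id, i.target_id)
                 for i in detect_interactions(net, l_min=0.0)}
        assert {(b, a) for a, b in pairs} == pairs

    def test_grid_and_plain_paths_identical(self):
        net, _ = make_random_network(n=10, seed=3)
        with_grid = detect_interactions(net, use_grid=True)
        without = detect_interactions(net, use_grid=False)
        assert len(with_grid) == len(without)
        for a, b in zip(with_grid, without):
            assert (a.source_id, a.target_id) == (b.source_id, b.target_id)
            assert a.length == pytest.approx(b.length, abs=1e-6)
            assert a.min_distance == pytest.approx(b.min_distance, abs=1e-6)

    def test_small_grid_cell_preserves_correctness(self):
        net, _ = make_random_network(n=8, seed=9)
        small = detect_interactions(net, use_grid=True, cell=40.0)
        plain = detect_interactions(net, use_grid=False)
        assert _pair_total_lengths(small).keys() == _pair_total_lengths(plain).keys()
        for a, b in zip(small, plain):
            assert a.length == pytest.approx(b.length, abs=1e-6)

    def test_symmetric_mode_deduplicates_pairs(self):
        net, _ = make_overlap_pairs(n_pairs=2, spacing=50, overlap_length=500)
        ordered = detect_interactions(net, mode="ordered")
        sym = detect_interactions(net, mode="symmetric")
        assert len(sym) == len(ordered) // 2
        unordered = {tuple(sorted((i.source_id, i.target_id))) for i in sym}
        assert len(unordered) == len(sym)

    def test_designed_spacing_and_overlap_recovered(self):
        net, truth = make_overlap_pairs(n_pairs=4, spacing=60, overlap_length=500)
        its = detect_interactions(net)
        md = np.array([i.min_distance for i in its])
        il = np.array([i.length for i in its])
        assert md.mean() == pytest.approx(60.0, abs=1.0)
        assert il.mean() == pytest.approx(500.0, abs=40.0)
        assert all(0 <= i.angle <= 180 for i in its)
        assert all(i.min_distance <= 100.0 for i in its)
        assert all(i.length >= 100.0 - 1e-9 for i in its)


# -------------------------------------------------------------------------
# Nearest neighbors and statistics
# -------------------------------------------------------------------------

class TestNearestNeighbors:
    def test_three_parallel_lines(self):
        net = FilamentNetwork(filaments=(
            straight(0, (0, 0, 0), (500, 0, 0)),
            straight(1, (0, 60, 0), (500, 60, 0)),
            straight(2, (0, 200, 0), (500, 200, 0)),
        ))
        tab = nearest_neighbor_distances(net).set_index("filament_id")
        assert tab.loc[0, "distance_nm"] == pytest.approx(60.0)
        assert tab.loc[1, "distance_nm"] == pytest.approx(60.0)
        assert tab.loc[2, "distance_nm"] == pytest.approx(140.0)
        assert tab.loc[1, "nearest_id"] == 0  # tie broken to smaller id

    def test_symmetric_pair_mutual_nearest(self, parallel_pair):
        tab = nearest_neighbor_distances(parallel_pair).set_index("filament_id")
        assert tab.loc[0, "nearest_id"] == 1
        assert tab.loc[1, "nearest_id"] == 0

    def test_matches_brute_force_on_random_network(self):
        net, _ = make_random_network(n=20, seed=11)
        tab = nearest_neighbor_distances(net).set_index("filament_id")
        for f in net:
            dists = {g.id: filament_pair_distance(f, g) for g in net if g.id != f.id}
            best = min(dists.values())
            best_id = min(i for i, d in dists.items() if d == best)
            assert tab.loc[f.id, "distance_nm"] == pytest.approx(best, abs=1e-6)
            assert tab.loc[f.id, "nearest_id"] == best_id

    def test_single_filament_is_error(self):
        net = FilamentNetwork(filaments=(straight(0, (0, 0, 0), (500, 0, 0)),))
        with pytest.raises(ValueError):
            nearest_neighbor_distances(net)


class TestNetworkStats:
    def test_density_arithmetic(self):
        # 31 filaments in a 10 um^3 box: 2500 x 2000 x 2000 nm
        vol = BoundingBox(np.zeros(3), np.array([2500.0, 2000.0, 2000.0]))
        fils = tuple(straight(i, (100, 60 * i + 50, 1000),
                              (600, 60 * i + 50, 1000)) for i in range(31))
        net = FilamentNetwork(filaments=fils, volume=vol)
        stats = network_stats(net, interactions=[])
        assert stats.density_per_um3 == pytest.approx(3.1)

    def test_population_sd_of_equal_lengths_is_zero(self):
        fils = tuple(straight(i, (0, 200 * i, 0), (400, 200 * i, 0))
                     for i in range(3))
        stats = network_stats(FilamentNetwork(filaments=fils), interactions=[])
        assert stats.mean_length_nm == pytest.approx(400.0)
        assert stats.sd_length_nm == 0.0

    def test_distance_bin_fractions(self):
        its = [Interaction(0, 1, 0, 200, 200, d, 0.0) for d in (30, 60, 90, 120)]
        net = FilamentNetwork(filaments=(
            straight(0, (0, 0, 0), (500, 0, 0)),
            straight(1, (0, 50, 0), (500, 50, 0)),
        ))
        stats = network_stats(net, its, bins=[100.0])
        assert stats.distance_bin_fractions[100.0] == pytest.approx(0.75)
        assert stats.distance_bin_fractions[np.inf] == pytest.approx(0.25)
        assert sum(stats.distance_bin_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_interactions_reported_absent(self, parallel_pair):
        stats = network_stats(parallel_pair, interactions=[])
        assert stats.n_interactions == 0
        assert stats.mean_interaction_length_nm is None
        assert stats.distance_bin_fractions is None
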