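import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.stats import norm

from coastcr.habitat import GridSpec
from coastcr.hotspots import (
    CountGrid,
    HotspotSet,
    average_nearest_neighbor,
    classify_hotspots,
    getis_ord_gi_star,
    gi_to_frame,
    grid_counts,
    hotspot_overlap,
    isa_threshold,
    morans_i,
)


def count_grid(arr, month="2023-08", cell=1.0):
    arr = np.asarray(arr)
    return CountGrid(month, arr, GridSpec((0.0, 0.0), arr.shape[1], arr.shape[0], cell))


def fixes(xy, month="2023-08"):
    return pd.DataFrame(
        {
            "animal_id": "a",
            "timestamp": pd.Timestamp(f"{month}-05 12:00"),
            "lc": "3",
            "x_km": [p[0] for p in xy],
            "y_km": [p[1] for p in xy],
        }
    )


# -- independent brute-force oracles ---------------------------------

def brute_force_gi_star(counts, threshold, cell=1.0, min_neighbors=8):
    """Direct loop evaluation of the Gi* formula."""
    ny, nx = counts.shape
    x = counts.ravel().astype(float)
    n = x.size
    xbar = x.mean()
    s = np.sqrt((x**2).sum() / n - xbar**2)
    coords = [( (c + 0.5) * cell, (r + 0.5) * cell) for r in range(ny) for c in range(nx)]
    z = np.zeros(n)
    for i in range(n):
        d = np.array([np.hypot(coords[i][0] - cx, coords[i][1] - cy) for cx, cy in coords])
        others = np.sort(np.delete(d, i))
        thr = threshold
        if len(others) >= min_neighbors and others[min_neighbors - 1] > thr:
            thr = others[min_neighbors - 1]
        w = (d <= thr).astype(float)
        sw, sw2 = w.sum(), (w**2).sum()
        num = (w * x).sum() - xbar * sw
        den = s * np.sqrt((n * sw2 - sw**2) / (n - 1))
        z[i] = num / den
    return z.reshape(ny, nx)


def brute_force_morans_i(counts, threshold, cell=1.0):
    ny, nx = counts.shape
    x = counts.ravel().astype(float)
    n = x.size
    xbar = x.mean()
    coords = [((c + 0.5) * cell, (r + 0.5) * cell) for r in range(ny) for c in range(nx)]
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1])
            if d <= threshold:
                num += (x[i] - xbar) * (x[j] - xbar)
                s0 += 1.0
    return (n / s0) * num / ((x - xbar) ** 2).sum()


class TestGridCounts:
    def test_three_fixes_one_cell(self, grid_10):
        cg = grid_counts(fixes([(2.2, 3.3), (2.4, 3.6), (2.9, 3.1)]), "2023-08", grid_10)
        assert cg.counts[3, 2] == 3
        assert cg.total == 3

    def test_edge_half_open(self, grid_10):
        cg = grid_counts(fixes([(1.0, 2.0)]), "2023-08", grid_10)
        assert cg.counts[2, 1] == 1  # edge belongs to the upper cell

    def test_conservation(self, grid_10):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (137, 2))
        cg = grid_counts(fixes(pts.tolist()), "2023-08", grid_10)
        assert cg.total == 137

    def test_outside_extent_errors(self, grid_10):
        with pytest.raises(ValueError, match="outside grid extent"):
            grid_counts(fixes([(12.0, 3.0)]), "2023-08", grid_10)

    def test_empty_month_warns(self, grid_10):
        with pytest.warns(UserWarning, match="no fixes"):
            cg = grid_counts(fixes([(1.0, 1.0)], month="2023-08"), "2023-09", grid_10)
        assert cg.total == 0


class TestMoransI:
    def test_random_field_expectation(self):
        # E[I] = -1/(n-1) under spatial randomness
        rng = np.random.default_rng(42)
        n_cells = 25
        vals = []
        for _ in range(500):
            cg = count_grid(rng.poisson(5.0, (5, 5)))
            try:
                I, _ = morans_i(cg, 1.5)
            except ValueError:
                continue
            vals.append(I)
        expect = -1.0 / (n_cells - 1)
        assert np.mean(vals) == pytest.approx(expect, abs=0.01)

    def test_two_block_field_positive(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:, :2] = 10
        cg = count_grid(counts)
        I, z = morans_i(cg, 1.0)
        assert I > 0
        assert I == pytest.approx(brute_force_morans_i(counts, 1.0))

    def test_checkerboard_negative(self):
        counts = np.indices((4, 4)).sum(axis=0) % 2 * 10
        cg = count_grid(counts)
        I, _ = morans_i(cg, 1.0)  # rook-distance band
        assert I < 0
        assert I == pytest.approx(brute_force_morans_i(counts, 1.0))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(count_grid(np.full((3, 3), 4)), 1.0)


class TestIsaThreshold:
    def test_known_correlation_length(self):
        # blur white noise with a ~3 km Gaussian kernel; the Moran z-score
        # scan should peak near the correlation scale
        rng = np.random.default_rng(7)
        field = ndimage.gaussian_filter(rng.normal(size=(30, 30)), sigma=1.5)
        counts = np.round((field - field.min()) * 20).astype(int)
        cg = count_grid(counts)
        thr = isa_threshold(cg, start=1.0, step=1.0, n_steps=8)
        assert 2.0 <= thr <= 5.0

    def test_monotone_returns_last_with_warning(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[:3] = 10  # single broad gradient: z keeps rising
        cg = count_grid(counts)
        with pytest.warns(UserWarning, match="monotone"):
            thr = isa_threshold(cg, start=1.0, step=1.0, n_steps=3)
        assert thr == 3.0

    def test_constant_grid_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            isa_threshold(count_grid(np.full((4, 4), 2)), start=1.0, step=1.0)

    def test_ann_default(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = counts[0, 2] = counts[4, 4] = 1
        assert average_nearest_neighbor(count_grid(counts)) > 0


class TestGiStar:
    def test_single_high_cell_formula(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[2, 2] = 10
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.0)
        expected = brute_force_gi_star(counts, 1.0)
        assert np.allclose(gi.z, expected, atol=1e-9)

    def test_brute_force_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            counts = rng.poisson(2.0, (10, 10))
            thr = rng.uniform(1.0, 3.0)
            gi = getis_ord_gi_star(count_grid(counts), threshold=thr)
            assert np.allclose(gi.z, brute_force_gi_star(counts, thr), atol=1e-9)

    def test_min_neighbor_expansion(self):
        # with threshold 1.0, corner cells have only 2 in-range neighbors,
        # so their band must expand to the 8 nearest cells
        counts = np.arange(25).reshape(5, 5)
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.0)
        z_corner = gi.z[0, 0]
        # brute-force corner: 8 nearest neighbors + self
        expected = brute_force_gi_star(counts, 1.0)[0, 0]
        assert z_corner == pytest.approx(expected, abs=1e-12)

    def test_hot_cluster_detected(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(1.0, (12, 12))
        counts[4:7, 4:7] += 30
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.5)
        hot = classify_hotspots(gi, 0.01)
        assert (5, 5) in hot.cells
        assert gi.z[5, 5] == gi.z.max()

    def test_constant_field_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            getis_ord_gi_star(count_grid(np.full((4, 4), 3)), 1.0)

    def test_p_two_sided(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[2, 2] = 10
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.0)
        assert np.allclose(gi.p, 2 * norm.sf(np.abs(gi.z)), atol=1e-12)


class TestClassifyAndOverlap:
    def test_alpha_nesting(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(2.0, (10, 10))
        counts[2:4, 2:4] += 12
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.5)
        h01 = classify_hotspots(gi, 0.01)
        h05 = classify_hotspots(gi, 0.05)
        assert h01.cells <= h05.cells

    def test_brute_force_threshold_pass(self):
        rng = np.random.default_rng(14)
        counts = rng.poisson(2.0, (8, 8))
        counts[5:7, 1:3] += 10
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.5)
        hot = classify_hotspots(gi, 0.05)
        manual = {
            (r, c)
            for r in range(8)
            for c in range(8)
            if gi.z[r, c] > 0 and gi.p[r, c] < 0.05
        }
        assert hot.cells == frozenset(manual)

    def test_printed_overlaps(self):
        g = GridSpec((0.0, 0.0), 20, 20, 1.0)
        cells = [(r, c) for r in range(20) for c in range(20)]
        a = HotspotSet("m1", 0.05, frozenset(cells[:60]), g)
        b = HotspotSet("m2", 0.05, frozenset(cells[28:86]), g)
        n, pct = hotspot_overlap(a, b)
        assert (len(a), len(b), n) == (60, 58, 32)
        assert round(pct, 1) == 37.2

        a = HotspotSet("m3", 0.05, frozenset(cells[:100]), g)
        b = HotspotSet("m4", 0.05, frozenset(cells[61:142]), g)
        n, pct = hotspot_overlap(a, b)
        assert (len(a), len(b), n) == (100, 81, 39)
        assert round(pct, 1) == 27.5

    def test_identical_sets_full_overlap(self):
        g = GridSpec((0.0, 0.0), 5, 5, 1.0)
        a = HotspotSet("m", 0.05, frozenset({(1, 1), (2, 2)}), g)
        _, pct = hotspot_overlap(a, a)
        assert pct == 100.0

    def test_both_empty_undefined(self):
        g = GridSpec((0.0, 0.0), 5, 5, 1.0)
        a = HotspotSet("m1", 0.05, frozenset(), g)
        b = HotspotSet("m2", 0.05, frozenset(), g)
        with pytest.warns(UserWarning, match="undefined"):
            n, pct = hotspot_overlap(a, b)
        assert n == 0 and np.isnan(pct)

    def test_symmetry(self):
        g = GridSpec((0.0, 0.0), 5, 5, 1.0)
        a = HotspotSet("m1", 0.05, frozenset({(0, 0), (1, 1)}), g)
        b = HotspotSet("m2", 0.05, frozenset({(1, 1), (2, 2), (3, 3)}), g)
        assert hotspot_overlap(a, b) == hotspot_overlap(b, a)

    def test_alpha_mismatch_errors(self):
        g = GridSpec((0.0, 0.0), 5, 5, 1.0)
        a = HotspotSet("m1", 0.05, frozenset(), g)
        b = HotspotSet("m2", 0.01, frozenset(), g)
        with pytest.raises(ValueError, match="same alpha"):
            hotspot_overlap(a, b)


class TestExport:
    def test_gi_frame_columns(self):
        rng = np.random.default_rng(15)
        counts = rng.poisson(3.0, (6, 6))
        gi = getis_ord_gi_star(count_grid(counts), threshold=1.5)
        df = gi_to_frame(gi)
        assert {"row", "col", "z", "p", "hot05", "hot01"} <= set(df.columns)
        assert len(df) == 36
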