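"""Filament morphometrics: detection accuracy against generator truth,
edge distances against a brute-force oracle, the strict thick filter,
skeleton branch/junction counts, and orientation distributions."""

import numpy as np
import pytest

from actinquant import filaments, synth
from actinquant.filaments import BinarizeParams

from conftest import angular_diff, random_fibre_specs

NOISELESS = BinarizeParams(sigma=0, method="half_max")


def render_single(f, image_size=256, seed=0):
    ch, truth = synth.generate_micropattern_cell(
        synth.CellSpec(pattern_shape="none", image_size=image_size, fibres=(f,), n_nuclei=0, seed=seed)
    )
    return ch["actin"], truth


class TestDetection:
    def test_single_horizontal_fibre_measured(self):
        img, _ = render_single(synth.FibreSpec(centre=(64, 64), length=50, width=3), image_size=128)
        fs = filaments.detect_filaments(img, binarize=NOISELESS)
        assert fs.count == 1
        r = fs.records[0]
        assert r.length_px == pytest.approx(50, abs=2)
        assert r.width_px == pytest.approx(3, abs=0.5)
        assert abs(r.orientation_deg) <= 2
        assert r.centre[0] == pytest.approx(64, abs=2)
        assert r.centre[1] == pytest.approx(64, abs=2)

    def test_blank_image_empty_set(self):
        assert filaments.detect_filaments(np.zeros((64, 64))).count == 0

    def test_two_parallel_fibres(self):
        fs_spec = (
            synth.FibreSpec(centre=(60, 50), length=60, width=3, orientation=30),
            synth.FibreSpec(centre=(80, 90), length=60, width=3, orientation=30),
        )
        ch, _ = synth.generate_micropattern_cell(
            synth.CellSpec(pattern_shape="none", image_size=160, fibres=fs_spec, n_nuclei=0)
        )
        fs = filaments.detect_filaments(ch["actin"], binarize=NOISELESS)
        assert fs.count == 2
        a, b = (r.orientation_deg for r in fs.records)
        assert angular_diff(a, b) <= 2

    def test_recovery_over_random_fibres(self):
        """Median absolute errors <= 5% length, 15% width, 3 deg over the
        20-200 px / 2-8 px / all-orientation range, with exact counts."""
        rng = np.random.default_rng(2024)
        errs = {"len": [], "wid": [], "ori": []}
        n_count_ok = 0
        specs = random_fibre_specs(rng, 40)
        for i, f in enumerate(specs):
            img, _ = render_single(f, seed=i)
            fs = filaments.detect_filaments(img, binarize=NOISELESS)
            if fs.count == 1:
                n_count_ok += 1
                r = fs.records[0]
                errs["len"].append(abs(r.length_px - f.length) / f.length * 100)
                errs["wid"].append(abs(r.width_px - f.width) / f.width * 100)
                errs["ori"].append(angular_diff(r.orientation_deg, f.orientation))
        assert n_count_ok == len(specs)
        assert np.median(errs["len"]) <= 5.0
        assert np.median(errs["wid"]) <= 15.0
        assert np.median(errs["ori"]) <= 3.0

    def test_units_scale_with_pixel_size(self):
        img, _ = render_single(synth.FibreSpec(centre=(64, 64), length=50, width=4), image_size=128)
        r1 = filaments.detect_filaments(img, pixel_size=1.0, binarize=NOISELESS).records[0]
        r2 = filaments.detect_filaments(img, pixel_size=0.25, binarize=NOISELESS).records[0]
        assert r2.length_um == pytest.approx(0.25 * r1.length_um)
        assert r2.width_um == pytest.approx(0.25 * r1.width_um)


class TestEdgeDistance:
    geom = synth.crossbow_geometry(256)

    def _rec(self, x, y):
        return filaments.FilamentRecord(
            centre=(x, y), length_um=10, width_um=2, orientation_deg=0, trace=np.zeros((1, 2))
        )

    def test_point_on_arc_zero(self):
        pts = self.geom.arc_points(400)
        p = pts[100]
        assert filaments.edge_distance(self._rec(*p), self.geom) == pytest.approx(0, abs=1e-9)

    def test_centre_of_curvature_gives_radius(self):
        d = filaments.edge_distance(self._rec(*self.geom.centre), self.geom)
        assert d == pytest.approx(self.geom.radius)

    def test_matches_bruteforce_sampling(self):
        rng = np.random.default_rng(7)
        pts = self.geom.arc_points(20000)
        for _ in range(50):
            x, y = rng.uniform(0, 255, size=2)
            exact = filaments.edge_distance(self._rec(x, y), self.geom)
            brute = np.hypot(pts[:, 0] - x, pts[:, 1] - y).min()
            assert abs(exact - brute) < 0.5

    def test_missing_geometry_errors(self):
        with pytest.raises(ValueError):
            filaments.edge_distance(self._rec(0, 0), None)


class TestThickFilter:
    def _recs(self, widths):
        return [
            filaments.FilamentRecord(
                centre=(i, i), length_um=10, width_um=w, orientation_deg=0,
                trace=np.zeros((1, 2)), width_px=w,
            )
            for i, w in enumerate(widths)
        ]

    def test_strictly_greater_than_gate(self):
        out = filaments.thick_object_map(self._recs([1, 2, 3]), width_threshold_px=2)
        assert len(out) == 1 and out[0][2] == 3

    def test_empty_and_passthrough(self):
        assert filaments.thick_object_map([]) == []
        assert len(filaments.thick_object_map(self._recs([3, 4, 5]))) == 3


def brute_force_skeleton_counts(skel):
    """Independent junction/branch count by explicit neighbour lookup."""
    pts = {tuple(p) for p in np.argwhere(skel)}
    nb = {
        p: sum(
            (p[0] + dr, p[1] + dc) in pts
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        for p in pts
    }
    junction = {p for p, n in nb.items() if n >= 3}

    def components(nodes):
        seen, comps = set(), 0
        for start in nodes:
            if start in seen:
                continue
            comps += 1
            stack = [start]
            while stack:
                p = stack.pop()
                if p in seen:
                    continue
                seen.add(p)
                stack.extend(
                    q
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (q := (p[0] + dr, p[1] + dc)) in nodes and q not in seen
                )
        return comps

    return components(pts - junction), components(junction)


class TestSkeletonStats:
    def test_straight_line(self):
        m = np.zeros((64, 64), bool)
        m[32, 5:60] = True
        st = filaments.skeleton_stats(m)
        assert (st.n_branches, st.n_junctions) == (1, 0)

    def test_crossing_x(self):
        m = np.zeros((64, 64), bool)
        for i in range(10, 54):
            m[i, i] = True
            m[i, 63 - i] = True
        st = filaments.skeleton_stats(m)
        assert (st.n_branches, st.n_junctions) == (4, 1)

    def test_empty_mask(self):
        st = filaments.skeleton_stats(np.zeros((32, 32), bool))
        assert (st.n_branches, st.n_junctions) == (0, 0)

    def test_matches_neighbour_count_oracle(self):
        from skimage.morphology import skeletonize

        rng = np.random.default_rng(11)
        for _ in range(5):
            m = np.zeros((96, 96), bool)
            for _ in range(4):
                r0, c0 = rng.integers(10, 86, 2)
                ang = rng.uniform(0, np.pi)
                for t in range(-30, 31):
                    r = int(round(r0 + t * np.sin(ang)))
                    c = int(round(c0 + t * np.cos(ang)))
                    if 0 <= r < 96 and 0 <= c < 96:
                        m[r, c] = True
            st = filaments.skeleton_stats(m)
            nb, nj = brute_force_skeleton_counts(skeletonize(m))
            assert (st.n_branches, st.n_junctions) == (nb, nj)


class TestOrientationDistribution:
    def test_horizontal_fibre_modal_bin_near_zero(self):
        img, _ = render_single(synth.FibreSpec(centre=(64, 64), length=60, width=4), image_size=128)
        h = filaments.orientation_distribution(img)
        mode = 0.5 * (h.bin_edges[np.argmax(h.weights)] + h.bin_edges[np.argmax(h.weights) + 1])
        binw = h.bin_edges[1] - h.bin_edges[0]
        assert angular_diff(mode, 0.0) <= binw

    def test_rotation_equivariance(self):
        img45, _ = render_single(
            synth.FibreSpec(centre=(64, 64), length=60, width=4, orientation=45), image_size=128
        )
        h = filaments.orientation_distribution(img45)
        binw = h.bin_edges[1] - h.bin_edges[0]
        mode = 0.5 * (h.bin_edges[np.argmax(h.weights)] + h.bin_edges[np.argmax(h.weights) + 1])
        assert angular_diff(mode, 45.0) <= binw
        assert angular_diff(h.circular_mean_deg, 45.0) <= 3

    def test_ninety_degree_rotation_shifts_histogram(self):
        img, _ = render_single(
            synth.FibreSpec(centre=(64, 64), length=60, width=4, orientation=20), image_size=128
        )
        h0 = filaments.orientation_distribution(img, bins=18)
        h90 = filaments.orientation_distribution(np.rot90(img), bins=18)
        assert angular_diff(h0.circular_mean_deg + 90.0, h90.circular_mean_deg) <= 3

    def test_isotropic_noise_low_coherence(self):
        rng = np.random.default_rng(3)
        h = filaments.orientation_distribution(rng.normal(100, 10, (128, 128)))
        assert h.coherence < 0.1

    def test_constant_image_zero_mass(self):
        import warnings

        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            h = filaments.orientation_distribution(np.full((32, 32), 3.0))
        assert h.weights.sum() == 0
        assert len(w) > 0
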