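"""Reference-cell pipeline: thresholding, nucleus QC, centring,
stack registration and frequency-map aggregation."""

import warnings

import numpy as np
import pytest

from actinquant import micropattern as mp
from actinquant import synth


@pytest.fixture
def bimodal():
    img = np.full((64, 64), 10.0)
    img[20:40, 20:40] = 200.0
    return img


class TestPreprocess:
    @pytest.mark.parametrize("method", ["huang_dark", "median", "max_entropy"])
    def test_bimodal_mask_is_exact(self, bimodal, method):
        _, mask = mp.preprocess(bimodal, gaussian_sigma=0, threshold_method=method)
        np.testing.assert_array_equal(mask, bimodal > 10)

    def test_constant_image_warns_empty(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            _, mask = mp.preprocess(np.full((32, 32), 5.0), gaussian_sigma=1)
        assert not mask.any()
        assert any("constant" in str(x.message) for x in w)

    def test_sigma_zero_leaves_intensities(self, bimodal):
        filtered, _ = mp.preprocess(bimodal, gaussian_sigma=0)
        np.testing.assert_array_equal(filtered, bimodal)

    def test_mask_covers_true_objects(self, single_fibre_cell):
        channels, truth, _ = single_fibre_cell
        _, mask = mp.preprocess(channels["actin"], gaussian_sigma=1)
        true = truth.masks["fibre_0"]
        assert (mask & true).sum() / true.sum() >= 0.99


class TestQC:
    def test_two_nuclei_excluded(self):
        ch, _ = synth.generate_micropattern_cell(synth.CellSpec(image_size=192, n_nuclei=2, seed=5))
        assert mp.qc_cell(ch["dapi"]) == mp.QC_MULTI

    def test_one_nucleus_passes(self):
        ch, _ = synth.generate_micropattern_cell(synth.CellSpec(image_size=192, n_nuclei=1, seed=6))
        assert mp.qc_cell(ch["dapi"]) == mp.QC_PASSED

    def test_zero_nuclei_offpattern(self):
        ch, _ = synth.generate_micropattern_cell(
            synth.CellSpec(image_size=192, n_nuclei=0, seed=7, pattern_intensity=0.0)
        )
        assert mp.qc_cell(ch["dapi"]) == mp.QC_OFFPATTERN

    def test_condensed_nucleus_flagged_mitotic(self):
        ch, _ = synth.generate_micropattern_cell(
            synth.CellSpec(image_size=192, n_nuclei=1, seed=8, nucleus_radius=8.0)
        )
        # cohort-median nucleus area corresponding to the usual radius 14
        params = mp.NucleusQCParams(reference_area=np.pi * 14.0**2)
        assert mp.qc_cell(ch["dapi"], params) == mp.QC_MITOTIC

    def test_no_false_accept_of_multinucleates(self):
        """No cell with >= 2 true nuclei may ever pass QC (noiseless)."""
        for seed in range(10):
            ch, _ = synth.generate_micropattern_cell(
                synth.CellSpec(image_size=192, n_nuclei=2 + seed % 3, seed=seed)
            )
            assert mp.qc_cell(ch["dapi"]) != mp.QC_PASSED


class TestCentring:
    @pytest.fixture
    def cell_and_template(self):
        spec = synth.CellSpec(
            image_size=192,
            n_nuclei=1,
            seed=8,
            fibres=(synth.FibreSpec(centre=(96, 80), length=40, width=3),),
        )
        ch, _ = synth.generate_micropattern_cell(spec)
        return ch, synth.crossbow_mask(192).astype(float)

    def test_known_shift_recovered(self, cell_and_template):
        ch, template = cell_and_template
        shifted = {k: np.roll(np.roll(v, -4, axis=0), 7, axis=1) for k, v in ch.items()}
        cen = mp.center_on_pattern(mp.CellImageSet(channels=shifted), template)
        assert abs(cen.centring_offset[0] - (-7)) <= 1
        assert abs(cen.centring_offset[1] - 4) <= 1
        assert cen.qc_status == mp.QC_PASSED

    def test_centring_idempotent(self, cell_and_template):
        ch, template = cell_and_template
        once = mp.center_on_pattern(mp.CellImageSet(channels=ch), template)
        twice = mp.center_on_pattern(once, template)
        d = np.subtract(twice.centring_offset, once.centring_offset)
        assert np.abs(d).max() <= 1

    def test_blank_image_offpattern(self, cell_and_template):
        _, template = cell_and_template
        blank = mp.CellImageSet(channels={"a": np.zeros((192, 192))})
        assert mp.center_on_pattern(blank, template).qc_status == mp.QC_OFFPATTERN


class TestRegistration:
    def test_single_image(self):
        img = np.random.default_rng(0).random((64, 64))
        aligned, shifts = mp.register_stack([img])
        assert shifts == [(0, 0)]
        np.testing.assert_array_equal(aligned[0], img)

    def test_integer_shifts_recovered_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.random((96, 96))
        stack = [base, np.roll(np.roll(base, 3, axis=0), -5, axis=1), np.roll(base, 8, axis=1)]
        _, shifts = mp.register_stack(stack)
        assert shifts == [(0, 0), (5, -3), (-8, 0)]

    def test_shift_under_noise(self):
        rng = np.random.default_rng(2)
        ch, _ = synth.generate_micropattern_cell(synth.CellSpec(image_size=128, n_nuclei=1, seed=3))
        base = ch["actin"]
        noisy = np.roll(base, 4, axis=1) + rng.normal(0, base.std() / 10, base.shape)
        _, shifts = mp.register_stack([base, noisy])
        assert abs(shifts[1][0] - (-4)) <= 1 and abs(shifts[1][1]) <= 1


class TestFrequencyMap:
    def test_identical_inputs_equal_rescaled_input(self):
        ch, _ = synth.generate_micropattern_cell(synth.CellSpec(image_size=128, n_nuclei=1, seed=4))
        img = ch["actin"]
        cells = [mp.CellImageSet(channels={"actin": img}) for _ in range(7)]
        fm = mp.build_frequency_map(cells, "actin")
        expect = np.rint((img - img.min()) / (img.max() - img.min()) * 255).astype(np.uint8)
        np.testing.assert_array_equal(fm.map, expect)
        assert fm.n_cells == 7

    def test_flip_symmetry(self):
        img = np.random.default_rng(5).random((64, 64))
        cells = [
            mp.CellImageSet(channels={"a": img}),
            mp.CellImageSet(channels={"a": img[:, ::-1]}),
        ]
        fm = mp.build_frequency_map(cells, "a")
        np.testing.assert_array_equal(fm.map, fm.map[:, ::-1])

    def test_shared_locus_dominates(self):
        """Cells sharing one fibre locus + random distractors: the map
        maximum falls inside the shared locus."""
        shared = synth.FibreSpec(centre=(96, 96), length=60, width=4, orientation=20)
        rng = np.random.default_rng(6)
        cells = []
        for seed in range(20):
            d = synth.FibreSpec(
                centre=(float(rng.uniform(50, 140)), float(rng.uniform(50, 140))),
                length=30,
                width=3,
                orientation=float(rng.uniform(-90, 90)),
                peak_intensity=150.0,
            )
            ch, _ = synth.generate_micropattern_cell(
                synth.CellSpec(pattern_shape="none", image_size=192, fibres=(shared, d), n_nuclei=0, seed=seed)
            )
            cells.append(mp.CellImageSet(channels={"actin": ch["actin"]}))
        fm = mp.build_frequency_map(cells, "actin")
        _, truth = synth.generate_micropattern_cell(
            synth.CellSpec(pattern_shape="none", image_size=192, fibres=(shared,), n_nuclei=0)
        )
        r, c = np.unravel_index(np.argmax(fm.map), fm.map.shape)
        assert truth.masks["fibre_0"][r, c]

    def test_rejects_unqc_cells_and_empty(self):
        img = np.ones((16, 16))
        bad = mp.CellImageSet(channels={"a": img}, qc_status=mp.QC_MULTI)
        with pytest.raises(ValueError):
            mp.build_frequency_map([bad], "a")
        with pytest.raises(ValueError):
            mp.build_frequency_map([], "a")

    def test_pipeline_deterministic_and_translation_commutes(self):
        """Fixed inputs give a bit-identical map, and globally translating
        every input leaves the centred map unchanged."""
        template = synth.crossbow_mask(160).astype(float)
        base = [
            synth.generate_micropattern_cell(synth.CellSpec(image_size=160, n_nuclei=1, seed=s))[0]
            for s in range(4)
        ]

        def run(shift):
            cells = []
            for ch in base:
                moved = {k: np.roll(np.roll(v, shift[0], axis=0), shift[1], axis=1) for k, v in ch.items()}
                cells.append(mp.center_on_pattern(mp.CellImageSet(channels=moved), template))
            return mp.build_frequency_map(cells, "actin").map

        m0 = run((0, 0))
        np.testing.assert_array_equal(m0, run((0, 0)))  # determinism
        np.testing.assert_array_equal(m0, run((6, -9)))  # translation commutes
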