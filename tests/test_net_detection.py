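"""NET detection: intact-cell exclusion, truth recovery, ring baseline."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from netquant.plate_io import FieldImage
from netquant.net_detection import (
    NetDetectionParams,
    detect_nets,
    perinuclear_ring_signal,
    well_net_signal,
)
from netquant.nucleus_segmentation import segment_nuclei
from netquant.synth_fields import ConditionParams, generate_field, preset


def _flat_field(shape=(256, 256), bg=100.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    nuc = np.clip(rng.normal(bg, noise, shape), 0, None)
    dna = np.clip(rng.normal(bg, noise, shape), 0, None)
    return nuc, dna


class TestDetectNets:
    def test_missing_nucleus_raster_is_an_error(self, pma240_field):
        field, _ = pma240_field
        with pytest.raises(ValueError, match="exclusion is mandatory"):
            detect_nets(field, None)

    def test_intact_nuclei_only_yields_zero_signal(self):
        field, _ = generate_field(preset("unstim_0", n_cells=40, seed=3), shape=(512, 512))
        labels, _ = segment_nuclei(field)
        regions, mask = detect_nets(field, labels)
        assert regions == []
        assert not mask.any()
        assert well_net_signal([regions])["net_signal"] == 0.0

    def test_isolated_filament_recovers_truth_signal(self):
        params = ConditionParams(n_cells=0, net_filament_count=1, seed=9)
        field, truth = generate_field(params, shape=(640, 640))
        regions, _ = detect_nets(field, np.zeros(field.shape, dtype=np.int32))
        assert len(regions) == 1
        measured = regions[0].integrated_intensity
        assert measured == pytest.approx(truth.total_filament_signal, rel=0.15)

    def test_half_excluded_filament_equals_mask_arithmetic_oracle(self):
        """Brute-force set difference: detected pixels == stripe \\ dilated nucleus."""
        nuc, dna = _flat_field(noise=0.0)  # deterministic oracle fixture
        yy, xx = np.mgrid[0:256, 0:256]
        nucleus = (yy - 128) ** 2 + (xx - 100) ** 2 <= 15 ** 2
        nuc[nucleus] = 1200.0
        stripe = (np.abs(yy - 128) <= 2) & (xx >= 60) & (xx <= 240)
        dna[stripe] = 600.0
        field = FieldImage("p", "A01", 0, nuc, dna)
        labels = nucleus.astype(np.int32)
        params = NetDetectionParams(filament_filter=False, min_net_area=10)
        regions, mask = detect_nets(field, labels, params)
        expected = stripe & ~ndimage.binary_dilation(nucleus, structure=disk(10))
        np.testing.assert_array_equal(mask, expected)

    def test_net_mask_never_intersects_exclusion_zone(self, pma240_field):
        field, _ = pma240_field
        labels, _ = segment_nuclei(field)
        params = NetDetectionParams()
        _, mask = detect_nets(field, labels, params)
        exclusion = ndimage.binary_dilation(
            labels > 0, structure=disk(params.exclusion_dilation_px))
        assert not (mask & exclusion).any()

    def test_filament_filter_drops_compact_blob_but_rescues_cloud(self):
        nuc, dna = _flat_field()
        yy, xx = np.mgrid[0:256, 0:256]
        dna[(yy - 60) ** 2 + (xx - 60) ** 2 <= 6 ** 2] = 600.0     # compact blob ~113 px
        dna[(yy - 180) ** 2 + (xx - 180) ** 2 <= 17 ** 2] = 600.0  # cloud ~900 px
        field = FieldImage("p", "A01", 0, nuc, dna)
        params = NetDetectionParams(min_net_area=50)
        regions, _ = detect_nets(field, np.zeros_like(yy, dtype=np.int32), params)
        areas = sorted(r.area for r in regions)
        assert len(regions) == 1 and areas[0] > 800  # only the cloud survives


class TestWellSignal:
    def test_signal_is_additive_over_fields_and_regions(self):
        params = ConditionParams(n_cells=0, net_filament_count=2, seed=21)
        f1, _ = generate_field(params, shape=(512, 512))
        f2, _ = generate_field(ConditionParams(n_cells=0, net_filament_count=1, seed=22),
                               shape=(512, 512))
        zeros = np.zeros(f1.shape, dtype=np.int32)
        r1, _ = detect_nets(f1, zeros)
        r2, _ = detect_nets(f2, zeros)
        both = well_net_signal([r1, r2])
        assert both["net_signal"] == pytest.approx(
            well_net_signal([r1])["net_signal"] + well_net_signal([r2])["net_signal"])
        assert both["n_regions"] == len(r1) + len(r2)

    def test_signal_rises_from_1h_to_3h(self):
        """The fixture encodes filament load peaking at 3 h; the detector must see it."""
        wins = 0
        for seed in range(5):
            sigs = {}
            for name in ("pma_60", "pma_180"):
                field, _ = generate_field(preset(name, n_cells=60, seed=800 + seed),
                                          shape=(640, 640))
                labels, _ = segment_nuclei(field)
                regions, _ = detect_nets(field, labels)
                sigs[name] = well_net_signal([regions])["net_signal"]
            wins += sigs["pma_180"] > sigs["pma_60"]
        assert wins >= 4

    def test_separation_grows_with_cell_density(self):
        """More cells (and proportional filaments) separate PMA from unstim better."""
        diffs = []
        for n in (10, 100):
            pma = unstim = 0.0
            for seed in range(2):
                fp, _ = generate_field(
                    ConditionParams(n_cells=n, decondensed_fraction=0.1,
                                    net_filament_count=max(n // 10, 1), seed=900 + seed),
                    shape=(640, 640))
                fu, _ = generate_field(
                    ConditionParams(n_cells=n, seed=950 + seed), shape=(640, 640))
                for f, acc in ((fp, "p"), (fu, "u")):
                    labels, _ = segment_nuclei(f)
                    regions, _ = detect_nets(f, labels)
                    val = well_net_signal([regions])["net_signal"]
                    if acc == "p":
                        pma += val
                    else:
                        unstim += val
            diffs.append(pma - unstim)
        assert diffs[1] > diffs[0]


class TestPerinuclearRing:
    def _nucleus_field(self, halo=0.0):
        nuc, dna = _flat_field(noise=3.0, seed=5)
        yy, xx = np.mgrid[0:256, 0:256]
        nucleus = (yy - 128) ** 2 + (xx - 128) ** 2 <= 15 ** 2
        nuc[nucleus] = 1200.0
        dna[nucleus] = 1200.0
        if halo:
            ring = ((yy - 128) ** 2 + (xx - 128) ** 2 <= 21 ** 2) & ~nucleus
            dna[ring] += halo
        return FieldImage("p", "A01", 0, nuc, dna), nucleus.astype(np.int32)

    def test_isolated_nucleus_ring_reads_background(self):
        field, labels = self._nucleus_field()
        out = perinuclear_ring_signal(field, labels, ring_width=5)
        assert out[1] == pytest.approx(100.0, abs=5.0)

    def test_halo_amplitude_recovered(self):
        field, labels = self._nucleus_field(halo=400.0)
        out = perinuclear_ring_signal(field, labels, ring_width=5)
        assert out[1] == pytest.approx(500.0, rel=0.10)

    def test_zero_ring_width_gives_null(self):
        field, labels = self._nucleus_field()
        out = perinuclear_ring_signal(field, labels, ring_width=0)
        assert out == {1: None}

    def test_fully_occluded_ring_gives_null(self):
        nuc, dna = _flat_field(noise=3.0, seed=6)
        yy, xx = np.mgrid[0:256, 0:256]
        inner = (yy - 128) ** 2 + (xx - 128) ** 2 <= 10 ** 2
        shell = ((yy - 128) ** 2 + (xx - 128) ** 2 <= 25 ** 2) & ~inner
        labels = np.zeros((256, 256), dtype=np.int32)
        labels[inner] = 1
        labels[shell] = 2
        field = FieldImage("p", "A01", 0, nuc, dna)
        out = perinuclear_ring_signal(field, labels, ring_width=5)
        assert out[1] is None  # ring of nucleus 1 lies entirely inside nucleus 2
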