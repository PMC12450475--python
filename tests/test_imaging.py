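import numpy as np
import pandas as pd
import pytest

from txstress import (
    FieldImage,
    HUMAN_FIBROBLAST,
    MOUSE_HEPATOCYTE,
    measure_nuclei,
    moments_threshold,
    normalize_cohort,
    quantify_field,
    segment_nuclei,
    segment_nucleoli,
    summarize_field,
)
from txstress.synth import FieldConfig, make_fields


def disk_field(centers_radii, shape=(200, 200), pixel_size=0.5, eu_level=50.0,
               dna_level=1.0, background=0.0):
    """Bright DNA disks on a dark background, uniform EU inside nuclei."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    eu = np.full(shape, background)
    dna = np.zeros(shape)
    for y, x, r in centers_radii:
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r**2
        dna[disk] = dna_level
        eu[disk] = eu_level
    return FieldImage(eu, dna, pixel_size)


class TestSegmentNuclei:
    def test_counts_separated_disks(self):
        centers = [(40, 40, 10), (40, 150, 12), (150, 40, 8), (150, 150, 11),
                   (100, 100, 9)]
        labels = segment_nuclei(disk_field(centers))
        assert labels.max() == 5

    def test_touching_disks_may_merge(self):
        labels = segment_nuclei(disk_field([(100, 95, 10), (100, 110, 10)]))
        assert labels.max() >= 1

    def test_disk_area_close_to_analytic(self):
        r = 20
        labels = segment_nuclei(disk_field([(100, 100, r)]))
        area_px = (labels == 1).sum()
        assert area_px == pytest.approx(np.pi * r**2, rel=0.05)

    def test_constant_channel_rejected(self):
        field = FieldImage(np.ones((50, 50)), np.ones((50, 50)), 0.5)
        with pytest.raises(ValueError, match="constant"):
            segment_nuclei(field)


class TestMomentsThreshold:
    def test_separates_bimodal_values(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(10, 1, 5_000), rng.normal(100, 5, 1_000)]
        )
        thr = moments_threshold(values)
        assert 15 < thr < 90

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            moments_threshold(np.array([]))


class TestSegmentNucleoli:
    def make_nucleolus_field(self, nucleolus_fraction=0.10):
        yy, xx = np.mgrid[0:200, 0:200]
        dna = np.zeros((200, 200))
        eu = np.full((200, 200), 2.0)
        r = 40
        disk = (yy - 100) ** 2 + (xx - 100) ** 2 <= r**2
        dna[disk] = 1.0
        eu[disk] = 50.0
        nr = r * np.sqrt(nucleolus_fraction)
        ndisk = (yy - 100) ** 2 + (xx - 100) ** 2 <= nr**2
        eu[ndisk] = 180.0  # EU-bright nucleolus (rRNA transcription)
        dna[ndisk] = 0.5
        return FieldImage(eu, dna, 0.3), disk, ndisk

    def test_interior_blob_captured(self):
        field, disk, ndisk = self.make_nucleolus_field()
        labels = segment_nuclei(field)
        nucleoli = segment_nucleoli(field, labels)
        overlap = (nucleoli & ndisk).sum() / ndisk.sum()
        assert overlap > 0.8

    def test_uniform_interior_gives_small_mask(self):
        field = disk_field([(100, 100, 40)], pixel_size=0.3)
        labels = segment_nuclei(field)
        nucleoli = segment_nucleoli(field, labels)
        assert nucleoli.sum() < 0.05 * (labels > 0).sum()

    def test_known_fraction_recovered(self):
        field, disk, _ = self.make_nucleolus_field(nucleolus_fraction=0.10)
        labels = segment_nuclei(field)
        nucleoli = segment_nucleoli(field, labels)
        fraction = nucleoli.sum() / (labels > 0).sum()
        assert fraction == pytest.approx(0.10, abs=0.03)

    def test_empty_nuclei_give_empty_mask(self):
        field = disk_field([(100, 100, 20)])
        nucleoli = segment_nucleoli(field, np.zeros((200, 200), dtype=int))
        assert not nucleoli.any()


class TestMeasureNuclei:
    def field_with_area(self, area_um2, pixel_size=0.3, eu=50.0):
        r_px = np.sqrt(area_um2 / np.pi) / pixel_size
        field = disk_field([(100, 100, r_px)], pixel_size=pixel_size,
                           eu_level=eu)
        labels = segment_nuclei(field)
        return field, labels

    @pytest.mark.parametrize(
        "area,flag",
        [(20.0, "too_small"), (80.0, "too_large_polyploid")],
    )
    def test_mouse_size_filters(self, area, flag):
        field, labels = self.field_with_area(area)
        table = measure_nuclei(field, labels, np.zeros_like(labels, bool),
                               MOUSE_HEPATOCYTE)
        assert bool(table[flag].iloc[0])
        assert not bool(table["passed"].iloc[0])

    def test_human_profile_accepts_larger_nuclei(self):
        field, labels = self.field_with_area(150.0)
        table = measure_nuclei(field, labels, np.zeros_like(labels, bool),
                               HUMAN_FIBROBLAST)
        assert bool(table["passed"].iloc[0])

    def test_disk_circularity_near_one(self):
        field, labels = self.field_with_area(50.0)
        table = measure_nuclei(field, labels, np.zeros_like(labels, bool),
                               MOUSE_HEPATOCYTE)
        assert table["circularity"].iloc[0] == pytest.approx(1.0, abs=0.1)
        assert table["circularity"].iloc[0] <= 1.0

    def test_elongated_shape_flagged_low_circularity(self):
        dna = np.zeros((120, 120))
        dna[55:65, 10:110] = 1.0  # 10x100 px bar
        eu = np.where(dna > 0, 50.0, 0.0)
        field = FieldImage(eu, dna, 0.5)
        labels = segment_nuclei(field)
        table = measure_nuclei(field, labels, np.zeros_like(labels, bool),
                               MOUSE_HEPATOCYTE)
        assert bool(table["low_circularity"].iloc[0])

    def test_nucleoplasm_excludes_nucleoli(self):
        field, labels = self.field_with_area(50.0, eu=50.0)
        nucleoli = np.zeros_like(labels, dtype=bool)
        inner = labels > 0
        # mark a quadrant of the nucleus as nucleolus with different EU
        ys, xs = np.nonzero(inner)
        quadrant = (ys < 100) & (xs < 100)
        nucleoli[ys[quadrant], xs[quadrant]] = True
        field.eu[nucleoli] = 500.0
        table = measure_nuclei(field, labels, nucleoli, MOUSE_HEPATOCYTE)
        assert table["nucleoplasm_mean_eu"].iloc[0] == pytest.approx(50.0)

    def test_flag_order_independence(self):
        """Flags are computed independently, so their conjunction does not
        depend on evaluation order: a nucleus violating two rules carries
        both flags."""
        field, labels = self.field_with_area(80.0)
        dna = np.zeros((120, 120))
        dna[55:65, 10:110] = 1.0
        eu = np.where(dna > 0, 50.0, 0.0)
        bar_field = FieldImage(eu, dna, 1.0)
        bar_labels = segment_nuclei(bar_field)
        table = measure_nuclei(bar_field, bar_labels,
                               np.zeros_like(bar_labels, bool),
                               MOUSE_HEPATOCYTE)
        # 10 x 100 px at 1 um/px = 1000 um^2: oversized AND elongated
        assert bool(table["too_large_polyploid"].iloc[0])
        assert bool(table["low_circularity"].iloc[0])


class TestSummaries:
    def test_field_median(self):
        table = pd.DataFrame(
            {"nucleoplasm_mean_eu": [10.0, 10.0, 10.0], "passed": [True] * 3}
        )
        assert summarize_field(table) == 10.0

    def test_no_passing_nuclei_rejected(self):
        table = pd.DataFrame({"nucleoplasm_mean_eu": [10.0], "passed": [False]})
        with pytest.raises(ValueError, match="no nuclei"):
            summarize_field(table)

    def test_reference_normalizes_to_100(self):
        out = normalize_cohort({"ref": 12.0, "sample": 12.0}, reference="ref")
        assert out["sample"] == pytest.approx(100.0)

    def test_intensity_scaling_invariance(self):
        """Scaling the EU channel scales summaries linearly and leaves
        normalized values unchanged."""
        fields, _ = make_fields(FieldConfig(n_nuclei=8), n_fields=1, seed=9)
        field = fields[0]
        _, summary = quantify_field(field)
        scaled = FieldImage(field.eu * 3.0, field.dna, field.pixel_size_um)
        _, scaled_summary = quantify_field(scaled)
        assert scaled_summary == pytest.approx(3.0 * summary, rel=1e-6)
        norm = normalize_cohort({"a": summary, "b": summary}, reference="a")
        norm_scaled = normalize_cohort(
            {"a": scaled_summary, "b": scaled_summary}, reference="a"
        )
        assert norm["b"] == pytest.approx(norm_scaled["b"])
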