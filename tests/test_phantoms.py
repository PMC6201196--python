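"""Synthetic-data module: spec validation, determinism, shape constructions."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats as sp_stats

from nucleomorph import (
    FieldTooCrowdedError,
    NucleusMask,
    PhantomSpec,
    generate_field,
    generate_shape_mask,
    measure_major_axis,
    measure_perimeter,
    peripheral_ratio,
)
from nucleomorph.morphometry import contour_ratio
from nucleomorph.phantoms import _sample_labels, canonical_mix

from .conftest import PX, as_mask, ramanujan_perimeter


class TestPhantomSpec:
    def test_shape_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PhantomSpec(shape_mix={frozenset(): 0.5, "blebs": 0.4})

    def test_elongated_length_must_exceed_threshold(self):
        with pytest.raises(ValueError, match="elongated"):
            PhantomSpec(shape_mix={"elongated": 1.0}, elongated_length_um=24.0)

    def test_normal_major_axis_capped(self):
        with pytest.raises(ValueError, match="25"):
            PhantomSpec(base_axes_um=(26.0, 10.0))

    def test_negative_rim_ratio_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(rim_ratio=-0.5)

    def test_json_round_trip(self):
        spec = PhantomSpec(shape_mix={frozenset(): 0.5, "blebs": 0.5}, seed=3)
        again = PhantomSpec.from_json(spec.to_json())
        assert canonical_mix(again.shape_mix) == canonical_mix(spec.shape_mix)
        assert again.seed == spec.seed
        assert again.field_size == spec.field_size


class TestGenerateShapeMask:
    def test_normal_ellipse_contour_ratio(self):
        # closed-form (Ramanujan) oracle for a 15 x 12 um ellipse: CR ~ 0.99
        mask = generate_shape_mask(frozenset(), (15.0, 12.0), PX)
        nm = as_mask(mask)
        a, b = 7.5, 6.0
        oracle = 4 * math.pi * (math.pi * a * b) / ramanujan_perimeter(a, b) ** 2
        assert oracle > 0.98
        cr = contour_ratio(nm.area_um2, measure_perimeter(nm))
        assert cr == pytest.approx(oracle, abs=0.02)

    def test_elongated_major_axis_forced(self):
        mask = generate_shape_mask({"elongated"}, (15.0, 10.0), PX, elongated_length_um=26.0)
        nm = as_mask(mask)
        assert measure_major_axis(nm) == pytest.approx(26.0, abs=PX)

    def test_bleb_lowers_solidity(self):
        from skimage.morphology import convex_hull_image

        def solidity(m):
            return m.sum() / convex_hull_image(m).sum()

        plain = generate_shape_mask(frozenset(), (15.0, 10.0), PX)
        blebbed = generate_shape_mask({"blebs"}, (15.0, 10.0), PX)
        assert solidity(blebbed) < solidity(plain)

    @pytest.mark.parametrize(
        "labels",
        [frozenset(), {"jellybean"}, {"severely_deformed"}, {"blebs"},
         {"strings"}, {"elongated"}],
        ids=lambda s: "+".join(sorted(s)) or "normal",
    )
    def test_masks_are_4connected_and_hole_free(self, labels):
        mask = generate_shape_mask(labels, (15.0, 10.0), PX)
        structure = ndi.generate_binary_structure(2, 1)
        _, n = ndi.label(mask, structure=structure)
        assert n == 1
        assert ndi.binary_fill_holes(mask).sum() == mask.sum()

    def test_string_protrusion_geometry(self):
        # thin protrusion: width <= 1 um, length >= 3 um beyond the ellipse
        plain = generate_shape_mask(frozenset(), (15.0, 10.0), PX)
        stringy = generate_shape_mask({"strings"}, (15.0, 10.0), PX)
        extra_cols = stringy.shape[1] - plain.shape[1]
        assert extra_cols * PX >= 3.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_shape_mask({"wiggly"}, (15.0, 10.0), PX)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            generate_shape_mask(frozenset(), (15.0, 10.0), 0.0)
        with pytest.raises(ValueError):
            generate_shape_mask(frozenset(), (-1.0, 10.0), PX)


class TestGenerateField:
    def test_identity_configuration(self):
        # all-normal mix, rim_ratio 1, noise off -> empty labels, uniform lamin
        spec = PhantomSpec(n_nuclei=5, field_size=(512, 512), rim_ratio=1.0, seed=1)
        field, truth = generate_field(spec)
        assert truth.table["is_normal"].all()
        assert (truth.table["labels"] == "").all()
        lamin = field.channels["lamin_ac"]
        for nid in truth.table["nucleus_id"]:
            vals = lamin[truth.mask_of(nid)]
            assert np.allclose(vals, vals[0])

    def test_forced_elongated_truth(self):
        spec = PhantomSpec(
            n_nuclei=4, field_size=(512, 512),
            shape_mix={"elongated": 1.0}, elongated_length_um=30.0, seed=5,
        )
        _, truth = generate_field(spec)
        assert (truth.table["major_axis_um"] == 30.0).all()
        assert (truth.table["labels"] == "elongated").all()

    def test_label_draw_matches_independent_replay(self):
        # replay the seeded multinomial with a second implementation
        spec = PhantomSpec(
            n_nuclei=100, field_size=(512, 512),
            shape_mix={frozenset(): 0.6, "elongated": 0.4}, seed=1,
        )
        drawn = _sample_labels(spec)

        mix = sorted(
            [(frozenset(), 0.6), (frozenset({"elongated"}), 0.4)],
            key=lambda kv: tuple(sorted(kv[0])),
        )
        rng = np.random.default_rng([1, 0x1ABE1])
        expect = rng.choice(2, size=100, p=[p for _, p in mix])
        assert [mix[i][0] for i in expect] == drawn

    def test_determinism_bit_identical(self):
        spec = PhantomSpec(
            n_nuclei=10, field_size=(512, 512), seed=9,
            shape_mix={frozenset(): 0.7, "blebs": 0.3},
            foci_fraction=0.5, myotube_fraction=0.3,
            noise_gaussian_sd=0.02, noise_poisson_gain=1.0,
        )
        f1, t1 = generate_field(spec)
        f2, t2 = generate_field(spec)
        for role in f1.channels:
            np.testing.assert_array_equal(f1.channels[role], f2.channels[role])
        assert t1.table.equals(t2.table)
        np.testing.assert_array_equal(t1.label_image, t2.label_image)

    def test_label_frequencies_converge(self):
        # chi-square GOF on the seeded sampler at n = 10,000
        spec = PhantomSpec(
            n_nuclei=10_000, field_size=(512, 512),
            shape_mix={frozenset(): 0.5, "blebs": 0.3, "strings": 0.2}, seed=123,
        )
        drawn = _sample_labels(spec)
        mix = canonical_mix(spec.shape_mix)
        counts = [sum(1 for d in drawn if d == k) for k, _ in mix]
        expected = [p * len(drawn) for _, p in mix]
        _, p = sp_stats.chisquare(counts, expected)
        assert p > 0.01

    def test_measured_rim_ratio_matches_spec(self):
        # couples the generator to the localization module as its oracle
        spec = PhantomSpec(n_nuclei=5, field_size=(512, 512), rim_ratio=2.0, seed=4)
        field, truth = generate_field(spec)
        lamin = field.channels["lamin_ac"]
        for nid in truth.table["nucleus_id"]:
            full = truth.mask_of(nid)
            nm = _crop(full)
            assert peripheral_ratio(lamin, nm, 1.0) == pytest.approx(2.0, rel=0.05)

    def test_too_crowded_raises(self):
        spec = PhantomSpec(n_nuclei=60, field_size=(256, 256), seed=0)
        with pytest.raises(FieldTooCrowdedError):
            generate_field(spec)

    def test_nuclei_clear_of_border(self, normal_field):
        _, field, truth = normal_field
        li = truth.label_image
        assert not li[0, :].any() and not li[-1, :].any()
        assert not li[:, 0].any() and not li[:, -1].any()

    def test_ground_truth_one_record_per_nucleus(self, mixed_field):
        spec, _, truth = mixed_field
        assert len(truth.table) == spec.n_nuclei
        ids = np.unique(truth.label_image)
        assert set(ids) - {0} == set(truth.table["nucleus_id"])


def _crop(full_mask: np.ndarray) -> NucleusMask:
    from nucleomorph.types import crop_from_field

    return crop_from_field(full_mask, 1, PX)


class TestPhantomIO:
    def test_write_phantom_round_trip(self, tmp_path):
        from nucleomorph import read_field
        from nucleomorph.phantoms import write_phantom

        spec = PhantomSpec(n_nuclei=3, field_size=(256, 256), seed=2)
        field, truth = generate_field(spec)
        write_phantom(tmp_path, field, truth, spec)
        assert (tmp_path / "ground_truth.csv").exists()
        assert (tmp_path / "spec.json").exists()
        again = read_field(tmp_path / "field.tif")
        assert again.pixel_size_um == pytest.approx(PX, rel=1e-6)
        np.testing.assert_allclose(
            again.channels["dna"], field.channels["dna"], rtol=1e-6
        )
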