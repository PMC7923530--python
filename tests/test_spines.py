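"""Unit and recovery tests for spine segmentation, metrics, classification,
PSD topology and astrocyte contact."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hippoquant.presets import DENDRITE_PRESETS, scaled_preset
from hippoquant.spines import (ClassRules, LabeledStack, SpineComponent,
                               SpineRecord, SpineTooSmallError, analyze_stack,
                               astro_contact, classify_spine,
                               euler_characteristic, headvol_vs_astro,
                               psd_measure, segment_spines,
                               spine_metrics, summarize_dendrite)
from hippoquant.synthetic import gen_dendrite_stack

ISO = (0.02, 0.02, 0.02)


class TestClassifier:
    @pytest.mark.parametrize("length,neck,head,expected", [
        (1.2, 0.15, 0.55, "mushroom"),    # ratio 3.67 >= 1.5
        (0.5, 0.45, 0.46, "stubby"),      # neck >= half the length
        (2.5, 0.10, 0.11, "filamentous"),  # long and headless
        (1.5, 0.12, 0.15, "thin"),        # ratio 1.25, not stubby
    ])
    def test_rule_table_examples(self, length, neck, head, expected):
        assert classify_spine(length, head, neck) == expected

    @given(st.floats(0.05, 5.0), st.floats(0.02, 2.0), st.floats(0.02, 2.0))
    def test_total_and_deterministic(self, length, head, neck):
        a = classify_spine(length, head, neck)
        b = classify_spine(length, head, neck)
        assert a == b
        assert a in ("thin", "mushroom", "stubby", "filamentous")

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_spine(0.0, 0.5, 0.1)

    def test_rules_configurable(self):
        loose = ClassRules(mushroom_ratio=1.2)
        assert classify_spine(1.5, 0.15, 0.12, loose) == "mushroom"
        assert classify_spine(1.5, 0.15, 0.12) == "thin"


def _cylinder_component(radius_um=0.2, length_um=1.0, spacing=ISO):
    """Digital cylinder along y with its base slab marked."""
    r = int(round(radius_um / spacing[1]))
    n = int(round(length_um / spacing[1]))
    zz, xx = np.mgrid[-r - 1:r + 2, -r - 1:r + 2]
    disc = (zz * spacing[0]) ** 2 + (xx * spacing[2]) ** 2 <= radius_um ** 2
    vox = []
    for y in range(n):
        for dz, dx in np.argwhere(disc):
            vox.append((dz, y, dx))
    vox = np.asarray(vox)
    base = vox[vox[:, 1] == 0]
    return SpineComponent(component_id=0, voxels=vox, base_voxels=base)


class TestSpineMetrics:
    def test_digital_cylinder_volume_and_neck(self):
        r, length = 0.2, 1.0
        comp = _cylinder_component(r, length)
        got_len, vol, head, neck = spine_metrics(comp, ISO)
        assert vol == pytest.approx(math.pi * r * r * length, rel=0.15)
        assert neck == pytest.approx(2 * r, rel=0.15)
        assert got_len == pytest.approx(length, rel=0.15)

    def test_mushroom_head_neck_ratio_recovered(self):
        preset = scaled_preset(
            DENDRITE_PRESETS["myelinated"], density_per_um=0.8,
            class_mixture={"thin": 0.0, "mushroom": 1.0, "stubby": 0.0,
                           "filamentous": 0.0})
        stack, truth = gen_dendrite_stack(preset, 10.0, 2)
        records, _, _ = analyze_stack(stack)
        assert len(records) >= 3
        for rec in records:
            assert rec.head_diam_um / rec.neck_diam_um >= 2.0

    def test_thin_filament_has_no_head(self):
        vox = np.array([(0, y, 0) for y in range(30)])
        comp = SpineComponent(0, voxels=vox, base_voxels=vox[:1])
        _, _, head, neck = spine_metrics(comp, ISO)
        assert head / neck < 1.2

    def test_too_small_component_raises(self):
        vox = np.array([(0, y, 0) for y in range(5)])
        comp = SpineComponent(0, voxels=vox, base_voxels=vox[:1])
        with pytest.raises(SpineTooSmallError):
            spine_metrics(comp, ISO)


def _stack_with(labels):
    return LabeledStack(labels=labels, voxel_nm=(20.0, 20.0, 75.0))


class TestSegmentation:
    def test_zero_spines(self):
        preset = scaled_preset(DENDRITE_PRESETS["myelinated"], density_per_um=0.0)
        stack, truth = gen_dendrite_stack(preset, 10.0, 1)
        comps, shaft_len, orphans = segment_spines(stack)
        assert comps == [] and orphans == []
        assert shaft_len > 9.5
        assert len(truth.table) == 0

    def test_component_count_matches_ground_truth(self):
        stack, truth = gen_dendrite_stack(DENDRITE_PRESETS["myelinated"], 12.0, 5)
        comps, _, orphans = segment_spines(stack)
        assert len(comps) == len(truth.table)
        assert orphans == []

    def test_merged_spines_collapse_to_one_component(self):
        labels = np.zeros((5, 30, 12), dtype=np.uint8)
        labels[2, :, 0:2] = 1                      # shaft slab
        labels[2, 5:8, 2:6] = 2                    # spine A
        labels[2, 8:11, 2:6] = 2                   # spine B, touching A
        comps, _, _ = segment_spines(_stack_with(labels))
        assert len(comps) == 1

    def test_orphan_component_excluded_and_reported(self):
        labels = np.zeros((5, 30, 12), dtype=np.uint8)
        labels[2, :, 0:2] = 1
        labels[2, 5:8, 2:5] = 2                    # attached spine
        labels[2, 20:23, 8:11] = 2                 # floating blob
        comps, _, orphans = segment_spines(_stack_with(labels))
        assert len(comps) == 1
        assert len(orphans) == 1


class TestEulerAndPsdTopology:
    def test_known_shapes(self):
        single = np.zeros((3, 3, 3), bool)
        single[1, 1, 1] = True
        assert euler_characteristic(single) == 1
        two = single.copy()
        two[0, 0, 0] = True  # corner-touching: one cubical component
        assert euler_characteristic(two) == 1
        ball = np.zeros((9, 9, 9), bool)
        zz, yy, xx = np.ogrid[:9, :9, :9]
        ball[(zz - 4) ** 2 + (yy - 4) ** 2 + (xx - 4) ** 2 <= 12] = True
        assert euler_characteristic(ball) == 1
        annulus = np.zeros((3, 15, 15), bool)
        yy, xx = np.ogrid[:15, :15]
        r2 = (yy - 7) ** 2 + (xx - 7) ** 2
        annulus[1] = (r2 <= 36) & (r2 >= 4)
        assert euler_characteristic(annulus) == 0

    def test_matches_skimage_on_random_masks(self):
        from skimage.measure import euler_number
        rng = np.random.default_rng(3)
        for _ in range(60):
            m = rng.random((5, 9, 9)) < rng.uniform(0.15, 0.5)
            assert euler_characteristic(m) == euler_number(m, connectivity=3)

    def _psd_stack(self, patch2d, n_layers=2):
        """Head slab + PSD patch above it + bouton above that."""
        h, w = patch2d.shape
        labels = np.zeros((9, h + 4, w + 4), dtype=np.uint8)
        labels[0, :, :] = 1                       # shaft (keeps stack valid)
        labels[1:3, 2:h + 2, 2:w + 2] = 2          # spine head slab
        for k in range(n_layers):
            labels[3 + k, 2:h + 2, 2:w + 2][patch2d] = 3
        labels[3 + n_layers:6 + n_layers, 2:h + 2, 2:w + 2] = 4
        stack = _stack_with(labels)
        comps, _, _ = segment_spines(stack)
        psd = np.argwhere(labels == 3)
        return comps[0], psd, stack

    def test_solid_disc_is_macular(self):
        yy, xx = np.ogrid[:15, :15]
        disc = (yy - 7) ** 2 + (xx - 7) ** 2 <= 36
        comp, psd, stack = self._psd_stack(disc)
        area, psd_type, _ = psd_measure(comp, psd, stack)
        assert psd_type == "macular"
        assert area > 0

    def test_annulus_is_perforated(self):
        yy, xx = np.ogrid[:15, :15]
        r2 = (yy - 7) ** 2 + (xx - 7) ** 2
        comp, psd, stack = self._psd_stack((r2 <= 36) & (r2 >= 4))
        _, psd_type, _ = psd_measure(comp, psd, stack)
        assert psd_type == "perforated"

    def test_split_patch_is_perforated(self):
        patch = np.zeros((15, 15), bool)
        patch[3:7, 3:7] = True
        patch[9:13, 9:13] = True
        comp, psd, stack = self._psd_stack(patch)
        _, psd_type, _ = psd_measure(comp, psd, stack)
        assert psd_type == "perforated"

    def test_no_psd_is_none(self):
        yy, xx = np.ogrid[:15, :15]
        disc = (yy - 7) ** 2 + (xx - 7) ** 2 <= 36
        comp, _, stack = self._psd_stack(disc)
        area, psd_type, head_surface = psd_measure(
            comp, np.zeros((0, 3), dtype=int), stack)
        assert (area, psd_type) == (0.0, "none")
        assert head_surface > 0


class TestAstroContact:
    def _make(self, coverage):
        preset = scaled_preset(
            DENDRITE_PRESETS["myelinated"], density_per_um=0.6,
            class_mixture={"thin": 0.0, "mushroom": 1.0, "stubby": 0.0,
                           "filamentous": 0.0},
            perforated_fraction=0.0, astro_contact_fraction=1.0)
        stack, truth = gen_dendrite_stack(preset, 10.0, 4,
                                          fixed_astro_coverage=coverage)
        records, _, _ = analyze_stack(stack)
        return [r.astro_contact_pct for r in records
                if r.astro_contact_pct is not None]

    def test_full_sheath_is_complete_contact(self):
        pcts = self._make(1.0)
        assert pcts and all(p == pytest.approx(100.0, abs=1e-9) for p in pcts)

    def test_half_sheath_is_intermediate(self):
        pcts = self._make(0.5)
        assert pcts and 35.0 <= np.mean(pcts) <= 65.0

    def test_no_astro_label_zero_contact(self):
        preset = scaled_preset(
            DENDRITE_PRESETS["myelinated"], density_per_um=0.6,
            astro_contact_fraction=0.0)
        stack, _ = gen_dendrite_stack(preset, 10.0, 4)
        records, _, _ = analyze_stack(stack)
        pcts = [r.astro_contact_pct for r in records
                if r.astro_contact_pct is not None]
        assert pcts and all(p == 0.0 for p in pcts)

    def test_requires_psd(self):
        vox = np.array([(1, y, 1) for y in range(10)])
        comp = SpineComponent(0, voxels=vox, base_voxels=vox[:1])
        labels = np.zeros((3, 12, 3), np.uint8)
        labels[0, :, 0] = 1
        with pytest.raises(ValueError):
            astro_contact(comp, np.zeros((0, 3), int), _stack_with(labels))


def _rec(cls="thin", psd="macular", astro=0.0, head=0.4):
    return SpineRecord(spine_id=0, length_um=1.0, volume_um3=0.05,
                       head_diam_um=head, neck_diam_um=0.15, spine_class=cls,
                       psd_area_um2=0.05 if psd != "none" else 0.0,
                       psd_type=psd, head_surface_um2=0.5,
                       astro_contact_pct=astro)


class TestSummaries:
    def test_density_arithmetic(self):
        records = [_rec() for _ in range(42)]
        s = summarize_dendrite(records, 10.0)
        assert s.density_per_um == pytest.approx(4.2)
        assert s.n_spines == 42

    def test_all_macular_flags_infinite_ratio(self):
        s = summarize_dendrite([_rec(psd="macular")] * 5, 10.0)
        assert s.perforated_pct == 0.0
        assert s.ratio_is_infinite and math.isinf(s.macular_to_perforated_ratio)

    def test_macular_to_perforated_ratio(self):
        records = [_rec(psd="macular")] * 20 + [_rec(psd="perforated")] * 10
        s = summarize_dendrite(records, 10.0)
        assert s.macular_to_perforated_ratio == pytest.approx(2.0)
        assert s.perforated_pct == pytest.approx(100 * 10 / 30)

    def test_empty_records(self):
        s = summarize_dendrite([], 12.0)
        assert s.n_spines == 0 and s.density_per_um == 0.0

    def test_class_percentages_exclude_filamentous(self):
        records = ([_rec(cls="thin")] * 4 + [_rec(cls="mushroom")] * 3
                   + [_rec(cls="stubby")] * 3 + [_rec(cls="filamentous",
                                                      psd="none")] * 2)
        s = summarize_dendrite(records, 10.0)
        assert s.pct_thin == pytest.approx(40.0)
        assert s.class_fractions["filamentous"] == pytest.approx(2 / 12)

    def test_short_shaft_rejected(self):
        with pytest.raises(ValueError):
            summarize_dendrite([_rec()], 5.0)


class TestHeadVolAstro:
    def test_zero_variance_flagged(self):
        r, binned = headvol_vs_astro([_rec(astro=50.0, head=h)
                                      for h in (0.3, 0.4, 0.5)])
        assert math.isnan(r) and binned is None

    def test_exact_linear_relation(self):
        records = [_rec(astro=10.0 * h, head=h)
                   for h in np.linspace(0.2, 0.8, 12)]
        r, binned = headvol_vs_astro(records)
        assert r > 0.9
        assert binned["astro_contact_pct"].is_monotonic_increasing

    def test_demyelinated_cohort_positive_coupling(self, em_cohorts):
        recs = em_cohorts["demyelinated"]["records"]
        sel = recs[recs.astro_contact_pct.notna()
                   & (recs.astro_contact_pct > 0)]
        rows = [_rec(astro=a, head=h) for a, h in
                zip(sel.astro_contact_pct, sel.head_diam_um)]
        r, _ = headvol_vs_astro(rows)
        assert r > 0

    def test_needs_three_defined_records(self):
        with pytest.raises(ValueError):
            headvol_vs_astro([_rec(), _rec()])


class TestGeneratorProperties:
    def test_degenerate_mixture_all_mushroom(self):
        preset = scaled_preset(
            DENDRITE_PRESETS["myelinated"], density_per_um=2.0,
            class_mixture={"thin": 0.0, "mushroom": 1.0, "stubby": 0.0,
                           "filamentous": 0.0})
        _, truth = gen_dendrite_stack(preset, 10.0, 6)
        assert len(truth.table) >= 15
        assert (truth.table.spine_class == "mushroom").all()

    def test_poisson_interval_on_count(self):
        from scipy.stats import poisson
        _, truth = gen_dendrite_stack(DENDRITE_PRESETS["myelinated"], 12.0, 7)
        lo, hi = poisson.ppf([0.0005, 0.9995], 4.2 * 12.0)
        assert lo <= len(truth.table) <= hi

    def test_determinism_bit_identical(self):
        a, ta = gen_dendrite_stack(DENDRITE_PRESETS["demyelinated"], 10.0, 8)
        b, tb = gen_dendrite_stack(DENDRITE_PRESETS["demyelinated"], 10.0, 8)
        np.testing.assert_array_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(ta.table, tb.table)

    def test_short_shaft_rejected(self):
        with pytest.raises(ValueError):
            gen_dendrite_stack(DENDRITE_PRESETS["myelinated"], 8.0, 1)

    def test_unique_spine_ids(self, em_cohorts):
        truth = em_cohorts["myelinated"]["truth"]
        assert not truth.duplicated(subset=["seed", "spine_id"]).any()

    def test_class_mixture_chi_square(self, em_cohorts):
        """Realized class proportions match the preset mixture (GOF not
        rejected at alpha = 0.001 over >= 500 spines)."""
        from scipy.stats import chisquare
        for name in ("myelinated", "demyelinated"):
            truth = em_cohorts[name]["truth"]
            assert len(truth) >= 450
            mix = DENDRITE_PRESETS[name].class_mixture
            counts = truth.spine_class.value_counts()
            observed = [counts.get(c, 0) for c in mix]
            expected = np.array([mix[c] for c in mix]) * len(truth)
            _, p = chisquare(observed, expected)
            assert p > 0.001


class TestRecoveryInvariants:
    def test_classification_accuracy_and_density(self, em_cohorts):
        """Noise-free phantom recovery: class accuracy >= 95%, density within
        5% of the realized ground truth."""
        for name in ("myelinated", "demyelinated"):
            data = em_cohorts[name]
            merged_acc = (data["records"].spine_class.values
                          == data["truth"].spine_class.values).mean()
            assert merged_acc >= 0.95
            for summary, seed in zip(data["summaries"], range(1, 11)):
                n_true = (data["truth"].seed == seed).sum()
                true_density = n_true / 12.0
                assert summary.density_per_um == pytest.approx(
                    true_density, rel=0.05)

    def test_condition_contrast_directions(self, em_cohorts):
        """Demyelinated vs myelinated reproduces the printed directions:
        mushroom% up, thin% down, density unchanged, perforated% up,
        astrocyte-contacted% up."""
        def mean(name, attr):
            return np.mean([getattr(s, attr)
                            for s in em_cohorts[name]["summaries"]])
        assert mean("demyelinated", "pct_mushroom") > mean("myelinated",
                                                           "pct_mushroom")
        assert mean("demyelinated", "pct_thin") < mean("myelinated", "pct_thin")
        d_myel = mean("myelinated", "density_per_um")
        assert abs(mean("demyelinated", "density_per_um") - d_myel) \
            < 0.10 * d_myel
        assert mean("demyelinated", "perforated_pct") > mean("myelinated",
                                                             "perforated_pct")
        assert mean("demyelinated", "astro_contacted_pct") > \
            mean("myelinated", "astro_contacted_pct")

    def test_anisotropy_robustness(self):
        """Halving the in-plane voxel size changes volume and length
        estimates by < 10%."""
        base = scaled_preset(DENDRITE_PRESETS["myelinated"], density_per_um=1.2)
        fine = scaled_preset(base, voxel_nm=(10.0, 10.0, 75.0))
        stack_a, truth_a = gen_dendrite_stack(base, 10.0, 9)
        stack_b, truth_b = gen_dendrite_stack(fine, 10.0, 9)
        rec_a, _, _ = analyze_stack(stack_a)
        rec_b, _, _ = analyze_stack(stack_b)
        assert len(rec_a) == len(rec_b)
        for a, b in zip(rec_a, rec_b):
            assert b.volume_um3 == pytest.approx(a.volume_um3, rel=0.10)
            # lengths are additionally quantized by the (unchanged) 75 nm
            # section thickness, which dominates for sub-um stubby spines
            assert abs(b.length_um - a.length_um) <= max(
                0.10 * a.length_um, 2 * 0.075)
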