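"""Tests of the synthetic histology generator: calibration, determinism,
cohort bookkeeping, and the statistical structure downstream stages rely on."""

import numpy as np
import pytest

from hfhisto.errors import InvalidArgumentError
from hfhisto.synthetic_data import (
    CohortSpec,
    TissueParams,
    class_presets,
    generate_cohort,
    generate_feature_clusters,
    generate_slide,
    generate_tissue_image,
    stroma_pixel_fraction,
    background_pixel_fraction,
)


class TestTissueImage:
    def test_zero_fibrosis_leaves_only_perivascular_stroma(self):
        img = generate_tissue_image(TissueParams(fibrosis_fraction=0.0, rng_seed=3), 512, 2.0)
        assert stroma_pixel_fraction(img) < 0.05

    @pytest.mark.parametrize("target", [0.2, 0.4])
    def test_stroma_fraction_calibrated_by_pixel_count(self, target):
        # independent check: count pixels matching the pale-stroma palette
        img = generate_tissue_image(TissueParams(fibrosis_fraction=target, rng_seed=1), 512, 2.0)
        assert abs(stroma_pixel_fraction(img) - target) <= 0.05

    def test_rendering_is_pure_function_of_arguments(self):
        p = TissueParams(fibrosis_fraction=0.3, rng_seed=9)
        a = generate_tissue_image(p, 256, 2.0)
        b = generate_tissue_image(p, 256, 2.0)
        assert np.array_equal(a, b)

    def test_presets_have_distinct_color_histograms(self):
        pre = class_presets("strong")
        nf = generate_tissue_image(pre["non_failing"], 256, 2.0)
        fl = generate_tissue_image(pre["failing_severe"], 256, 2.0)
        chi2 = 0.0
        for c in range(3):
            h1 = np.bincount(nf[..., c].ravel(), minlength=256).astype(float)
            h2 = np.bincount(fl[..., c].ravel(), minlength=256).astype(float)
            h1, h2 = h1 / h1.sum(), h2 / h2.sum()
            denom = h1 + h2
            nz = denom > 0
            chi2 += ((h1[nz] - h2[nz]) ** 2 / denom[nz]).sum()
        assert chi2 > 0.05

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_tissue_image(TissueParams(), 64, 2.0)  # below minimum side
        with pytest.raises(InvalidArgumentError):
            generate_tissue_image(TissueParams(), 256, -1.0)
        with pytest.raises(InvalidArgumentError):
            TissueParams(fibrosis_fraction=1.5)
        with pytest.raises(InvalidArgumentError):
            TissueParams(nucleus_scale=0.5)


class TestSlide:
    def test_background_fraction_matches_tissue_area(self):
        slide = generate_slide(TissueParams(rng_seed=5), 1200, 900, rng_seed=5)
        expected_bg = 1.0 - np.pi * (900 / 2) ** 2 / 1200**2
        assert abs(background_pixel_fraction(slide.pixels) - expected_bg) <= 0.05

    def test_same_seed_is_bit_identical(self):
        a = generate_slide(TissueParams(rng_seed=2), 600, 400, rng_seed=2)
        b = generate_slide(TissueParams(rng_seed=2), 600, 400, rng_seed=2)
        assert np.array_equal(a.pixels, b.pixels)

    def test_tissue_must_fit_inside_canvas(self):
        with pytest.raises(InvalidArgumentError):
            generate_slide(TissueParams(), 400, 400, rng_seed=0)


class TestCohort:
    def test_exact_class_counts(self):
        cohort = generate_cohort(CohortSpec(n_patients=10, prop_failing=0.5, rois_per_patient=2,
                                            roi_side_px=128, rng_seed=0))
        labels = [p.label_v1 for p in cohort.patients]
        assert labels.count("failing") == 5 and labels.count("non-failing") == 5

    def test_full_scale_cohort_roi_count(self):
        # 209 patients x 11 ROIs = 2299 images (ROI recipes only; nothing rendered)
        cohort = generate_cohort(CohortSpec(n_patients=209, rois_per_patient=11,
                                            roi_side_px=128, rng_seed=1))
        n_rois = sum(len(p.roi_params) for p in cohort.patients)
        assert n_rois == 2299

    def test_occult_patients_counted_and_labeled(self):
        cohort = generate_cohort(CohortSpec(n_patients=40, prop_failing=0.5, occult_fraction=0.1,
                                            rois_per_patient=2, roi_side_px=128, rng_seed=3))
        occ = [p for p in cohort.patients if p.occult]
        assert len(occ) == 2  # round(20 * 0.1)
        for p in occ:
            assert p.label_v1 == "non-failing"
            assert p.label_v2 == "abnormal or heart failure"
            assert p.tier == "failing_severe"

    def test_schema_relabeling_flips_exactly_the_occult_patients(self):
        cohort = generate_cohort(CohortSpec(n_patients=30, occult_fraction=0.2,
                                            rois_per_patient=2, roi_side_px=128, rng_seed=4))
        from hfhisto.synthetic_data import is_failing_label

        flipped = [p.patient_id for p in cohort.patients
                   if is_failing_label(p.label_v1) != is_failing_label(p.label_v2)]
        occult = [p.patient_id for p in cohort.patients if p.occult]
        assert sorted(flipped) == sorted(occult)

    def test_every_roi_inherits_patient_label_and_is_reproducible(self, small_cohort):
        p = small_cohort.patients[0]
        rois = list(small_cohort.iter_rois(p))
        assert len(rois) == small_cohort.spec.rois_per_patient
        assert all(r.patient_id == p.patient_id for r in rois)
        again = next(iter(small_cohort.iter_rois(p)))
        assert np.array_equal(rois[0].pixels, again.pixels)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CohortSpec(n_patients=10, prop_failing=1.2)
        with pytest.raises(InvalidArgumentError):
            CohortSpec(n_patients=10, occult_fraction=-0.1)

    def test_effect_size_monotonicity_of_simple_stroma_discriminator(self):
        """A fixed threshold on the measured stroma fraction separates the
        classes strictly better as the class separation grows."""
        accs = {}
        for effect in ("weak", "moderate", "strong"):
            cohort = generate_cohort(CohortSpec(
                n_patients=20, prop_failing=0.5, rois_per_patient=10,
                roi_side_px=160, effect_size=effect, rng_seed=77))
            pre = class_presets(effect)
            mid = 0.5 * (pre["non_failing"].fibrosis_fraction
                         + 0.5 * (pre["failing_severe"].fibrosis_fraction
                                  + pre["failing_moderate"].fibrosis_fraction))
            correct = total = 0
            for p in cohort.patients:
                failing = p.label_v1 == "failing"
                for k in range(10):
                    frac = stroma_pixel_fraction(cohort.roi_image(p, k))
                    correct += (frac > mid) == failing
                    total += 1
            accs[effect] = correct / total
        assert accs["weak"] < accs["moderate"] < accs["strong"]


class TestFeatureClusters:
    def test_single_component_has_unit_variance_spread(self, rng):
        X, lab = generate_feature_clusters(1, 200, 0.0, 5, rng_seed=0)
        assert set(lab) == {0}
        # mean pairwise squared distance for N(0, I_d) is 2d
        d2 = ((X[:100] - X[100:]) ** 2).sum(axis=1)
        assert abs(d2.mean() - 10.0) < 1.5

    def test_zero_separation_is_chance_level(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist
        from sklearn.metrics import adjusted_rand_score

        X, lab = generate_feature_clusters(2, 50, 0.0, 4, rng_seed=1)
        pred = fcluster(linkage(pdist(X), "average"), 2, "maxclust")
        assert abs(adjusted_rand_score(lab, pred)) < 0.1

    def test_strong_separation_recovered_exactly_by_average_linkage(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist
        from sklearn.metrics import adjusted_rand_score

        X, lab = generate_feature_clusters(3, 30, 8.0, 3, rng_seed=2)
        pred = fcluster(linkage(pdist(X), "average"), 3, "maxclust")
        assert adjusted_rand_score(lab, pred) == 1.0

    def test_centers_mutually_separated(self):
        X, lab = generate_feature_clusters(3, 500, 10.0, 6, rng_seed=3)
        centers = np.array([X[lab == c].mean(axis=0) for c in range(3)])
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(np.linalg.norm(centers[i] - centers[j]) - 10.0) < 0.5

    def test_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            generate_feature_clusters(0, 10, 1.0, 5, 0)
        with pytest.raises(InvalidArgumentError):
            generate_feature_clusters(3, 10, 1.0, 2, 0)
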