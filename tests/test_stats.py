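"""Quantitative histology statistics against exact fixture ledgers."""

import numpy as np
import pandas as pd
import pytest

from ibdmil.datasets import COHORT_SLIDE_COUNTS, cohort_slide_manifest
from ibdmil.grouping import get_grouping
from ibdmil.stats import (
    aggregate_slide_stats,
    circularity,
    compute_tile_stats,
    gb_baseline,
    slide_stats_table,
    tabulate_label_distribution,
)
from ibdmil.synthetic import BundleSpec, GlandSpec, gen_bundle


def _disc_mask(r):
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= r**2


class TestCircularity:
    @pytest.mark.parametrize("r", [10, 15, 25, 40])
    def test_disc_within_five_percent_of_unity(self, r):
        assert circularity(_disc_mask(r)) == pytest.approx(1.0, rel=0.05)

    def test_square_approaches_quarter_pi(self):
        # continuous value 4*pi*s^2 / (4s)^2 = pi/4
        mask = np.ones((100, 100), dtype=bool)
        assert circularity(mask) == pytest.approx(np.pi / 4, rel=0.05)

    def test_elongated_shape_less_circular_than_disc(self):
        bar = np.ones((4, 100), dtype=bool)
        assert circularity(bar) < circularity(_disc_mask(20))

    def test_clamped_to_unit_interval(self):
        assert 0 < circularity(np.ones((3, 3), bool)) <= 1.0


class TestTileStats:
    def test_matches_ledger_exactly(self, standard_bundle):
        bundle, ledger = standard_bundle
        ts = compute_tile_stats(bundle)
        assert ts.tissue_areas == ledger.tissue_areas
        assert ts.nuclear_counts == ledger.nuclear_counts
        assert ts.nuclear_counts_by_tissue == ledger.nuclear_counts_by_tissue
        assert ts.gland_count == ledger.gland_count
        assert ts.surface_epithelium_area == ledger.surface_epithelium_area
        assert ts.nuclei_in_glands == ledger.nuclei_in_glands
        assert ts.nuclei_in_surface_epithelium == ledger.nuclei_in_surface_epithelium

    def test_many_seeded_bundles_match_ledgers(self):
        """Exact count/area agreement over a catalogue of seeded bundles."""
        spec = BundleSpec(
            tile_size=128,
            composition={"stroma": 0.35, "inflammatory": 0.15, "debris": 0.05},
            glands=GlandSpec(count=2, shape="disc", size=10),
            nuclei={"lymphocyte": (4, "stroma"), "neutrophil": (2, "inflammatory")},
        )
        for seed in range(12):
            bundle, ledger = gen_bundle(spec, seed)
            ts = compute_tile_stats(bundle)
            assert ts.tissue_areas == ledger.tissue_areas, seed
            assert ts.nuclear_counts == ledger.nuclear_counts, seed
            assert ts.nuclear_counts_by_tissue == ledger.nuclear_counts_by_tissue, seed
            assert ts.gland_count == ledger.gland_count, seed

    def test_gland_circularity_tracks_analytic_truth(self):
        spec = BundleSpec(tile_size=200, glands=GlandSpec(count=1, shape="disc", size=20))
        bundle, ledger = gen_bundle(spec, 1)
        ts = compute_tile_stats(bundle)
        assert ts.gland_circularities[0] == pytest.approx(
            ledger.gland_circularities_analytic[0], rel=0.05
        )

    def test_square_gland_circularity(self):
        spec = BundleSpec(tile_size=200, glands=GlandSpec(count=1, shape="square", size=30))
        bundle, _ = gen_bundle(spec, 1)
        ts = compute_tile_stats(bundle)
        assert ts.gland_circularities[0] == pytest.approx(np.pi / 4, rel=0.06)

    def test_empty_bundle_all_zero(self):
        bundle, _ = gen_bundle(BundleSpec(tile_size=64), 0)
        ts = compute_tile_stats(bundle)
        assert ts.gland_count == 0 and not ts.gland_circularities
        assert sum(ts.nuclear_counts.values()) == 0
        assert ts.tissue_areas["background"] == 64 * 64

    def test_tissue_area_conservation(self, standard_bundle):
        bundle, _ = standard_bundle
        ts = compute_tile_stats(bundle)
        assert sum(ts.tissue_areas.values()) == bundle.shape[0] * bundle.shape[1]

    def test_cross_tab_bounded_by_type_counts(self, standard_bundle):
        bundle, _ = standard_bundle
        ts = compute_tile_stats(bundle)
        for ty in ts.nuclear_counts:
            by_tissue = sum(v for (t, _), v in ts.nuclear_counts_by_tissue.items() if t == ty)
            assert by_tissue <= ts.nuclear_counts[ty]

    def test_missing_required_map_raises_naming_it(self, standard_bundle):
        import dataclasses

        bundle, _ = standard_bundle
        mutant = dataclasses.replace(bundle, tissue_type=None)
        with pytest.raises(ValueError, match="tissue_type"):
            compute_tile_stats(mutant)

    def test_brute_force_pixel_oracle(self, standard_bundle):
        """Independent per-pixel/per-instance recount of one bundle."""
        bundle, _ = standard_bundle
        ts = compute_tile_stats(bundle)
        vocab = bundle.vocabulary
        # area oracle: direct pixel scan
        for name, code in vocab.tissue_classes.items():
            assert ts.tissue_areas[name] == int((bundle.tissue_type == code).sum())
        # nucleus oracle: loop over instance ids
        counts = {name: 0 for name in vocab.nucleus_types}
        for uid in np.unique(bundle.nucleus_instance):
            if uid == 0:
                continue
            codes = bundle.nucleus_type[bundle.nucleus_instance == uid]
            counts[vocab.nucleus_name(int(np.bincount(codes).argmax()))] += 1
        assert counts == ts.nuclear_counts


class TestSlideAggregation:
    def test_single_tile_identity(self, standard_bundle):
        bundle, _ = standard_bundle
        ts = compute_tile_stats(bundle)
        slide = aggregate_slide_stats([ts])
        total = sum(v for k, v in ts.tissue_areas.items() if k != "background")
        assert slide.normalizer == total
        assert slide.features["nucleus_density_lymphocyte"] == pytest.approx(
            ts.nuclear_counts["lymphocyte"] / total
        )

    def test_duplicating_tiles_leaves_densities_unchanged(self, standard_bundle):
        """Scale invariance: k copies of the same content, same features."""
        bundle, _ = standard_bundle
        ts = compute_tile_stats(bundle)
        one = aggregate_slide_stats([ts])
        three = aggregate_slide_stats([ts, ts, ts])
        for key in one.features:
            assert one.features[key] == pytest.approx(three.features[key], abs=1e-12)

    def test_area_fractions_sum_to_one(self, standard_bundle):
        bundle, _ = standard_bundle
        slide = aggregate_slide_stats([compute_tile_stats(bundle)])
        frac = sum(v for k, v in slide.features.items() if k.startswith("tissue_fraction_"))
        assert frac == pytest.approx(1.0, abs=1e-9)

    def test_planted_gradient_matches_area_weighted_mean(self):
        """A slide whose tiles ramp the inflamed fraction."""
        tiles, expected_inflamed, expected_total = [], 0, 0
        for i, frac in enumerate([0.1, 0.2, 0.3]):
            spec = BundleSpec(tile_size=100, composition={"stroma": 0.4, "inflammatory": frac})
            bundle, ledger = gen_bundle(spec, i)
            tiles.append(compute_tile_stats(bundle))
            expected_inflamed += ledger.tissue_areas["inflammatory"]
            expected_total += sum(v for k, v in ledger.tissue_areas.items() if k != "background")
        slide = aggregate_slide_stats(tiles)
        assert slide.features["tissue_fraction_inflammatory"] == pytest.approx(
            expected_inflamed / expected_total
        )

    def test_monotone_inflamed_fraction_feature(self):
        """More planted inflamed area strictly raises the inflamed feature."""
        values = []
        for frac in (0.05, 0.15, 0.30):
            spec = BundleSpec(tile_size=100, composition={"stroma": 0.4, "inflammatory": frac})
            bundle, _ = gen_bundle(spec, 7)
            values.append(
                aggregate_slide_stats([compute_tile_stats(bundle)]).features[
                    "tissue_fraction_inflammatory"
                ]
            )
        assert values[0] < values[1] < values[2]

    def test_adding_glands_increases_gland_density(self):
        densities = []
        for n_glands in (1, 4):
            spec = BundleSpec(
                tile_size=200, composition={"stroma": 0.5},
                glands=GlandSpec(count=n_glands, size=8),
            )
            bundle, _ = gen_bundle(spec, 3)
            densities.append(
                aggregate_slide_stats([compute_tile_stats(bundle)]).features["gland_density"]
            )
        assert densities[0] < densities[1]

    def test_zero_tissue_slide_flagged_degenerate(self):
        bundle, _ = gen_bundle(BundleSpec(tile_size=64), 0)
        slide = aggregate_slide_stats([compute_tile_stats(bundle)])
        assert slide.degenerate
        assert "gland_density" in slide.undefined

    def test_undefined_ratio_flagged_not_nan_propagated(self):
        # nuclei only on epithelium: stromal denominator is zero
        spec = BundleSpec(
            tile_size=100,
            composition={"normal_epithelium": 0.5},
            nuclei={"epithelial": (3, "normal_epithelium")},
        )
        bundle, _ = gen_bundle(spec, 2)
        slide = aggregate_slide_stats([compute_tile_stats(bundle)])
        assert "epithelial_stromal_nuclear_ratio" in slide.undefined
        assert np.isfinite(slide.features["epithelial_stromal_nuclear_ratio"])


class TestTabulation:
    def test_published_cohort_grand_total(self):
        """Re-entering the published per-location grade counts reproduces
        the printed cohort total of 1743 slides."""
        table = tabulate_label_distribution(cohort_slide_manifest())
        assert int(table.loc["total", "total"]) == 1743
        for loc, counts in COHORT_SLIDE_COUNTS.items():
            assert tuple(table.loc[loc, [f"NHI-{i}" for i in range(5)]]) == counts

    def test_empty_manifest(self):
        table = tabulate_label_distribution(
            pd.DataFrame(columns=["slide_id", "location", "nhi"])
        )
        assert int(table.loc["total", "total"]) == 0

    def test_grouping_preserves_column_sums(self):
        manifest = cohort_slide_manifest()
        five = tabulate_label_distribution(manifest)
        grouped = tabulate_label_distribution(manifest, get_grouping("type_A"))
        assert int(grouped.loc["total", "total"]) == int(five.loc["total", "total"])
        # per-location totals conserved too
        for loc in COHORT_SLIDE_COUNTS:
            assert int(grouped.loc[loc, "total"]) == int(five.loc[loc, "total"])

    def test_unknown_rows_listed_in_error(self):
        bad = pd.DataFrame(
            {"slide_id": ["a", "b"], "location": ["rectum", "nowhere"], "nhi": [9, 1]}
        )
        with pytest.raises(ValueError, match="nowhere"):
            tabulate_label_distribution(bad)


class TestGBBaseline:
    @staticmethod
    def _planted_cohort(n_patients=60, seed=0):
        """Slide features linearly separable by inflamed fraction."""
        rng = np.random.default_rng(seed)
        slides = []
        labels, patients = [], []
        for p in range(n_patients):
            nhi = int(rng.integers(0, 4))
            frac = 0.05 + 0.12 * nhi + rng.normal(0, 0.01)
            spec = BundleSpec(
                tile_size=64, composition={"stroma": 0.4, "inflammatory": max(0.0, frac)}
            )
            bundle, _ = gen_bundle(spec, seed + p)
            slides.append(aggregate_slide_stats([compute_tile_stats(bundle)], slide_id=f"s{p}"))
            labels.append(nhi)
            patients.append(f"p{p}")
        return slide_stats_table(slides), labels, patients

    def test_recovers_planted_signal(self):
        X, y, groups = self._planted_cohort()
        res = gb_baseline(X, y, groups, grouping=get_grouping("binary"), seed=0)
        assert res.pooled_accuracy >= 0.95

    def test_shuffled_labels_near_chance(self):
        X, y, groups = self._planted_cohort()
        rng = np.random.default_rng(1)
        y_shuf = rng.permutation(y).tolist()
        res = gb_baseline(X, y_shuf, groups, grouping=get_grouping("binary"), seed=0)
        # binomial noise around chance for 60 samples
        assert res.pooled_accuracy <= 0.72

    def test_single_class_errors(self):
        X, y, groups = self._planted_cohort(n_patients=12)
        with pytest.raises(ValueError, match="two classes"):
            gb_baseline(X, [1] * len(y), groups, seed=0)
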