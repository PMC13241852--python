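"""Region-filter rules, tile subdivision and the filter stage."""

import itertools

import numpy as np
import pytest

from ibdmil.filtering import (
    FilterConfig,
    GeometryError,
    make_patch_id,
    patch_background_filter,
    run_filter_stage,
    subdivide_tile,
    tile_filter,
)
from ibdmil.synthetic import BundleSpec, gen_bundle
from ibdmil.vocab import default_vocabulary


def _composition_map(vocab, fractions, size=100):
    """Tissue map with exact class fractions (flattened fill)."""
    flat = np.zeros(size * size, dtype=np.int32)
    cursor = 0
    for name, frac in fractions.items():
        n = int(round(frac * size * size))
        flat[cursor : cursor + n] = vocab.tissue_code(name)
        cursor += n
    return flat.reshape(size, size)


class TestTileFilter:
    def test_worked_instance_from_the_rule(self, vocab):
        """15% stroma + 5% normal epithelium + a trace of inflammation
        + muscle elsewhere -> kept (reference 20% >= 10%, presence)."""
        tm = _composition_map(
            vocab, {"stroma": 0.15, "normal_epithelium": 0.05, "muscle": 0.7999}
        )
        tm[-1, -1] = vocab.tissue_code("inflammatory")  # one pixel
        d = tile_filter(tm, vocab)
        assert d.kept
        assert d.reference_fraction == pytest.approx(0.20, abs=1e-3)
        assert d.ibd_presence["inflammatory"]

    def test_pure_muscle_rejected(self, vocab):
        tm = _composition_map(vocab, {"muscle": 1.0})
        d = tile_filter(tm, vocab)
        assert not d.kept
        assert d.reference_fraction == 0.0

    def test_reference_without_ibd_presence_rejected(self, vocab):
        tm = _composition_map(vocab, {"stroma": 0.5})
        d = tile_filter(tm, vocab)
        assert not d.kept and "IBD" in d.reason

    def test_exactly_ten_percent_reference_keeps(self, vocab):
        tm = _composition_map(vocab, {"stroma": 0.10})
        tm[-1, -1] = vocab.tissue_code("debris")
        # one debris pixel nudges stroma below quota: rebuild exactly
        tm = _composition_map(vocab, {"stroma": 0.10, "debris": 0.0001})
        d = tile_filter(tm, vocab)
        assert d.reference_fraction >= 0.10 and d.kept

    def test_exhaustive_rule_oracle_over_composition_grid(self, vocab):
        """Compare against an independent oracle over a catalogue of
        composition vectors, including the 10% boundary."""
        grid = [0.0, 0.05, 0.0999, 0.10, 0.15, 0.40]
        ibd_options = [0, 1]
        for stroma, epi, has_ibd in itertools.product(grid, grid, ibd_options):
            if stroma + epi > 0.99:
                continue
            comp = {"stroma": stroma, "normal_epithelium": epi}
            tm = _composition_map(vocab, comp, size=100)
            if has_ibd:
                tm[-1, -1] = vocab.tissue_code("abnormal_epithelium")
            d = tile_filter(tm, vocab)
            # oracle recomputes from the raw map, independent of the rule code
            ref = np.isin(
                tm, [vocab.tissue_code("stroma"), vocab.tissue_code("normal_epithelium")]
            ).mean()
            ibd = any(
                (tm == vocab.tissue_code(c)).any()
                for c in ("abnormal_epithelium", "inflammatory", "debris")
            )
            assert d.kept == ((ref >= 0.10) and ibd), (stroma, epi, has_ibd)

    def test_monotone_in_reference_threshold(self, vocab):
        tm = _composition_map(vocab, {"stroma": 0.25})
        tm[-1, -1] = vocab.tissue_code("debris")
        kept = [tile_filter(tm, vocab, tau_ref=t).kept for t in (0.05, 0.15, 0.25, 0.30)]
        # once rejected, stays rejected as the threshold rises
        assert kept == sorted(kept, reverse=True)


class TestSubdivide:
    def test_published_grid_arithmetic(self):
        tile = np.zeros((1250, 1250, 3), dtype=np.uint8)
        patches = subdivide_tile(tile, 250)
        assert len(patches) == 25

    def test_single_patch_identity(self):
        tile = np.arange(250 * 250 * 3, dtype=np.uint8).reshape(250, 250, 3)
        patches = subdivide_tile(tile, 250)
        assert len(patches) == 1
        np.testing.assert_array_equal(patches[0][1], tile)

    def test_center_crop_union_is_central_region(self):
        tile = np.random.default_rng(0).integers(0, 255, (1520, 1520, 3), dtype=np.uint8)
        patches = subdivide_tile(tile, 250, crop_to=1250, tile_origin=(0, 0))
        assert len(patches) == 25
        origins = np.array([rec.origin for rec, _ in patches])
        assert origins.min(axis=0).tolist() == [135, 135]  # (1520-1250)//2
        assert (origins.max(axis=0) + 250).tolist() == [135 + 1250, 135 + 1250]
        # reassembled patches equal the central crop
        rebuilt = np.zeros((1250, 1250, 3), dtype=np.uint8)
        for rec, px in patches:
            i, j = rec.grid_pos
            rebuilt[i * 250 : (i + 1) * 250, j * 250 : (j + 1) * 250] = px
        np.testing.assert_array_equal(rebuilt, tile[135:1385, 135:1385])

    def test_non_divisible_geometry_raises(self):
        with pytest.raises(GeometryError):
            subdivide_tile(np.zeros((300, 300, 3)), 250)

    def test_patch_ids_deterministic(self):
        a = make_patch_id("s1", (1520, 0), (2, 3))
        b = make_patch_id("s1", (1520, 0), (2, 3))
        assert a == b
        assert make_patch_id("s1", (0, 0), (2, 3)) != a

    def test_row_major_order_and_partition(self):
        patches = subdivide_tile(np.zeros((500, 500)), 250)
        assert [rec.grid_pos for rec, _ in patches] == [(0, 0), (0, 1), (1, 0), (1, 1)]


class TestBackgroundFilter:
    def test_exactly_sixty_percent_excludes(self, vocab):
        tm = np.zeros((10, 10), dtype=np.int32)
        tm[:4] = vocab.tissue_code("stroma")  # 60% background
        kept, frac = patch_background_filter(patch_tissue_map=tm)
        assert frac == pytest.approx(0.60) and not kept

    def test_all_tissue_kept(self, vocab):
        tm = np.full((10, 10), vocab.tissue_code("stroma"), dtype=np.int32)
        kept, frac = patch_background_filter(patch_tissue_map=tm)
        assert kept and frac == 0.0

    def test_half_background_kept(self, vocab):
        tm = np.zeros((10, 10), dtype=np.int32)
        tm[:5] = vocab.tissue_code("stroma")
        kept, frac = patch_background_filter(patch_tissue_map=tm)
        assert kept and frac == pytest.approx(0.50)

    def test_rule_oracle_over_fraction_grid(self, vocab):
        for bg_rows in range(11):
            tm = np.zeros((10, 10), dtype=np.int32)
            tm[bg_rows:] = vocab.tissue_code("stroma")
            kept, frac = patch_background_filter(patch_tissue_map=tm)
            assert frac == pytest.approx(bg_rows / 10)
            assert kept == (bg_rows / 10 < 0.60)

    def test_intensity_fallback_without_map(self):
        bright = np.full((20, 20, 3), 250, dtype=np.uint8)
        kept, frac = patch_background_filter(patch_pixels=bright)
        assert not kept and frac == 1.0
        dark = np.full((20, 20, 3), 100, dtype=np.uint8)
        kept, frac = patch_background_filter(patch_pixels=dark)
        assert kept and frac == 0.0

    def test_no_evidence_source_errors(self):
        with pytest.raises(ValueError):
            patch_background_filter()


class TestFilterStage:
    @staticmethod
    def _tiles(n_keep, n_reject, size=200, seed=0):
        # full-tissue tiles so the patch background rule never bites:
        # the reduction then isolates the tile-level retention rule
        keep_spec = BundleSpec(
            tile_size=size, composition={"stroma": 0.5, "inflammatory": 0.2, "muscle": 0.3}
        )
        reject_spec = BundleSpec(tile_size=size, composition={"muscle": 1.0})
        tiles = []
        for i in range(n_keep):
            b, _ = gen_bundle(keep_spec, seed + i, tile_id=f"keep{i}")
            tiles.append((f"keep{i}", np.zeros((size, size, 3), np.uint8), b))
        for i in range(n_reject):
            b, _ = gen_bundle(reject_spec, seed + 100 + i, tile_id=f"rej{i}")
            tiles.append((f"rej{i}", np.zeros((size, size, 3), np.uint8), b))
        return tiles

    def test_all_rejected_empty_manifest(self):
        tiles = self._tiles(0, 3)
        cfg = FilterConfig(patch_size=50, crop_to=None)
        manifest, summary, kept = run_filter_stage(tiles, cfg)
        assert manifest.empty and not kept
        assert summary.reduction_fraction == 1.0

    def test_planted_uninformative_fraction_recovered(self):
        """60% informative / 40% uninformative tiles -> reduction equals
        the planted fraction (all kept-tile patches pass background)."""
        tiles = self._tiles(6, 4)
        cfg = FilterConfig(patch_size=50, crop_to=None)
        manifest, summary, kept = run_filter_stage(tiles, cfg)
        assert summary.tiles_kept == 6
        assert summary.reduction_fraction == pytest.approx(0.4)
        assert len(kept) == 6 * 16

    def test_unfiltered_mode_keeps_every_non_background_patch(self):
        tiles = self._tiles(2, 3)
        cfg = FilterConfig(enabled=False, patch_size=50, crop_to=None)
        manifest, summary, kept = run_filter_stage(tiles, cfg)
        assert summary.tiles_kept == 5
        # background rule still applies; these fixtures are >=50% tissue
        assert len(kept) == 5 * 16

    def test_filtered_mode_requires_bundles(self):
        tiles = [("t0", np.zeros((100, 100, 3), np.uint8), None)]
        with pytest.raises(ValueError, match="tissue-type map"):
            run_filter_stage(tiles, FilterConfig(patch_size=50, crop_to=None))

    def test_subdivision_conservation(self):
        tiles = self._tiles(3, 0)
        cfg = FilterConfig(patch_size=50, crop_to=None)
        manifest, summary, _ = run_filter_stage(tiles, cfg)
        per_tile = manifest.groupby("tile_id").size()
        assert (per_tile == 16).all()  # kept + excluded = (200/50)^2
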