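"""Region filtering: pick informative tiles, subdivide into patches.

Weak slide-level labels leave a MIL model to sift signal from
thousands of patches, most of which are irrelevant.  The filter uses
the tissue-type segmentation map to keep only tiles that (a) contain
at least a minimum fraction of baseline reference tissue — stroma plus
normal epithelium, summed — and (b) show any presence of an
IBD-relevant class (abnormal epithelium, inflammatory tissue, or
debris).  Kept tiles are center-cropped to a side divisible by the
patch size and subdivided into a non-overlapping patch grid (default
1250 -> 25 patches of 250 px); patches that are mostly background
(>= 60% by default) are excluded.

The tile retention rule runs before subdivision; the background rule
runs per patch.  Boundary semantics follow the rules' wording: a
reference fraction of exactly 10% keeps, a background fraction of
exactly 60% excludes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bundle import AnnotationBundle
from .vocab import IBD_TISSUE_CLASSES, REFERENCE_TISSUE_CLASSES, LabelVocabulary

DEFAULT_TAU_REF = 0.10
DEFAULT_TAU_BG = 0.60
DEFAULT_PATCH_SIZE = 250
DEFAULT_CROP_SIZE = 1250


class GeometryError(ValueError):
    """Raised when a tile cannot be subdivided without padding."""


@dataclass
class FilterDecision:
    """Outcome of the tile-level retention rule."""

    tile_id: str
    kept: bool
    reference_fraction: float
    ibd_presence: dict[str, bool]
    reason: str


@dataclass
class PatchRecord:
    """One grid patch of a subdivided tile."""

    patch_id: str
    tile_id: str
    slide_id: str
    grid_pos: tuple[int, int]
    origin: tuple[int, int]  # slide pixels, (row, col)
    size: tuple[int, int]
    background_fraction: float = 0.0
    kept: bool = True


def tile_filter(
    tissue_map: np.ndarray,
    vocabulary: LabelVocabulary,
    tau_ref: float = DEFAULT_TAU_REF,
    *,
    tile_id: str = "tile",
) -> FilterDecision:
    """Apply the tissue-composition retention rule to one tile.

    The reference fraction is the summed share of stroma and normal
    epithelium over *all* tile pixels (background included in the
    denominator).  Presence of an IBD class means at least one pixel.
    Kept iff ``reference_fraction >= tau_ref`` and any IBD class is
    present.
    """
    try:
        ref_codes = [vocabulary.tissue_code(n) for n in REFERENCE_TISSUE_CLASSES]
        ibd_codes = {n: vocabulary.tissue_code(n) for n in IBD_TISSUE_CLASSES}
    except KeyError as e:
        raise ValueError(f"vocabulary missing tissue class required for filtering: {e}")

    total = tissue_map.size
    ref_frac = float(np.isin(tissue_map, ref_codes).sum() / total) if total else 0.0
    presence = {name: bool((tissue_map == code).any()) for name, code in ibd_codes.items()}
    ref_ok = ref_frac >= tau_ref
    ibd_ok = any(presence.values())
    kept = ref_ok and ibd_ok
    if kept:
        reason = "kept"
    elif not ref_ok and not ibd_ok:
        reason = "insufficient reference tissue and no IBD-relevant class"
    elif not ref_ok:
        reason = f"reference tissue {ref_frac:.3f} < {tau_ref}"
    else:
        reason = "no IBD-relevant tissue class present"
    return FilterDecision(
        tile_id=tile_id, kept=kept, reference_fraction=ref_frac,
        ibd_presence=presence, reason=reason,
    )


def center_crop(array: np.ndarray, side: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Deterministic center crop to ``side`` x ``side``; returns the
    crop and its (row, col) offset within the input."""
    h, w = array.shape[:2]
    if h < side or w < side:
        raise GeometryError(f"cannot crop {h}x{w} to {side}x{side}")
    r0, c0 = (h - side) // 2, (w - side) // 2
    return array[r0 : r0 + side, c0 : c0 + side], (r0, c0)


def make_patch_id(slide_id: str, tile_origin: tuple[int, int], grid_pos: tuple[int, int]) -> str:
    """Deterministic patch identity ('patch base name'): pure function
    of slide, tile origin and grid position, so embedding-store keys
    are reproducible across runs."""
    return f"{slide_id}_t{tile_origin[0]}-{tile_origin[1]}_p{grid_pos[0]}-{grid_pos[1]}"


def subdivide_tile(
    tile_pixels: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    *,
    slide_id: str = "slide",
    tile_id: str = "tile",
    tile_origin: tuple[int, int] = (0, 0),
    crop_to: Optional[int] = None,
) -> list[tuple[PatchRecord, np.ndarray]]:
    """Subdivide a tile into a row-major grid of non-overlapping patches.

    When ``crop_to`` is given (e.g. 1250 for 1520-px tiles) the tile is
    center-cropped first.  The (possibly cropped) side must be exactly
    divisible by ``patch_size``; otherwise a :class:`GeometryError` is
    raised — never silent padding.
    """
    pixels = tile_pixels
    off = (0, 0)
    if crop_to is not None:
        pixels, off = center_crop(pixels, crop_to)
    h, w = pixels.shape[:2]
    if h % patch_size or w % patch_size:
        raise GeometryError(
            f"tile side {h}x{w} not divisible by patch size {patch_size}; "
            "configure crop_to to a divisible side"
        )
    out = []
    for i in range(h // patch_size):
        for j in range(w // patch_size):
            r0, c0 = i * patch_size, j * patch_size
            origin = (tile_origin[0] + off[0] + r0, tile_origin[1] + off[1] + c0)
            rec = PatchRecord(
                patch_id=make_patch_id(slide_id, tile_origin, (i, j)),
                tile_id=tile_id,
                slide_id=slide_id,
                grid_pos=(i, j),
                origin=origin,
                size=(patch_size, patch_size),
            )
            out.append((rec, pixels[r0 : r0 + patch_size, c0 : c0 + patch_size]))
    return out


def patch_background_filter(
    patch_tissue_map: Optional[np.ndarray] = None,
    patch_pixels: Optional[np.ndarray] = None,
    tau_bg: float = DEFAULT_TAU_BG,
    *,
    brightness_threshold: float = 220.0,
) -> tuple[bool, float]:
    """Exclude mostly-background patches.

    Background evidence comes from the tissue map (code 0) when one is
    available, else from a brightness threshold on the pixels.  A
    patch is kept iff its background fraction is strictly below
    ``tau_bg`` (exactly 60% background excludes).

    Returns ``(kept, background_fraction)``.
    """
    if patch_tissue_map is not None:
        bg = float((patch_tissue_map == 0).mean())
    elif patch_pixels is not None:
        gray = np.asarray(patch_pixels, dtype=np.float64)
        if gray.ndim == 3:
            gray = gray.mean(axis=2)
        bg = float((gray >= brightness_threshold).mean())
    else:
        raise ValueError("need a tissue map or pixel data to estimate background")
    return bg < tau_bg, bg


@dataclass
class FilterConfig:
    """Configuration of the full filter stage."""

    enabled: bool = True
    tau_ref: float = DEFAULT_TAU_REF
    tau_bg: float = DEFAULT_TAU_BG
    patch_size: int = DEFAULT_PATCH_SIZE
    crop_to: Optional[int] = DEFAULT_CROP_SIZE


@dataclass
class FilterSummary:
    """Bookkeeping of one filter run."""

    tiles_total: int = 0
    tiles_kept: int = 0
    patches_total: int = 0
    patches_kept: int = 0
    decisions: list[FilterDecision] = field(default_factory=list)

    @property
    def reduction_fraction(self) -> float:
        """Fraction of candidate patches removed relative to the
        unfiltered grid (all tiles subdivided)."""
        if self.patches_total == 0:
            return 0.0
        return 1.0 - self.patches_kept / self.patches_total


def run_filter_stage(
    tiles: Sequence[tuple[str, np.ndarray, Optional[AnnotationBundle]]],
    config: FilterConfig = FilterConfig(),
    *,
    slide_id: str = "slide",
    tile_origins: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[pd.DataFrame, FilterSummary, list[tuple[PatchRecord, np.ndarray]]]:
    """Run tile retention + subdivision + patch background exclusion.

    ``tiles`` is a sequence of ``(tile_id, pixels, bundle_or_None)``.
    In filtered mode every tile must carry a bundle (the filter needs
    segmentation); in unfiltered/ablation mode (``config.enabled``
    False) the retention rule is bypassed and only the background rule
    applies, falling back to pixel brightness when no bundle exists.

    Returns the patch manifest (kept and excluded patches, with
    fractions), a :class:`FilterSummary`, and the kept patches with
    pixel data.
    """
    summary = FilterSummary()
    kept_patches: list[tuple[PatchRecord, np.ndarray]] = []
    rows = []
    origins = tile_origins or [(0, 0)] * len(tiles)
    for (tile_id, pixels, bundle), origin in zip(tiles, origins):
        summary.tiles_total += 1
        n_grid = ((config.crop_to or pixels.shape[0]) // config.patch_size) ** 2
        summary.patches_total += n_grid
        if config.enabled:
            if bundle is None or bundle.tissue_type is None:
                raise ValueError(
                    f"tile {tile_id}: region filtering requires a tissue-type map"
                )
            decision = tile_filter(
                bundle.tissue_type, bundle.vocabulary, config.tau_ref, tile_id=tile_id
            )
            summary.decisions.append(decision)
            if not decision.kept:
                continue
        summary.tiles_kept += 1

        tissue_map = bundle.tissue_type if bundle is not None else None
        cropped_map = None
        if tissue_map is not None and config.crop_to is not None:
            cropped_map, _ = center_crop(tissue_map, config.crop_to)
        elif tissue_map is not None:
            cropped_map = tissue_map

        for rec, patch_px in subdivide_tile(
            pixels,
            config.patch_size,
            slide_id=slide_id,
            tile_id=tile_id,
            tile_origin=origin,
            crop_to=config.crop_to,
        ):
            i, j = rec.grid_pos
            ps = config.patch_size
            patch_map = (
                cropped_map[i * ps : (i + 1) * ps, j * ps : (j + 1) * ps]
                if cropped_map is not None
                else None
            )
            kept, bg = patch_background_filter(
                patch_tissue_map=patch_map,
                patch_pixels=patch_px if patch_map is None else None,
                tau_bg=config.tau_bg,
            )
            rec.background_fraction = bg
            rec.kept = kept
            rows.append(
                {
                    "patch_id": rec.patch_id,
                    "slide_id": rec.slide_id,
                    "tile_id": rec.tile_id,
                    "row": rec.origin[0],
                    "col": rec.origin[1],
                    "background_fraction": bg,
                    "kept": kept,
                }
            )
            if kept:
                summary.patches_kept += 1
                kept_patches.append((rec, patch_px))
    manifest = pd.DataFrame(
        rows,
        columns=["patch_id", "slide_id", "tile_id", "row", "col", "background_fraction", "kept"],
    )
    return manifest, summary, kept_patches
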