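"""Deterministic synthetic fixtures for every pipeline input kind.

The clinical cohorts this kind of pipeline runs on are private, so the
package ships generators that emulate each input's *statistical*
structure with exactly known ground truth:

* :func:`gen_bundle` — annotation bundles with controlled tissue
  composition, planted glands and typed nuclei, plus a ledger of the
  exact pixel truths (areas, counts, analytic circularities) for
  oracle tests.
* :func:`gen_slide_image` — slide-like RGB rasters (tissue blobs on a
  white background) with controllable brightness/blur, plus the exact
  foreground mask, for tiling and QC tests.
* :func:`gen_bags` — labelled embedding bags where the class label is
  carried by a minority of planted signal instances (Gaussian mixture
  with a class-specific mean shift), mirroring the MIL assumption that
  sparse diagnostic lesions drive the slide label; optional pure-noise
  instances emulate uninformative patches that region filtering would
  remove.

Every generator is a pure function of (spec, seed).  None of this is
photorealistic histology; it exists to make algorithmic behavior
testable, not to model tissue appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .bundle import AnnotationBundle
from .embeddings import EmbeddingBag
from .vocab import LabelVocabulary, default_vocabulary


class PackingError(RuntimeError):
    """Raised when the requested shapes cannot be placed in the tile."""


# ---------------------------------------------------------------------------
# Annotation bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlandSpec:
    count: int = 0
    shape: str = "disc"  # disc | square | ellipse
    size: int = 15  # radius / half-side / major semi-axis
    aspect: float = 0.5  # minor/major for ellipses


@dataclass(frozen=True)
class BundleSpec:
    """Recipe for one synthetic annotation bundle.

    ``composition`` maps tissue class names to area fractions (sum
    <= 1; the remainder is background).  ``nuclei`` maps nucleus type
    names to ``(count, tissue_class)`` placements.  ``surface_rows``
    paints the top rows of the gland-type map as surface epithelium.
    """

    tile_size: int = 256
    composition: dict[str, float] = field(default_factory=dict)
    glands: GlandSpec = GlandSpec()
    nuclei: dict[str, tuple[int, str]] = field(default_factory=dict)
    surface_rows: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"composition fractions sum to {total} > 1")
        if any(f < 0 for f in self.composition.values()):
            raise ValueError("composition fractions must be non-negative")
        if self.glands.count < 0 or any(c < 0 for c, _ in self.nuclei.values()):
            raise ValueError("counts must be non-negative")


@dataclass
class BundleLedger:
    """Exact ground truths recorded while rasterizing a bundle."""

    tissue_areas: dict[str, int]
    nuclear_counts: dict[str, int]
    nuclear_counts_by_tissue: dict[tuple[str, str], int]
    gland_count: int
    gland_areas: list[int]
    gland_circularities_analytic: list[float]
    surface_epithelium_area: int
    nuclei_in_glands: int
    nuclei_in_surface_epithelium: int
    nucleus_centroids: list[tuple[int, int]]
    signal_free: bool = False


def _analytic_circularity(shape: str, size: int, aspect: float) -> float:
    if shape == "disc":
        return 1.0
    if shape == "square":
        return float(np.pi / 4.0)
    if shape == "ellipse":
        a, b = float(size), float(size) * aspect
        area = np.pi * a * b
        perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        return float(4 * np.pi * area / perim**2)
    raise ValueError(f"unknown gland shape {shape!r}")


def _shape_mask(shape: str, size: int, aspect: float) -> np.ndarray:
    if shape == "disc":
        r = size
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        return yy**2 + xx**2 <= r**2
    if shape == "square":
        return np.ones((2 * size, 2 * size), dtype=bool)
    if shape == "ellipse":
        a, b = size, max(1, int(round(size * aspect)))
        yy, xx = np.mgrid[-b : b + 1, -a : a + 1]
        return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    raise ValueError(f"unknown gland shape {shape!r}")


def gen_bundle(
    spec: BundleSpec,
    seed: int,
    *,
    tile_id: str = "tile",
    slide_id: str = "slide",
    origin: tuple[int, int] = (0, 0),
    vocabulary: Optional[LabelVocabulary] = None,
) -> tuple[AnnotationBundle, BundleLedger]:
    """Rasterize a synthetic bundle with an exact ground-truth ledger.

    Tissue classes fill exact pixel quotas in flattened row-major
    order (areas are exact by construction).  Glands are placed
    without mutual overlap by rejection sampling; nuclei are 3x3
    blocks whose centroid pixel is guaranteed to lie on the requested
    tissue class.  Raises :class:`PackingError` when the requested
    geometry cannot be placed.
    """
    rng = np.random.default_rng(seed)
    vocab = vocabulary or default_vocabulary()
    n = spec.tile_size
    total_px = n * n

    # --- tissue map: exact per-class pixel quotas, flattened fill ----
    flat = np.zeros(total_px, dtype=np.int32)
    cursor = 0
    tissue_areas = {name: 0 for name in vocab.tissue_classes}
    for name, frac in spec.composition.items():
        quota = int(round(frac * total_px))
        quota = min(quota, total_px - cursor)
        flat[cursor : cursor + quota] = vocab.tissue_code(name)
        tissue_areas[name] = quota
        cursor += quota
    tissue_areas["background"] = total_px - cursor
    tissue = flat.reshape(n, n)

    # --- glands -------------------------------------------------------
    gland_instance = np.zeros((n, n), dtype=np.int32)
    gland_type = np.zeros((n, n), dtype=np.int32)
    g_code = vocab.gland_code("gland")
    s_code = vocab.gland_code("surface_epithelium")
    if spec.surface_rows > 0:
        if spec.surface_rows > n:
            raise PackingError("surface band taller than tile")
        gland_type[: spec.surface_rows, :] = s_code
    surface_area = spec.surface_rows * n

    gland_areas: list[int] = []
    circ_analytic: list[float] = []
    stamp = _shape_mask(spec.glands.shape, spec.glands.size, spec.glands.aspect)
    sh, sw = stamp.shape
    row_min = spec.surface_rows  # keep glands clear of the surface band
    for gid in range(1, spec.glands.count + 1):
        placed = False
        for _ in range(2000):
            r0 = int(rng.integers(row_min, max(row_min + 1, n - sh)))
            c0 = int(rng.integers(0, max(1, n - sw)))
            if r0 + sh > n or c0 + sw > n:
                continue
            window = gland_instance[r0 : r0 + sh, c0 : c0 + sw]
            if (window[stamp] != 0).any():
                continue
            window[stamp] = gid
            gland_type[r0 : r0 + sh, c0 : c0 + sw][stamp] = g_code
            gland_areas.append(int(stamp.sum()))
            circ_analytic.append(
                _analytic_circularity(spec.glands.shape, spec.glands.size, spec.glands.aspect)
            )
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place gland {gid}/{spec.glands.count} "
                f"({spec.glands.shape}, size {spec.glands.size}) in {n}x{n} tile"
            )

    # --- nuclei: 3x3 blocks, centroid on the requested class ----------
    nucleus_instance = np.zeros((n, n), dtype=np.int32)
    nucleus_type = np.zeros((n, n), dtype=np.int32)
    occupied = np.zeros((n, n), dtype=bool)
    nuclear_counts = {name: 0 for name in vocab.nucleus_types}
    by_tissue: dict[tuple[str, str], int] = {}
    centroids: list[tuple[int, int]] = []
    in_gland = in_surface = 0
    nid = 0
    for ty_name, (count, tcl) in spec.nuclei.items():
        ty_code = vocab.nucleus_code(ty_name)
        # candidate centers: 3x3 footprint entirely on the class, 1 px margin
        cls_mask = tissue == vocab.tissue_code(tcl)
        eroded = ndimage.binary_erosion(cls_mask, structure=np.ones((3, 3)))
        eroded[:1, :] = eroded[-1:, :] = eroded[:, :1] = eroded[:, -1:] = False
        for _ in range(count):
            # spacing: footprint must not touch existing nuclei
            free = eroded & ~ndimage.binary_dilation(occupied, structure=np.ones((5, 5)))
            cand = np.flatnonzero(free.ravel())
            if cand.size == 0:
                raise PackingError(
                    f"no room for nucleus of type {ty_name} on tissue {tcl}"
                )
            pick = int(cand[rng.integers(cand.size)])
            r, c = divmod(pick, n)
            nid += 1
            nucleus_instance[r - 1 : r + 2, c - 1 : c + 2] = nid
            nucleus_type[r - 1 : r + 2, c - 1 : c + 2] = ty_code
            occupied[r - 1 : r + 2, c - 1 : c + 2] = True
            nuclear_counts[ty_name] += 1
            key = (ty_name, tcl)
            by_tissue[key] = by_tissue.get(key, 0) + 1
            centroids.append((r, c))
            gt = int(gland_type[r, c])
            if gt == g_code:
                in_gland += 1
            elif gt == s_code:
                in_surface += 1

    boundary = (nucleus_instance > 0) & (
        ndimage.minimum_filter(nucleus_instance, size=3) != nucleus_instance
    )

    bundle = AnnotationBundle(
        tile_id=tile_id,
        slide_id=slide_id,
        origin=origin,
        nucleus_instance=nucleus_instance,
        nucleus_type=nucleus_type,
        nucleus_boundary=boundary.astype(np.int32),
        gland_instance=gland_instance,
        gland_type=gland_type,
        lumen_instance=np.zeros((n, n), dtype=np.int32),
        tissue_type=tissue,
        vocabulary=vocab,
    )
    ledger = BundleLedger(
        tissue_areas=tissue_areas,
        nuclear_counts=nuclear_counts,
        nuclear_counts_by_tissue=by_tissue,
        gland_count=spec.glands.count,
        gland_areas=gland_areas,
        gland_circularities_analytic=circ_analytic,
        surface_epithelium_area=surface_area,
        nuclei_in_glands=in_gland,
        nuclei_in_surface_epithelium=in_surface,
        nucleus_centroids=centroids,
    )
    return bundle, ledger


# ---------------------------------------------------------------------------
# Slide-like images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideImageSpec:
    """Recipe for a slide-like RGB raster: tissue blobs on white."""

    height: int = 1024
    width: int = 1024
    n_blobs: int = 3
    blob_radius: int = 120
    tissue_color: tuple[int, int, int] = (200, 120, 160)
    noise_sigma: float = 12.0
    blur_sigma: float = 0.0
    brightness_shift: float = 0.0


def gen_slide_image(spec: SlideImageSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate a slide-like RGB image and its exact foreground mask.

    Blobs are discs of a tissue-like color with additive pixel noise
    (so sharpness metrics are non-trivial); optional Gaussian blur and
    a global brightness shift let QC-threshold tests dial quality up
    and down.  The returned mask marks the blob pixels (the truth the
    detector is compared against).
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    r = spec.blob_radius
    for _ in range(spec.n_blobs):
        cr = int(rng.integers(r, max(r + 1, h - r)))
        cc = int(rng.integers(r, max(r + 1, w - r)))
        yy, xx = np.ogrid[:h, :w]
        mask |= (yy - cr) ** 2 + (xx - cc) ** 2 <= r**2

    img = np.full((h, w, 3), 255.0)
    color = np.asarray(spec.tissue_color, dtype=float)
    img[mask] = color
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(h, w, 3))
        img[mask] += noise[mask]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    img = img + spec.brightness_shift
    return np.clip(img, 0, 255).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# Embedding bags with planted MIL structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BagSpec:
    """Recipe for a labelled bag cohort.

    Class 0 is the null class (background-only unless given its own
    rate); classes >= 1 plant signal instances drawn from
    ``N(separation * e_c, I)`` at ``signal_rate`` per instance, with at
    least one signal instance per bag so the label is always defined.
    ``noise_rate`` adds pure-noise instances (``N(0, noise_sigma^2 I)``)
    emulating uninformative patches a region filter would remove.
    """

    n_classes: int = 3
    n_per_class: int | tuple[int, ...] = 20
    bag_size: tuple[int, int] = (30, 60)
    signal_rate: float = 0.1
    dim: int = 32
    separation: float = 6.0
    noise_rate: float = 0.0
    noise_sigma: float = 6.0
    null_class_rate: float = 0.0
    label_values: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dim must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_classes >= 2 and self.signal_rate <= 0:
            raise ValueError(
                "signal_rate 0 for non-null classes leaves their labels undefined"
            )

    def counts(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * self.n_classes
        if len(self.n_per_class) != self.n_classes:
            raise ValueError("n_per_class length must equal n_classes")
        return tuple(self.n_per_class)

    def nhi_labels(self) -> tuple[int, ...]:
        """NHI grade carried by each fixture class.

        Defaults spread the classes across grades that stay distinct
        under every grouping scheme: a 3-class cohort uses grades
        (0, 2, 3) — remission, mild activity, severe activity — so the
        conventional three-class grouping keeps one class per group.
        """
        if self.label_values is not None:
            if len(self.label_values) != self.n_classes:
                raise ValueError("label_values length must equal n_classes")
            return tuple(self.label_values)
        defaults = {1: (0,), 2: (0, 2), 3: (0, 2, 3), 4: (0, 1, 2, 3), 5: (0, 1, 2, 3, 4)}
        return defaults[self.n_classes]


@dataclass
class BagLedger:
    """Per-bag instance annotations: which instances carry signal/noise."""

    signal_masks: list[np.ndarray]
    noise_masks: list[np.ndarray]


def _class_direction(c: int, dim: int) -> np.ndarray:
    e = np.zeros(dim)
    e[c % dim] = 1.0
    return e


def gen_bags(spec: BagSpec, seed: int) -> tuple[list[EmbeddingBag], BagLedger]:
    """Generate labelled embedding bags with planted signal instances.

    Background instances come from a shared standard normal; each
    class's signal instances shift by ``separation`` along a
    class-specific axis.  The ledger marks every signal and noise
    instance for attention-recovery and filtering tests.
    """
    rng = np.random.default_rng(seed)
    bags: list[EmbeddingBag] = []
    signal_masks: list[np.ndarray] = []
    noise_masks: list[np.ndarray] = []
    idx = 0
    nhi_of = spec.nhi_labels()
    for cls, n_bags in enumerate(spec.counts()):
        rate = spec.null_class_rate if cls == 0 else spec.signal_rate
        direction = _class_direction(cls, spec.dim)
        for _ in range(n_bags):
            n = int(rng.integers(spec.bag_size[0], spec.bag_size[1] + 1))
            sig = rng.random(n) < rate
            if rate > 0 and not sig.any():
                sig[rng.integers(n)] = True
            noise = (rng.random(n) < spec.noise_rate) & ~sig
            vecs = rng.standard_normal((n, spec.dim))
            vecs[sig] += spec.separation * direction
            vecs[noise] = rng.standard_normal((int(noise.sum()), spec.dim)) * spec.noise_sigma
            side = int(np.ceil(np.sqrt(n)))
            grid = np.array([(250 * (k // side), 250 * (k % side)) for k in range(n)])
            bag = EmbeddingBag(
                slide_id=f"S{idx:04d}",
                patient_id=f"P{idx:04d}",
                label=nhi_of[cls],
                vectors=vecs.astype(np.float32),
                patch_ids=[f"S{idx:04d}_p{k}" for k in range(n)],
                origins=grid,
            )
            bags.append(bag)
            signal_masks.append(sig)
            noise_masks.append(noise)
            idx += 1
    return bags, BagLedger(signal_masks=signal_masks, noise_masks=noise_masks)


def filter_bags(
    bags: Sequence[EmbeddingBag], ledger: BagLedger
) -> tuple[list[EmbeddingBag], BagLedger]:
    """Drop ledger-flagged noise instances from every bag.

    This is the fixture-level counterpart of region filtering: the
    generator knows exactly which instances are uninformative, so the
    "filtered pipeline" of an ablation experiment sees bags with those
    instances removed.  A bag never becomes empty (noise never covers
    a whole bag because signal instances are exempt).
    """
    out_bags: list[EmbeddingBag] = []
    out_sig: list[np.ndarray] = []
    out_noise: list[np.ndarray] = []
    for bag, sig, noise in zip(bags, ledger.signal_masks, ledger.noise_masks):
        keep = ~noise
        if not keep.any():
            keep = np.ones_like(keep)
        out_bags.append(
            EmbeddingBag(
                slide_id=bag.slide_id,
                patient_id=bag.patient_id,
                label=bag.label,
                vectors=bag.vectors[keep],
                patch_ids=[p for p, k in zip(bag.patch_ids, keep) if k],
                origins=bag.origins[keep],
            )
        )
        out_sig.append(sig[keep])
        out_noise.append(noise[keep])
    return out_bags, BagLedger(signal_masks=out_sig, noise_masks=out_noise)


def split_bags(
    bags: Sequence[EmbeddingBag],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> dict[str, list[int]]:
    """Patient-level stratified split of a bag cohort; returns bag
    *indices* per subset so parallel (filtered/unfiltered) views of
    the same cohort stay aligned."""
    import pandas as pd

    from .grouping import patient_level_split

    manifest = pd.DataFrame(
        {
            "slide_id": [b.slide_id for b in bags],
            "patient_id": [b.patient_id for b in bags],
            "nhi": [b.label for b in bags],
        }
    )
    split = patient_level_split(manifest, fractions, seed)
    by_slide = {b.slide_id: i for i, b in enumerate(bags)}
    return {name: sorted(by_slide[s] for s in ids) for name, ids in split.items()}
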