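"""Annotation bundles: co-registered label maps for one tile.

A bundle carries up to seven integer label maps for a single tile —
nucleus instance/type/boundary, gland instance/type, lumen instance and
tissue type — all with identical pixel dimensions.  Maps may be
individually absent (``None``): a segmenter that emits only a tissue
type map and a lumen instance map produces a perfectly valid bundle,
and absence is recorded explicitly rather than zero-filled.

Bundles round-trip bit-exactly through a single HDF5 container per
tile (:func:`write_bundle` / :func:`read_bundle`); dataset names are
fixed (``maps/<map_name>``) and the vocabulary, tile identity and tile
origin travel as attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Protocol, runtime_checkable

import h5py
import numpy as np

from .vocab import LabelVocabulary, default_vocabulary

#: fixed map names, and the HDF5 dataset layout ``maps/<name>``
MAP_NAMES = (
    "nucleus_instance",
    "nucleus_type",
    "nucleus_boundary",
    "gland_instance",
    "gland_type",
    "lumen_instance",
    "tissue_type",
)


class BundleFormatError(IOError):
    """Raised when a container file does not conform to the layout."""


class SegmenterNotConfiguredError(RuntimeError):
    """Raised when a real external segmenter is requested but absent."""


class Violation(NamedTuple):
    """One invariant violation: which map, which rule, human message."""

    map_name: str
    rule: str
    message: str


@dataclass
class AnnotationBundle:
    """Co-registered integer label maps for one tile.

    ``origin`` is the (row, col) pixel offset of the tile in its slide,
    0-based, top-left; the tile covers the half-open rectangle
    ``[row, row+h) x [col, col+w)``.
    """

    tile_id: str
    slide_id: str
    origin: tuple[int, int]
    nucleus_instance: Optional[np.ndarray] = None
    nucleus_type: Optional[np.ndarray] = None
    nucleus_boundary: Optional[np.ndarray] = None
    gland_instance: Optional[np.ndarray] = None
    gland_type: Optional[np.ndarray] = None
    lumen_instance: Optional[np.ndarray] = None
    tissue_type: Optional[np.ndarray] = None
    vocabulary: LabelVocabulary = field(default_factory=default_vocabulary)

    def maps(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (name, array) for every present map."""
        for name in MAP_NAMES:
            arr = getattr(self, name)
            if arr is not None:
                yield name, arr

    @property
    def shape(self) -> tuple[int, int]:
        for _, arr in self.maps():
            return arr.shape  # type: ignore[return-value]
        raise ValueError("bundle has no maps")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationBundle):
            return NotImplemented
        if (self.tile_id, self.slide_id, tuple(self.origin)) != (
            other.tile_id,
            other.slide_id,
            tuple(other.origin),
        ):
            return False
        if self.vocabulary.to_dict() != other.vocabulary.to_dict():
            return False
        for name in MAP_NAMES:
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


def validate_bundle(bundle: AnnotationBundle) -> list[Violation]:
    """Check every structural invariant; return violations, never raise.

    An empty list means the bundle is consistent.  Each violation names
    the offending map and the rule it breaks, so a catalogue of
    single-fault corruptions maps back to its faults.
    """
    out: list[Violation] = []
    present = dict(bundle.maps())
    if not present:
        out.append(Violation("*", "presence", "bundle contains no maps"))
        return out

    shapes = {name: arr.shape for name, arr in present.items()}
    ref_name, ref_shape = next(iter(shapes.items()))
    for name, arr in present.items():
        if arr.ndim != 2:
            out.append(Violation(name, "ndim", f"{name} is {arr.ndim}-D, expected 2-D"))
        elif arr.shape != ref_shape:
            out.append(
                Violation(name, "shape", f"{name} {arr.shape} != {ref_name} {ref_shape}")
            )
        if not np.issubdtype(arr.dtype, np.integer):
            out.append(Violation(name, "dtype", f"{name} dtype {arr.dtype} not integer"))
        elif arr.size and arr.min() < 0:
            out.append(Violation(name, "nonnegative", f"{name} contains negative codes"))

    vocab = bundle.vocabulary
    code_sets = {
        "tissue_type": set(vocab.tissue_classes.values()),
        "nucleus_type": set(vocab.nucleus_types.values()) | {0},
        "gland_type": set(vocab.gland_types.values()) | {0},
    }
    for name, allowed in code_sets.items():
        arr = present.get(name)
        if arr is None or not np.issubdtype(arr.dtype, np.integer):
            continue
        unknown = sorted(set(np.unique(arr).tolist()) - allowed)
        if unknown:
            out.append(
                Violation(name, "vocabulary", f"{name} codes {unknown} absent from vocabulary")
            )

    nt, ni = present.get("nucleus_type"), present.get("nucleus_instance")
    if nt is not None and ni is not None and nt.shape == ni.shape:
        if np.any((nt != 0) & (ni == 0)):
            out.append(
                Violation(
                    "nucleus_type",
                    "typed_without_instance",
                    "nucleus_type is nonzero where nucleus_instance is zero",
                )
            )
    return out


def _require_valid(bundle: AnnotationBundle) -> None:
    violations = validate_bundle(bundle)
    if violations:
        lines = "; ".join(f"{v.map_name}/{v.rule}: {v.message}" for v in violations)
        raise ValueError(f"invalid bundle: {lines}")


def write_bundle(bundle: AnnotationBundle, path: str | Path) -> None:
    """Write a validated bundle to a single HDF5 container.

    Layout: datasets ``maps/<name>`` for each present map; root
    attributes ``tile_id``, ``slide_id``, ``origin`` and the vocabulary
    as a JSON string.  Absent maps simply have no dataset.
    """
    _require_valid(bundle)
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("maps")
        for name, arr in bundle.maps():
            grp.create_dataset(name, data=arr, compression="gzip", compression_opts=1)
        f.attrs["tile_id"] = bundle.tile_id
        f.attrs["slide_id"] = bundle.slide_id
        f.attrs["origin"] = np.asarray(bundle.origin, dtype=np.int64)
        f.attrs["vocabulary"] = json.dumps(bundle.vocabulary.to_dict())
        f.attrs["present_maps"] = json.dumps([n for n, _ in bundle.maps()])


def read_bundle(path: str | Path) -> AnnotationBundle:
    """Read a bundle container; inverse of :func:`write_bundle`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in ("tile_id", "slide_id", "origin", "vocabulary", "present_maps"):
            if attr not in f.attrs:
                raise BundleFormatError(f"{path}: missing attribute {attr!r}")
        declared = json.loads(f.attrs["present_maps"])
        grp = f.get("maps")
        if grp is None:
            raise BundleFormatError(f"{path}: missing 'maps' group")
        kwargs: dict[str, np.ndarray] = {}
        for name in declared:
            if name not in MAP_NAMES:
                raise BundleFormatError(f"{path}: unknown map dataset {name!r}")
            if name not in grp:
                raise BundleFormatError(f"{path}: declared map {name!r} has no dataset")
            kwargs[name] = grp[name][()]
        bundle = AnnotationBundle(
            tile_id=str(f.attrs["tile_id"]),
            slide_id=str(f.attrs["slide_id"]),
            origin=tuple(int(v) for v in f.attrs["origin"]),
            vocabulary=LabelVocabulary.from_dict(json.loads(f.attrs["vocabulary"])),
            **kwargs,
        )
    violations = validate_bundle(bundle)
    if violations:
        v = violations[0]
        raise BundleFormatError(f"{path}: invalid stored bundle ({v.map_name}/{v.rule})")
    return bundle


# ---------------------------------------------------------------------------
# Segmenter adapter contract
# ---------------------------------------------------------------------------


@runtime_checkable
class SegmenterAdapter(Protocol):
    """Contract for a pluggable tissue/nucleus segmenter.

    Implementations take an RGB tile and return an
    :class:`AnnotationBundle` with whatever map subset the backing
    model produces.  The external model itself is out of scope; the
    shipped :class:`MockSegmenter` keeps the pipeline runnable offline.
    """

    def segment(
        self, tile: np.ndarray, *, tile_id: str, slide_id: str, origin: tuple[int, int]
    ) -> AnnotationBundle: ...


class MockSegmenter:
    """Deterministic rule-based stand-in segmenter (synthetic).

    Thresholds the tile to a tissue/background partition, classifies
    darker tissue pixels as stroma, and labels small dark foci as
    lymphocyte nuclei.  Output is a pure function of (pixels, seed), so
    the end-to-end pipeline is exercisable with no external model; it
    makes no claim of histological accuracy.
    """

    def __init__(self, seed: int = 0, vocabulary: LabelVocabulary | None = None,
                 tissue_threshold: float = 220.0, nucleus_threshold: float = 100.0):
        self.seed = int(seed)
        self.vocabulary = vocabulary or default_vocabulary()
        self.tissue_threshold = float(tissue_threshold)
        self.nucleus_threshold = float(nucleus_threshold)

    def segment(
        self, tile: np.ndarray, *, tile_id: str, slide_id: str, origin: tuple[int, int]
    ) -> AnnotationBundle:
        from scipy import ndimage

        if tile.ndim != 3 or tile.shape[2] != 3:
            raise ValueError("mock segmenter expects an RGB tile (h, w, 3)")
        gray = tile.astype(np.float64).mean(axis=2)
        vocab = self.vocabulary
        tissue = np.zeros(gray.shape, dtype=np.int32)
        tissue[gray < self.tissue_threshold] = vocab.tissue_code("stroma")
        nuc_mask = gray < self.nucleus_threshold
        nuc_instance, _ = ndimage.label(nuc_mask)
        nuc_instance = nuc_instance.astype(np.int32)
        nuc_type = np.where(nuc_instance > 0, vocab.nucleus_code("lymphocyte"), 0).astype(
            np.int32
        )
        boundary = (nuc_instance > 0) & (
            ndimage.minimum_filter(nuc_instance, size=3) != nuc_instance
        )
        return AnnotationBundle(
            tile_id=tile_id,
            slide_id=slide_id,
            origin=origin,
            nucleus_instance=nuc_instance,
            nucleus_type=nuc_type,
            nucleus_boundary=boundary.astype(np.int32),
            tissue_type=tissue,
            vocabulary=vocab,
        )


def get_segmenter(name: str | None, **kwargs) -> SegmenterAdapter:
    """Resolve a segmenter by name.

    ``"mock"`` returns the bundled deterministic segmenter.  Any other
    name (or ``None``) raises :class:`SegmenterNotConfiguredError`:
    there is never a silent fallback to the mock.
    """
    if name == "mock":
        return MockSegmenter(**kwargs)
    raise SegmenterNotConfiguredError(
        f"external segmenter {name!r} not configured; pass an adapter implementing "
        "SegmenterAdapter, or use the explicit 'mock' segmenter for offline runs"
    )


__all__ = [
    "MAP_NAMES",
    "AnnotationBundle",
    "Violation",
    "BundleFormatError",
    "SegmenterNotConfiguredError",
    "validate_bundle",
    "write_bundle",
    "read_bundle",
    "SegmenterAdapter",
    "MockSegmenter",
    "get_segmenter",
]
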