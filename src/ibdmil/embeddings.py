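"""Frozen-encoder adapter and per-patch embedding storage.

Patch embeddings come from a frozen external encoder (histology
foundation models emit 1024-D or 2560-D vectors depending on the
backbone).  The encoder is a pluggable contract; the shipped
:class:`MockEncoder` is a seeded random linear map of downsampled
patch pixels, which keeps the whole pipeline executable and
deterministic with no model download (it is synthetic and carries no
histological meaning).

Embeddings persist in one HDF5 container per slide, indexed by patient
id and patch base name, so a bag loads in a single read and
patient-level splits induce disjoint embedding sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import h5py
import numpy as np
from skimage.transform import resize


@runtime_checkable
class EncoderAdapter(Protocol):
    """Contract for a frozen patch encoder."""

    dim: int

    def encode(self, patch: np.ndarray) -> np.ndarray: ...


class MockEncoder:
    """Deterministic synthetic encoder: seeded random projection.

    The patch is resized to a small fixed raster, flattened, and
    passed through a fixed Gaussian random matrix drawn from ``seed``.
    Output is a pure function of (patch pixels, seed); any single
    pixel change propagates to the vector because the projection is
    dense.
    """

    def __init__(self, dim: int = 1024, seed: int = 0, input_side: int = 16):
        self.dim = int(dim)
        self.seed = int(seed)
        self.input_side = int(input_side)
        n_in = self.input_side * self.input_side * 3
        rng = np.random.default_rng(self.seed)
        self._proj = rng.standard_normal((self.dim, n_in)).astype(np.float32) / np.sqrt(n_in)

    def encode(self, patch: np.ndarray) -> np.ndarray:
        arr = np.asarray(patch, dtype=np.float64)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        arr = resize(
            arr / 255.0,
            (self.input_side, self.input_side, 3),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        vec = self._proj @ arr.ravel().astype(np.float32)
        return vec.astype(np.float32)


@dataclass
class PatchEmbedding:
    patch_id: str
    patient_id: str
    slide_id: str
    vector: np.ndarray


@dataclass
class EmbeddingBag:
    """All patch embeddings of one slide, in manifest order."""

    slide_id: str
    patient_id: str
    label: int  # NHI grade 0-4
    vectors: np.ndarray  # (n_patches, dim)
    patch_ids: list[str]
    origins: np.ndarray  # (n_patches, 2) slide pixels (row, col)

    def __post_init__(self) -> None:
        if len(self.vectors) == 0:
            raise ValueError(f"bag {self.slide_id} is empty")
        if len(self.patch_ids) != len(self.vectors):
            raise ValueError("patch_ids and vectors disagree in length")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError(f"bag {self.slide_id} contains non-finite embeddings")

    @property
    def n(self) -> int:
        return len(self.patch_ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class EmbeddingStore:
    """One HDF5 container per slide under a root directory.

    Layout per file ``<slide_id>.h5``: datasets ``vectors`` (n, dim),
    ``patch_ids`` (n, utf-8), ``origins`` (n, 2); attributes
    ``slide_id``, ``patient_id``, ``label``, ``dim``.
    """

    def __init__(self, root: str | Path, dim: int | None = None):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.dim = dim

    def _path(self, slide_id: str) -> Path:
        return self.root / f"{slide_id}.h5"

    def store_embeddings(
        self,
        slide_id: str,
        patient_id: str,
        label: int,
        patch_ids: Sequence[str],
        vectors: np.ndarray,
        origins: np.ndarray | Sequence[tuple[int, int]],
    ) -> None:
        """Persist one slide's embeddings; keys must be unique.

        Appending to an existing slide is allowed but any duplicate
        patch id — within the call or against stored keys — raises.
        """
        vectors = np.asarray(vectors, dtype=np.float32)
        origins = np.asarray(origins, dtype=np.int64)
        ids = [str(p) for p in patch_ids]
        if len(set(ids)) != len(ids):
            raise KeyError(f"duplicate patch ids in insert for slide {slide_id}")
        if vectors.ndim != 2 or len(ids) != len(vectors) or len(origins) != len(vectors):
            raise ValueError("patch_ids, vectors and origins must align")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embeddings must be finite")
        if self.dim is not None and vectors.shape[1] != self.dim:
            raise ValueError(
                f"embedding dim {vectors.shape[1]} != store dim {self.dim}"
            )

        path = self._path(slide_id)
        if path.exists():
            with h5py.File(path, "a") as f:
                existing = [s.decode() for s in f["patch_ids"][()]]
                clash = set(existing) & set(ids)
                if clash:
                    raise KeyError(f"duplicate patch ids for slide {slide_id}: {sorted(clash)[:5]}")
                if f["vectors"].shape[1] != vectors.shape[1]:
                    raise ValueError("embedding dimension mismatch with stored vectors")
                all_vecs = np.concatenate([f["vectors"][()], vectors])
                all_ids = existing + ids
                all_orig = np.concatenate([f["origins"][()], origins])
                del f["vectors"], f["patch_ids"], f["origins"]
                f.create_dataset("vectors", data=all_vecs)
                f.create_dataset("patch_ids", data=np.array(all_ids, dtype="S"))
                f.create_dataset("origins", data=all_orig)
        else:
            with h5py.File(path, "w") as f:
                f.create_dataset("vectors", data=vectors)
                f.create_dataset("patch_ids", data=np.array(ids, dtype="S"))
                f.create_dataset("origins", data=origins)
                f.attrs["slide_id"] = slide_id
                f.attrs["patient_id"] = patient_id
                f.attrs["label"] = int(label)
                f.attrs["dim"] = vectors.shape[1]

    def load_bag(self, slide_id: str) -> EmbeddingBag:
        """Load one slide's bag, embeddings in stored (manifest) order."""
        path = self._path(slide_id)
        if not path.exists():
            raise KeyError(f"unknown slide {slide_id!r} in store {self.root}")
        with h5py.File(path, "r") as f:
            return EmbeddingBag(
                slide_id=str(f.attrs["slide_id"]),
                patient_id=str(f.attrs["patient_id"]),
                label=int(f.attrs["label"]),
                vectors=f["vectors"][()].astype(np.float32),
                patch_ids=[s.decode() for s in f["patch_ids"][()]],
                origins=f["origins"][()],
            )

    def slide_ids(self) -> list[str]:
        return sorted(p.stem for p in self.root.glob("*.h5"))


def embed_patches(
    encoder: EncoderAdapter,
    patches: Sequence[tuple[str, np.ndarray, tuple[int, int]]],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Encode ``(patch_id, pixels, origin)`` triples into aligned arrays."""
    ids, vecs, origins = [], [], []
    for patch_id, pixels, origin in patches:
        v = encoder.encode(pixels)
        if v.shape != (encoder.dim,):
            raise ValueError(f"encoder returned shape {v.shape}, expected ({encoder.dim},)")
        ids.append(patch_id)
        vecs.append(v)
        origins.append(origin)
    return ids, np.asarray(vecs, dtype=np.float32), np.asarray(origins, dtype=np.int64)
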