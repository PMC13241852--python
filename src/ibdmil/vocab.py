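"""Label vocabularies for multi-level segmentation maps.

A vocabulary binds the integer codes appearing in tissue-type,
nucleus-type and gland-type label maps to named histological
categories.  Code 0 is reserved for background/no-instance in every
map family.  The default vocabulary covers the tissue and nuclear
classes a colorectal multitask segmenter emits; projects with a
different segmenter override it from a YAML/JSON config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

# Tissue classes that must exist in any usable vocabulary.
REQUIRED_TISSUE_CLASSES = (
    "background",
    "normal_epithelium",
    "abnormal_epithelium",
    "inflammatory",
    "debris",
    "stroma",
    "muscle",
    "mucous",
    "adipose",
)

REQUIRED_NUCLEUS_TYPES = ("epithelial", "lymphocyte", "neutrophil")

#: tissue classes counted as baseline reference tissue by the region filter
REFERENCE_TISSUE_CLASSES = ("stroma", "normal_epithelium")

#: tissue classes whose presence marks a tile as diagnostically relevant
IBD_TISSUE_CLASSES = ("abnormal_epithelium", "inflammatory", "debris")

#: tissue classes counted as epithelium for the epithelial/stromal ratio
EPITHELIUM_TISSUE_CLASSES = ("normal_epithelium", "abnormal_epithelium")


class VocabularyError(ValueError):
    """Raised when a vocabulary violates its structural invariants."""


@dataclass(frozen=True)
class LabelVocabulary:
    """Named integer codes for each label-map family.

    Parameters
    ----------
    tissue_classes
        Mapping of tissue class name -> integer code; must contain all
        of :data:`REQUIRED_TISSUE_CLASSES` and map ``background`` to 0.
    nucleus_types
        Mapping of nucleus type name -> positive integer code; must
        contain all of :data:`REQUIRED_NUCLEUS_TYPES`.  Code 0 means
        "no nucleus" and is implicit.
    gland_types
        Mapping for the gland-type map, distinguishing glandular from
        surface epithelium.
    """

    tissue_classes: Mapping[str, int]
    nucleus_types: Mapping[str, int]
    gland_types: Mapping[str, int] = field(
        default_factory=lambda: {"gland": 1, "surface_epithelium": 2}
    )

    def __post_init__(self) -> None:
        for family, mapping in (
            ("tissue_classes", self.tissue_classes),
            ("nucleus_types", self.nucleus_types),
            ("gland_types", self.gland_types),
        ):
            codes = list(mapping.values())
            if any((not isinstance(c, int)) or c < 0 for c in codes):
                raise VocabularyError(f"{family}: codes must be non-negative integers")
            if len(set(codes)) != len(codes):
                raise VocabularyError(f"{family}: duplicate codes {sorted(codes)}")
        if self.tissue_classes.get("background") != 0:
            raise VocabularyError("tissue_classes must map 'background' to code 0")
        missing = [n for n in REQUIRED_TISSUE_CLASSES if n not in self.tissue_classes]
        if missing:
            raise VocabularyError(f"tissue_classes missing required names {missing}")
        missing = [n for n in REQUIRED_NUCLEUS_TYPES if n not in self.nucleus_types]
        if missing:
            raise VocabularyError(f"nucleus_types missing required names {missing}")
        if any(c == 0 for c in self.nucleus_types.values()):
            raise VocabularyError("nucleus_types may not use code 0 (reserved)")
        if any(c == 0 for c in self.gland_types.values()):
            raise VocabularyError("gland_types may not use code 0 (reserved)")

    # -- lookups -------------------------------------------------------
    def tissue_code(self, name: str) -> int:
        return self.tissue_classes[name]

    def nucleus_code(self, name: str) -> int:
        return self.nucleus_types[name]

    def gland_code(self, name: str) -> int:
        return self.gland_types[name]

    def tissue_name(self, code: int) -> str:
        for name, c in self.tissue_classes.items():
            if c == code:
                return name
        raise KeyError(code)

    def nucleus_name(self, code: int) -> str:
        for name, c in self.nucleus_types.items():
            if c == code:
                return name
        raise KeyError(code)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tissue_classes": dict(self.tissue_classes),
            "nucleus_types": dict(self.nucleus_types),
            "gland_types": dict(self.gland_types),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LabelVocabulary":
        return cls(
            tissue_classes=dict(d["tissue_classes"]),
            nucleus_types=dict(d["nucleus_types"]),
            gland_types=dict(d.get("gland_types", {"gland": 1, "surface_epithelium": 2})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelVocabulary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_vocabulary() -> LabelVocabulary:
    """Vocabulary matching the named classes of a colorectal multitask
    segmenter (tissue) and its nuclear typing head."""
    return LabelVocabulary(
        tissue_classes={
            "background": 0,
            "normal_epithelium": 1,
            "abnormal_epithelium": 2,
            "inflammatory": 3,
            "debris": 4,
            "stroma": 5,
            "muscle": 6,
            "mucous": 7,
            "adipose": 8,
        },
        nucleus_types={
            "epithelial": 1,
            "lymphocyte": 2,
            "plasma": 3,
            "neutrophil": 4,
            "eosinophil": 5,
            "connective": 6,
        },
    )
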