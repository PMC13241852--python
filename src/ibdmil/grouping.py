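"""Nancy Histological Index (NHI) label grouping and patient-level splits.

The NHI grades ulcerative-colitis activity 0-4.  Downstream tasks use
either the raw five grades or clinically motivated collapsed schemes:

* ``type_A`` (conventional): 0-1 "No Active Colitis", 2 "Mild Active
  Colitis", 3-4 "Severe Active Colitis".
* ``type_B`` (remission-separating): 0 "No Disease", 1-2 "Low-grade
  Inflammation", 3-4 "Severe Active Colitis".
* ``binary``: inactive (NHI < 2) vs active (NHI >= 2).

Because one patient contributes biopsies from up to four anatomical
locations, data splits must happen at the patient level; a slide-level
split would leak near-duplicate tissue between train and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GroupingScheme:
    """A total surjective mapping from NHI grades 0-4 to class indices."""

    name: str
    mapping: tuple[int, int, int, int, int]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.class_names)
        if set(self.mapping) != set(range(k)):
            raise ValueError(f"{self.name}: mapping must be surjective onto 0..{k-1}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def map_nhi(self, nhi: int) -> int:
        if nhi not in range(5):
            raise ValueError(f"NHI grade {nhi!r} out of range 0-4")
        return self.mapping[nhi]


GROUPINGS: Mapping[str, GroupingScheme] = {
    "five_class": GroupingScheme(
        "five_class", (0, 1, 2, 3, 4), ("NHI-0", "NHI-1", "NHI-2", "NHI-3", "NHI-4")
    ),
    "type_A": GroupingScheme(
        "type_A",
        (0, 0, 1, 2, 2),
        ("No Active Colitis", "Mild Active Colitis", "Severe Active Colitis"),
    ),
    "type_B": GroupingScheme(
        "type_B",
        (0, 1, 1, 2, 2),
        ("No Disease", "Low-grade Inflammation", "Severe Active Colitis"),
    ),
    "binary": GroupingScheme("binary", (0, 0, 1, 1, 1), ("inactive", "active")),
}


def get_grouping(name: str) -> GroupingScheme:
    try:
        return GROUPINGS[name]
    except KeyError:
        raise KeyError(f"unknown grouping {name!r}; choose from {sorted(GROUPINGS)}")


def group_labels(nhi: int, scheme: GroupingScheme | str) -> int:
    """Map one NHI grade through a grouping scheme."""
    if isinstance(scheme, str):
        scheme = get_grouping(scheme)
    return scheme.map_nhi(int(nhi))


def patient_max_label(slide_labels: Sequence[int]) -> int:
    """Patient-level NHI: the worst (maximum) grade over the patient's
    biopsy slides, matching how clinicians summarize multi-site biopsies."""
    labels = [int(v) for v in slide_labels]
    if not labels:
        raise ValueError("patient has no slides")
    if any(v not in range(5) for v in labels):
        raise ValueError(f"NHI grades out of range in {labels}")
    return max(labels)


def patient_level_split(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    *,
    stratify_scheme: GroupingScheme | str | None = None,
) -> dict[str, set[str]]:
    """Deterministic stratified train/val/test split at the patient level.

    ``manifest`` needs ``slide_id``, ``patient_id`` and ``nhi`` columns.
    Patients are stratified by their maximum NHI (optionally collapsed
    through ``stratify_scheme``), shuffled with ``seed``, and allocated
    to subsets by largest-remainder apportionment within each stratum,
    so every patient's slides land in exactly one subset.  Strata with
    fewer than 3 patients trigger a warning and fall back to assigning
    those patients to the training set.

    Returns ``{"train": slide_ids, "val": ..., "test": ...}``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions {fractions} must sum to 1")
    required = {"slide_id", "patient_id", "nhi"}
    if required - set(manifest.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(manifest.columns))}")

    scheme = None
    if stratify_scheme is not None:
        scheme = (
            get_grouping(stratify_scheme) if isinstance(stratify_scheme, str) else stratify_scheme
        )

    pat_label = manifest.groupby("patient_id")["nhi"].apply(lambda s: patient_max_label(list(s)))
    if scheme is not None:
        pat_label = pat_label.map(scheme.map_nhi)

    rng = np.random.default_rng(seed)
    subset_of: dict[str, str] = {}
    names = ("train", "val", "test")
    for label in sorted(pat_label.unique()):
        patients = sorted(pat_label.index[pat_label == label].tolist())
        if len(patients) < 3:
            warnings.warn(
                f"stratum {label} has {len(patients)} patient(s); assigning to train",
                stacklevel=2,
            )
            for p in patients:
                subset_of[p] = "train"
            continue
        order = rng.permutation(len(patients))
        shuffled = [patients[i] for i in order]
        # largest-remainder apportionment of stratum size over the fractions
        quotas = np.array(fractions) * len(patients)
        base = np.floor(quotas).astype(int)
        rem = len(patients) - base.sum()
        frac_order = np.argsort(-(quotas - base))
        for i in range(rem):
            base[frac_order[i]] += 1
        idx = 0
        for name, n in zip(names, base):
            for p in shuffled[idx : idx + n]:
                subset_of[p] = name
            idx += n

    out: dict[str, set[str]] = {name: set() for name in names}
    for _, row in manifest.iterrows():
        out[subset_of[row["patient_id"]]].add(row["slide_id"])
    return out
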