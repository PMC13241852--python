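"""Reference tabulations used in worked examples and checks.

The slide-count table below is the published slide-level distribution
of Nancy index grades across the four standard biopsy locations in a
single-center IBD inception cohort (1743 whole-slide images from 442
patients).  It ships here as printed numbers only — the underlying
images are not public — and serves as a realistic input for the
tabulation utilities.
"""

from __future__ import annotations

import pandas as pd

#: slide counts per (location, NHI grade); grades 0..4 left to right
COHORT_SLIDE_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "terminal_ileum": (270, 27, 84, 6, 15),
    "right_colon": (223, 44, 124, 45, 17),
    "left_colon": (197, 35, 106, 70, 18),
    "rectum": (108, 45, 183, 113, 13),
}

#: patient-level distribution of maximum NHI grades (n = 442 patients)
COHORT_PATIENT_MAX_COUNTS: tuple[int, int, int, int, int] = (63, 52, 204, 145, 52)


def cohort_slide_manifest() -> pd.DataFrame:
    """Expand the published slide-count table into a per-slide manifest.

    Returns one row per slide with ``slide_id``, ``location`` and
    ``nhi`` columns — the input format of
    :func:`ibdmil.stats.tabulate_label_distribution`.
    """
    rows = []
    i = 0
    for location, counts in COHORT_SLIDE_COUNTS.items():
        for nhi, count in enumerate(counts):
            for _ in range(count):
                rows.append({"slide_id": f"W{i:04d}", "location": location, "nhi": nhi})
                i += 1
    return pd.DataFrame(rows)
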