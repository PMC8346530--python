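"""Informational vs operational super-class comparisons.

COG/KOG one-letter functional categories split into two super-classes:
*informational* (genetic-information storage and processing: J, A, K, L, B)
and *operational* (everything else — metabolism, transport, regulation,
cellular processes).  Group differences in GRAVY and T2-A2 are tested with
an unpaired two-sample t-test; subcellular-location contrasts (cytoplasmic
vs cytoplasmic membrane) with a 2x2 chi-square.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "INFORMATIONAL_LETTERS",
    "OPERATIONAL_LETTERS",
    "FunctionAnnotation",
    "GroupComparison",
    "LocationTable",
    "classify_super_class",
    "compare_metric",
    "location_chi2",
    "read_annotation_table",
    "read_location_table",
    "write_comparison_tsv",
]

#: Information storage and processing categories (translation, transcription,
#: replication, chromatin, RNA processing).
INFORMATIONAL_LETTERS = frozenset("ABJKL")

#: The remaining 21 single-letter categories.
OPERATIONAL_LETTERS = frozenset(string.ascii_uppercase) - INFORMATIONAL_LETTERS


@dataclass(frozen=True)
class FunctionAnnotation:
    """One protein's COG/KOG letters and resolved super-class."""

    protein_id: str
    cog_letters: str
    super_class: str  # informational | operational | mixed | unassigned


def classify_super_class(
    letters: str,
    informational: frozenset[str] = INFORMATIONAL_LETTERS,
    operational: frozenset[str] = OPERATIONAL_LETTERS,
) -> str:
    """Resolve a letter set to a super-class.

    ``informational`` iff every letter is informational, ``operational`` iff
    every letter is operational; a mix of the two is ``mixed`` (excluded from
    both groups by default), and an empty or non-alphabetic set is
    ``unassigned``.
    """
    letter_set = {c for c in letters.upper() if c in string.ascii_uppercase}
    if not letter_set:
        return "unassigned"
    if letter_set <= informational:
        return "informational"
    if letter_set <= operational:
        return "operational"
    if letter_set <= (informational | operational):
        return "mixed"
    return "unassigned"


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_informational: float
    mean_operational: float
    n_informational: int
    n_operational: int
    t: float
    p: float


def compare_metric(
    values_info: Sequence[float],
    values_op: Sequence[float],
    metric: str = "metric",
    equal_var: bool = True,
) -> GroupComparison:
    """Unpaired two-sample t-test between the two super-classes.

    Student's equal-variance test by default; ``equal_var=False`` switches to
    Welch.  Both groups need at least two observations.  If both groups are
    degenerate (zero variance) the test is undefined and t/p come back NaN.
    """
    a = np.asarray(values_info, dtype=float)
    b = np.asarray(values_op, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 observations per group, got ({len(a)}, {len(b)})"
        )
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            # identical constant groups: no difference by definition
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float("nan"), float("nan")
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        metric=metric,
        mean_informational=float(a.mean()),
        mean_operational=float(b.mean()),
        n_informational=len(a),
        n_operational=len(b),
        t=float(t_stat),
        p=float(p),
    )


@dataclass(frozen=True)
class LocationTable:
    """2x2 (super-class x location) contingency result."""

    counts: tuple[tuple[int, int], tuple[int, int]]  # rows: info, op
    chi2: float
    p: float


def location_chi2(
    counts: Sequence[Sequence[int]], correction: bool = False
) -> LocationTable:
    """Chi-square test of independence on a 2x2 location table.

    Rows are super-classes, columns location types (cytoplasmic,
    cytoplasmic membrane).  Yates continuity correction off by default.
    Raises ``ValueError`` on negative entries or a zero margin.
    """
    arr = np.asarray(counts, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return LocationTable(
        counts=((int(arr[0, 0]), int(arr[0, 1])), (int(arr[1, 0]), int(arr[1, 1]))),
        chi2=float(chi2),
        p=float(p),
    )


def read_annotation_table(path: str | Path) -> list[FunctionAnnotation]:
    """Read a tab-separated functional annotation table.

    Expected columns: protein_id, cog_id, letters[, description]; two-column
    (protein_id, letters) files are also accepted.  Lines starting with ``#``
    are skipped.
    """
    path = Path(path)
    out: list[FunctionAnnotation] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{i}: expected >= 2 tab-separated fields")
        protein_id = fields[0].strip()
        letters = (fields[2] if len(fields) >= 3 else fields[1]).strip()
        out.append(
            FunctionAnnotation(
                protein_id=protein_id,
                cog_letters=letters,
                super_class=classify_super_class(letters),
            )
        )
    return out


def read_location_table(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Read (protein_id, location_label) TSV into an id -> canonical-label map.

    ``label_map`` translates free-form labels to {cytoplasmic, cytoplasmic
    membrane, other}; unlisted labels map to ``other``.
    """
    path = Path(path)
    canonical = {"cytoplasmic": "cytoplasmic", "cytoplasmic membrane": "cytoplasmic membrane"}
    out: dict[str, str] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        pid, label = fields[0].strip(), fields[1].strip().lower()
        if label_map is not None:
            label = label_map.get(label, "other")
        else:
            label = canonical.get(label, "other")
        out[pid] = label
    return out


def write_comparison_tsv(
    comparisons: Sequence[GroupComparison], path: str | Path
) -> None:
    lines = [
        "metric\tmean_informational\tmean_operational\tn_informational\t"
        "n_operational\tt\tp"
    ]
    for c in comparisons:
        lines.append(
            f"{c.metric}\t{c.mean_informational!r}\t{c.mean_operational!r}\t"
            f"{c.n_informational}\t{c.n_operational}\t{c.t!r}\t{c.p!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
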