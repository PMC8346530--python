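"""Exhaustive codon-position grouping/value-assignment catalogue.

A *value assignment* partitions the four nucleotides at one codon position
into 2-4 groups and gives each group a number; the groups' value sets are
fixed at {-1,+1} (two groups), {-1,0,+1} (three groups) and {-2,-1,+1,+2}
(four groups).  Per position there are exactly 74 assignments:

    4 groups:  1 partition  x 4! orderings            = 24
    3 groups:  6 partitions x 3! orderings            = 36
    2 groups (1 vs 3): 4 partitions x 2 orientations  =  8
    2 groups (2 vs 2): 6 partitions x 1 orientation   =  6

(the 2-vs-2 family counts the C(4,2) = 6 choices of the pair valued -1, the
complementary pair taking +1, so each bipartition appears in both sign
orientations and no further per-split orderings exist).  Each amino acid then gets a numeric position
value: the unweighted mean of the assignment values over the nucleotides at
that position across its sense codons.  Correlating that 20-vector against a
property scale (Pearson, n = 20, two-sided p from t with 18 df) yields one
catalogue record; the full catalogue over 3 positions and 13 properties has
74 x 3 x 13 = 2886 records.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .aa_tables import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    CodonTable,
    PropertyScale,
    PROPERTY_NAMES,
    STANDARD_TABLE,
    load_property_scale,
)

__all__ = [
    "GROUP_TYPES",
    "AssociationRecord",
    "Catalogue",
    "ValueAssignment",
    "aa_position_value",
    "best_per_cell",
    "build_catalogue",
    "combined_assoc",
    "enumerate_assignments",
    "parse_assignment_string",
    "pearson_assoc",
    "position_value_vector",
    "write_catalogue_tsv",
]

GROUP_TYPES = ("four_group", "three_group", "two_group_1v3", "two_group_2v2")


@dataclass(frozen=True)
class ValueAssignment:
    """Numeric values for the four nucleotides at one codon position."""

    position: int
    values: Mapping[str, float]
    group_type: str

    def __post_init__(self) -> None:
        if self.position not in (1, 2, 3):
            raise ValueError(f"codon position must be 1, 2 or 3, got {self.position}")
        if set(self.values) != set(NUCLEOTIDES):
            raise ValueError("assignment must value exactly A, C, G, T")
        if self.group_type not in GROUP_TYPES:
            raise ValueError(f"unknown group_type {self.group_type!r}")

    @property
    def n_groups(self) -> int:
        return len(set(self.values.values()))

    def negated(self) -> "ValueAssignment":
        return ValueAssignment(
            position=self.position,
            values={n: -v for n, v in self.values.items()},
            group_type=self.group_type,
        )

    def to_string(self) -> str:
        """Compact grouped form, e.g. ``"A:-1,T:1,GC:0"``.

        Groups are ordered by descending value; nucleotides within a group
        keep A,T,G,C order (the order the field's tables print).  The format
        round-trips through :func:`parse_assignment_string` bit-exactly.
        """
        by_value: dict[float, list[str]] = {}
        for nuc in ("A", "T", "G", "C"):
            by_value.setdefault(self.values[nuc], []).append(nuc)
        parts = []
        for val in sorted(by_value, reverse=True):
            num = int(val) if float(val).is_integer() else val
            parts.append(f"{''.join(by_value[val])}:{num}")
        return ",".join(parts)


def parse_assignment_string(
    text: str, position: int, group_type: str | None = None
) -> ValueAssignment:
    """Inverse of :meth:`ValueAssignment.to_string`.

    Accepts any ``GROUP:value`` comma list, e.g. ``"T:-1,CAG:1"``.  The
    group_type is inferred from the value multiset when not given.
    """
    values: dict[str, float] = {}
    for part in text.split(","):
        nucs, _, val = part.partition(":")
        for nuc in nucs.strip():
            values[nuc] = float(val)
    if group_type is None:
        n_groups = len(set(values.values()))
        if n_groups == 4:
            group_type = "four_group"
        elif n_groups == 3:
            group_type = "three_group"
        else:
            sizes = sorted(
                sum(1 for v in values.values() if v == u)
                for u in set(values.values())
            )
            group_type = "two_group_2v2" if sizes == [2, 2] else "two_group_1v3"
    return ValueAssignment(position=position, values=values, group_type=group_type)


def enumerate_assignments(position: int) -> list[ValueAssignment]:
    """All 74 grouping/value assignments for one codon position.

    Ordering is deterministic: four-group, three-group, two-group 1v3,
    two-group 2v2; lexicographic within each family.
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    out: list[ValueAssignment] = []

    # 4 groups: one partition, 24 orderings of {-2,-1,1,2}
    for perm in sorted(itertools.permutations((-2.0, -1.0, 1.0, 2.0))):
        out.append(ValueAssignment(position, dict(zip(NUCLEOTIDES, perm)), "four_group"))

    # 3 groups: choose the fused pair (6 ways), order {-1,0,1} over groups (6 ways)
    for pair in itertools.combinations(NUCLEOTIDES, 2):
        singles = [n for n in NUCLEOTIDES if n not in pair]
        for perm in sorted(itertools.permutations((-1.0, 0.0, 1.0))):
            vals = {pair[0]: perm[0], pair[1]: perm[0],
                    singles[0]: perm[1], singles[1]: perm[2]}
            out.append(ValueAssignment(position, vals, "three_group"))

    # 2 groups, 1 vs 3: 4 singleton choices x 2 sign orientations
    for single in NUCLEOTIDES:
        for sign in (-1.0, 1.0):
            vals = {n: (sign if n == single else -sign) for n in NUCLEOTIDES}
            out.append(ValueAssignment(position, vals, "two_group_1v3"))

    # 2 groups, 2 vs 2: C(4,2) = 6 choices of the -1 pair; the +1 pair is the
    # complement, so there is exactly one value ordering per choice and each
    # of the 3 bipartitions appears once per sign orientation.
    for pair in itertools.combinations(NUCLEOTIDES, 2):
        rest = [n for n in NUCLEOTIDES if n not in pair]
        vals = {pair[0]: -1.0, pair[1]: -1.0, rest[0]: 1.0, rest[1]: 1.0}
        out.append(ValueAssignment(position, vals, "two_group_2v2"))

    return out


def aa_position_value(
    aa: str,
    position: int,
    assignment: ValueAssignment,
    table: CodonTable = STANDARD_TABLE,
) -> float:
    """Codon-averaged assignment value of one amino acid at one position.

    Uniform weight per synonymous sense codon; no codon-usage weighting.
    """
    codons = table.codons_for(aa)
    return float(np.mean([assignment.values[c[position - 1]] for c in codons]))


def position_value_vector(
    assignment: ValueAssignment, table: CodonTable = STANDARD_TABLE
) -> np.ndarray:
    """Position values for all 20 amino acids, in ``AMINO_ACIDS`` order."""
    return np.array(
        [aa_position_value(a, assignment.position, assignment, table) for a in AMINO_ACIDS]
    )


@dataclass(frozen=True)
class AssociationRecord:
    """One (position, property, assignment) Pearson association."""

    position: int
    property_name: str
    assignment: ValueAssignment
    r: float
    p: float
    n: int = 20
    defined: bool = True

    def oriented_positive(self) -> "AssociationRecord":
        """The same association reported in its positive-r sign orientation."""
        if self.r >= 0 or not self.defined:
            return self
        return AssociationRecord(
            position=self.position,
            property_name=self.property_name,
            assignment=self.assignment.negated(),
            r=-self.r,
            p=self.p,
            n=self.n,
        )


def pearson_assoc(
    assignment: ValueAssignment,
    scale: PropertyScale,
    table: CodonTable = STANDARD_TABLE,
) -> AssociationRecord:
    """Pearson association between an assignment and a property scale.

    Sample = the 20 amino acids; two-sided p from the t distribution with
    n - 2 = 18 degrees of freedom.  If the realized position values have zero
    variance the correlation is undefined and the record is flagged
    ``defined=False`` (r and p set to NaN) so maxima ignore it.
    """
    x = position_value_vector(assignment, table)
    y = np.array(scale.vector())
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return AssociationRecord(
            position=assignment.position,
            property_name=scale.name,
            assignment=assignment,
            r=float("nan"),
            p=float("nan"),
            defined=False,
        )
    r, p = stats.pearsonr(x, y)
    return AssociationRecord(
        position=assignment.position,
        property_name=scale.name,
        assignment=assignment,
        r=float(r),
        p=float(p),
    )


@dataclass
class Catalogue:
    """The full association catalogue over positions, properties, assignments."""

    records: list[AssociationRecord]

    def __len__(self) -> int:
        return len(self.records)

    def cell(self, property_name: str, position: int) -> list[AssociationRecord]:
        return [
            rec for rec in self.records
            if rec.property_name == property_name and rec.position == position
        ]


def build_catalogue(
    scales: Sequence[PropertyScale] | None = None,
    table: CodonTable = STANDARD_TABLE,
    positions: Sequence[int] = (1, 2, 3),
) -> Catalogue:
    """Compute every (position x property x assignment) association.

    With the 13 bundled scales and all three positions this yields
    74 x 3 x 13 = 2886 records, in deterministic
    (position, property, family, lexicographic-assignment) order.
    """
    if scales is None:
        scales = [load_property_scale(n) for n in PROPERTY_NAMES]
    records: list[AssociationRecord] = []
    for position in positions:
        assignments = enumerate_assignments(position)
        for scale in scales:
            for assignment in assignments:
                records.append(pearson_assoc(assignment, scale, table))
    return Catalogue(records=records)


# group-count then lexicographic-value tiebreak for equal |r| within a cell
def _tiebreak_key(rec: AssociationRecord) -> tuple:
    vals = tuple(rec.assignment.values[n] for n in NUCLEOTIDES)
    return (-abs(rec.r), rec.assignment.n_groups, vals)


def best_per_cell(catalogue: Catalogue) -> list[AssociationRecord]:
    """The strongest association of each (property, position) cell.

    Exactly one record per cell (39 for the full catalogue), each the maximum
    |r| re-oriented so r is positive, as summary tables conventionally print.
    Ties break toward fewer groups, then lexicographic assignment values.
    """
    cells: dict[tuple[str, int], list[AssociationRecord]] = {}
    for rec in catalogue.records:
        if rec.defined:
            cells.setdefault((rec.property_name, rec.position), []).append(rec)
    out = []
    for key in sorted(cells, key=lambda k: (PROPERTY_NAMES.index(k[0])
                                            if k[0] in PROPERTY_NAMES else 99, k[1])):
        winner = min(cells[key], key=_tiebreak_key)
        out.append(winner.oriented_positive())
    return out


def combined_assoc(
    property_name: str,
    winners: Sequence[AssociationRecord],
    table: CodonTable = STANDARD_TABLE,
    scale: PropertyScale | None = None,
) -> tuple[float, float, float]:
    """Multiple correlation of one property on the three per-position winners.

    Ordinary least squares of the 20 property values on the three winning
    position-value vectors (plus intercept); returns (R, R^2, p) where p is
    the overall F-test p-value.  Collinear predictors are handled by
    reduced-rank least squares with a warning.
    """
    if scale is None:
        scale = load_property_scale(property_name)
    y = np.array(scale.vector())
    cols = [position_value_vector(w.assignment, table) for w in winners]
    X = np.column_stack([np.ones(len(y)), *cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"collinear position predictors for {property_name!r}; "
            "using reduced-rank least squares",
            stacklevel=2,
        )
    if np.ptp(y) == 0 or all(np.ptp(c) == 0 for c in cols):
        warnings.warn(f"degenerate regression for {property_name!r}", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    n = len(y)
    k = rank - 1  # predictors actually identified
    if k <= 0 or n - rank <= 0 or ss_res == 0.0:
        return float(np.sqrt(max(r2, 0.0))), r2, 0.0 if ss_res == 0.0 else float("nan")
    f = (r2 / k) / ((1.0 - r2) / (n - rank))
    p = float(stats.f.sf(f, k, n - rank))
    return float(np.sqrt(max(r2, 0.0))), r2, p


def write_catalogue_tsv(records: Iterable[AssociationRecord], path: str | Path) -> None:
    """Write association records as a TSV with a round-trippable assignment column."""
    lines = ["property\tposition\tgroup_type\tassignment\tr\tp\tn"]
    for rec in records:
        lines.append(
            f"{rec.property_name}\t{rec.position}\t{rec.assignment.group_type}\t"
            f"{rec.assignment.to_string()}\t{rec.r!r}\t{rec.p!r}\t{rec.n}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
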