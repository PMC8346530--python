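"""Assignment enumeration, position values, Pearson associations, catalogue."""

import math
import random
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from codonassoc.aa_tables import (
    AMINO_ACIDS,
    PROPERTY_NAMES,
    PropertyScale,
    load_property_scale,
)
from codonassoc.catalogue import (
    ValueAssignment,
    aa_position_value,
    best_per_cell,
    build_catalogue,
    combined_assoc,
    enumerate_assignments,
    parse_assignment_string,
    pearson_assoc,
    position_value_vector,
    write_catalogue_tsv,
)


def brute_force_pearson(x, y):
    """Explicit-sum Pearson r and two-sided p from t with n-2 df."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestEnumeration:
    def test_total_and_family_counts(self):
        for position in (1, 2, 3):
            assignments = enumerate_assignments(position)
            assert len(assignments) == 74
            counts = Counter(a.group_type for a in assignments)
            assert counts == {
                "four_group": 24,
                "three_group": 36,
                "two_group_1v3": 8,
                "two_group_2v2": 6,
            }

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            enumerate_assignments(0)

    def test_no_duplicate_value_maps(self):
        seen = {tuple(sorted(a.values.items())) for a in enumerate_assignments(1)}
        assert len(seen) == 74

    def test_value_sets_per_family(self):
        for a in enumerate_assignments(1):
            values = sorted(set(a.values.values()))
            if a.group_type == "four_group":
                assert values == [-2, -1, 1, 2]
            elif a.group_type == "three_group":
                assert values == [-1, 0, 1]
            else:
                assert values == [-1, 1]
            assert len(values) == a.n_groups

    def test_closed_under_negation(self):
        """Every assignment's value-negation is itself an enumerated assignment."""
        assignments = enumerate_assignments(2)
        maps = {tuple(sorted(a.values.items())) for a in assignments}
        for a in assignments:
            assert tuple(sorted(a.negated().values.items())) in maps

    def test_assignment_string_round_trip(self):
        for a in enumerate_assignments(3):
            back = parse_assignment_string(a.to_string(), position=3)
            assert dict(back.values) == dict(a.values)
            assert back.group_type == a.group_type


class TestPositionValues:
    def test_serine_all_zero_at_position_two(self):
        # all six Ser codons have C or G at position 2
        a = parse_assignment_string("A:-1,T:1,GC:0", position=2)
        assert aa_position_value("S", 2, a) == 0.0

    def test_leucine_mean_over_six_codons(self):
        # TTA,TTG start with T; CTT,CTC,CTA,CTG start with C -> (2*1 + 4*-1)/6
        a = parse_assignment_string("T:1,C:-1,AG:0", position=1)
        assert aa_position_value("L", 1, a) == pytest.approx(-1 / 3)

    def test_single_codon_amino_acid_returns_raw_value(self):
        # Met = ATG only: position-2 value is whatever T is assigned
        for a in enumerate_assignments(2):
            assert aa_position_value("M", 2, a) == a.values["T"]


class TestPearsonAssociation:
    def test_hydropathy_headline(self):
        a = parse_assignment_string("A:-1,T:1,GC:0", position=2)
        rec = pearson_assoc(a, load_property_scale("hydropathy index"))
        assert rec.r == pytest.approx(0.864, abs=5e-4)
        assert rec.p == pytest.approx(9.40e-7, rel=0.01)
        assert rec.n == 20

    def test_polarity_row(self):
        a = parse_assignment_string("A:1,T:-1,GC:0", position=2)
        rec = pearson_assoc(a, load_property_scale("polarity"))
        assert rec.r == pytest.approx(0.788, abs=5e-4)
        assert rec.p == pytest.approx(3.70e-5, rel=0.02)

    def test_negation_antisymmetry(self):
        scale = load_property_scale("molecular volume")
        for a in enumerate_assignments(1)[::7]:
            rec = pearson_assoc(a, scale)
            neg = pearson_assoc(a.negated(), scale)
            assert neg.r == pytest.approx(-rec.r, abs=1e-12)
            assert neg.p == pytest.approx(rec.p, rel=1e-9)

    def test_degenerate_assignment_flagged(self):
        # Trp (TGG) aside, an assignment can realize a single value: e.g. at
        # position 3 every amino acid uses >= 1 codon, but a constant scale
        # cannot happen; force zero variance via a constant property instead.
        flat = PropertyScale(
            name="flat", values={a: 1.0 for a in AMINO_ACIDS}, source="test"
        )
        rec = pearson_assoc(enumerate_assignments(1)[0], flat)
        assert not rec.defined and math.isnan(rec.r)

    def test_matches_brute_force_oracle(self):
        """r and p agree with explicit sum formulas to 1e-12 on 50 random pairs."""
        rng = random.Random(42)
        assignments = enumerate_assignments(1) + enumerate_assignments(2) + enumerate_assignments(3)
        names = list(PROPERTY_NAMES)
        checked = 0
        while checked < 50:
            a = rng.choice(assignments)
            scale = load_property_scale(rng.choice(names))
            rec = pearson_assoc(a, scale)
            x = list(position_value_vector(a))
            y = scale.vector()
            if not rec.defined:
                # both routes must agree the correlation is undefined
                assert max(x) == min(x) or max(y) == min(y)
                continue
            r_ref, p_ref = brute_force_pearson(x, y)
            assert rec.r == pytest.approx(r_ref, abs=1e-12)
            assert rec.p == pytest.approx(p_ref, abs=1e-12)
            checked += 1

    def test_scale_affine_invariance(self):
        scale = load_property_scale("refractivity")
        shifted = PropertyScale(
            name="refractivity",
            values={a: 3.0 * v - 7.0 for a, v in scale.values.items()},
            source="affine",
        )
        a = enumerate_assignments(2)[10]
        assert pearson_assoc(a, shifted).r == pytest.approx(
            pearson_assoc(a, scale).r, abs=1e-12
        )


class TestCatalogue:
    def test_full_size(self, full_catalogue):
        assert len(full_catalogue) == 74 * 3 * 13 == 2886

    def test_restricted_sizes(self):
        scale = [load_property_scale("hydropathy index")]
        assert len(build_catalogue(scales=scale, positions=(2,))) == 74
        assert len(build_catalogue(scales=scale)) == 222
        assert len(build_catalogue(scales=[])) == 0

    def test_deterministic_ordering(self, full_catalogue):
        again = build_catalogue()
        assert [
            (r.position, r.property_name, r.assignment.to_string())
            for r in full_catalogue.records
        ] == [
            (r.position, r.property_name, r.assignment.to_string())
            for r in again.records
        ]

    def test_catalogue_tsv_round_trips_assignments(self, full_catalogue, tmp_path):
        path = tmp_path / "cat.tsv"
        write_catalogue_tsv(full_catalogue.records[:100], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 101
        for line, rec in zip(lines[1:], full_catalogue.records):
            fields = line.split("\t")
            parsed = parse_assignment_string(fields[3], int(fields[1]))
            assert dict(parsed.values) == dict(rec.assignment.values)


class TestBestPerCell:
    def test_one_winner_per_cell(self, full_catalogue):
        best = best_per_cell(full_catalogue)
        assert len(best) == 39
        cells = {(r.property_name, r.position) for r in best}
        assert len(cells) == 39

    def test_winners_oriented_positive(self, full_catalogue):
        assert all(r.r >= 0 for r in best_per_cell(full_catalogue))

    def test_winner_is_cell_max(self, full_catalogue):
        best = {(r.property_name, r.position): r for r in best_per_cell(full_catalogue)}
        for (prop, pos), winner in best.items():
            cell_max = max(
                abs(r.r) for r in full_catalogue.cell(prop, pos) if r.defined
            )
            assert winner.r == pytest.approx(cell_max, abs=1e-12)

    def test_hydropathy_position_two_winner(self, full_catalogue):
        best = {(r.property_name, r.position): r for r in best_per_cell(full_catalogue)}
        winner = best[("hydropathy index", 2)]
        assert winner.assignment.values == {"A": -1, "T": 1, "G": 0, "C": 0}
        assert winner.r == pytest.approx(0.864, abs=5e-4)

    def test_position_two_dominates(self, full_catalogue):
        """Most properties peak at the middle base, and its mean best-r is highest."""
        best = best_per_cell(full_catalogue)
        by_prop: dict[str, list] = {}
        for rec in best:
            by_prop.setdefault(rec.property_name, []).append(rec)
        top_positions = Counter(
            max(recs, key=lambda r: r.r).position for recs in by_prop.values()
        )
        assert top_positions[2] > top_positions[1]
        assert top_positions[2] > top_positions[3]
        mean_r = {
            pos: np.mean([r.r for r in best if r.position == pos]) for pos in (1, 2, 3)
        }
        assert mean_r[2] > mean_r[1] > mean_r[3]

    def test_invariant_under_catalogue_negation(self, full_catalogue):
        """Max |r| per cell is unchanged if every assignment is sign-flipped."""
        from codonassoc.catalogue import Catalogue

        negated = Catalogue(
            records=[
                pearson_assoc(r.assignment.negated(), load_property_scale(r.property_name))
                for r in full_catalogue.records[:222]  # one property, 3 positions
            ]
        )
        sub = Catalogue(records=full_catalogue.records[:222])
        for a, b in zip(best_per_cell(sub), best_per_cell(negated)):
            assert a.r == pytest.approx(b.r, abs=1e-12)


class TestCombinedAssociation:
    def test_hydropathy_general_column(self, full_catalogue):
        winners = [
            r for r in best_per_cell(full_catalogue)
            if r.property_name == "hydropathy index"
        ]
        r, r2, p = combined_assoc("hydropathy index", winners)
        assert r2 == pytest.approx(0.793, abs=0.005)
        assert r == pytest.approx(0.891, abs=0.005)
        assert p < 1e-4

    def test_self_regression_is_perfect(self):
        # a property equal to one predictor's own position values fits with R = 1
        a = parse_assignment_string("A:-1,T:1,GC:0", position=2)
        self_scale = PropertyScale(
            name="self",
            values=dict(zip(AMINO_ACIDS, position_value_vector(a))),
            source="test",
        )
        rec = pearson_assoc(a, self_scale)
        r, r2, p = combined_assoc("self", [rec], scale=self_scale)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_predictors_warn(self):
        flat = ValueAssignment(
            position=1, values={"A": -1.0, "C": -1.0, "G": 1.0, "T": 1.0},
            group_type="two_group_2v2",
        )
        zero = ValueAssignment(
            position=1, values=dict.fromkeys("ACGT", 0.0), group_type="two_group_2v2"
        )
        # all-constant predictors: undefined regression
        rec = pearson_assoc(flat, load_property_scale("polarity"))
        degenerate = [
            type(rec)(position=1, property_name="polarity", assignment=zero,
                      r=float("nan"), p=float("nan"), defined=False)
        ] * 3
        with pytest.warns(UserWarning):
            r, r2, p = combined_assoc("polarity", degenerate)
        assert math.isnan(r2)
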