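"""Crosslink parsing, contact grouping, chain assignment, validation."""

import itertools

import numpy as np
import pytest

from kinfold.errors import EmptyReportError, ParseError, SchemaError, SiteLookupError
from kinfold.structmodel import AtomRecord, StructureModel
from kinfold.xlmap import (
    CrosslinkRecord,
    DomainMap,
    assign_chains,
    classify_contact,
    evaluate_restraints,
    export_pseudobonds,
    parse_crosslinks,
)


@pytest.fixture(scope="module")
def domains():
    return DomainMap.kif5b_default()


def write_table(path, rows, header="Protein1,Site1,Protein2,Site2,E-value"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestParse:
    def test_evalue_filter_is_strict(self, tmp_path):
        p = write_table(
            tmp_path / "x.csv",
            [
                "KIF5B,100,KIF5B,200,0.02",     # at/above cutoff: dropped
                "KIF5B,100,KIF5B,300,0.01",     # exactly the cutoff: dropped
                "KIF5B,100,KIF5B,400,0.009999", # below: kept
            ],
        )
        recs = parse_crosslinks(p)
        assert [(r.site_a, r.site_b) for r in recs] == [(100, 400)]

    def test_unordered_duplicates_keep_min_evalue(self, tmp_path):
        p = write_table(
            tmp_path / "x.csv",
            ["K5B,100,K5B,200,1e-4", "K5B,200,K5B,100,1e-3"],
        )
        recs = parse_crosslinks(p)
        assert len(recs) == 1
        assert recs[0].evalue == pytest.approx(1e-4)

    def test_self_pairs_dropped(self, tmp_path):
        p = write_table(tmp_path / "x.csv", ["K5B,100,K5B,100,1e-4"])
        assert parse_crosslinks(p) == []

    def test_counts_by_construction(self, tmp_path, rng):
        rows = []
        for i in range(50):
            ev = 0.02 if i < 10 else 10 ** rng.uniform(-6, -3)
            rows.append(f"K5B,{100 + 2 * i},K5B,{500 + 2 * i},{ev}")
        recs = parse_crosslinks(write_table(tmp_path / "x.csv", rows))
        assert len(recs) == 40

    def test_tab_delimiter_sniffed(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text(
            "Protein1\tSite1\tProtein2\tSite2\tE-value\nK5B\t10\tK5B\t50\t1e-5\n"
        )
        assert len(parse_crosslinks(p)) == 1

    def test_missing_column_is_schema_error(self, tmp_path):
        p = write_table(
            tmp_path / "x.csv", ["K5B,1,K5B"], header="Protein1,Site1,Protein2"
        )
        with pytest.raises(SchemaError, match="site_b"):
            parse_crosslinks(p)

    def test_non_numeric_evalue_reports_row(self, tmp_path):
        p = write_table(
            tmp_path / "x.csv", ["K5B,1,K5B,2,1e-5", "K5B,3,K5B,4,oops"]
        )
        with pytest.raises(ParseError, match="row 3"):
            parse_crosslinks(p)


class TestClassify:
    @pytest.mark.parametrize(
        "site_a,site_b,group",
        [
            (141, 427, "motor_cc2"),   # motor to CC2
            (903, 98, "motor_tail"),   # CC4 C-terminus to motor
            (50, 300, "motor_intra"),  # both within the motor domain
            (430, 700, "stalk_intra"), # CC2 to CC3b
            (909, 940, "stalk_intra"), # CC4 to tail
            (100, 380, "other"),       # motor to CC1 (neck) is none of the four
        ],
    )
    def test_groups(self, domains, site_a, site_b, group):
        rec = CrosslinkRecord("KIF5B", site_a, "KIF5B", site_b, 1e-5)
        assert classify_contact(rec, domains) == group

    def test_interprotein_and_unmapped(self, domains):
        assert (
            classify_contact(CrosslinkRecord("KIF5B", 10, "KLC1", 50, 1e-5), domains)
            == "interprotein"
        )
        assert (
            classify_contact(CrosslinkRecord("KIF5B", 10, "KIF5B", 9999, 1e-5), domains)
            == "other"
        )


def model_from_positions(positions):
    """positions: {(chain, residue): xyz}"""
    return StructureModel(
        [
            AtomRecord(c, r, "LYS", "CA", np.asarray(xyz, dtype=float))
            for (c, r), xyz in positions.items()
        ]
    )


class TestAssignChains:
    def test_picks_minimum_with_lexicographic_tie_break(self):
        # A100-A200 = 30, A100-B200 = 20, B100-A200 = 20, B100-B200 = 30
        m = model_from_positions(
            {
                ("A", 100): (0, 0, 0),
                ("A", 200): (30, 0, 0),
                ("B", 100): (30, 20, 0),
                ("B", 200): (0, 20, 0),
            }
        )
        got = assign_chains(CrosslinkRecord("P", 100, "P", 200, 1e-5), m)
        assert (got.chain_a, got.chain_b) == ("A", "B")
        assert got.distance == pytest.approx(20.0)

    def test_symmetric_dimer_intra_chain_equal(self):
        m = model_from_positions(
            {
                ("A", 1): (0, 0, 0),
                ("A", 2): (0, 0, 12),
                ("B", 1): (10, 0, 0),
                ("B", 2): (10, 0, 12),
            }
        )
        got = assign_chains(CrosslinkRecord("P", 1, "P", 2, 1e-5), m)
        assert got.distance == pytest.approx(12.0)
        assert (got.chain_a, got.chain_b) == ("A", "A")  # lexicographic tie

    def test_site_absent_from_one_chain_restricts_candidates(self):
        m = model_from_positions(
            {("A", 1): (0, 0, 0), ("A", 2): (5, 0, 0), ("B", 1): (1, 0, 0)}
        )
        got = assign_chains(CrosslinkRecord("P", 1, "P", 2, 1e-5), m)
        assert got.chain_b == "A"
        assert got.chain_a == "B"  # B1 is closer to A2 than A1 is

    def test_site_missing_everywhere_raises(self):
        m = model_from_positions({("A", 1): (0, 0, 0), ("A", 2): (1, 0, 0)})
        with pytest.raises(SiteLookupError, match="99"):
            assign_chains(CrosslinkRecord("P", 1, "P", 99, 1e-5), m)

    def test_matches_exhaustive_enumeration(self, rng):
        """Oracle: brute force over all chain combinations on random dimers."""
        for trial in range(50):
            coords = {
                (c, r): rng.uniform(0, 50, size=3) for c in "AB" for r in (7, 42)
            }
            m = model_from_positions(coords)
            rec = CrosslinkRecord("P", 7, "P", 42, 1e-5)
            got = assign_chains(rec, m)
            best = min(
                np.linalg.norm(coords[(ca, 7)] - coords[(cb, 42)])
                for ca, cb in itertools.product("AB", repeat=2)
            )
            assert got.distance == pytest.approx(best, abs=1e-12)


class TestEvaluate:
    def test_inclusive_boundary(self):
        m = model_from_positions(
            {
                ("A", 1): (0, 0, 0),
                ("A", 2): (10, 0, 0),
                ("A", 3): (20, 0, 0),
                ("A", 4): (24, 0, 0),
                ("A", 5): (30, 0, 0),
            }
        )
        recs = [
            CrosslinkRecord("P", 1, "P", 2, 1e-5, source_row=2),   # 10
            CrosslinkRecord("P", 1, "P", 3, 1e-5, source_row=3),   # 20
            CrosslinkRecord("P", 1, "P", 4, 1e-5, source_row=4),   # 24 inclusive
            CrosslinkRecord("P", 1, "P", 5, 1e-5, source_row=5),   # 30
        ]
        rep = evaluate_restraints(recs, m, threshold=24.0)
        assert rep.n_satisfied == 3
        assert rep.fraction_satisfied == pytest.approx(0.75)
        assert rep.distance_range == (pytest.approx(10.0), pytest.approx(30.0))

    def test_empty_records_error(self, folded_model):
        with pytest.raises(EmptyReportError):
            evaluate_restraints([], folded_model)

    def test_true_links_on_ground_truth_all_satisfied(self, folded_model, folded_links):
        rep = evaluate_restraints(folded_links.records, folded_model)
        assert rep.fraction_satisfied == 1.0

    def test_fraction_monotone_in_threshold(self, folded_model, folded_links):
        fractions = [
            evaluate_restraints(folded_links.records, folded_model, threshold=t)
            .fraction_satisfied
            for t in (5.0, 12.0, 18.0, 24.0, 40.0)
        ]
        assert fractions == sorted(fractions)

    def test_reversing_all_rows_gives_identical_report(self, folded_model, folded_links):
        fwd = evaluate_restraints(folded_links.records, folded_model)
        reversed_recs = [
            CrosslinkRecord(
                r.protein_b, r.site_b, r.protein_a, r.site_a, r.evalue, r.source_row
            )
            for r in folded_links.records
        ]
        rev = evaluate_restraints(reversed_recs, folded_model)
        assert rev.n_satisfied == fwd.n_satisfied
        assert sorted(a.distance for a in rev.assigned) == pytest.approx(
            sorted(a.distance for a in fwd.assigned)
        )


class TestPseudobonds:
    def test_lines_and_determinism(self, tmp_path, folded_model, folded_links):
        rep = evaluate_restraints(folded_links.records, folded_model)
        p1, p2 = tmp_path / "a.pb", tmp_path / "b.pb"
        export_pseudobonds(rep, p1)
        export_pseudobonds(rep, p2)
        assert p1.read_text() == p2.read_text()
        lines = p1.read_text().strip().splitlines()
        assert len(lines) == rep.n_total
        assert all("satisfied" in ln or "violated" in ln for ln in lines)

    def test_single_link_format(self, tmp_path):
        m = model_from_positions(
            {("A", 100): (0, 0, 0), ("B", 903): (18.2, 0, 0)}
        )
        rep = evaluate_restraints(
            [CrosslinkRecord("P", 100, "P", 903, 1e-5)], m
        )
        out = tmp_path / "x.pb"
        export_pseudobonds(rep, out)
        line = out.read_text().strip()
        assert ":100@CA" in line and ":903@CA" in line and "18.2" in line
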