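import csv
import io
import json

import numpy as np
import pytest

from interlis.errors import ConsistencyError
from interlis.fixtures import FixtureSpec, PlantedInterface, make_complex_fixture
from interlis.interface_metrics import compute_pair_metrics, compute_score_matrix
from interlis.viz_export import (
    ColorScheme,
    _blend_toward_white,
    _compress_ranges,
    build_script_spec,
    export_contact_map,
    export_metrics_csv,
    render_chimerax,
    render_pymol,
)


@pytest.fixture(scope="module")
def analyzed(planted_fixture):
    record, truth, _ = planted_fixture
    return record, compute_score_matrix(record), truth


class TestHelpers:
    @pytest.mark.parametrize(
        "nums,expected",
        [([], ""), ([5], "5"), ([1, 2, 3], "1-3"), ([1, 2, 4, 7, 8], "1-2,4,7-8"),
         ([3, 1, 2, 2], "1-3")],
    )
    def test_compress_ranges(self, nums, expected):
        assert _compress_ranges(nums) == expected

    def test_blend_toward_white(self):
        assert _blend_toward_white("#000000", 1.0) == "#ffffff"
        assert _blend_toward_white("#204060", 0.0) == "#204060"
        assert _blend_toward_white("#000000", 0.5) == "#808080"


class TestScriptSpec:
    def test_clir_takes_precedence_and_classes_partition(self, analyzed):
        record, matrix, _ = analyzed
        spec = build_script_spec(record, matrix)
        for ch in spec.chains:
            classes = [set(ch.clir), set(ch.lir_only), set(ch.noninteracting)]
            union = set().union(*classes)
            chain = record.structure.chain(ch.chain_id)
            assert union == set(chain.author_seq_nums)
            assert sum(len(c) for c in classes) == len(union)  # disjoint

    def test_planted_interface_selected_as_clir(self, analyzed):
        record, matrix, truth = analyzed
        spec = build_script_spec(record, matrix)
        by_chain = {c.chain_id: c for c in spec.chains}
        # planted residues 0-4 are author numbers 1-5
        assert by_chain["A"].clir == (1, 2, 3, 4, 5)
        assert by_chain["B"].clir == (1, 2, 3, 4, 5)
        assert by_chain["A"].lir_only == ()

    def test_empty_interface_all_gray(self):
        spec_def = FixtureSpec(n_chains=2, residues_per_chain=10, seed=2)
        records, _ = make_complex_fixture(spec_def)
        record = records[0]
        spec = build_script_spec(record, compute_score_matrix(record))
        assert all(not c.clir and not c.lir_only for c in spec.chains)
        assert all(len(c.noninteracting) == 10 for c in spec.chains)

    def test_mismatched_metrics_rejected(self, analyzed):
        record, matrix, _ = analyzed
        other_records, _ = make_complex_fixture(
            FixtureSpec(n_chains=3, residues_per_chain=10, seed=9)
        )
        other = compute_score_matrix(other_records[0])
        with pytest.raises(ConsistencyError):
            build_script_spec(record, other)


class TestRenderers:
    def test_chimerax_one_color_command_per_selection(self, analyzed):
        record, matrix, _ = analyzed
        text = render_chimerax(build_script_spec(record, matrix))
        assert text.startswith("open ")
        assert "color /A:1-5 " in text
        assert "color /B:1-5 " in text
        assert "hide /A:" in text  # non-LIR region hidden by default

    def test_pymol_same_selections(self, analyzed):
        record, matrix, _ = analyzed
        text = render_pymol(build_script_spec(record, matrix))
        assert "load " in text
        assert "select A_clir, model and chain A and resi 1-5" in text
        assert "hide cartoon, model and chain A and not resi" in text

    def test_empty_interface_keeps_everything_visible(self):
        records, _ = make_complex_fixture(
            FixtureSpec(n_chains=2, residues_per_chain=10, seed=2)
        )
        record = records[0]
        spec = build_script_spec(record, compute_score_matrix(record))
        cxc = render_chimerax(spec)
        assert "hide /" not in cxc
        assert cxc.count("color") == 1  # only the global gray

    def test_byte_determinism(self, analyzed):
        record, matrix, _ = analyzed
        spec1 = build_script_spec(record, matrix)
        spec2 = build_script_spec(record, compute_score_matrix(record))
        assert render_chimerax(spec1) == render_chimerax(spec2)
        assert render_pymol(spec1) == render_pymol(spec2)


class TestCsvExport:
    def test_pair_table_row_counts(self, planted_fixture):
        record, _, _ = planted_fixture
        spec = FixtureSpec(
            n_chains=2,
            residues_per_chain=12,
            interface_pairs=(PlantedInterface("A", (0, 4), "B", (0, 4), 6.0, True),),
            seed=21,
            n_models=3,
            model_jitter_sd=0.3,
        )
        records, _ = make_complex_fixture(spec)
        analyses = [(r, compute_score_matrix(r)) for r in records]
        pair_csv, res_csv = export_metrics_csv(analyses)
        pair_rows = list(csv.DictReader(io.StringIO(pair_csv)))
        assert len(pair_rows) == 3  # 1 pair x 3 models
        res_rows = list(csv.DictReader(io.StringIO(res_csv)))
        assert len(res_rows) == 3 * (12 + 12)

    def test_round_trip_preserves_metrics_to_format_precision(self, analyzed):
        record, matrix, _ = analyzed
        pair_csv, _ = export_metrics_csv([(record, matrix)])
        row = next(csv.DictReader(io.StringIO(pair_csv)))
        cell = matrix.cell(row["chain_a"], row["chain_b"])
        for col, attr in (("lis", "lis"), ("clis", "clis"), ("ilis", "ilis"),
                          ("ipsae", "ipsae"), ("actifptm", "actifptm")):
            assert float(row[col]) == pytest.approx(getattr(cell, attr), abs=1e-6)
        assert int(row["n_contact_pairs"]) == len(cell.contacts.pairs)

    def test_residue_rows_flag_planted_interface(self, analyzed):
        record, matrix, truth = analyzed
        _, res_csv = export_metrics_csv([(record, matrix)])
        rows = [
            r
            for r in csv.DictReader(io.StringIO(res_csv))
            if r["chain"] == "A" and r["is_clir"] == "True"
        ]
        assert sorted(int(r["author_seq_num"]) for r in rows) == [1, 2, 3, 4, 5]


class TestContactMap:
    def test_no_clir_pairs_empty_edges(self):
        records, _ = make_complex_fixture(
            FixtureSpec(n_chains=2, residues_per_chain=10, seed=2)
        )
        record = records[0]
        doc = json.loads(export_contact_map(record, compute_score_matrix(record)))
        assert doc["edges"] == []

    def test_chain_ring_touches_every_chain(self):
        n = 9
        pairs = tuple(
            PlantedInterface(chr(ord("A") + k), (0, 3),
                             chr(ord("A") + (k + 1) % n), (5, 8), 4.0, True)
            for k in range(n)
        )
        records, _ = make_complex_fixture(
            FixtureSpec(n_chains=n, residues_per_chain=12, interface_pairs=pairs,
                        seed=31)
        )
        record = records[0]
        doc = json.loads(
            export_contact_map(record, compute_score_matrix(record), "circular")
        )
        touched = {e["chain_a"] for e in doc["edges"]} | {
            e["chain_b"] for e in doc["edges"]
        }
        assert len(touched) == n

    def test_circular_arcs_sum_to_total_residues(self, analyzed):
        record, matrix, _ = analyzed
        doc = json.loads(export_contact_map(record, matrix, "circular"))
        assert sum(a["length"] for a in doc["arcs"]) == record.structure.n_residues
        assert doc["total_residues"] == record.structure.n_residues

    def test_determinism(self, analyzed):
        record, matrix, _ = analyzed
        a = export_contact_map(record, matrix, "circular")
        b = export_contact_map(record, compute_score_matrix(record), "circular")
        assert a == b
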