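"""CNR, two-sigma flags, PAS scoring and network export."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from radres.pathways import (
    PathwayDefinition,
    PathwayError,
    build_network,
    compute_cnr,
    compute_pas,
    export_network,
    flag_two_sigma,
    load_pathway,
    pas_timecourse,
)
from radres.simulate import atm_pathway


def brute_force_pas(cnr: dict, flags: dict, nodes: dict) -> float:
    """Independent loop-and-log oracle for the PAS sum."""
    total = 0.0
    for gene, arr in nodes.items():
        if gene in cnr and flags.get(gene, False):
            total += arr * math.log10(cnr[gene])
    return total


class TestPathwayDefinition:
    def test_packaged_fixture_loads_with_required_genes(self):
        pw = atm_pathway()
        assert {"ATM", "CHEK2", "TP53", "SMC1A", "H2AFX"} <= set(pw.genes)
        assert all(kind in {"activation", "inhibition"} for _, _, kind in pw.edges)

    @pytest.mark.parametrize(
        "nodes, edges, message",
        [
            ({"A": 0.3}, [], "invalid role"),
            ({"A": 0.0}, [], "non-zero role"),
            ({"A": 1.0}, [("A", "B", "activation")], "not a declared node"),
            ({"A": 1.0}, [("A", "A", "promotes")], "edge kind"),
        ],
    )
    def test_invalid_definitions_rejected(self, nodes, edges, message):
        with pytest.raises(PathwayError, match=message):
            PathwayDefinition("p", nodes, edges)

    def test_duplicate_gene_in_yaml_rejected(self, tmp_path):
        path = tmp_path / "p.yaml"
        path.write_text(
            "pathway_id: p\nnodes:\n  - {gene: A, arr: 1}\n  - {gene: A, arr: -1}\n"
        )
        with pytest.raises(PathwayError, match="duplicate"):
            load_pathway(path)


class TestCNR:
    def test_identical_case_and_controls_give_unity(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=["x", "a", "b"])
        assert compute_cnr(expr, "x", ["a", "b"])["g"] == pytest.approx(1.0)

    def test_geometric_control_average(self):
        expr = pd.DataFrame([[8.0, 2.0, 8.0]], index=["g"], columns=["x", "a", "b"])
        assert compute_cnr(expr, "x", ["a", "b"])["g"] == pytest.approx(2.0)

    def test_empty_controls_and_case_in_controls_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0]], index=["g"], columns=["x", "a"])
        with pytest.raises(ValueError, match="empty"):
            compute_cnr(expr, "x", [])
        with pytest.raises(ValueError, match="controls"):
            compute_cnr(expr, "x", ["x", "a"])


class TestTwoSigmaFlags:
    def test_hand_computed_bound(self, control_frame):
        controls = ["c1", "c2", "c3", "c4", "c5"]  # mean 10, sd 1.5811
        assert flag_two_sigma(control_frame, "case_hi", controls)["g1"]
        assert not flag_two_sigma(control_frame, "case_lo", controls)["g1"]

    def test_case_at_control_mean_not_flagged(self):
        expr = pd.DataFrame([[10.0, 9.0, 11.0]], index=["g"], columns=["x", "a", "b"])
        assert not flag_two_sigma(expr, "x", ["a", "b"])["g"]

    def test_zero_sd_controls_flag_any_deviation(self):
        expr = pd.DataFrame(
            [[10.1] + [10.0] * 5], index=["g"],
            columns=["x", "a", "b", "c", "d", "e"],
        )
        assert flag_two_sigma(expr, "x", ["a", "b", "c", "d", "e"])["g"]

    def test_fewer_than_two_controls_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["x", "a"])
        with pytest.raises(ValueError, match="two-sigma"):
            flag_two_sigma(expr, "x", ["a"])


class TestPAS:
    def test_flagged_activator_and_repressor_hand_case(self):
        pw = PathwayDefinition("p", {"A": 1.0, "B": -1.0})
        cnr = pd.Series({"A": 10.0, "B": 0.1}, name="s")
        flags = pd.Series({"A": True, "B": True})
        res = compute_pas(cnr, flags, pw)
        assert res.pas == pytest.approx(2.0)
        assert res.per_gene_terms == pytest.approx({"A": 1.0, "B": 1.0})

    def test_unit_cnr_and_unflagged_genes_contribute_zero(self):
        pw = PathwayDefinition("p", {"A": 1.0, "B": 1.0})
        cnr = pd.Series({"A": 1.0, "B": 100.0}, name="s")
        flags = pd.Series({"A": True, "B": False})
        assert compute_pas(cnr, flags, pw).pas == pytest.approx(0.0)

    def test_missing_pathway_genes_contribute_zero_with_report(self):
        pw = PathwayDefinition("p", {"A": 1.0, "Z": 1.0})
        cnr = pd.Series({"A": 10.0}, name="s")
        res = compute_pas(cnr, pd.Series({"A": True}), pw)
        assert res.pas == pytest.approx(1.0)
        assert res.per_gene_terms["Z"] == 0.0

    def test_nonpositive_cnr_rejected(self):
        pw = PathwayDefinition("p", {"A": 1.0})
        with pytest.raises(ValueError, match="positive"):
            compute_pas(pd.Series({"A": 0.0}), pd.Series({"A": True}), pw)

    def test_matches_brute_force_oracle_on_small_pathways(self):
        rng = np.random.default_rng(7)
        arr_choices = [-1.0, -0.5, 0.0, 0.5, 1.0]
        for _ in range(50):
            n = rng.integers(1, 6)
            genes = [f"g{i}" for i in range(n)]
            nodes = dict(zip(genes, rng.choice(arr_choices, n)))
            if all(a == 0 for a in nodes.values()):
                nodes[genes[0]] = 1.0
            cnr = pd.Series(10.0 ** rng.normal(0, 0.7, n), index=genes, name="s")
            flags = pd.Series(rng.random(n) < 0.6, index=genes)
            res = compute_pas(cnr, flags, PathwayDefinition("p", nodes))
            expected = brute_force_pas(cnr.to_dict(), flags.to_dict(), nodes)
            assert res.pas == pytest.approx(expected, abs=1e-12)

    def test_disjoint_pathway_concatenation_is_additive(self):
        p1 = PathwayDefinition("p1", {"A": 1.0, "B": -0.5})
        p2 = PathwayDefinition("p2", {"C": 0.5})
        both = PathwayDefinition("p12", {**p1.nodes, **p2.nodes})
        cnr = pd.Series({"A": 3.0, "B": 0.5, "C": 7.0}, name="s")
        flags = pd.Series(True, index=cnr.index)
        assert compute_pas(cnr, flags, both).pas == pytest.approx(
            compute_pas(cnr, flags, p1).pas + compute_pas(cnr, flags, p2).pas
        )

    def test_sign_monotonicity_in_cnr(self):
        flags = pd.Series({"A": True})
        for arr, direction in [(1.0, 1), (-1.0, -1)]:
            pw = PathwayDefinition("p", {"A": arr})
            pas_vals = [
                compute_pas(pd.Series({"A": c}, name="s"), flags, pw).pas
                for c in (0.5, 1.0, 2.0, 8.0)
            ]
            diffs = np.diff(pas_vals) * direction
            assert (diffs > 0).all()


class TestTimecourse:
    @staticmethod
    def _constant_dataset():
        samples, meta_rows = [], []
        for week in (4, 8):
            for rep in (1, 2, 3):
                sid = f"n{week}_{rep}"
                samples.append(sid)
                meta_rows.append((sid, "CL", "naive", week))
            for drug in ("d1", "d2"):
                sid = f"{drug}_{week}"
                samples.append(sid)
                meta_rows.append((sid, "CL", drug, week))
        expr = pd.DataFrame(
            5.0, index=["ATM", "CHEK2"], columns=samples
        )
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "cell_line", "drug", "week"]
        ).set_index("sample_id", drop=False)
        return expr, meta

    def test_constant_expression_scores_zero_everywhere(self):
        expr, meta = self._constant_dataset()
        scores, dispersion = pas_timecourse(expr, meta, [atm_pathway()])
        assert (scores["pas"] == 0).all()
        assert (dispersion["pas_sd"] == 0).all()
        assert set(scores["week"]) == {4, 8}

    def test_single_drug_week_has_zero_dispersion(self):
        expr, meta = self._constant_dataset()
        keep = meta[(meta["drug"] != "d2") | (meta["week"] != 4)]
        scores, dispersion = pas_timecourse(expr[keep["sample_id"]], keep, [atm_pathway()])
        w4 = dispersion[dispersion["week"] == 4]
        assert (w4["pas_sd"] == 0).all()

    def test_week_without_controls_skipped_with_warning(self, caplog):
        expr, meta = self._constant_dataset()
        keep = meta[(meta["drug"] != "naive") | (meta["week"] != 8)]
        with caplog.at_level("WARNING"):
            scores, _ = pas_timecourse(expr[keep["sample_id"]], keep, [atm_pathway()])
        assert set(scores["week"]) == {4}
        assert any("skipping" in r.message for r in caplog.records)


class TestNetworkExport:
    def test_node_color_depth_is_clamped_log_cnr(self):
        pw = PathwayDefinition(
            "p", {"A": 1.0, "B": 1.0, "C": -1.0},
            [("A", "B", "activation"), ("C", "A", "inhibition")],
        )
        cnr = pd.Series({"A": 1.0, "B": 1000.0, "C": 0.01})
        g = build_network(pw, cnr, pas=1.5)
        assert g.nodes["A"]["log_cnr"] == 0.0
        assert g.nodes["B"]["log_cnr"] == 1.0  # clamped from 3
        assert g.nodes["C"]["log_cnr"] == -1.0
        assert g.edges["A", "B"] == {"kind": "activation", "color": "green"}
        assert g.edges["C", "A"]["color"] == "red"
        assert g.graph["pas"] == 1.5

    def test_missing_cnr_renders_neutral(self):
        pw = PathwayDefinition("p", {"A": 1.0})
        g = build_network(pw, pd.Series(dtype=float))
        assert g.nodes["A"]["log_cnr"] == 0.0

    def test_graphml_and_dot_files_written(self, tmp_path):
        pw = atm_pathway()
        cnr = pd.Series(2.0, index=pw.genes)
        export_network(pw, cnr, tmp_path / "p.graphml", tmp_path / "p.dot", pas=0.3)
        back = nx.read_graphml(tmp_path / "p.graphml")
        assert set(back.nodes) == set(pw.genes)
        dot = (tmp_path / "p.dot").read_text()
        assert "color=green" in dot and "digraph" in dot
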