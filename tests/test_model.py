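"""Network model: edge dedup, revision history, boundary filter, diffs, shares."""
import pytest

from belnet import (BoundaryConfig, Evidence, Network, Phase, Provenance,
                    apply_boundary_filter, copd_boundary_config,
                    count_edges_by_phase, diff_versions, parse_statement,
                    share_report, statement_key)
from belnet.fixtures import (VersionScriptRow, gen_version_pairs,
                             jamboree_version_script,
                             open_phase_version_script, phase1_version_script)


def ev(n, citation="12345678"):
    return Evidence(citation=citation, quote=f"quote {n}", id=f"e{n}")


@pytest.fixture()
def prov():
    return Provenance(Phase.PHASE2_CROWD, actor="tester")


class TestAddEdge:
    def test_new_edge_creates_endpoints(self, prov):
        net = Network("Th1 Signaling")
        stmt = parse_statement("p(HGNC:EGR2) increases act(p(HGNC:CBLB))")
        net.add_edge(stmt, [ev(1)], prov)
        assert net.node_count == 2
        assert net.edge_count == 1

    def test_duplicate_statement_appends_evidence(self, prov):
        net = Network("Th1 Signaling")
        stmt = parse_statement("p(HGNC:EGR2) increases act(p(HGNC:CBLB))")
        net.add_edge(stmt, [ev(1)], prov)
        net.add_edge(parse_statement("p( HGNC:EGR2 ) increases act(p(HGNC:CBLB))"),
                     [ev(2)], prov)
        assert (net.node_count, net.edge_count, net.evidence_count) == (2, 1, 2)

    def test_empty_evidence_list_rejected(self, prov):
        net = Network("n")
        stmt = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        with pytest.raises(ValueError):
            net.add_edge(stmt, [], prov)

    def test_duplicate_evidence_id_rejected(self, prov):
        net = Network("n")
        stmt = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        net.add_edge(stmt, [ev(1)], prov)
        with pytest.raises(ValueError):
            net.add_edge(stmt, [ev(1)], prov)

    def test_revision_monotonicity(self, prov):
        """Every mutation bumps revision by one and appends one history entry."""
        net = Network("n")
        stmt = parse_statement("p(HGNC:A) increases p(HGNC:B)")
        checkpoints = []
        net.add_edge(stmt, [ev(1)], prov)
        checkpoints.append((net.revision, len(net.history)))
        net.add_edge(stmt, [ev(2)], prov)
        checkpoints.append((net.revision, len(net.history)))
        net.add_evidence(statement_key(stmt), ev(3), prov)
        checkpoints.append((net.revision, len(net.history)))
        assert checkpoints == [(1, 1), (2, 2), (3, 3)]

    def test_evidence_status_transitions_one_way(self):
        e = ev(9)
        e.set_status("approved")
        with pytest.raises(ValueError):
            e.set_status("rejected")


class TestBoundaryFilter:
    def test_human_lung_context_accepted(self):
        e = Evidence("1", context={"species": "human", "cell_type": "alveolar macrophage"})
        assert apply_boundary_filter(e, copd_boundary_config()).accepted

    def test_tumor_cell_line_rejected(self):
        e = Evidence("1", context={"cell_type": "tumor-derived cell line"})
        decision = apply_boundary_filter(e, copd_boundary_config())
        assert (decision.accepted, decision.reason) == (False, "excluded_cell_system")

    def test_solid_particle_exposure_rejected(self):
        e = Evidence("1", context={"exposure": "titanium dioxide"})
        decision = apply_boundary_filter(e, copd_boundary_config())
        assert decision.reason == "excluded_exposure"

    def test_mouse_accepted_with_homologization_annotation(self):
        e = Evidence("1", context={"species": "mouse"})
        decision = apply_boundary_filter(e, copd_boundary_config())
        assert decision.accepted and "homologized" in decision.annotations

    def test_rodents_rejected_without_homologization(self):
        config = BoundaryConfig(homologize_rodents=False)
        e = Evidence("1", context={"species": "rat"})
        decision = apply_boundary_filter(e, config)
        assert (decision.accepted, decision.reason) == (False, "excluded_species")

    def test_first_matching_rule_in_fixed_order(self):
        # disease outranks cell system outranks exposure outranks species
        e = Evidence("1", context={"disease": "asthma",
                                   "cell_type": "tumor-derived cell line",
                                   "exposure": "quartz", "species": "dog"})
        assert apply_boundary_filter(e, copd_boundary_config()).reason == "excluded_disease"

    def test_empty_context_passes(self):
        assert apply_boundary_filter(Evidence("1"), copd_boundary_config()).accepted

    def test_idempotent_and_partitioning(self, rng):
        config = copd_boundary_config()
        contexts = [
            {}, {"species": "human"}, {"species": "mouse"}, {"species": "zebrafish"},
            {"disease": "Lung Cancer"}, {"cell_type": "Immortalized Cell Line"},
            {"exposure": "carbon black"}, {"tissue": "lung"},
        ]
        for ctx in contexts:
            e = Evidence("1", context=ctx)
            first = apply_boundary_filter(e, config)
            second = apply_boundary_filter(e, config)
            assert first == second  # deterministic + idempotent
            assert first.accepted != (first.reason is not None)


class TestDiffAndShares:
    def test_identical_sets_diff_to_zero(self):
        fx = gen_version_pairs([VersionScriptRow("N", 2, 3)])
        diff = diff_versions(fx.old, fx.old)
        assert (diff.nodes_added, diff.edges_added, diff.evidences_added) == (0, 0, 0)

    def test_jamboree_th1_counts(self):
        """12 nodes and 28 edges added to the Th1-Th2 model during jamboree."""
        fx = gen_version_pairs([VersionScriptRow("Th1-Th2 Signaling", 12, 28,
                                                 phase=Phase.PHASE3_JAMBOREE)])
        diff = diff_versions(fx.old, fx.new)
        assert (diff.nodes_added, diff.edges_added) == (12, 28)

    def test_neutrophil_open_phase_counts(self):
        fx = gen_version_pairs([VersionScriptRow("Neutrophil Signaling", 116, 160, 181)])
        diff = diff_versions(fx.old, fx.new)
        assert (diff.nodes_added, diff.edges_added, diff.evidences_added) == (116, 160, 181)

    def test_diff_matches_fixture_expectation(self):
        fx = gen_version_pairs(open_phase_version_script())
        diff = diff_versions(fx.old, fx.new)
        assert diff.breakdown == fx.expected.breakdown

    def test_diff_additivity_along_edit_path(self):
        """diff(v1,v3) = diff(v1,v2) + diff(v2,v3) when v2 lies on the path."""
        fx1 = gen_version_pairs([VersionScriptRow("N", 3, 4)])
        v1, v2 = fx1.old, fx1.new
        v3 = [n.copy() for n in v2]
        prov = Provenance(Phase.PHASE3_JAMBOREE, actor="t")
        stmt = parse_statement("p(HGNC:NEW1) increases p(HGNC:NEW2)")
        v3[0].add_edge(stmt, [ev("x", citation="99999999")], prov)
        d12 = diff_versions(v1, v2)
        d23 = diff_versions(v2, v3)
        d13 = diff_versions(v1, v3)
        assert d13.nodes_added == d12.nodes_added + d23.nodes_added
        assert d13.edges_added == d12.edges_added + d23.edges_added
        assert d13.evidences_added == d12.evidences_added + d23.evidences_added

    def test_discussion_share_percentages(self):
        """Focus shares: 266/885 evidences -> 30%; 208/451 edges -> 46%."""
        fx = gen_version_pairs(open_phase_version_script())
        diff = diff_versions(fx.old, fx.new)
        focus = ["Neutrophil Signaling", "Macrophage Signaling", "Th1-Th2 Signaling"]
        report = share_report(diff, focus)
        assert report["evidences"]["focus"] == 266
        assert report["evidences"]["total"] == 885
        assert report["evidences"]["percent"] == 30
        assert report["edges"] == {"focus": 208, "total": 451, "percent": 46}

    def test_jamboree_share_percentages(self):
        """Three inflammatory networks took 148/167 nodes and 263/296 edges (89%)."""
        fx = gen_version_pairs(jamboree_version_script())
        diff = diff_versions(fx.old, fx.new)
        focus = ["Neutrophil Signaling", "Macrophage Signaling", "Th1-Th2 Signaling"]
        report = share_report(diff, focus)
        assert report["nodes"] == {"focus": 148, "total": 167, "percent": 89}
        assert report["edges"] == {"focus": 263, "total": 296, "percent": 89}

    def test_full_focus_is_100_percent(self):
        fx = gen_version_pairs(jamboree_version_script())
        diff = diff_versions(fx.old, fx.new)
        report = share_report(diff, list(diff.breakdown))
        assert report["nodes"]["percent"] == 100

    def test_zero_total_share_is_undefined(self):
        fx = gen_version_pairs([VersionScriptRow("N", 0, 0)])
        diff = diff_versions(fx.old, fx.old)
        # rebuild diff with the network present but nothing added
        report = share_report(diff_versions(fx.old, fx.old), ["N"])
        assert report["nodes"]["percent"] is None

    def test_phase1_edge_arithmetic(self):
        """415 literature + 72 RCR edges = 487 edges added in phase 1."""
        fx = gen_version_pairs(phase1_version_script())
        diff = diff_versions(fx.old, fx.new)
        assert diff.edges_added == 487
        assert diff.nodes_added == 200
        by_phase = count_edges_by_phase(fx.new)
        assert by_phase[Phase.PHASE1_LITERATURE] == 415
        assert by_phase[Phase.PHASE1_RCR] == 72
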