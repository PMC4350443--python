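"""Crowd verification: vote locking, summaries, leaderboard, edits."""
import random

import pytest

from belnet import (ActionEntry, ActionLog, CrowdEdit, Evidence, LockState,
                    LockedEvidenceError, Network, Phase, PointScheme,
                    Provenance, Vote, VoteLedger, apply_edit, cast_vote,
                    jamboree_invitees, leaderboard, lock_summary,
                    parse_statement, replay_ledger, statement_key)
from belnet.crowd import read_vote_csv, write_vote_csv
from belnet.fixtures import (gen_random_ledger, gen_vote_ledgers,
                             open_phase_vote_profiles)


def votes(*directions, user_prefix="u"):
    return [Vote(i + 1, f"{user_prefix}{i}", "ev", d)
            for i, d in enumerate(directions)]


def brute_force_lock(vote_list):
    """Independent first-crossing oracle over effective (superseding) tallies."""
    effective = {}
    for idx, vote in enumerate(sorted(vote_list, key=lambda v: v.seq)):
        effective[vote.user] = vote.direction
        up = sum(1 for d in effective.values() if d == "up")
        down = len(effective) - up
        if up >= 4:
            return ("approved", vote.seq, idx)
        if down >= 4:
            return ("rejected", vote.seq, idx)
    return ("open", None, None)


class TestCastVote:
    def test_four_up_votes_approve(self):
        _, state, refused = replay_ledger(votes("up", "up", "up", "up"))
        assert (state.status, state.locked_at_seq, refused) == ("approved", 4, [])

    def test_three_all_stays_open(self):
        _, state, _ = replay_ledger(votes("up", "down", "up", "down", "up", "down"))
        assert state.status == "open"

    def test_first_threshold_crossed_wins(self):
        """U,U,U,D,D,D,D rejects at seq 7; up never reached four."""
        _, state, _ = replay_ledger(votes("up", "up", "up", "down", "down",
                                          "down", "down"))
        assert (state.status, state.locked_at_seq) == ("rejected", 7)

    def test_supersession_one_effective_vote_per_user(self):
        ledger = VoteLedger([Vote(1, "alice", "ev", "up"),
                             Vote(2, "alice", "ev", "down")])
        assert ledger.effective_tally() == (0, 1)
        assert ledger.raw_tally() == (1, 1)

    def test_vote_on_locked_evidence_refused_with_status(self):
        ledger, state, _ = replay_ledger(votes("up", "up", "up", "up"))
        with pytest.raises(LockedEvidenceError) as err:
            cast_vote(ledger, Vote(5, "u9", "ev", "down"), state)
        assert err.value.status == "approved"

    def test_duplicate_seq_rejected(self):
        ledger = VoteLedger([Vote(1, "a", "ev", "up")])
        with pytest.raises(ValueError):
            ledger.append(Vote(1, "b", "ev", "up"))

    def test_locked_state_never_changes_on_replay(self):
        stream = votes("up", "up", "up", "up", "down", "down")
        first = replay_ledger(stream)[1]
        second = replay_ledger(stream)[1]
        assert first == second == LockState("approved", 4)

    @pytest.mark.parametrize("seed", range(50))
    def test_engine_agrees_with_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        stream = gen_random_ledger(rng)
        _, state, _ = replay_ledger(stream)
        status, seq, _ = brute_force_lock(stream)
        assert (state.status, state.locked_at_seq) == (status, seq)


class TestLockSummary:
    def test_open_phase_totals(self):
        """1795 up + 661 down raw votes = 2456 total."""
        fx = gen_vote_ledgers(open_phase_vote_profiles())
        ledgers = {ev: VoteLedger(vs) for ev, vs in fx.by_evidence.items()}
        summary = lock_summary(ledgers, networks=fx.networks)
        assert summary["total_votes"] == 2456
        assert summary["up_votes"] == 1795
        assert summary["down_votes"] == 661

    def test_neutrophil_share_rounds_to_ten_percent(self):
        fx = gen_vote_ledgers(open_phase_vote_profiles())
        ledgers = {ev: VoteLedger(vs) for ev, vs in fx.by_evidence.items()}
        summary = lock_summary(ledgers, networks=fx.networks)
        assert summary["per_network"]["Neutrophil Signaling"] == 241
        assert summary["network_share_pct"]["Neutrophil Signaling"] == 10

    def test_expected_states_match_replay(self):
        fx = gen_vote_ledgers(open_phase_vote_profiles())
        for ev_id, stream in fx.by_evidence.items():
            _, state, _ = replay_ledger(stream)
            assert (state.status, state.locked_at_seq) == fx.expected[ev_id]

    def test_empty_ledger_set_all_zero(self):
        summary = lock_summary({})
        assert summary["total_votes"] == 0
        assert summary["approved"] == 0

    def test_totals_permutation_invariant(self):
        fx = gen_vote_ledgers(open_phase_vote_profiles())
        items = list(fx.by_evidence.items())
        forward = lock_summary({k: VoteLedger(v) for k, v in items})
        backward = lock_summary({k: VoteLedger(v) for k, v in reversed(items)})
        assert forward == backward

    def test_csv_round_trip(self):
        fx = gen_vote_ledgers(open_phase_vote_profiles()[:5])
        text = write_vote_csv(fx.votes)
        grouped = read_vote_csv(text)
        assert sum(len(v) for v in grouped.values()) == len(fx.votes)


class TestLeaderboard:
    def log_for(self, spec):
        """spec: list of (user, action, count)."""
        entries, seq = [], 0
        for user, action, count in spec:
            for _ in range(count):
                seq += 1
                entries.append(ActionEntry(seq, user, action, f"t{seq}"))
        return ActionLog(entries)

    def test_default_scheme_points(self):
        """3 new_evidence (5 pts each) + 2 votes (1 pt each) = 17 points."""
        log = self.log_for([("alice", "new_evidence", 3), ("alice", "vote", 2)])
        from belnet import LeaderboardRow
        assert leaderboard(log)[0] == LeaderboardRow("alice", 17, 3, 2)

    def test_points_linear_in_action_counts(self):
        single = self.log_for([("a", "new_evidence", 2), ("a", "vote", 3),
                               ("a", "new_node", 1)])
        double = self.log_for([("a", "new_evidence", 4), ("a", "vote", 6),
                               ("a", "new_node", 2)])
        assert leaderboard(double)[0].points == 2 * leaderboard(single)[0].points

    def test_invitee_filter_top20_with_min_votes(self):
        """30 users, 25 with >=20 votes: exactly 20 invited, all qualified."""
        spec = []
        for i in range(30):
            n_votes = 25 if i < 25 else 5
            spec.append((f"user{i:02d}", "vote", n_votes))
            spec.append((f"user{i:02d}", "new_evidence", 30 - i))
        invitees = jamboree_invitees(self.log_for(spec))
        assert len(invitees) == 20
        assert all(r.votes_cast >= 20 for r in invitees)
        created = [r.evidences_created for r in invitees]
        assert created == sorted(created, reverse=True)

    def test_empty_log_empty_board(self):
        assert leaderboard(ActionLog()) == []

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            PointScheme({"new_evidence": 1, "new_edge": 5, "new_node": 2, "vote": 1})


class TestApplyEdit:
    def make_network(self):
        net = Network("Macrophage Signaling")
        stmt = parse_statement("p(HGNC:SFTPA1) increases p(HGNC:IL1B)")
        ev = Evidence("11111111", quote="base", id="base-1")
        net.add_edge(stmt, [ev], Provenance(Phase.PHASE1_LITERATURE))
        return net, statement_key(stmt)

    def test_new_evidence_on_existing_edge(self):
        net, key = self.make_network()
        log = ActionLog()
        edit = CrowdEdit("new_evidence", actor="bob", seq=1, target_statement=key,
                         evidence=Evidence("22222222", quote="support", id="c-1"))
        apply_edit(net, edit, log)
        assert (net.edge_count, net.evidence_count) == (1, 2)
        assert log.entries[0].action == "new_evidence"

    def test_new_edge_with_new_endpoints(self):
        net, _ = self.make_network()
        edit = CrowdEdit("new_edge", actor="bob", seq=1,
                         statement="p(HGNC:NOD2) increases p(HGNC:IFNG)",
                         evidence=Evidence("33333333", quote="q", id="c-2"))
        nodes_before = net.node_count
        apply_edit(net, edit)
        assert net.node_count == nodes_before + 2
        assert net.edge_count == 2

    def test_duplicate_new_edge_degrades_to_new_evidence(self):
        net, _ = self.make_network()
        log = ActionLog()
        edit = CrowdEdit("new_edge", actor="bob", seq=1,
                         statement="p(HGNC:SFTPA1) increases p(HGNC:IL1B)",
                         evidence=Evidence("44444444", quote="another", id="c-3"))
        apply_edit(net, edit, log)
        assert (net.edge_count, net.evidence_count) == (1, 2)
        assert log.entries[0].action == "new_evidence"

    def test_crowd_provenance_recorded(self):
        net, _ = self.make_network()
        edit = CrowdEdit("new_node", actor="carol", seq=9, term="p(HGNC:CD69)")
        apply_edit(net, edit)
        assert net.history[-1][2].phase is Phase.PHASE2_CROWD
        assert net.history[-1][2].actor == "carol"
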