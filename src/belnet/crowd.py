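"""Open-phase crowd verification: vote ledgers, locking, edits, leaderboard.

Evidence is verified by the crowd through up/down votes.  Each user has one
*effective* vote per evidence (a later vote supersedes their earlier one);
once the effective tally reaches four up-votes the evidence is locked as
approved, four down-votes locks it as rejected, and the first threshold
crossed wins.  Locked evidence refuses further votes.  Summary totals
count raw cast votes, mirroring how participation is reported.
"""
from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Optional, Union

from .bel import parse_statement, parse_term, statement_key
from .model import Evidence, Network, Phase, Provenance
from .registries import FunctionRegistry, NamespaceRegistry

LOCK_THRESHOLD = 4


@dataclass(frozen=True)
class Vote:
    seq: int
    user: str
    evidence_id: str
    direction: str  # "up" | "down"

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"invalid vote direction: {self.direction!r}")


class VoteLedger:
    """Append-only, seq-ordered list of votes on one evidence."""

    def __init__(self, votes: Iterable[Vote] = ()):
        self.votes: list[Vote] = []
        for v in votes:
            self.append(v)

    def append(self, vote: Vote) -> None:
        if self.votes and vote.seq <= self.votes[-1].seq:
            raise ValueError(
                f"vote seq {vote.seq} does not increase past {self.votes[-1].seq}")
        self.votes.append(vote)

    def effective(self) -> dict:
        """Last vote per user wins."""
        result: dict[str, str] = {}
        for v in self.votes:
            result[v.user] = v.direction
        return result

    def effective_tally(self) -> tuple[int, int]:
        eff = self.effective()
        up = sum(1 for d in eff.values() if d == "up")
        return up, len(eff) - up

    def raw_tally(self) -> tuple[int, int]:
        up = sum(1 for v in self.votes if v.direction == "up")
        return up, len(self.votes) - up

    def __len__(self) -> int:
        return len(self.votes)


@dataclass(frozen=True)
class LockState:
    status: str = "open"  # open | approved | rejected
    locked_at_seq: Optional[int] = None


class LockedEvidenceError(RuntimeError):
    """Raised when a vote is cast on already-locked evidence."""

    def __init__(self, status: str, seq: int):
        super().__init__(f"evidence is locked ({status}); vote seq {seq} refused")
        self.status = status
        self.seq = seq


def cast_vote(ledger: VoteLedger, vote: Vote, state: LockState) -> tuple[VoteLedger, LockState]:
    """Record a vote and re-check the lock thresholds.

    The effective tallies (with supersession) are recomputed after every
    vote; the first threshold crossed locks the evidence permanently.
    """
    if state.status != "open":
        raise LockedEvidenceError(state.status, vote.seq)
    ledger.append(vote)
    up, down = ledger.effective_tally()
    if up >= LOCK_THRESHOLD:
        state = LockState("approved", vote.seq)
    elif down >= LOCK_THRESHOLD:
        state = LockState("rejected", vote.seq)
    return ledger, state


def replay_ledger(votes: Iterable[Vote]) -> tuple[VoteLedger, LockState, list[Vote]]:
    """Fold ``cast_vote`` over a recorded vote stream.

    Votes arriving after the lock are collected as refused (they remain in
    the raw record for reporting but never change the state).
    """
    ledger, state = VoteLedger(), LockState()
    refused: list[Vote] = []
    for vote in sorted(votes, key=lambda v: v.seq):
        try:
            ledger, state = cast_vote(ledger, vote, state)
        except LockedEvidenceError:
            refused.append(vote)
    return ledger, state, refused


def lock_summary(ledgers: dict, states: Optional[dict] = None,
                 networks: Optional[dict] = None) -> dict:
    """Aggregate vote totals (raw cast votes) and lock outcomes.

    ``ledgers`` maps evidence id -> VoteLedger; ``states`` may supply
    precomputed LockStates (otherwise each ledger is replayed); ``networks``
    optionally maps evidence id -> network name for per-network totals and
    integer percent shares (rounded half-up).
    """
    if states is None:
        states = {ev: replay_ledger(ledger.votes)[1] for ev, ledger in ledgers.items()}
    up_total = down_total = 0
    status_counts: Counter = Counter()
    per_network: Counter = Counter()
    for ev_id, ledger in ledgers.items():
        up, down = ledger.raw_tally()
        up_total += up
        down_total += down
        status_counts[states[ev_id].status] += 1
        if networks is not None:
            per_network[networks.get(ev_id, "unassigned")] += len(ledger)
    total = up_total + down_total
    summary = {
        "total_votes": total,
        "up_votes": up_total,
        "down_votes": down_total,
        "approved": status_counts["approved"],
        "rejected": status_counts["rejected"],
        "open": status_counts["open"],
    }
    if networks is not None:
        summary["per_network"] = dict(sorted(per_network.items()))
        summary["network_share_pct"] = {
            name: int((100.0 * count / total) + 0.5) if total else None
            for name, count in sorted(per_network.items())
        }
    return summary


# ---------------------------------------------------------------------------
# Action log, points, leaderboard

ACTIONS = ("vote", "new_evidence", "new_edge", "new_node")


@dataclass(frozen=True)
class ActionEntry:
    seq: int
    user: str
    action: str
    target: str

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action: {self.action!r}")


class ActionLog:
    """Append-only chronological record of crowd activity."""

    def __init__(self, entries: Iterable[ActionEntry] = ()):
        self.entries: list[ActionEntry] = []
        for e in entries:
            self.append(e)

    def append(self, entry: ActionEntry) -> None:
        if self.entries and entry.seq <= self.entries[-1].seq:
            raise ValueError(f"action seq {entry.seq} does not increase")
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PointScheme:
    """Credit points per action type.

    The platform's exact values were never published; these defaults are a
    declared convention (creating evidence must outscore voting) and every
    leaderboard reports the scheme it used.
    """

    points: dict = field(default_factory=lambda: {
        "new_evidence": 5, "new_edge": 5, "new_node": 2, "vote": 1})

    def __post_init__(self):
        missing = set(ACTIONS) - set(self.points)
        if missing:
            raise ValueError(f"point scheme missing actions: {sorted(missing)}")
        if self.points["new_evidence"] <= self.points["vote"]:
            raise ValueError("new_evidence points must exceed vote points")


@dataclass(frozen=True)
class LeaderboardRow:
    user: str
    points: int
    evidences_created: int
    votes_cast: int


def leaderboard(log: ActionLog, scheme: Optional[PointScheme] = None) -> list[LeaderboardRow]:
    """Rank users by points, ties broken by evidences created then user id."""
    scheme = scheme or PointScheme()
    per_user: dict[str, Counter] = {}
    for entry in log.entries:
        per_user.setdefault(entry.user, Counter())[entry.action] += 1
    rows = [
        LeaderboardRow(
            user=user,
            points=sum(scheme.points[a] * c for a, c in counts.items()),
            evidences_created=counts["new_evidence"],
            votes_cast=counts["vote"],
        )
        for user, counts in per_user.items()
    ]
    rows.sort(key=lambda r: (-r.points, -r.evidences_created, r.user))
    return rows


def jamboree_invitees(log: ActionLog, min_votes: int = 20, top_n: int = 20,
                      scheme: Optional[PointScheme] = None) -> list[LeaderboardRow]:
    """Top performers by evidences created among users with >= min_votes votes."""
    eligible = [r for r in leaderboard(log, scheme) if r.votes_cast >= min_votes]
    eligible.sort(key=lambda r: (-r.evidences_created, -r.points, r.user))
    return eligible[:top_n]


# ---------------------------------------------------------------------------
# Crowd edits


@dataclass
class CrowdEdit:
    """One open-phase contribution: a new node, edge, or piece of evidence."""

    kind: str  # new_node | new_edge | new_evidence
    actor: str
    seq: int
    statement: Optional[str] = None  # BEL statement text (new_edge)
    term: Optional[str] = None  # BEL term text (new_node)
    target_statement: Optional[str] = None  # canonical key or text (new_evidence)
    evidence: Optional[Evidence] = None

    def __post_init__(self):
        if self.kind not in ("new_node", "new_edge", "new_evidence"):
            raise ValueError(f"unknown edit kind: {self.kind!r}")


def apply_edit(network: Network, edit: CrowdEdit,
               log: Optional[ActionLog] = None,
               functions: Optional[FunctionRegistry] = None,
               namespaces: Optional[NamespaceRegistry] = None) -> Network:
    """Apply a crowd edit with phase2_crowd provenance and log the action.

    A new_edge duplicating an existing canonical statement degrades to (and
    is logged as) new_evidence, matching the edge-dedup rule.
    """
    prov = Provenance(Phase.PHASE2_CROWD, actor=edit.actor, timestamp=edit.seq)
    if edit.kind == "new_node":
        term = parse_term(edit.term, functions, namespaces)
        key = network.add_node(term, prov)
        action = "new_node"
    elif edit.kind == "new_edge":
        if edit.evidence is None:
            raise ValueError("new_edge requires an evidence record")
        stmt = parse_statement(edit.statement, functions, namespaces)
        key = statement_key(stmt)
        pre_existing = network.get_edge(key) is not None
        network.add_edge(stmt, [edit.evidence], prov)
        action = "new_evidence" if pre_existing else "new_edge"
    else:  # new_evidence
        if edit.evidence is None:
            raise ValueError("new_evidence requires an evidence record")
        key = edit.target_statement
        if network.get_edge(key) is None:
            # allow statement text instead of a canonical key
            key = statement_key(parse_statement(edit.target_statement,
                                                functions, namespaces))
        network.add_evidence(key, edit.evidence, prov)
        action = "new_evidence"
    if log is not None:
        log.append(ActionEntry(edit.seq, edit.actor, action, key))
    return network


# ---------------------------------------------------------------------------
# CSV interfaces


def read_vote_csv(source: str) -> dict:
    """Parse a ledger CSV (seq,user,evidence_id,direction) into per-evidence
    vote lists, ordered by seq."""
    text = source if "\n" in source else open(source, encoding="utf-8").read()
    reader = csv.DictReader(StringIO(text))
    votes = [Vote(int(r["seq"]), r["user"], r["evidence_id"], r["direction"])
             for r in reader]
    votes.sort(key=lambda v: v.seq)
    grouped: dict[str, list[Vote]] = {}
    for v in votes:
        grouped.setdefault(v.evidence_id, []).append(v)
    return grouped


def write_vote_csv(votes: Iterable[Vote]) -> str:
    out = StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["seq", "user", "evidence_id", "direction"])
    for v in sorted(votes, key=lambda v: v.seq):
        writer.writerow([v.seq, v.user, v.evidence_id, v.direction])
    return out.getvalue()


def read_action_csv(source: str) -> ActionLog:
    text = source if "\n" in source else open(source, encoding="utf-8").read()
    reader = csv.DictReader(StringIO(text))
    entries = [ActionEntry(int(r["seq"]), r["user"], r["action"], r["target"])
               for r in reader]
    entries.sort(key=lambda e: e.seq)
    return ActionLog(entries)


def write_action_csv(log: ActionLog) -> str:
    out = StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["seq", "user", "action", "target"])
    for e in log.entries:
        writer.writerow([e.seq, e.user, e.action, e.target])
    return out.getvalue()
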