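"""Deterministic synthetic inputs for every stage of the toolkit.

Nothing here downloads anything: gene identifiers are synthesized in the
numeric EGID namespace, knowledgebases are random signed target sets with
optional planted (truly active) mechanisms, vote ledgers realize
configured tallies, and network version pairs are built by scripted
additions so the expected diff is known by construction.

Truth records are computed by direct closed-form summation (``math.comb``),
independently of the scoring engine, so they can serve as oracles.

All generators consume a :class:`random.Random` seeded from
``FixtureConfig.seed``; a fixed seed gives byte-identical text output.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .bel import (BelStatement, BelTerm, EntityRef, Relation, canonical_key,
                  statement_key)
from .model import Evidence, Network, Phase, PhaseDiff, Provenance
from .crowd import Vote

# ---------------------------------------------------------------------------
# Independent tail oracles (exact integer arithmetic via math.comb)


def hypergeom_upper_tail(k: int, n: int, m: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, m, n), by direct summation."""
    if k == 0:
        return 1.0
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, m) + 1):
        acc += math.comb(m, j) * math.comb(N - m, n - j)
    return acc / total


def binom_upper_tail(c: int, k: int) -> float:
    """P(X >= c) for X ~ Binomial(k, 1/2), by direct summation."""
    if k == 0 or c == 0:
        return 1.0
    return sum(math.comb(k, j) for j in range(c, k + 1)) / 2 ** k


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate one early-COPD-scale comparison: a 1000-gene measured
    universe, a 10-mechanism knowledgebase with 20 signed targets each, one
    planted mechanism whose targets include 18 concordant state changes,
    and background state changes at a rate giving ~50 SCs in total.
    """

    seed: int = 0
    n_genes: int = 1000
    n_hyps: int = 10
    targets_per_hyp: int = 20
    signal_hyps: tuple = ((0, 18),)  # (hyp index, n concordant planted SCs)
    background_sc_rate: float = 0.033

    def __post_init__(self):
        if self.targets_per_hyp > self.n_genes:
            raise ValueError("targets_per_hyp exceeds universe size")
        for idx, n_conc in self.signal_hyps:
            if not 0 <= idx < self.n_hyps:
                raise ValueError(f"signal hyp index {idx} out of range")
            if n_conc > self.targets_per_hyp:
                raise ValueError("planted signal exceeds targets_per_hyp")

    def rng(self) -> random.Random:
        return random.Random(self.seed)


# ---------------------------------------------------------------------------
# RCR fixture: knowledgebase + expression table + truth record


@dataclass
class RcrFixture:
    kb_tsv: str
    expression_tsv: str
    truth: dict  # hyp upstream key -> {k, c, richness_p, concordance_p, significant, planted}


def gen_kb_and_expression(config: Optional[FixtureConfig] = None) -> RcrFixture:
    """Generate a KB, an expression table, and a directly computed truth record.

    Planted mechanisms get their configured number of concordant state
    changes among their targets; remaining genes become background SCs at
    ``background_sc_rate`` with random direction.  Significance in the
    truth record is computed with the closed-form tail oracles at the
    0.1/0.1 cutoffs, never with the scoring engine.
    """
    config = config or FixtureConfig()
    rng = config.rng()
    gene_ids = [str(i) for i in range(1, config.n_genes + 1)]
    gene_keys = [f"EGID:{g}" for g in gene_ids]

    hyps = []
    for h in range(config.n_hyps):
        upstream = f"p(EGID:{900000 + h})"
        targets = rng.sample(range(config.n_genes), config.targets_per_hyp)
        signs = {gene_keys[t]: rng.choice("+-") for t in targets}
        hyps.append((upstream, signs))

    # plant concordant state changes for the signal mechanisms
    sc_direction: dict[str, str] = {}
    for idx, n_conc in config.signal_hyps:
        upstream, signs = hyps[idx]
        chosen = rng.sample(sorted(signs), n_conc)
        for gene in chosen:
            sc_direction[gene] = "up" if signs[gene] == "+" else "down"
    # background state changes on the remaining genes
    for gene in gene_keys:
        if gene not in sc_direction and rng.random() < config.background_sc_rate:
            sc_direction[gene] = rng.choice(["up", "down"])

    # expression rows: SCs pass all three cutoffs, others fail exactly one
    expr_lines = ["gene_ns\tgene_id\tfold_change\tfdr_p\tmean_expression"]
    for gene_id, gene_key in zip(gene_ids, gene_keys):
        if gene_key in sc_direction:
            fc = rng.uniform(1.5, 4.0)
            if sc_direction[gene_key] == "down":
                fc = -fc
            fdr = rng.uniform(0.001, 0.04)
            expr = rng.uniform(150.0, 5000.0)
        else:
            mode = rng.randrange(3)
            fc = rng.uniform(1.01, 1.25) * rng.choice((1, -1))
            fdr = rng.uniform(0.001, 0.04)
            expr = rng.uniform(150.0, 5000.0)
            if mode == 0:
                fdr = rng.uniform(0.1, 0.9)
                fc = rng.uniform(1.5, 4.0) * rng.choice((1, -1))
            elif mode == 1:
                pass  # small fold change is the failing criterion
            else:
                expr = rng.uniform(1.0, 90.0)
                fc = rng.uniform(1.5, 4.0) * rng.choice((1, -1))
        expr_lines.append(f"EGID\t{gene_id}\t{fc:.4f}\t{fdr:.5f}\t{expr:.2f}")

    kb_lines = ["upstream\tdownstream\tsign"]
    for upstream, signs in hyps:
        for gene, sign in sorted(signs.items()):
            kb_lines.append(f"{upstream}\t{gene}\t{sign}")

    planted = {hyps[idx][0] for idx, _ in config.signal_hyps}
    n_sc, n_universe = len(sc_direction), config.n_genes
    truth = {}
    for upstream, signs in hyps:
        overlap = [g for g in signs if g in sc_direction]
        k = len(overlap)
        c = sum(1 for g in overlap
                if (signs[g] == "+") == (sc_direction[g] == "up"))
        rp = hypergeom_upper_tail(k, n_sc, len(signs), n_universe)
        cp = binom_upper_tail(c, k)
        truth[upstream] = {
            "k": k, "c": c, "n_sc": n_sc, "m": len(signs), "N": n_universe,
            "richness_p": rp, "concordance_p": cp,
            "significant": rp < 0.1 and cp < 0.1,
            "planted": upstream in planted,
        }
    return RcrFixture("\n".join(kb_lines) + "\n", "\n".join(expr_lines) + "\n", truth)


# ---------------------------------------------------------------------------
# Vote-ledger fixture


@dataclass
class VoteProfile:
    evidence_id: str
    network: str
    n_up: int
    n_down: int
    pattern: str = "up_first"  # up_first | down_first | alternate


@dataclass
class VoteFixture:
    votes: list  # all Vote records, seq-ordered
    by_evidence: dict  # evidence id -> list of Vote
    networks: dict  # evidence id -> network name
    expected: dict  # evidence id -> (status, locked_at_seq or None)


def _interleave(n_up: int, n_down: int, pattern: str) -> list[str]:
    if pattern == "up_first":
        return ["up"] * n_up + ["down"] * n_down
    if pattern == "down_first":
        return ["down"] * n_down + ["up"] * n_up
    if pattern == "alternate":
        out = []
        ups, downs = n_up, n_down
        while ups or downs:
            if ups:
                out.append("up")
                ups -= 1
            if downs:
                out.append("down")
                downs -= 1
        return out
    raise ValueError(f"unknown interleaving pattern: {pattern!r}")


def gen_vote_ledgers(profiles: Iterable[VoteProfile]) -> VoteFixture:
    """Realize vote profiles as a global seq-ordered ledger with expected states.

    Every vote comes from a distinct user, so raw and effective tallies
    coincide.  Expected lock states come from a direct first-crossing scan
    of each evidence's vote sequence (independent of the voting engine).
    """
    votes: list[Vote] = []
    by_evidence: dict[str, list[Vote]] = {}
    networks: dict[str, str] = {}
    expected: dict[str, tuple] = {}
    seq = 0
    for profile in profiles:
        directions = _interleave(profile.n_up, profile.n_down, profile.pattern)
        ev_votes: list[Vote] = []
        for d in directions:
            seq += 1
            vote = Vote(seq, f"user{seq:05d}", profile.evidence_id, d)
            votes.append(vote)
            ev_votes.append(vote)
        by_evidence[profile.evidence_id] = ev_votes
        networks[profile.evidence_id] = profile.network
        # first-crossing scan
        up = down = 0
        status, locked_at = "open", None
        for vote in ev_votes:
            if status != "open":
                break
            if vote.direction == "up":
                up += 1
            else:
                down += 1
            if up >= 4:
                status, locked_at = "approved", vote.seq
            elif down >= 4:
                status, locked_at = "rejected", vote.seq
        expected[profile.evidence_id] = (status, locked_at)
    return VoteFixture(votes, by_evidence, networks, expected)


def open_phase_vote_profiles() -> list[VoteProfile]:
    """The open-phase voting record at full published scale.

    484 evidences realize 1795 up and 661 down votes (2456 in all):
    406 approved evidences (4 up, 1 down, down first), 21 rejected
    (4 down), and 57 still open (3 up / 3 down alternating).  The
    Neutrophil Signaling network holds 241 of the votes (~10%),
    Macrophage Signaling 180, and Th1-Th2 Signaling 105; the remainder
    spread over the other networks.
    """
    profiles: list[VoteProfile] = []
    approved = [("Neutrophil Signaling", 43), ("Macrophage Signaling", 36),
                ("Th1-Th2 Signaling", 21), ("Other Networks", 306)]
    i = 0
    for network, count in approved:
        for _ in range(count):
            profiles.append(VoteProfile(f"ev{i:04d}", network, 4, 1, "down_first"))
            i += 1
    rejected = [("Neutrophil Signaling", 5), ("Other Networks", 16)]
    for network, count in rejected:
        for _ in range(count):
            profiles.append(VoteProfile(f"ev{i:04d}", network, 0, 4, "down_first"))
            i += 1
    still_open = [("Neutrophil Signaling", 1), ("Other Networks", 56)]
    for network, count in still_open:
        for _ in range(count):
            profiles.append(VoteProfile(f"ev{i:04d}", network, 3, 3, "alternate"))
            i += 1
    return profiles


def gen_random_ledger(rng: random.Random, n_votes: Optional[int] = None,
                      n_users: Optional[int] = None) -> list[Vote]:
    """A random single-evidence vote sequence (for oracle-agreement sweeps)."""
    n_votes = n_votes if n_votes is not None else rng.randint(1, 12)
    n_users = n_users if n_users is not None else rng.randint(2, 8)
    return [Vote(i + 1, f"u{rng.randrange(n_users)}", "ev",
                 rng.choice(["up", "down"])) for i in range(n_votes)]


# ---------------------------------------------------------------------------
# Random terms and networks (round-trip sweeps)

_GENERATOR_NAMESPACES = ("HGNC", "EGID", "MGI", "RGD", "CHEBI", "GO")
_LEAF_FUNCTIONS = ("p", "r", "g", "m", "a", "bp", "path")
_WRAPPER_FUNCTIONS = ("act", "cat", "kin", "tscript", "deg", "sec", "surf")


def gen_random_entity(rng: random.Random) -> EntityRef:
    ns = rng.choice(_GENERATOR_NAMESPACES)
    if rng.random() < 0.15:
        name = f"{rng.choice(('cellular', 'oxidative', 'immune'))} " \
               f"{rng.choice(('stress response', 'senescence', 'activation'))}"
    else:
        name = f"G{rng.randrange(1, 99999)}"
    return EntityRef(ns, name)


def gen_random_term(rng: random.Random, depth: int = 1, max_depth: int = 4) -> BelTerm:
    """A random valid term with nesting depth <= ``max_depth``."""
    roll = rng.random()
    if depth >= max_depth or roll < 0.55:
        return BelTerm(rng.choice(_LEAF_FUNCTIONS), (gen_random_entity(rng),))
    if roll < 0.85:
        return BelTerm(rng.choice(_WRAPPER_FUNCTIONS),
                       (gen_random_term(rng, depth + 1, max_depth),))
    n_args = rng.randint(2, 3)
    args = tuple(
        gen_random_term(rng, depth + 1, max_depth) if rng.random() < 0.4
        else BelTerm("p", (gen_random_entity(rng),))
        for _ in range(n_args))
    return BelTerm(rng.choice(("complex", "composite")), args)


def gen_random_network(rng: random.Random, name: str = "random",
                       n_nodes: int = 8, n_edges: int = 10) -> Network:
    """A random small network with literature-phase evidence on every edge."""
    network = Network(name, description=f"synthetic network {name}")
    terms: dict[str, BelTerm] = {}
    while len(terms) < n_nodes:
        term = gen_random_term(rng, max_depth=3)
        terms[canonical_key(term)] = term
    keys = sorted(terms)
    prov = Provenance(Phase.PHASE1_LITERATURE, actor="fixture")
    attempts = 0
    while network.edge_count < n_edges and attempts < n_edges * 20:
        attempts += 1
        a, b = rng.sample(keys, 2)
        relation = rng.choice((Relation.INCREASES, Relation.DECREASES))
        stmt = BelStatement(terms[a], relation, terms[b])
        if network.get_edge(statement_key(stmt)) is not None:
            continue
        ev = Evidence(citation=f"{rng.randrange(10000000, 29999999)}",
                      quote=f"synthetic evidence {rng.randrange(1_000_000)}",
                      id=f"fx-{name}-{network.edge_count}-{rng.randrange(1_000_000)}")
        network.add_edge(stmt, [ev], prov)
    for key in keys:
        network.add_node(terms[key], prov)
    return network


# ---------------------------------------------------------------------------
# Version pairs with known diffs


@dataclass
class VersionScriptRow:
    """Scripted additions to one network: node, edge, and evidence counts.

    ``evidences`` defaults to the edge count (each new edge carries one
    evidence); a larger value appends the surplus to existing edges.
    """

    network: str
    nodes: int
    edges: int
    evidences: Optional[int] = None
    phase: Phase = Phase.PHASE2_CROWD

    def __post_init__(self):
        if self.evidences is None:
            self.evidences = self.edges
        if self.evidences < self.edges:
            raise ValueError("evidences cannot be fewer than new edges")


@dataclass
class VersionFixture:
    old: list  # Networks before
    new: list  # Networks after
    expected: PhaseDiff


def _base_network(name: str, offset: int, n_nodes: int = 4) -> Network:
    """A small chain network over synthetic EGID genes."""
    net = Network(name, description=f"base fixture {name}")
    prov = Provenance(Phase.PHASE0_NONDISEASED, actor="fixture")
    terms = [BelTerm("p", (EntityRef("EGID", str(offset + i)),))
             for i in range(n_nodes)]
    for i in range(n_nodes - 1):
        ev = Evidence(citation=f"{20000000 + offset + i}",
                      quote=f"base evidence {name} {i}",
                      id=f"base-{offset}-{i}")
        net.add_edge(BelStatement(terms[i], Relation.INCREASES, terms[i + 1]),
                     [ev], prov)
    return net


def gen_version_pairs(script: Iterable[VersionScriptRow],
                      rng: Optional[random.Random] = None) -> VersionFixture:
    """Build (old, new) network sets where the diff is known by construction.

    Each script row adds the stated numbers of nodes, edges, and evidences
    to a fresh copy of a small base network; ``diff_versions(old, new)``
    must equal the script's counts exactly.
    """
    rng = rng or random.Random(0)
    script = list(script)
    old: list[Network] = []
    new: list[Network] = []
    breakdown: dict[str, tuple[int, int, int]] = {}
    citations: set[str] = set()
    for row_idx, row in enumerate(script):
        offset = (row_idx + 1) * 10_000
        base = _base_network(row.network, offset)
        updated = base.copy()
        prov = Provenance(row.phase, actor="fixture", timestamp=row_idx)
        new_keys = []
        for i in range(row.nodes):
            term = BelTerm("p", (EntityRef("EGID", str(offset + 1000 + i)),))
            new_keys.append(updated.add_node(term, prov))
        pool = sorted(updated.nodes)
        if len(pool) < 2 and row.edges:
            raise ValueError("not enough nodes to add edges")
        added_edges = 0
        ev_serial = 0
        pairs = [(a, b) for a in pool for b in pool if a != b]
        rng.shuffle(pairs)
        for a, b in pairs:
            if added_edges >= row.edges:
                break
            stmt = BelStatement(updated.nodes[a], Relation.INCREASES, updated.nodes[b])
            if updated.get_edge(statement_key(stmt)) is not None:
                continue
            citation = f"{30000000 + offset + ev_serial}"
            ev = Evidence(citation=citation, quote=f"added evidence {offset}-{ev_serial}",
                          id=f"add-{offset}-{ev_serial}")
            updated.add_edge(stmt, [ev], prov)
            citations.add(citation)
            ev_serial += 1
            added_edges += 1
        if added_edges < row.edges:
            raise ValueError(f"could not place {row.edges} edges in {row.network}")
        surplus = row.evidences - row.edges
        base_edge_keys = sorted(e.key for e in base.edges)
        if surplus and not base_edge_keys:
            raise ValueError("no existing edges to attach surplus evidence to")
        for j in range(surplus):
            citation = f"{40000000 + offset + j}"
            ev = Evidence(citation=citation, quote=f"surplus evidence {offset}-{j}",
                          id=f"sur-{offset}-{j}")
            updated.add_evidence(base_edge_keys[j % len(base_edge_keys)], ev, prov)
            citations.add(citation)
        old.append(base)
        new.append(updated)
        breakdown[row.network] = (row.nodes, row.edges, row.evidences)
    totals = tuple(sum(v[i] for v in breakdown.values()) for i in range(3))
    expected = PhaseDiff(*totals, breakdown=breakdown, citations=citations)
    return VersionFixture(old, new, expected)


def jamboree_version_script() -> list[VersionScriptRow]:
    """Jamboree-phase additions: 167 nodes and 296 edges in total, with the
    three inflammatory networks receiving 148 nodes and 263 edges (89%)."""
    return [
        VersionScriptRow("Neutrophil Signaling", 69, 129, phase=Phase.PHASE3_JAMBOREE),
        VersionScriptRow("Macrophage Signaling", 49, 88, phase=Phase.PHASE3_JAMBOREE),
        VersionScriptRow("Th1-Th2 Signaling", 30, 46, phase=Phase.PHASE3_JAMBOREE),
        VersionScriptRow("Other Networks", 19, 33, phase=Phase.PHASE3_JAMBOREE),
    ]


def open_phase_version_script() -> list[VersionScriptRow]:
    """Open-phase additions: 351 nodes, 451 edges, 885 evidences in total,
    with 266 of the evidences and 208 of the edges in the three focus
    networks (30% and 46%), including the neutrophil record of 116 nodes,
    160 edges, and 181 evidences."""
    return [
        VersionScriptRow("Neutrophil Signaling", 116, 160, 181),
        VersionScriptRow("Macrophage Signaling", 23, 39, 72),
        VersionScriptRow("Th1-Th2 Signaling", 10, 9, 13),
        VersionScriptRow("Other Networks", 202, 243, 619),
    ]


def phase1_version_script() -> list[VersionScriptRow]:
    """Phase-1 additions: 200 nodes and 487 edges, of which 415 edges come
    from literature curation and 72 from RCR predictions."""
    return [
        VersionScriptRow("Literature Enhanced", 120, 415,
                         phase=Phase.PHASE1_LITERATURE),
        VersionScriptRow("Data Enhanced", 80, 72, phase=Phase.PHASE1_RCR),
    ]


# ---------------------------------------------------------------------------
# Merge fixture (network agglomeration arithmetic)


def gen_merge_fixture(rng: Optional[random.Random] = None):
    """90 small networks plus a spec merging 56 of them into 16 groups with
    34 standalone networks (16 + 34 = 50 outputs).  Returns (networks, spec).
    """
    from .agglomerate import MergeSpec

    rng = rng or random.Random(0)
    names = [f"Network {i:02d}" for i in range(1, 91)]
    networks = [_base_network(name, offset=(i + 1) * 100)
                for i, name in enumerate(names)]
    # 16 groups over 56 sources: 8 groups of 4 and 8 groups of 3
    group_sizes = [4] * 8 + [3] * 8
    cursor = 0
    groups = []
    for g, size in enumerate(group_sizes):
        groups.append((f"Merged Model {g + 1:02d}", names[cursor:cursor + size]))
        cursor += size
    standalone = names[cursor:]
    assert cursor == 56 and len(standalone) == 34
    return networks, MergeSpec(groups=groups, standalone=standalone)


def th1_merge_fixture():
    """The three T-helper source networks and the spec merging them into a
    single Th1 Signaling model."""
    from .agglomerate import MergeSpec

    sources = ["Th1 Differentiation", "Th1 Response", "T-cell Recruitment/Activation"]
    networks = [_base_network(name, offset=(i + 1) * 500)
                for i, name in enumerate(sources)]
    spec = MergeSpec(groups=[("Th1 Signaling", sources)], standalone=[])
    return networks, spec
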