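"""Versioned causal network models with evidence, provenance, and diffs.

A :class:`Network` holds BEL-term nodes keyed by their canonical
serialization and a list of edges, each backed by one or more literature
:class:`Evidence` records.  Every mutation bumps the revision counter and
appends a history entry, so the construction phases (initial non-diseased
scaffold, literature/data enhancement, crowd verification, jamboree) leave
a full audit trail.  Deletion is modeled as an evidence status change,
never physical removal.
"""
from __future__ import annotations

import copy as _copy
import hashlib
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Union

import networkx as nx
import yaml

from .bel import (BelStatement, BelTerm, OpaqueTerm, Relation, TermLike,
                  canonical_key, statement_key)

CONTEXT_KEYS = ("species", "tissue", "cell_type", "disease", "exposure")


class Phase(str, Enum):
    """Network-construction phase a change originated from."""

    PHASE0_NONDISEASED = "phase0_nondiseased"
    PHASE1_LITERATURE = "phase1_literature"
    PHASE1_RCR = "phase1_rcr"
    PHASE2_CROWD = "phase2_crowd"
    PHASE3_JAMBOREE = "phase3_jamboree"


def evidence_id(citation: str, quote: str, extra: str = "") -> str:
    """Default evidence identity: short hash of citation + quote (+ extra)."""
    digest = hashlib.sha1(f"{citation}\x1f{quote}\x1f{extra}".encode()).hexdigest()
    return digest[:12]


@dataclass
class Evidence:
    """A citation + supporting quote + experimental context for an edge."""

    citation: str
    quote: str = ""
    context: dict = field(default_factory=dict)
    id: str = ""
    status: str = "open"  # open | approved | rejected
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        if not self.citation:
            raise ValueError("evidence citation must be non-empty")
        unknown = set(self.context) - set(CONTEXT_KEYS)
        if unknown:
            raise ValueError(f"unknown context keys: {sorted(unknown)}")
        if self.status not in ("open", "approved", "rejected"):
            raise ValueError(f"invalid evidence status: {self.status!r}")
        if not self.id:
            self.id = evidence_id(self.citation, self.quote)

    def set_status(self, status: str) -> None:
        """Only open -> approved and open -> rejected are legal transitions."""
        if self.status != "open":
            raise ValueError(f"evidence {self.id} is already {self.status}")
        if status not in ("approved", "rejected"):
            raise ValueError(f"invalid target status: {status!r}")
        self.status = status


@dataclass(frozen=True)
class Provenance:
    phase: Phase
    actor: str = ""
    timestamp: int = 0


@dataclass
class Edge:
    """A BEL statement plus its supporting evidence and provenance."""

    statement: BelStatement
    evidences: list
    provenance: Provenance
    collapsed_forms: list = field(default_factory=list)

    def __post_init__(self):
        if not self.evidences:
            raise ValueError("an edge requires at least one evidence")
        ids = [ev.id for ev in self.evidences]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate evidence ids within an edge")

    @property
    def key(self) -> str:
        return statement_key(self.statement)


class Network:
    """A named, versioned causal network model."""

    def __init__(self, name: str, description: str = ""):
        self.name = name
        self.description = description
        self.nodes: dict[str, TermLike] = {}
        self.edges: list[Edge] = []
        self._edges_by_key: dict[str, Edge] = {}
        self.revision = 0
        self.history: list[tuple[int, str, Provenance]] = []

    # -- bookkeeping -------------------------------------------------------
    def _record(self, description: str, provenance: Provenance) -> None:
        self.revision += 1
        self.history.append((self.revision, description, provenance))

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    @property
    def evidence_count(self) -> int:
        return sum(len(e.evidences) for e in self.edges)

    @property
    def unparsed_nodes(self) -> set:
        return {k for k, t in self.nodes.items() if isinstance(t, OpaqueTerm)}

    def citations(self) -> set:
        return {ev.citation for e in self.edges for ev in e.evidences}

    def get_edge(self, key: str) -> Optional[Edge]:
        return self._edges_by_key.get(key)

    def evidence_ids(self) -> set:
        return {ev.id for e in self.edges for ev in e.evidences}

    # -- mutation ----------------------------------------------------------
    def add_node(self, term: TermLike, provenance: Provenance) -> str:
        """Add a node (no-op if already present); returns its canonical key."""
        key = canonical_key(term)
        if key not in self.nodes:
            self.nodes[key] = term
            self._record(f"node added: {key}", provenance)
        return key

    def add_edge(self, statement: BelStatement, evidences: Iterable[Evidence],
                 provenance: Provenance) -> Edge:
        """Add an edge, or append evidence to the existing canonical edge.

        Endpoints are auto-created; an identical canonical statement never
        yields a duplicate edge.  Raises on an empty evidence list or a
        duplicate evidence id.
        """
        evidences = list(evidences)
        if not evidences:
            raise ValueError("an edge requires at least one evidence")
        new_ids = [ev.id for ev in evidences]
        if len(new_ids) != len(set(new_ids)):
            raise ValueError("duplicate evidence ids in submission")
        key = statement_key(statement)
        existing = self._edges_by_key.get(key)
        if existing is not None:
            have = {ev.id for ev in existing.evidences}
            clash = have.intersection(new_ids)
            if clash:
                raise ValueError(f"duplicate evidence id(s) {sorted(clash)} on edge {key}")
            existing.evidences.extend(evidences)
            self._record(f"evidence added to edge: {key}", provenance)
            return existing
        for endpoint in (statement.subject, statement.object):
            ep_key = canonical_key(endpoint)
            if ep_key not in self.nodes:
                self.nodes[ep_key] = endpoint
        edge = Edge(statement, evidences, provenance)
        self.edges.append(edge)
        self._edges_by_key[key] = edge
        self._record(f"edge added: {key}", provenance)
        return edge

    def add_evidence(self, statement_key_str: str, evidence: Evidence,
                     provenance: Provenance) -> Edge:
        """Append one evidence to an existing edge (by canonical statement key)."""
        edge = self._edges_by_key.get(statement_key_str)
        if edge is None:
            raise KeyError(f"no edge with statement key {statement_key_str!r}")
        if any(ev.id == evidence.id for ev in edge.evidences):
            raise ValueError(f"duplicate evidence id {evidence.id!r}")
        edge.evidences.append(evidence)
        self._record(f"evidence added to edge: {statement_key_str}", provenance)
        return edge

    # -- conversion --------------------------------------------------------
    def copy(self) -> "Network":
        return _copy.deepcopy(self)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(name=self.name)
        for key, term in self.nodes.items():
            g.add_node(key, unparsed=isinstance(term, OpaqueTerm))
        for edge in self.edges:
            g.add_edge(canonical_key(edge.statement.subject),
                       canonical_key(edge.statement.object),
                       relation=edge.statement.relation.code,
                       evidences=len(edge.evidences))
        return g

    def __repr__(self) -> str:
        return (f"Network({self.name!r}, nodes={self.node_count}, "
                f"edges={self.edge_count}, rev={self.revision})")


# ---------------------------------------------------------------------------
# Boundary-condition evidence filter

#: Exclusions used for the early-COPD models: diseases with a different
#: pathogenesis, non-lung in-vitro systems, and solid-particle exposures.
COPD_EXCLUDED_DISEASES = (
    "acute exacerbation", "lung cancer", "cystic fibrosis",
    "acute respiratory distress syndrome", "idiopathic pulmonary fibrosis",
    "septic pneumonitis", "obliterative bronchiolitis", "pneumoconiosis",
    "bronchiectasis", "viral infection", "bacterial infection", "asthma",
    "bronchitis",
)
COPD_EXCLUDED_CELL_SYSTEMS = (
    "tumor-derived cell line", "immortalized cell line", "neuronal cells",
)
COPD_EXCLUDED_EXPOSURES = (
    "titanium dioxide", "quartz", "asbestos", "carbon black", "diesel exhaust",
)


@dataclass
class BoundaryConfig:
    """Which experimental contexts an evidence may come from.

    Human is always allowed; mouse/rat evidence passes only when
    ``homologize_rodents`` is set, and is then annotated ``homologized``.
    Matching against exclusion lists is case-insensitive exact-string.
    """

    allowed_species: list = field(default_factory=lambda: ["human"])
    homologize_rodents: bool = True
    excluded_diseases: list = field(default_factory=list)
    excluded_cell_systems: list = field(default_factory=list)
    excluded_exposures: list = field(default_factory=list)

    def __post_init__(self):
        lowered = [s.lower() for s in self.allowed_species]
        if "human" not in lowered:
            self.allowed_species = ["human"] + list(self.allowed_species)

    @classmethod
    def from_yaml(cls, text: str) -> "BoundaryConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def copd_boundary_config() -> BoundaryConfig:
    """The early-COPD exclusion lists as a ready-made config."""
    return BoundaryConfig(
        excluded_diseases=list(COPD_EXCLUDED_DISEASES),
        excluded_cell_systems=list(COPD_EXCLUDED_CELL_SYSTEMS),
        excluded_exposures=list(COPD_EXCLUDED_EXPOSURES),
    )


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: Optional[str] = None
    annotations: tuple = ()


def apply_boundary_filter(evidence: Evidence, config: BoundaryConfig) -> FilterDecision:
    """Deterministic accept/reject with the first matching exclusion rule.

    Rules are checked in fixed order: disease, cell system, exposure,
    species.  Missing context fields are unconstrained and pass.
    """
    ctx = {k: v.lower() for k, v in evidence.context.items() if v}
    disease = ctx.get("disease")
    if disease and disease in (d.lower() for d in config.excluded_diseases):
        return FilterDecision(False, "excluded_disease")
    cell = ctx.get("cell_type")
    if cell and cell in (c.lower() for c in config.excluded_cell_systems):
        return FilterDecision(False, "excluded_cell_system")
    exposure = ctx.get("exposure")
    if exposure and exposure in (e.lower() for e in config.excluded_exposures):
        return FilterDecision(False, "excluded_exposure")
    species = ctx.get("species")
    if species:
        if species in (s.lower() for s in config.allowed_species):
            return FilterDecision(True)
        if species in ("mouse", "rat") and config.homologize_rodents:
            return FilterDecision(True, annotations=("homologized",))
        return FilterDecision(False, "excluded_species")
    return FilterDecision(True)


# ---------------------------------------------------------------------------
# Version diffs and share reports


@dataclass
class PhaseDiff:
    """Nodes/edges/evidences present in the new version but not the old."""

    nodes_added: int
    edges_added: int
    evidences_added: int
    breakdown: dict  # network name -> (nodes, edges, evidences)
    citations: set = field(default_factory=set)

    def __post_init__(self):
        sums = tuple(sum(v[i] for v in self.breakdown.values()) for i in range(3))
        if sums != (self.nodes_added, self.edges_added, self.evidences_added):
            raise ValueError("diff totals inconsistent with per-network breakdown")


def diff_versions(old: Iterable[Network], new: Iterable[Network]) -> PhaseDiff:
    """Count additions between two network-set versions, matched by name."""
    old_by_name = {n.name: n for n in old}
    breakdown: dict[str, tuple[int, int, int]] = {}
    citations: set[str] = set()
    for net in new:
        base = old_by_name.get(net.name)
        old_nodes = set(base.nodes) if base else set()
        old_edges = set(base._edges_by_key) if base else set()
        old_ev = base.evidence_ids() if base else set()
        nodes_added = len(set(net.nodes) - old_nodes)
        edges_added = len(set(net._edges_by_key) - old_edges)
        ev_added = 0
        for edge in net.edges:
            for ev in edge.evidences:
                if ev.id not in old_ev:
                    ev_added += 1
                    citations.add(ev.citation)
        breakdown[net.name] = (nodes_added, edges_added, ev_added)
    totals = tuple(sum(v[i] for v in breakdown.values()) for i in range(3))
    return PhaseDiff(*totals, breakdown=breakdown, citations=citations)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def share_report(diff: PhaseDiff, focus: Iterable[str]) -> dict:
    """Share of added material falling within the focus networks.

    Percentages are rounded half-up to integers; a zero total leaves the
    share undefined (None), never 0.
    """
    focus = list(focus)
    missing = [n for n in focus if n not in diff.breakdown]
    if missing:
        raise KeyError(f"focus networks absent from diff: {missing}")
    report: dict = {}
    for i, metric in enumerate(("nodes", "edges", "evidences")):
        total = sum(v[i] for v in diff.breakdown.values())
        in_focus = sum(diff.breakdown[n][i] for n in focus)
        percent = _round_half_up(100.0 * in_focus / total) if total else None
        report[metric] = {"focus": in_focus, "total": total, "percent": percent}
    report["unique_citations"] = len(diff.citations)
    return report


def count_edges_by_phase(networks: Iterable[Network]) -> Counter:
    """Tally edges by the construction phase recorded in their provenance."""
    counts: Counter = Counter()
    for net in networks:
        for edge in net.edges:
            counts[edge.provenance.phase] += 1
    return counts
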