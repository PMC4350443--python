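"""Network agglomeration: merge related networks and collapse edge variants.

Two reductions prepare a model set for crowd review.  First, related
networks are merged per a :class:`MergeSpec` (each group of source
networks becomes one consolidated model; the rest pass through standalone).
Second, within a network, protein / RNA / gene / secretion variants of the
same causal assertion — edges sharing subject, target gene, and sign whose
objects are bare ``p(X)``, ``r(X)``, ``g(X)``, or ``sec(X)`` — are
collapsed into a single representative edge carrying the union of the
evidence, so each assertion needs verifying only once.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .bel import BelTerm, EntityRef, canonical_key, serialize_term
from .model import Edge, Network, Phase, Provenance

#: Family-eligible object functions, in representative-preference order.
FAMILY_FUNCTIONS = ("p", "r", "g", "sec")


@dataclass
class MergeSpec:
    """Agglomeration instructions: groups of sources plus standalone names."""

    groups: list  # of (target name, [source names])
    standalone: list = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for target, sources in self.groups:
            if len(sources) < 2:
                raise ValueError(f"group {target!r} needs at least 2 sources")
            for s in sources:
                if s in seen:
                    raise ValueError(f"source network covered twice: {s!r}")
                seen.add(s)
        for s in self.standalone:
            if s in seen:
                raise ValueError(f"source network covered twice: {s!r}")
            seen.add(s)

    def covered(self) -> set:
        out = set(self.standalone)
        for _, sources in self.groups:
            out.update(sources)
        return out

    @classmethod
    def from_yaml(cls, text: str) -> "MergeSpec":
        data = yaml.safe_load(text) or {}
        groups = [(target, list(sources))
                  for target, sources in (data.get("groups") or {}).items()]
        return cls(groups=groups, standalone=list(data.get("standalone") or []))


def merge_networks(networks: Iterable[Network], spec: MergeSpec) -> list[Network]:
    """Merge per spec; output count = number of groups + standalone networks.

    Group node sets are unions by canonical key; edges are deduplicated by
    canonical statement with evidence lists concatenated on collision.
    The spec must cover exactly the input network names.
    """
    by_name = {n.name: n for n in networks}
    covered = spec.covered()
    missing = set(by_name) - covered
    if missing:
        raise ValueError(f"merge spec does not cover networks: {sorted(missing)}")
    unknown = covered - set(by_name)
    if unknown:
        raise ValueError(f"merge spec names absent from input: {sorted(unknown)}")
    out: list[Network] = []
    for target, sources in spec.groups:
        merged = Network(target, description=f"agglomerated from {len(sources)} networks")
        prov = Provenance(Phase.PHASE1_LITERATURE, actor="agglomeration")
        for source_name in sources:
            src = by_name[source_name]
            for key, term in src.nodes.items():
                if key not in merged.nodes:
                    merged.nodes[key] = term
            for edge in src.edges:
                existing = merged.get_edge(edge.key)
                if existing is None:
                    new_edge = Edge(edge.statement, list(edge.evidences),
                                    edge.provenance, list(edge.collapsed_forms))
                    merged.edges.append(new_edge)
                    merged._edges_by_key[new_edge.key] = new_edge
                else:
                    have = {ev.id for ev in existing.evidences}
                    existing.evidences.extend(
                        ev for ev in edge.evidences if ev.id not in have)
        merged._record(f"merged from sources: {', '.join(sources)}", prov)
        out.append(merged)
    out.extend(by_name[name] for name in spec.standalone)
    return out


def _family_key(edge: Edge):
    """(subject key, gene key, sign) when the edge is family-eligible, else None."""
    if not edge.statement.relation.is_causal:
        return None
    obj = edge.statement.object
    if not isinstance(obj, BelTerm) or obj.function not in FAMILY_FUNCTIONS:
        return None
    if len(obj.args) != 1 or not isinstance(obj.args[0], EntityRef):
        return None
    return (canonical_key(edge.statement.subject),
            canonical_key(obj.args[0]),
            edge.statement.relation.code)


def agglomerate_edges(network: Network) -> Network:
    """Collapse each edge family into one representative edge (p > r > g > sec).

    The representative keeps the preferred object form, the union of the
    family's evidences, and a ``collapsed_forms`` annotation listing the
    original object forms.  Edge count never increases; evidence count is
    conserved.  Networks with no family of size >= 2 are returned unchanged.
    """
    families: dict = {}
    for edge in network.edges:
        fam = _family_key(edge)
        if fam is not None:
            families.setdefault(fam, []).append(edge)
    collapsible = {fam: members for fam, members in families.items()
                   if len(members) > 1}
    if not collapsible:
        return network

    def preference(edge: Edge) -> int:
        return FAMILY_FUNCTIONS.index(edge.statement.object.function)

    replaced: dict[int, Edge] = {}  # id(first member) -> representative
    dropped: set[int] = set()
    for members in collapsible.values():
        rep_source = min(members, key=preference)
        evidences: list = []
        seen_ids: set[str] = set()
        for member in members:
            for ev in member.evidences:
                if ev.id not in seen_ids:
                    seen_ids.add(ev.id)
                    evidences.append(ev)
        forms = sorted(serialize_term(m.statement.object) for m in members)
        rep = Edge(rep_source.statement, evidences, rep_source.provenance,
                   collapsed_forms=forms)
        replaced[id(members[0])] = rep
        dropped.update(id(m) for m in members)
    new_edges: list[Edge] = []
    for edge in network.edges:
        if id(edge) in replaced:
            new_edges.append(replaced[id(edge)])
        elif id(edge) not in dropped:
            new_edges.append(edge)
    network.edges = new_edges
    network._edges_by_key = {e.key: e for e in new_edges}
    network._record(
        f"agglomerated {len(collapsible)} edge families",
        Provenance(Phase.PHASE1_LITERATURE, actor="agglomeration"))
    return network
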