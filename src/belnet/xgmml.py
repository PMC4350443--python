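"""XGMML export/import for network sharing with graph viewers.

Export is structure-only and deterministic: one node element per network
node (label = canonical key, shape attribute by function class) and one
edge element per edge (interaction = relation code, evidence count).
Import reconstructs the graph, re-parsing labels as BEL where possible and
retaining the rest as opaque nodes flagged unparsed.  Evidence details are
not carried in XGMML; they live in the BEL-script serialization.
"""
from __future__ import annotations

from typing import Optional

from lxml import etree

from .bel import (BelParseError, BelStatement, BelTerm, OpaqueTerm, Relation,
                  canonical_key, parse_term, statement_key)
from .model import Edge, Evidence, Network, Phase, Provenance
from .registries import FunctionRegistry, NamespaceRegistry

XGMML_NS = "http://www.cs.rpi.edu/XGMML"

#: Node shape by function class (activities are triangles, processes and
#: pathologies diamonds, translocation/transport rounded squares, chemical
#: and other plain abundances circles, proteins and complexes squares).
_SHAPES = {
    "act": "triangle", "cat": "triangle", "kin": "triangle", "pep": "triangle",
    "phos": "triangle", "tscript": "triangle", "gtp": "triangle",
    "chap": "triangle", "ribo": "triangle",
    "bp": "diamond", "path": "diamond",
    "tloc": "rounded-square", "tport": "rounded-square",
    "sec": "rounded-square", "surf": "rounded-square",
    "p": "square", "complex": "square", "composite": "square",
    "a": "circle", "g": "circle", "r": "circle", "m": "circle",
}
_DEFAULT_SHAPE = "circle"
_UNPARSED_SHAPE = "octagon"


def shape_for(term) -> str:
    if isinstance(term, BelTerm):
        return _SHAPES.get(term.function, _DEFAULT_SHAPE)
    return _UNPARSED_SHAPE


def export_xgmml(network: Network) -> str:
    """Serialize a network to standalone UTF-8 XGMML text (byte-deterministic)."""
    graph = etree.Element("graph", nsmap={None: XGMML_NS})
    graph.set("label", network.name)
    graph.set("directed", "1")
    if network.description:
        att = etree.SubElement(graph, "att")
        att.set("name", "description")
        att.set("value", network.description)
    node_ids: dict[str, str] = {}
    for i, key in enumerate(sorted(network.nodes)):
        node_ids[key] = f"n{i}"
        node = etree.SubElement(graph, "node")
        node.set("id", node_ids[key])
        node.set("label", key)
        att = etree.SubElement(node, "att")
        att.set("name", "shape")
        att.set("value", shape_for(network.nodes[key]))
    for edge in sorted(network.edges, key=lambda e: e.key):
        el = etree.SubElement(graph, "edge")
        el.set("source", node_ids[canonical_key(edge.statement.subject)])
        el.set("target", node_ids[canonical_key(edge.statement.object)])
        el.set("label", edge.key)
        att = etree.SubElement(el, "att")
        att.set("name", "interaction")
        att.set("value", edge.statement.relation.code)
        att = etree.SubElement(el, "att")
        att.set("name", "evidences")
        att.set("value", str(len(edge.evidences)))
    return etree.tostring(graph, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


class XgmmlError(ValueError):
    """Malformed XGMML document or unresolvable structure."""


def import_xgmml(text: str,
                 functions: Optional[FunctionRegistry] = None,
                 namespaces: Optional[NamespaceRegistry] = None) -> Network:
    """Rebuild a structure-only Network from XGMML text.

    Node labels that fail BEL parsing become opaque nodes flagged unparsed.
    Each edge receives one placeholder evidence (XGMML carries only counts).
    Raises :class:`XgmmlError` on malformed XML or dangling edge endpoints.
    """
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise XgmmlError(f"malformed XML: {exc}") from exc
    ns = {"x": XGMML_NS}
    if etree.QName(root).localname != "graph":
        raise XgmmlError("root element is not <graph>")
    network = Network(root.get("label") or "imported")
    desc = root.findall("x:att[@name='description']", ns) or \
        root.findall("att[@name='description']")
    if desc:
        network.description = desc[0].get("value") or ""
    terms_by_id: dict[str, object] = {}
    node_elems = root.findall("x:node", ns) or root.findall("node")
    for node in node_elems:
        node_id = node.get("id")
        label = node.get("label") or node_id
        if node_id is None:
            raise XgmmlError("node element missing id")
        if node_id in terms_by_id:
            raise XgmmlError(f"duplicate node id {node_id!r}")
        try:
            term = parse_term(label, functions, namespaces)
        except BelParseError:
            term = OpaqueTerm(label)
        terms_by_id[node_id] = term
        network.nodes[canonical_key(term)] = term
    edge_elems = root.findall("x:edge", ns) or root.findall("edge")
    for el in edge_elems:
        src, tgt = el.get("source"), el.get("target")
        for endpoint in (src, tgt):
            if endpoint not in terms_by_id:
                raise XgmmlError(f"edge endpoint {endpoint!r} does not resolve")
        att = el.findall("x:att[@name='interaction']", ns) or \
            el.findall("att[@name='interaction']")
        relation = Relation.from_code(att[0].get("value")) if att else Relation.INCREASES
        stmt = BelStatement(terms_by_id[src], relation, terms_by_id[tgt])
        placeholder = Evidence(citation="unspecified",
                               quote="structure-only import",
                               id=f"xgmml-{statement_key(stmt)}")
        edge = Edge(stmt, [placeholder],
                    Provenance(Phase.PHASE0_NONDISEASED, actor="xgmml-import"))
        network.edges.append(edge)
        network._edges_by_key[edge.key] = edge
    return network
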