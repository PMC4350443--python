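"""Line-oriented BEL-script dialect: the evidence-preserving serialization.

Layout: a header block (``SET Network``/``SET Description``), then per
evidence a ``SET Citation``, ``SET Evidence``, and optional context lines
(Species/Tissue/CellType/Disease/Exposure), followed by one or more
statement lines that the current evidence supports.  Evidence ids are
derived from citation + quote + canonical statement, so two statements
under one evidence block yield two edges with distinct evidence ids.
"""
from __future__ import annotations

from typing import Optional

from .bel import BelParseError, parse_statement, statement_key
from .model import Evidence, Network, Phase, Provenance, evidence_id
from .registries import FunctionRegistry, NamespaceRegistry

_CONTEXT_SET_KEYS = {
    "Species": "species",
    "Tissue": "tissue",
    "CellType": "cell_type",
    "Disease": "disease",
    "Exposure": "exposure",
}
_HEADER_SET_KEYS = ("Network", "Description")
_EVIDENCE_SET_KEYS = ("Citation", "Evidence")
_ALL_SET_KEYS = set(_HEADER_SET_KEYS) | set(_EVIDENCE_SET_KEYS) | set(_CONTEXT_SET_KEYS)


class BelScriptError(ValueError):
    """Script-level failure, reported with the 1-based line number."""

    def __init__(self, message: str, line: int, column: int = 1):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


def _unquote(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    return value


def _quote(value: str) -> str:
    escaped = value.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def read_bel_script(text: str,
                    functions: Optional[FunctionRegistry] = None,
                    namespaces: Optional[NamespaceRegistry] = None,
                    phase: Phase = Phase.PHASE1_LITERATURE) -> Network:
    """Parse BEL-script text into a Network.

    SET blocks populate the pending Evidence; each statement line creates
    (or extends) an edge carrying that evidence.  Errors report line and
    column; a statement before any ``SET Citation`` is an error.
    """
    network = Network("unnamed")
    citation: Optional[str] = None
    quote = ""
    context: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("SET "):
            body = line[4:]
            if "=" not in body:
                raise BelScriptError("SET line missing '='", lineno)
            key, _, value = body.partition("=")
            key = key.strip()
            value = _unquote(value)
            if key not in _ALL_SET_KEYS:
                raise BelScriptError(f"unknown SET key {key!r}", lineno)
            if key == "Network":
                network.name = value
            elif key == "Description":
                network.description = value
            elif key == "Citation":
                citation = value
                quote = ""
                context = {}
            elif key == "Evidence":
                quote = value
            else:
                context[_CONTEXT_SET_KEYS[key]] = value
            continue
        # statement line
        if citation is None:
            raise BelScriptError("statement before any SET Citation", lineno)
        try:
            stmt = parse_statement(line, functions, namespaces)
        except BelParseError as exc:
            raise BelScriptError(str(exc), lineno, exc.pos + 1) from exc
        ev = Evidence(citation=citation, quote=quote, context=dict(context),
                      id=evidence_id(citation, quote, statement_key(stmt)))
        network.add_edge(stmt, [ev], Provenance(phase, actor="belscript"))
    return network


def write_bel_script(network: Network) -> str:
    """Deterministic BEL-script serialization (edges sorted by statement key).

    Round trip preserves edge and evidence counts; opaque (unparsed) nodes
    cannot be expressed in this dialect and raise.
    """
    if network.unparsed_nodes:
        raise ValueError("network contains unparsed nodes; use XGMML instead")
    lines = [f'SET Network = {_quote(network.name)}']
    if network.description:
        lines.append(f'SET Description = {_quote(network.description)}')
    lines.append("")
    reverse_ctx = {v: k for k, v in _CONTEXT_SET_KEYS.items()}
    for edge in sorted(network.edges, key=lambda e: e.key):
        for ev in edge.evidences:
            lines.append(f'SET Citation = {_quote(ev.citation)}')
            lines.append(f'SET Evidence = {_quote(ev.quote)}')
            for ctx_key in ("species", "tissue", "cell_type", "disease", "exposure"):
                if ctx_key in ev.context:
                    lines.append(
                        f'SET {reverse_ctx[ctx_key]} = {_quote(ev.context[ctx_key])}')
            lines.append(edge.key)
            lines.append("")
    return "\n".join(lines)
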