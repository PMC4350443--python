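"""Parsing, validation, and canonical serialization of restricted BEL.

A BEL term is a function applied to one or more arguments; arguments are
namespaced entity references (``HGNC:CCL3``), nested terms
(``act(p(HGNC:SIRT1))``), or — for qualifier-style functions such as
``pmod`` — bare tokens.  A statement connects two terms with a causal
(``increases``/``decreases``) or non-causal relation.

Canonical form: whitespace between tokens is dropped, names containing
characters outside the identifier set are double-quoted, and the arguments
of the unordered functions ``complex``/``composite`` are sorted
lexicographically by their serialized form.  ``canonical_key`` — the
canonical serialization — is the node identity used for deduplication and
merging throughout the toolkit.
"""
from __future__ import annotations

import string
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

from .registries import FunctionRegistry, NamespaceRegistry

MAX_NESTING_DEPTH = 4

#: Functions whose arguments may include bare (namespace-less) tokens,
#: e.g. the modification code and position in pmod(P, S, 15).
QUALIFIER_FUNCTIONS = frozenset({"pmod", "tloc", "sub", "trunc", "fus"})

_IDENT_CHARS = frozenset(string.ascii_letters + string.digits + "_-.+")


class BelParseError(ValueError):
    """A parse or validation failure, carrying the offending position.

    ``code`` classifies the failure: ``syntax``, ``unknown_function``,
    ``unknown_namespace``, ``missing_namespace``, or ``depth``.
    """

    def __init__(self, message: str, pos: int, code: str = "syntax"):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos
        self.code = code


@dataclass(frozen=True)
class EntityRef:
    """A namespaced biological entity, e.g. EntityRef('HGNC', 'CCL3')."""

    namespace: str
    name: str


@dataclass(frozen=True)
class BelTerm:
    """A BEL function applied to an ordered tuple of arguments."""

    function: str
    args: tuple  # of EntityRef | BelTerm | str


@dataclass(frozen=True)
class OpaqueTerm:
    """A node label that could not be parsed as BEL (graph-import survivor)."""

    text: str


TermLike = Union[BelTerm, OpaqueTerm]


class Relation(Enum):
    INCREASES = "increases"
    DECREASES = "decreases"
    NON_CAUSAL = "nonCausal"

    @property
    def code(self) -> str:
        return self.value

    @property
    def is_causal(self) -> bool:
        return self is not Relation.NON_CAUSAL

    @classmethod
    def from_code(cls, code: str) -> "Relation":
        for rel in cls:
            if rel.value == code:
                return rel
        raise ValueError(f"unknown relation code: {code!r}")


@dataclass(frozen=True)
class BelStatement:
    """subject --relation--> object; causal self-loops are invalid."""

    subject: TermLike
    relation: Relation
    object: TermLike

    def __post_init__(self):
        if self.relation.is_causal and canonical_key(self.subject) == canonical_key(self.object):
            raise ValueError("causal statement may not connect a term to itself")


# ---------------------------------------------------------------------------
# Tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # one of "(", ")", ",", ":", "ident", "string", "end"
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "(),:":
            tokens.append(_Token(ch, ch, i))
            i += 1
            continue
        if ch == '"':
            j = i + 1
            buf: list[str] = []
            closed = False
            while j < n:
                c = text[j]
                if c == "\\" and j + 1 < n and text[j + 1] in '"\\':
                    buf.append(text[j + 1])
                    j += 2
                    continue
                if c == '"':
                    closed = True
                    break
                buf.append(c)
                j += 1
            if not closed:
                raise BelParseError("unterminated quoted name", i)
            tokens.append(_Token("string", "".join(buf), i))
            i = j + 1
            continue
        if ch in _IDENT_CHARS:
            j = i
            while j < n and text[j] in _IDENT_CHARS:
                j += 1
            tokens.append(_Token("ident", text[i:j], i))
            i = j
            continue
        raise BelParseError(f"unexpected character {ch!r}", i)
    tokens.append(_Token("end", "", n))
    return tokens


# ---------------------------------------------------------------------------
# Recursive-descent parser


class _Parser:
    def __init__(self, tokens: list[_Token], functions: FunctionRegistry,
                 namespaces: NamespaceRegistry):
        self.tokens = tokens
        self.i = 0
        self.functions = functions
        self.namespaces = namespaces

    def peek(self, offset: int = 0) -> _Token:
        return self.tokens[min(self.i + offset, len(self.tokens) - 1)]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        if tok.kind != "end":
            self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        tok = self.peek()
        if tok.kind != kind:
            found = "end of input" if tok.kind == "end" else repr(tok.value)
            raise BelParseError(f"expected {what}, found {found}", tok.pos)
        return self.advance()

    def parse_term(self, depth: int = 1) -> BelTerm:
        tok = self.expect("ident", "function prefix")
        func = tok.value
        if func not in self.functions:
            raise BelParseError(f"unknown function prefix {func!r}", tok.pos,
                                code="unknown_function")
        if depth > MAX_NESTING_DEPTH:
            raise BelParseError(
                f"nesting depth exceeds {MAX_NESTING_DEPTH}", tok.pos, code="depth")
        self.expect("(", "'('")
        if self.peek().kind == ")":
            raise BelParseError("empty argument list", self.peek().pos)
        args = [self.parse_arg(func, depth)]
        while True:
            tok = self.peek()
            if tok.kind == ",":
                self.advance()
                args.append(self.parse_arg(func, depth))
            elif tok.kind == ")":
                self.advance()
                break
            else:
                found = "end of input" if tok.kind == "end" else repr(tok.value)
                raise BelParseError(f"expected ',' or ')', found {found}", tok.pos)
        return BelTerm(func, tuple(args))

    def parse_arg(self, func: str, depth: int):
        tok = self.peek()
        if tok.kind == "ident":
            nxt = self.peek(1)
            if nxt.kind == "(":
                return self.parse_term(depth + 1)
            if nxt.kind == ":":
                ns = tok.value
                if ns not in self.namespaces:
                    raise BelParseError(f"unknown namespace prefix {ns!r}", tok.pos,
                                        code="unknown_namespace")
                self.advance()  # namespace
                self.advance()  # colon
                name_tok = self.peek()
                if name_tok.kind not in ("ident", "string"):
                    raise BelParseError("expected entity name after namespace",
                                        name_tok.pos)
                self.advance()
                if not name_tok.value:
                    raise BelParseError("empty entity name", name_tok.pos)
                return EntityRef(ns, name_tok.value)
            if func in QUALIFIER_FUNCTIONS:
                self.advance()
                return tok.value
            raise BelParseError(
                f"entity {tok.value!r} lacks a namespace prefix", tok.pos,
                code="missing_namespace")
        if tok.kind == "string":
            if func in QUALIFIER_FUNCTIONS:
                self.advance()
                return tok.value
            raise BelParseError(
                f"quoted name {tok.value!r} lacks a namespace prefix", tok.pos,
                code="missing_namespace")
        found = "end of input" if tok.kind == "end" else repr(tok.value)
        raise BelParseError(f"expected term or entity, found {found}", tok.pos)


def parse_term(text: str,
               functions: Optional[FunctionRegistry] = None,
               namespaces: Optional[NamespaceRegistry] = None) -> BelTerm:
    """Parse a BEL term; raises :class:`BelParseError` with position on failure."""
    if not text or not text.strip():
        raise BelParseError("empty input", 0)
    functions = functions or FunctionRegistry.default()
    namespaces = namespaces or NamespaceRegistry.default()
    parser = _Parser(_tokenize(text), functions, namespaces)
    term = parser.parse_term()
    trailing = parser.peek()
    if trailing.kind != "end":
        raise BelParseError(f"unexpected trailing input {trailing.value!r}",
                            trailing.pos)
    return term


def validate_term(term: BelTerm,
                  functions: Optional[FunctionRegistry] = None,
                  namespaces: Optional[NamespaceRegistry] = None,
                  _depth: int = 1) -> None:
    """Validate a programmatically constructed term against the registries."""
    functions = functions or FunctionRegistry.default()
    namespaces = namespaces or NamespaceRegistry.default()
    if _depth > MAX_NESTING_DEPTH:
        raise BelParseError(f"nesting depth exceeds {MAX_NESTING_DEPTH}", 0, code="depth")
    if term.function not in functions:
        raise BelParseError(f"unknown function prefix {term.function!r}", 0,
                            code="unknown_function")
    if not term.args:
        raise BelParseError("empty argument list", 0)
    for arg in term.args:
        if isinstance(arg, BelTerm):
            validate_term(arg, functions, namespaces, _depth + 1)
        elif isinstance(arg, EntityRef):
            if arg.namespace not in namespaces:
                raise BelParseError(f"unknown namespace prefix {arg.namespace!r}", 0,
                                    code="unknown_namespace")
            if not arg.name:
                raise BelParseError("empty entity name", 0)
        elif isinstance(arg, str):
            if term.function not in QUALIFIER_FUNCTIONS:
                raise BelParseError(
                    f"entity {arg!r} lacks a namespace prefix", 0,
                    code="missing_namespace")
        else:
            raise BelParseError(f"invalid argument type {type(arg).__name__}", 0)


# ---------------------------------------------------------------------------
# Serialization / canonicalization

#: Functions whose argument order is not meaningful and is canonicalized
#: by lexicographic sort of the serialized arguments.
UNORDERED_FUNCTIONS = frozenset({"complex", "composite"})


def _format_name(name: str) -> str:
    if name and all(c in _IDENT_CHARS for c in name):
        return name
    escaped = name.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def _serialize(term) -> str:
    if isinstance(term, EntityRef):
        return f"{term.namespace}:{_format_name(term.name)}"
    if isinstance(term, OpaqueTerm):
        return term.text
    if isinstance(term, str):
        return _format_name(term)
    inner = ",".join(_serialize(a) for a in term.args)
    return f"{term.function}({inner})"


def canonicalize(term: BelTerm) -> BelTerm:
    """Return the canonical form: unordered-function args sorted, bottom-up."""
    args = tuple(canonicalize(a) if isinstance(a, BelTerm) else a for a in term.args)
    if term.function in UNORDERED_FUNCTIONS:
        args = tuple(sorted(args, key=_serialize))
    return BelTerm(term.function, args)


def serialize_term(term: TermLike) -> str:
    """Canonical text form; ``parse_term(serialize_term(t)) == canonicalize(t)``."""
    if isinstance(term, BelTerm):
        return _serialize(canonicalize(term))
    return _serialize(term)


def canonical_key(term) -> str:
    """Node identity string: canonical serialization (labels pass through)."""
    if isinstance(term, str):
        return term
    if isinstance(term, EntityRef):
        return f"{term.namespace}:{term.name}"
    return serialize_term(term)


def serialize_statement(stmt: BelStatement) -> str:
    return (f"{serialize_term(stmt.subject)} {stmt.relation.code} "
            f"{serialize_term(stmt.object)}")


def statement_key(stmt: BelStatement) -> str:
    """Edge identity: canonical subject, relation code, canonical object."""
    return serialize_statement(stmt)


# ---------------------------------------------------------------------------
# Statement parsing

_RELATION_CODES = tuple(rel.value for rel in Relation)


def _find_relations(text: str) -> list[tuple[int, str]]:
    """Top-level relation keyword occurrences (outside parens and quotes)."""
    hits: list[tuple[int, str]] = []
    depth = 0
    in_quote = False
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if in_quote:
            if ch == "\\":
                i += 2
                continue
            if ch == '"':
                in_quote = False
            i += 1
            continue
        if ch == '"':
            in_quote = True
            i += 1
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif depth == 0:
            for code in _RELATION_CODES:
                if text.startswith(code, i):
                    before_ok = i == 0 or text[i - 1] not in _IDENT_CHARS
                    after = i + len(code)
                    after_ok = after >= n or text[after] not in _IDENT_CHARS
                    if before_ok and after_ok:
                        hits.append((i, code))
                        i = after
                        break
            else:
                i += 1
                continue
            continue
        i += 1
    return hits


def parse_statement(text: str,
                    functions: Optional[FunctionRegistry] = None,
                    namespaces: Optional[NamespaceRegistry] = None) -> BelStatement:
    """Parse ``subject RELATION object`` with exactly one top-level relation."""
    hits = _find_relations(text)
    if not hits:
        raise BelParseError("no relation keyword found", 0)
    if len(hits) > 1:
        raise BelParseError("multiple top-level relation keywords", hits[1][0])
    pos, code = hits[0]
    subject_text = text[:pos].strip()
    object_text = text[pos + len(code):].strip()
    if not subject_text:
        raise BelParseError("missing subject term", 0)
    if not object_text:
        raise BelParseError("missing object term", pos + len(code))
    subject = parse_term(subject_text, functions, namespaces)
    obj = parse_term(object_text, functions, namespaces)
    relation = Relation.from_code(code)
    if relation.is_causal and canonical_key(subject) == canonical_key(obj):
        raise BelParseError("causal statement may not connect a term to itself", 0)
    return BelStatement(subject, relation, obj)
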