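"""Reverse causal reasoning: state-change selection and HYP scoring.

A *state change* (SC) is a gene passing the differential-expression
thresholds (FDR-adjusted p < 0.05, |fold change| >= 1.3, mean expression
>= 100 by default), with a direction.  A *HYP* is a candidate upstream
mechanism with a signed downstream gene set taken from a causal
knowledgebase.  Each HYP is scored against the SCs with two tail
probabilities:

* richness — the hypergeometric upper tail P(X >= k) for the overlap k
  between the HYP's downstream genes and the SCs, drawn from a universe of
  N genes (the measured genes by default);
* concordance — the binomial upper tail P(X >= c) under a fair-coin null
  for the number c of overlapping genes whose observed direction matches
  the predicted sign.

HYPs with richness p < 0.1 and concordance p < 0.1 (no multiple-testing
correction) are reported, and those absent from a network can be proposed
as curation candidates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from scipy.stats import binom, hypergeom

from .bel import (BelStatement, BelTerm, EntityRef, Relation, canonical_key,
                  parse_term)
from .model import Edge, Evidence, Network, Phase, Provenance
from .registries import FunctionRegistry, NamespaceRegistry


@dataclass(frozen=True)
class ExpressionRow:
    gene: EntityRef
    fold_change: float  # signed, linear scale; sign encodes direction
    fdr_p: float
    mean_expression: float


@dataclass(frozen=True)
class ScThresholds:
    """State-change cutoffs; FDR is strict, fold change and expression inclusive."""

    fdr_max: float = 0.05
    fc_min: float = 1.3
    expr_min: float = 100.0

    def __post_init__(self):
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1 (linear scale)")
        if self.expr_min < 0:
            raise ValueError("expr_min must be non-negative")


@dataclass(frozen=True)
class StateChange:
    gene: EntityRef
    direction: str  # "up" | "down"


@dataclass
class Hyp:
    """Candidate upstream mechanism with signed downstream gene predictions."""

    upstream: BelTerm
    downstream: dict  # gene key ("NS:name") -> "+" | "-"

    def __post_init__(self):
        if not self.downstream:
            raise ValueError("HYP downstream set must be non-empty")
        bad = {s for s in self.downstream.values()} - {"+", "-"}
        if bad:
            raise ValueError(f"invalid predicted signs: {sorted(bad)}")


@dataclass
class HypScore:
    hyp: Hyp
    overlap_k: int
    concordant_c: int
    discordant_d: int
    richness_p: float
    concordance_p: float


@dataclass
class RcrConfig:
    thresholds: ScThresholds = field(default_factory=ScThresholds)
    richness_max: float = 0.1
    concordance_max: float = 0.1
    universe_policy: str = "measured_genes"  # or "kb_covered_genes"
    log2_fold_change: bool = False

    def __post_init__(self):
        for name in ("richness_max", "concordance_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.universe_policy not in ("measured_genes", "kb_covered_genes"):
            raise ValueError(f"unknown universe policy: {self.universe_policy!r}")


# ---------------------------------------------------------------------------
# State-change selection


def select_state_changes(rows: Iterable[ExpressionRow],
                         thresholds: Optional[ScThresholds] = None) -> list[StateChange]:
    """Pure filter: rows passing all three cutoffs, in input order."""
    thresholds = thresholds or ScThresholds()
    seen: set[str] = set()
    out: list[StateChange] = []
    for row in rows:
        key = canonical_key(row.gene)
        if key in seen:
            raise ValueError(f"duplicate gene id: {key}")
        seen.add(key)
        values = (row.fold_change, row.fdr_p, row.mean_expression)
        if not all(math.isfinite(v) for v in values):
            raise ValueError(f"non-finite value for gene {key}")
        if row.fold_change == 0:
            raise ValueError(f"zero fold change for gene {key}")
        if (row.fdr_p < thresholds.fdr_max
                and abs(row.fold_change) >= thresholds.fc_min
                and row.mean_expression >= thresholds.expr_min):
            out.append(StateChange(row.gene, "up" if row.fold_change > 0 else "down"))
    return out


def linearize_fold_change(log2_fc: float) -> float:
    """Signed linear fold change from a log2 ratio (sign preserved)."""
    if log2_fc == 0:
        raise ValueError("zero log2 fold change has no direction")
    return math.copysign(2.0 ** abs(log2_fc), log2_fc)


# ---------------------------------------------------------------------------
# Tail statistics


def richness_p(k: int, n: int, m: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k), X ~ Hypergeom(N, m, n).

    k = overlap count, n = number of state changes, m = HYP downstream
    size, N = universe size.  Returns 1 when k = 0.
    """
    if not (0 <= k <= min(n, m) <= N and n <= N and m <= N):
        raise ValueError(f"invalid bounds: k={k}, n={n}, m={m}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def concordance_p(c: int, k: int) -> float:
    """Binomial upper tail P(X >= c), X ~ Binomial(k, 1/2); 1 when k = 0."""
    if not 0 <= c <= k:
        raise ValueError(f"invalid bounds: c={c}, k={k}")
    if k == 0 or c == 0:
        return 1.0
    return float(binom.sf(c - 1, k, 0.5))


# ---------------------------------------------------------------------------
# HYP evaluation


def evaluate_hyps(kb: Iterable[Hyp], scs: Iterable[StateChange],
                  config: Optional[RcrConfig] = None,
                  measured_genes: Optional[Iterable[str]] = None) -> list[HypScore]:
    """Score every HYP and return the significant ones, deterministically sorted.

    The gene universe is either the measured genes (which must then be
    supplied) or the union of KB downstream genes.  A HYP is returned iff
    richness p < richness_max and concordance p < concordance_max; sort
    order is richness p, then concordance p, then upstream canonical key.
    """
    config = config or RcrConfig()
    kb = list(kb)
    if config.universe_policy == "measured_genes":
        if measured_genes is None:
            raise ValueError("measured_genes required under the measured_genes policy")
        universe = {g if isinstance(g, str) else canonical_key(g) for g in measured_genes}
    else:
        universe = {g for hyp in kb for g in hyp.downstream}
    if not universe:
        raise ValueError("empty gene universe")
    sc_dir = {canonical_key(sc.gene): sc.direction for sc in scs
              if canonical_key(sc.gene) in universe}
    n, N = len(sc_dir), len(universe)
    scored: list[HypScore] = []
    for hyp in kb:
        down = {g: s for g, s in hyp.downstream.items() if g in universe}
        m = len(down)
        overlap = [g for g in down if g in sc_dir]
        k = len(overlap)
        c = sum(1 for g in overlap
                if (down[g] == "+") == (sc_dir[g] == "up"))
        rp = richness_p(k, n, m, N) if m else 1.0
        cp = concordance_p(c, k)
        if rp < config.richness_max and cp < config.concordance_max:
            scored.append(HypScore(hyp, k, c, k - c, rp, cp))
    scored.sort(key=lambda s: (s.richness_p, s.concordance_p,
                               canonical_key(s.hyp.upstream)))
    return scored


def propose_enhancements(network: Network, scores: Iterable[HypScore],
                         anchor: Union[str, BelTerm]) -> list[Edge]:
    """Candidate edges for significant HYPs not yet represented in the network.

    Each candidate connects the HYP's upstream term to the caller-supplied
    anchor process node, with the relation following the net predicted
    direction (concordant >= discordant -> increases).  Candidates carry
    phase1_rcr provenance and open status; they are never auto-merged.
    """
    anchor_key = canonical_key(anchor) if not isinstance(anchor, str) else anchor
    if anchor_key not in network.nodes:
        raise ValueError(f"anchor node {anchor_key!r} missing from network")
    anchor_term = network.nodes[anchor_key]
    candidates: list[Edge] = []
    for score in scores:
        upstream_key = canonical_key(score.hyp.upstream)
        if upstream_key in network.nodes:
            continue
        relation = (Relation.INCREASES if score.concordant_c >= score.discordant_d
                    else Relation.DECREASES)
        evidence = Evidence(
            citation="RCR:computational-prediction",
            quote=(f"Mechanism predicted from expression data: overlap k={score.overlap_k}, "
                   f"concordant={score.concordant_c}, richness_p={score.richness_p:.3g}, "
                   f"concordance_p={score.concordance_p:.3g}"),
            id=f"rcr-{upstream_key}",
        )
        statement = BelStatement(score.hyp.upstream, relation, anchor_term)
        candidates.append(Edge(statement, [evidence],
                               Provenance(Phase.PHASE1_RCR, actor="rcr_engine")))
    return candidates


# ---------------------------------------------------------------------------
# TSV interfaces


def load_expression_tsv(source: Union[str, Path], log2: bool = False) -> list[ExpressionRow]:
    """Read an expression table (gene_ns, gene_id, fold_change, fdr_p,
    mean_expression); ``log2`` converts log2 ratios to signed linear."""
    buf = StringIO(source) if isinstance(source, str) and "\n" in source else source
    df = pd.read_csv(buf, sep="\t", dtype={"gene_id": str})
    required = {"gene_ns", "gene_id", "fold_change", "fdr_p", "mean_expression"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        fc = linearize_fold_change(rec.fold_change) if log2 else float(rec.fold_change)
        rows.append(ExpressionRow(EntityRef(rec.gene_ns, rec.gene_id), fc,
                                  float(rec.fdr_p), float(rec.mean_expression)))
    return rows


def load_kb_tsv(source: Union[str, Path],
                functions: Optional[FunctionRegistry] = None,
                namespaces: Optional[NamespaceRegistry] = None) -> tuple[list[Hyp], int]:
    """Read a causal KB (upstream BEL term, downstream NS:id, sign).

    Downstream genes listed with both signs under one upstream are
    contradictory and dropped; the count of dropped genes is returned.
    """
    buf = StringIO(source) if isinstance(source, str) and "\n" in source else source
    df = pd.read_csv(buf, sep="\t", dtype=str)
    required = {"upstream", "downstream", "sign"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"KB table missing columns: {sorted(missing)}")
    grouped: dict[str, dict[str, set]] = {}
    for rec in df.itertuples(index=False):
        if rec.sign not in ("+", "-"):
            raise ValueError(f"invalid sign {rec.sign!r} for {rec.upstream!r}")
        grouped.setdefault(rec.upstream, {}).setdefault(rec.downstream, set()).add(rec.sign)
    hyps: list[Hyp] = []
    dropped = 0
    for upstream_text, genes in grouped.items():
        upstream = parse_term(upstream_text, functions, namespaces)
        downstream = {}
        for gene, signs in genes.items():
            if len(signs) > 1:
                dropped += 1
                continue
            downstream[gene] = next(iter(signs))
        if downstream:
            hyps.append(Hyp(upstream, downstream))
    return hyps, dropped


def scores_to_tsv(scores: Iterable[HypScore]) -> str:
    """HypScore rows as TSV (one line per significant mechanism)."""
    lines = ["upstream\toverlap_k\tconcordant_c\tdiscordant_d\trichness_p\tconcordance_p"]
    for s in scores:
        lines.append(f"{canonical_key(s.hyp.upstream)}\t{s.overlap_k}\t{s.concordant_c}"
                     f"\t{s.discordant_d}\t{s.richness_p:.6g}\t{s.concordance_p:.6g}")
    return "\n".join(lines) + "\n"
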