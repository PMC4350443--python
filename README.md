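# belnet

A toolkit for building, enhancing, and crowd-verifying causal biological
network models written in a restricted dialect of the Biological Expression
Language (BEL). It targets the workflow used to turn a library of
non-diseased lung network models into a disease-relevant model set — e.g.
for chronic obstructive pulmonary disease (COPD) — in three phases:
data- and literature-driven enhancement, open crowd verification, and an
expert "jamboree" batch-edit phase, with every change carrying provenance.

It is intended for computational/systems biologists who curate causal
network models and need reproducible machinery for the non-curation parts:
parsing and canonicalizing BEL, scoring upstream mechanisms against
transcriptomics data, aggregating crowd votes, merging related networks,
and exchanging models as BEL scripts or XGMML.

## What it computes

**BEL core.** Nodes are BEL terms — a function prefix (28 registered
functions: `p`, `r`, `g`, `a`, `bp`, `act`, `complex`, ...) applied to
namespaced entities (33 registered namespaces: `HGNC`, `EGID`, `CHEBI`,
`GO`, ...), nested up to depth 4. Edges are statements
`subject increases|decreases|nonCausal object`. Canonical serialization
(whitespace-free, `complex`/`composite` arguments sorted) is the node and
edge identity used everywhere for deduplication and merging.

**Reverse causal reasoning (RCR).** Given a differential-expression table,
*state changes* are genes with FDR-adjusted p < 0.05, |fold change| ≥ 1.3,
and mean expression ≥ 100. Each candidate upstream mechanism (HYP) with a
signed downstream gene set of size *m* is scored against the *n* state
changes in an *N*-gene universe via

- richness: `P(X ≥ k)`, `X ~ Hypergeom(N, m, n)`, where *k* is the overlap;
- concordance: `P(X ≥ c)`, `X ~ Binomial(k, ½)`, where *c* of the *k*
  overlapping genes changed in the predicted direction.

Mechanisms with richness p < 0.1 and concordance p < 0.1 are reported and
can be proposed as candidate edges for curation.

**Crowd verification.** Chronological vote ledgers with one effective vote
per user per evidence (later votes supersede); four effective up-votes lock
an evidence as approved, four down-votes as rejected, first threshold
crossed wins, and locked evidence refuses further votes. Plus leaderboard
points, jamboree-invitee selection, and crowd edits with provenance.

**Agglomeration and I/O.** Merge related networks per a spec (node-set
union, edge dedup with evidence concatenation), collapse protein / RNA /
gene / secretion variants of one assertion into a single verifiable edge,
diff network versions into added node/edge/evidence counts with share
percentages, and read/write BEL scripts and XGMML.

## Worked example

```python
import random
from belnet import (select_state_changes, evaluate_hyps, load_expression_tsv,
                    load_kb_tsv, canonical_key)
from belnet.fixtures import FixtureConfig, gen_kb_and_expression

fx = gen_kb_and_expression(FixtureConfig(seed=1))   # 1000 genes, 10 HYPs, 1 planted
rows = load_expression_tsv(fx.expression_tsv)
hyps, _ = load_kb_tsv(fx.kb_tsv)
scs = select_state_changes(rows)
scores = evaluate_hyps(hyps, scs, measured_genes=[r.gene for r in rows])
print(len(scs))
for s in scores:
    print(canonical_key(s.hyp.upstream), s.overlap_k, s.concordant_c,
          f"{s.richness_p:.3g}", f"{s.concordance_p:.3g}")
```

prints

```
48
p(EGID:900000) 18 18 9.78e-24 3.81e-06
```

i.e. 48 of the 1000 genes pass the state-change cutoffs, and the one
planted mechanism — 18 of whose 20 downstream genes changed in the
predicted direction — is the only HYP passing both 0.1 cutoffs, with a
vanishing richness p-value and concordance `P(X ≥ 18 | 18, ½) ≈ 3.8e-6`.

The same pipeline is available from the shell:

```
belnet fixtures --seed 1 --outdir fx/
belnet rcr --deg fx/expression.tsv --kb fx/kb.tsv
belnet votes --ledger fx/votes.csv
```

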