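# Methods

This note documents the models, statistics, conventions, and numerical
choices behind `belnet`, and what the synthetic fixtures do and do not
establish about real data.

## The restricted BEL dialect

Terms are `function(arg, ...)` with arguments that are namespaced entity
references, nested terms, or — only for the qualifier-style functions
`pmod`, `tloc`, `sub`, `trunc`, `fus` — bare tokens (modification codes,
positions). Every entity must carry a namespace prefix; a bare name inside
any other function is a `missing_namespace` error. The function and
namespace registries ship as packaged TSV data (28 functions, 33
namespaces) and are user-extensible, since namespace vocabularies evolve
faster than code. Prefixes and names are case-sensitive; there is no fuzzy
matching. Nesting is capped at depth 4 — deeper terms do not occur in this
modeling style and almost always indicate a parenthesis error.

Canonical form drives all identity decisions: whitespace is dropped, names
containing characters outside `[A-Za-z0-9_.+-]` are double-quoted (with
backslash escapes), and the arguments of the unordered container functions
`complex` and `composite` are sorted lexicographically by serialized form,
bottom-up. All other functions preserve argument order because their
arguments are positional. `canonical_key(term)` is the canonical
serialization; `statement_key` concatenates subject key, relation code,
and object key. Relations are restricted to `increases`, `decreases`, and
`nonCausal` (reserved for self-links such as a protein to its own
activity); richer relation vocabularies are out of scope.

## Network model and provenance

Networks deduplicate edges by canonical statement: re-adding a statement
appends its evidence to the existing edge. Evidence identity defaults to a
short hash of citation + quote (BEL-script reading adds the statement key
to the hash so one evidence block can support several statements). Every
mutating operation increments the revision by exactly one and appends one
history entry with a `Provenance` (phase, actor, ordinal timestamp); the
five phases cover the initial non-diseased scaffold, literature and RCR
enhancement, crowd verification, and the jamboree. Rejection is a status
change on the evidence, never removal, so the revision history stays
complete. Whether a published model set would retain rejected evidence is
unknowable from the outside; retention is the safer archival choice.

The boundary filter encodes the inclusion rules for early-disease
curation as data: exclusion lists for diseases with different pathogenesis,
non-lung in-vitro systems, and solid-particle exposures, checked in fixed
order (disease → cell system → exposure → species) with the first match
reported as the reason code. Matching is case-insensitive exact-string —
deliberate, because ontology expansion would silently change decisions;
missing context fields pass. Human context always passes; mouse/rat passes
only with the homologization flag and is annotated `homologized`.

Version diffs count nodes, edges, and evidence present in the new version
but not the old, per network name, and share reports round percentages
half-up to integers (matching how such bookkeeping is normally reported);
a zero denominator yields an undefined (None) share, never 0%.

## RCR scoring

The two tail statistics are the standard reverse-causal-reasoning
definitions: richness is the hypergeometric upper tail of the overlap
between a HYP's downstream genes and the state changes, concordance is the
binomial(½) upper tail of the directionally consistent overlap. Both are
computed via `scipy.stats` survival functions with `k = 0` mapped to 1
exactly. The state-change filter applies a strict inequality to the FDR
(p < 0.05) and inclusive inequalities to fold change (|FC| ≥ 1.3, linear
scale, sign = direction; log2 input is converted on request) and mean
expression (≥ 100, an intensity floor for array platforms). Cutoffs of
0.1 on both p-values are applied raw, with no multiple-testing correction
across HYPs — these are screening cutoffs for human curation, not
discovery claims.

The default gene universe is the measured genes of the expression table,
because state-change rates are platform-dependent; a KB-covered-genes
universe is available for sensitivity analysis. Downstream genes listed
with contradictory signs under one HYP are dropped from that HYP (counted
and reported). Significant HYPs are sorted by richness p, then concordance
p, then upstream canonical key, so output order is fully deterministic.

`propose_enhancements` emits one candidate edge per significant HYP whose
upstream term is absent from the target network, connecting it to a
caller-supplied anchor process node. The relation follows the net
predicted direction: concordant ≥ discordant → `increases`, otherwise
`decreases`. Mapping many mechanisms onto fewer curated edges is a human
act; the engine deliberately stops at one-candidate-per-mechanism and
never auto-merges.

## Vote locking

Lock thresholds are four effective up-votes (approved) or four effective
down-votes (rejected). Effective means one vote per user per evidence with
later votes superseding earlier ones — the published protocol is silent on
revotes, and supersession is the declared convention here. Thresholds are
re-checked after every vote, so the first threshold crossed wins and ties
cannot arise (a single vote moves a single user's effective direction).
Locked evidence refuses further votes; replaying a recorded CSV keeps
post-lock votes in the raw record (and counts them in summaries, which
report raw cast votes) without letting them change state. Leaderboard
points default to new_evidence 5, new_edge 5, new_node 2, vote 1 — the
platform's actual values were never published, so the scheme is a
config-overridable declared constant, with the invariant that creating
evidence must outscore voting. Jamboree invitees are the top 20 by
evidences created among users with at least 20 votes.

## Agglomeration

Merging unions node sets by canonical key and deduplicates edges by
canonical statement, concatenating evidence on collision (deduplicated by
evidence id, which is globally unique in all shipped generators). The
output count is |groups| + |standalone|, and the spec must cover the input
names exactly. Edge-family collapse groups causal edges sharing (subject
key, target gene, sign) whose objects are bare `p(X)`, `r(X)`, `g(X)`, or
`sec(X)`; nested objects such as `act(p(X))` are not family-eligible. The
surviving object form follows the preference protein > RNA > gene >
secretion — a convention of this package, since only the fact of
agglomeration, not the canonical survivor, is externally fixed — and the
collapsed forms are retained as an annotation on the representative edge.
Evidence count is conserved; edge count never increases; the operation is
idempotent, and a network with no collapsible family is returned untouched
(no revision bump).

## Serialization

The BEL-script dialect is line-oriented: `SET Network`/`SET Description`
header, then per evidence `SET Citation`, `SET Evidence`, optional context
lines (Species, Tissue, CellType, Disease, Exposure), and the statement
line(s) it supports. Errors carry line/column. XGMML export follows the
public XGMML 1.0 draft with a plain-string shape attribute per function
class (activities → triangle, processes/pathologies → diamond,
translocation/transport/secretion/surface → rounded square, proteins and
complexes → square, other abundances → circle) and an evidence-count
attribute per edge; element order is sorted by canonical key, so exports
are byte-deterministic. XGMML is structure-only: import re-parses labels
as BEL where possible, keeps the rest as opaque nodes flagged unparsed,
and synthesizes one placeholder evidence per edge (citation
"unspecified") so model invariants hold. Evidence-preserving round trips
go through BEL script.

## Synthetic fixtures and what passing means

The generators are seeded `random.Random` state machines emitting plain
text, so fixed seeds give byte-identical files across platforms. Gene
identifiers are synthetic numeric EGID entries — no claims about real
genes. The default RCR condition is a 1000-gene measured universe, a
10-mechanism KB with 20 signed targets each, one planted mechanism with 18
concordant state changes among its targets, and background state changes
at rate 0.033 (≈50 SCs in total). Under these conditions the planted
mechanism's tails are astronomically small (richness ~1e-20, concordance
≤ 2e-4), while a random 20-target HYP needs overlap ≥ 4 *and* near-perfect
concordance to pass both 0.1 cutoffs (joint probability ≈ 1e-3 per HYP),
which is what the recovery (≥95% of seeds) and false-positive (≤10% of
seeds) checks exercise. Truth records are computed inside the generator by
exact `math.comb` summation — independent of the scipy-based engine — so
they double as oracles.

Vote fixtures realize the open-phase aggregate exactly: 484 evidences with
profiles 406×(4 up, 1 down, down first), 21×(4 down), and 57×(3 up, 3 down
alternating) give 1795 up + 661 down = 2456 raw votes, all cast before
locking; 49 of those evidences (241 votes, ≈10%) sit on the neutrophil
network, 36 (180) on the macrophage network, and 21 (105) on the Th1-Th2
network. Version-pair fixtures apply scripted additions to small base
chains, so the expected diff is known by construction: the phase-1 script
adds 200 nodes and 415 literature + 72 RCR = 487 edges; the open-phase
script adds 351/451/885 nodes/edges/evidences with 266 evidences and 208
edges in the three focus networks; the jamboree script adds 167/296 with
148/263 (89%/89%) in the focus networks; the merge fixture combines 56 of
90 networks into 16 groups, leaving 34 standalone (50 outputs).

These fixtures validate the *machinery* — arithmetic, statistics,
protocols, round trips — under exactly realized conditions. They do not
emulate real expression distributions, correlated gene behavior, curator
judgment, or voter dynamics, so passing says nothing about the biological
content a real curation effort would produce.

## Problem sizes and numerics

The acceptance sweep sizes are 200 RCR fixture seeds, 10,000 random vote
ledgers, 10,000 random terms, 1,000 random networks, and the exhaustive
richness grid over all (k, n, m, N) with N ≤ 20 — chosen to give stable
rate estimates while completing in seconds. Tail values are compared to
closed-form summation at 1e-12 absolute tolerance; observed deviations are
at machine epsilon. Random-term generation covers all leaf/wrapper/
container function classes with occasional quoted multi-word names to
exercise the quoting path.

## Known limitations

- The grammar is the restricted dialect only: no annotation DSL, statement
  lists, nested statement objects, or orthology mapping between species
  namespaces.
- Context matching is exact-string; no ontology expansion.
- XGMML import cannot recover evidence details (the format does not carry
  them here).
- Writing a network to BEL script requires all nodes to be parseable BEL;
  two identical (citation, quote) evidences on one edge would collide
  under the hash-based id scheme on re-read.
- The crowd module models the verification protocol, not participant
  behavior or incentives.
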