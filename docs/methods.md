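# Methods

## Model and assumptions

`nrpairs` treats an NRPS product as its ordered monomer backbone and
compares products through the multiset of **adjacent monomer pairs**.
The underlying assumptions are:

* the number of monomers equals the number of NRPS modules, in gene
  order (collinearity);
* a pair of adjacent monomers is a chemically meaningful unit whose
  identity does not depend on reading direction — hence alphabetical
  normalization (`ser,orn → orn.ser`), which makes fragmentation of a
  backbone and of its reversal identical;
* tailoring modifications (cyclization, methylation, …) do not change
  which building block a module loads, so modification tags are
  stripped before comparison and never affect monomer equality;
* fragmentation is linear: no pair joins the terminal monomer back to
  the start, even for macrocyclic products. The bundled Delftibactin
  backbone ends in a cyclized ornithine, yet its pair set contains no
  terminal–initial pair; this is the package-wide convention.

## Consensus calling

Per module, three predictors (NRPSpredictor2, Stachelhaus, Minowa) each
propose a raw token. After normalization (lowercase, modification
stripping, synonym resolution through an editable TSV), the default
`strict` policy accepts a monomer only on three-way agreement; anything
else — including an absent call — yields the unresolved token `nrp`.
A `majority` (2-of-3) policy is exposed as configuration; it is never
the default because the accept-only-full-agreement rule is the
conservative choice and the two policies differ only on modules where
exactly two predictors agree.

## Point matching

A POP is compared with a compound's PEC set after **symmetric
polyketide pooling**: every member of the polyketide class
(`pk, mal, mmal, ohmal, emal, mxmal`; a one-column TSV, editable)
collapses onto `pk` on both the POP and the PEC side. Matching is then

| outcome | points | condition |
|---|---|---|
| exact | 1 | pooled POP equals some pooled PEC |
| partial_nrp | 0.5 | exactly one POP member is `nrp`, the other occurs in the pooled PEC token pool |
| none | 0 | everything else (`nrp.nrp`, non-adjacent token pairs, foreign tokens) |

Design choices here, and why:

* *Symmetric pooling* is the only variant among {no pooling, POP-side
  only, PEC-side only, symmetric} that simultaneously reproduces the
  validation cluster's six point values and keeps self-consistency (a
  compound whose backbone names a specific extender like `ohmal` must
  score 1 per POP against itself). The test suite proves this by brute
  force; the rule is therefore not configurable.
* *PECs are types, not slots*: matching does not consume a PEC, so one
  PEC can confirm several POPs and a duplicated pair needs no bipartite
  assignment.
* *Distinct POPs are scored once each* by default; a multiplicity
  option repeats results by occurrence count for sensitivity analysis.
  The per-cluster summary divides total points by the number of scored
  POPs, so the fraction lies in [0, 1] by construction.
* The partial rule requires only that the non-`nrp` token occur
  somewhere in the PECs, not that it have an unmatched neighbor: a
  half-confirmed fragment is evidence regardless of which specific
  junction it came from.

## Jaccard similarity and clustering

Instances (gene clusters by default — keys like `B. caribensis-C9` — or
organisms, which pool their clusters' POP sets by union) form a binary
presence/absence matrix over the alphabetically ordered pair
vocabulary. Similarity is the Jaccard index over row supports, computed
with set arithmetic; JI(∅, ∅) is defined as 0 and empty instances are
flagged, because an all-zero fingerprint carries no evidence of
similarity (a distance routine treating two empty rows as identical
would say the opposite). `nrp.nrp` columns are retained — their
prevalence measures how often modules could not be called — even though
`nrp.nrp` scores zero in point matching; this asymmetry is deliberate.

Row clustering is agglomerative with Euclidean distance on the 0/1
vectors and unweighted average linkage (UPGMA), via
`scipy.cluster.hierarchy` on a condensed distance matrix; ties break
deterministically by input order. The merge tree serializes to Newick
with branch lengths equal to parent-minus-child merge height. WPGMA
was the alternative reading of "average" linkage; UPGMA was chosen as
the common default in this field's heatmap tools, and the test suite
pins the choice against a naive UPGMA oracle.

## Distributions

`pop_distribution` reports `100 × count / total` per pair over a group
of fragment multisets. Multiplicities count by default (a pair occurring
twice in one backbone contributes two counts — this is what makes a
duplicated pair half as frequent again as its singleton peers); a
unique-pair view is a flag. Branch-wise tables add a global table under
the label `Branch_0`. The PEC-vs-POP table pairs, per record with a
resolvable known compound, the compound's PEC multiset against the
record's POP multiset, yielding two percentage columns over the union
vocabulary; at zero prediction corruption the columns are identical.

## Networks

Both networks are directed bipartite multigraphs with organisms as
sources (shape attribute `diamond`) and features as targets (`circle`):
compound mode adds one edge per cluster weighted by its gene-homology
percentage, with unmatched clusters pointing at a shared `unknown` node
(weight 0, since exports cannot carry null); POP mode aggregates one
edge per organism→pair weighted by count. Degree-based subsetting
keeps nodes whose degree **in the originally built network** meets the
threshold (inclusive, default 5) — so subsetting a subset at the same
threshold is a no-op — and optionally their first neighbors; the
`degree` attribute is recomputed on the subset for rendering. Exports
are SIF and GraphML with sorted nodes and edges for byte-deterministic
output; layout is left to the viewing tool.

## Synthetic cohorts

The generator emulates a homolog cohort of a template compound
(Delftibactin by default). Corruption acts on the three predictor calls
*before* consensus, so `nrp` arises mechanistically from discordance:

* `nrp_rate × g(identity)` — three mutually distinct calls (consensus
  fails under either policy);
* `wrong_monomer_rate × g(identity)` — a unanimous decoy token
  (confidently wrong);
* otherwise the true template monomer, unanimously.

`g` is the identity→corruption link: linear (`1 − identity/100`) by
default, so a 100 %-identity cluster is uncorrupted and corruption grows
proportionally as identity falls; `none` applies base rates verbatim
(needed e.g. to realize a fully wrong cohort at high nominal identity).
Defaults — 500 clusters over identity levels 100/75/50/25 %, base rates
`nrp_rate = 0.30`, `wrong_monomer_rate = 0.15`, ten decoy monomers
disjoint from the template backbone — span the identity range a real
homolog cohort exhibits (roughly 9–100 %) while keeping every stage's
statistics testable in seconds on one CPU. An outlier variant relabels
a chosen fraction of clusters to the top identity level while
regenerating their modules under heavy corruption (0.45 + 0.45 per
module), for testing outlier visibility in the identity-vs-correctness
table.

What the generator does **not** emulate: real adenylation-domain
sequence signal (predictor errors are independent across modules and
predictors, with no shared bias), variable backbone lengths within a
cohort, tailoring-domain architecture, and correlated errors between
the three predictors. Passing tests therefore show that the pipeline
recovers planted statistical structure — identity–correctness
monotonicity, distribution identities, outlier visibility — not that
any particular real cohort will behave identically.

## Numerical and degenerate-input choices

* Rank correlation is Spearman's ρ; it is reported as undefined (NaN,
  flagged) for fewer than two usable rows or zero variance in either
  column, rather than raising.
* Backbones shorter than the fragment size yield an empty, flagged
  multiset; records without predictions are retained but contribute
  nothing (natural filtering), and their all-zero matrix rows are
  flagged.
* Percentages are exact rationals times 100 in double precision; tables
  sum to 100 within 1e-9 before rounding.
* Trigram keys sort all three tokens, extending the pair rule; unigram
  keys are the bare token.
* Equal seeds give byte-identical synthetic cohorts and pipeline
  re-runs give byte-identical artifacts (verified via SHA-256 manifests).

## Known limitations

* Scoring targets one compound per cluster (the most similar known
  cluster); multi-compound scoring is a caller-side loop.
* Branched or side-chain-linked peptide topologies are out of scope;
  backbones are strictly linear chains.
* The bundled compound library contains only Delftibactin, the one
  backbone needed by the validation path; users supply further
  compounds in the documented TSV format.
* The bundled monomer vocabulary and synonym table cover the tokens
  exercised here; both are plain-text package data intended to be
  extended.
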