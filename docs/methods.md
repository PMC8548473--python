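# Methods

## Morphological inventories

The package encodes the closed inventories of Hebrew verb morphology
as data, not heuristics: seven binyan conjugations, five temporal
categories, and the 31 defined binyan-temporal stem templates (Hufal
and Pual lack imperative and infinitive forms). Agreement cells per
temporal category follow the attested paradigm: infinitives carry no
agreement; imperatives are implicitly 2nd person (person is left
unexpressed in labels) with a gender-syncretic plural; present-tense
forms mark number and gender but not person; 1st-person and most
non-present plural cells carry no gender. This yields 25 inflection
categories for a full-paradigm binyan and 21 for Hufal/Pual — 167
unique inflected-pattern labels in all.

Node identity is purely categorical: a root node is the hyphen-joined
radical string (`l-m-d`), a pattern node the dot-joined categorical
label (`Qal.Present.Fm.Sg`). The two label grammars are disjoint, so
the bipartite node classes cannot collide. `interpolate_template`
renders a symbolic stem by slotting radicals into a template's C
positions; it is explicitly naive — real Hebrew surface forms undergo
stem changes (vowel alternation, spirantization) that are out of
scope — and is never used for node identity. Glyphs that break naive
encodings (ʔ, ℏ) are romanized to ASCII (`?`, `H`) with a configurable
display map, so labels survive CSV round-trips.

## Networks and measures

Each (session, speaker) stratum yields one bipartite network whose
nodes are the constructs with at least one token that session and
whose edges are the attested wordforms. The **binary** adjacency
(distinct partners) is the default: the worked degree example counts
distinct roots, so the binary reading reproduces it; token-weighted
adjacency is an option. Empty strata produce explicitly empty, flagged
networks so time series keep their index; measures on them propagate
as missing values, never as silent zeros.

*Degree* is the adjacency row/column sum. *Eigenvector centrality* is
the nonnegative leading eigenvector of the full symmetrized adjacency,
normalized to unit Euclidean norm, computed by power iteration with an
identity shift (`A + I`): bipartite spectra are symmetric (±λ), and
the shift suppresses the −λ branch that would make plain power
iteration oscillate, while leaving the leading eigenvector unchanged.
Defaults: tolerance 1e−10 on the iterate, 10,000 iterations maximum;
non-convergence raises an error carrying the iteration count and
residual. On disconnected networks mass concentrates on the dominant
component; a per-component option renormalizes each component
separately. *Density* uses the unipartite denominator `n(n−1)/2` by
default, for fidelity to the formula as printed, with the bipartite
maximum `|roots|·|patterns|` as an option; for a bipartite graph the
unipartite density is ≤ 1 for n ≥ 3 and exactly 1 at n = 2.

Activation timelines record, per node, the sessions in which it is
active; a *run* is a maximal stretch of consecutive active sessions
and gaps are counted between first and last activity. Many short runs
per node quantify punctuated usage.

## Adaptation models

Node-level frames keep only nodes active in *both* CS and CDS at a
session (adaptation is undefined for constructs only one party used),
drop the first session (no lag), take `prior.*` columns from the
preceding recording, and z-score every measure column; the scaling
means/sds are stored for back-transformation. When a node was inactive
at N−1 its prior measures are imputed as 0 before scaling — inactive
means zero links — with row-dropping available as an alternative.
Scaling is per assembled frame (per dyad), since models are fitted per
dyad; whether the original analyses scaled globally or per participant
is not recoverable, so the choice is documented rather than claimed.

The four node-level responses (degree and centrality, CS and CDS) are
fitted as linear mixed models with a random intercept per node name,
estimated by REML (the optimizer is an implementation detail;
statsmodels' default is used). Fixed effects are age plus the twelve
current/lag-1 measures of both parties excluding the response itself;
a per-fit exclusion list reproduces designs with blank cells.
Inference is Wald (95% intervals, normal approximation), with no
multiple-testing correction. Reported variance components: residual
σ², random-intercept τ₀₀, ICC = τ₀₀/(τ₀₀+σ²). Marginal and conditional
R² follow the variance-partition definition: var(Xβ̂)/(var(Xβ̂)+τ₀₀+σ²)
and (var(Xβ̂)+τ₀₀)/(same). The two density responses are ordinary
least squares on exactly four predictors (age, the partner's current
density, both parties' prior densities); node-level measures are
deliberately excluded. A `tau_zero` option pins the random-intercept
variance at a negligible value (1e−10; the exact-zero boundary makes
the profiled likelihood singular), and must reproduce OLS — a
degenerate-limit check exercised in the tests.

The effect ledger flattens fitted models into (model, predictor,
estimate, sign, significant-at-0.05) rows and exports the significant
effects as affecting→affected edges.

## The synthetic dyad generator

The generator emulates the statistical shape reported for dense
Hebrew-acquisition corpora, with defaults that are the study
conditions, not tuning knobs: 47 sessions between ages 664 and 810
days; negative-binomial token volumes (mean 650 CDS / 100 CS per
session, shape 10); a 400-root parent lexicon with Zipf–Mandelbrot
frequencies (exponent 1.05, offset 15 — the offset flattens the head,
as observed in lexical frequency distributions); a binyan mixture with
80% Qal; a child inventory acquired in frequency-rank order (25 roots
+ 3 per session; 12 pattern categories + 1.5 per session). Realized
token totals, lemma counts and the Qal share land on the reported
corpus anchors (e.g. ~4.8k CS / ~28–32k CDS verb tokens, ~180 CS /
~500 CDS lemmas, Qal share 0.80 ± 0.02).

Within a session, generation is ordered: parent base batch → child →
parent responsive batch, giving well-defined "current" couplings in
both directions. Two mechanism classes implement adaptation:

- **Current-session attunement is token re-use.** With probability
  `1 − exp(−b)` a child token re-uses a wordform from the parent's
  current base batch (restricted to the child's inventory), and a
  responsive share of parent tokens (default 30%) re-uses the child's
  current wordforms. Re-use transfers the partner's realized wordform
  concentration link-for-link, which is what makes coupling *signs
  identifiable by the density regressions*: purely multiplicative
  per-construct reweighting was tried first and transmits far too
  little session-level concentration, because a toddler-sized
  inventory overlaps mostly with the parent's stable head vocabulary.
- **Lagged couplings and persistence are log-linear opinion pools.**
  A coefficient `b` multiplies a construct's sampling weight by the
  coupled stratum's smoothed previous-session empirical share raised
  to `b`. Uniform components cancel in the softmax, so only usage
  *shape* transfers, and geometric pooling cannot run away.

Three further features make the sessions realistic:

- **AR(1) topic noise** (sd 1.3, persistence 0.9) on the 150 head
  roots: conversation topics make common, concrete verbs hot or cold
  for stretches of sessions, the dominant source of session-to-session
  variation in parental usage.
- **Parent priming** (`parent_persistence`): a parent token re-uses
  one of the parent's own previous-session wordforms with probability
  `1 − exp(−b)`, producing the continuous, coherent parental usage
  that contrasts with punctuated child activation. A separate
  `parent_routine` pool weight can additionally damp constructs the
  parent did not use at N−1 (routine-driven concentration); it is off
  by default.
- **Stratified root sampling**: tokens are allocated between
  Qal-primary and other-primary roots binomially at the *base* class
  share, so no amount of persistence or adaptation reweighting can
  drift the realized binyan mixture away from its calibration
  (unstratified persistence pushed the Qal share from 0.80 to ~0.95).

The parent-expansion channel flattens the parent's pattern logits
(temperature > 1) when the child's previous-session density rises
above its running average — a parent offering a broader paradigm when
the child's network looks exhausted (dense, low growth potential).

Determinism: one `numpy` Generator seeded from the user's seed drives
every draw; identical (params, seed) give byte-identical corpora.

## Validation design

Because the coupling coefficients are known, the adaptation models are
validated by parameter recovery rather than by reproducing coefficient
values from unavailable recordings:

- **Recovery condition** (`recovery_params()`): strong positive
  current-session couplings (2.0 ⇒ re-use probability 0.86), a
  stationary established child inventory (200 roots, 110 patterns, no
  growth), topic sd 1.5 with persistence 0.6, parent routine damping
  0.9, responsive fraction 0.45 — at calibration scale (47 sessions,
  reported token volumes). A recovery experiment isolates the
  adaptation channels from the growth trend, as a validation of an
  estimator should; the growth scenario is assessed separately. Under
  this condition the contemporaneous CDS-density coefficient in the
  CS-density model is recovered as positive and significant in ≳90% of
  replicates, with a mean standardized estimate ~0.6 — the same order
  as published estimates of this effect.
- **Null condition** (`null_params()`): identical scale with every
  adaptation channel off; the pooled rejection rate of the four
  coupling terms in the density models stays near the nominal 5%.
- **Default (growth) condition**: CS density falls with age (Spearman
  ρ typically −0.5 to −0.8) while CDS density stays comparatively
  flat, and child activation shows more runs per node than the
  parent's — the qualitative developmental signatures the analysis is
  designed to detect.

Model machinery is checked against independent oracles: OLS against
closed-form normal equations, the eigensolver against dense symmetric
eigendecomposition (component-wise only on connected graphs, where the
Perron vector is unique), noiseless mixed-model recovery of an
injected age slope, Wald-interval coverage of a null predictor, and
the Bernoulli closed form for activation run counts under the
no-coupling, no-growth generator.

## Problem sizes

Test and validation runs use deliberately modest sizes chosen for the
package's own CI hygiene: recovery and null experiments use 50
replicates of the 47-session dyad; qualitative-pattern checks use 20
replicates; coverage simulations use 100 replicates of a 40-node,
10-session frame. All are seeded and deterministic.

## Known limitations

- The generator produces coded token tables, not utterances: no
  discourse structure, dialogue acts, imitation windows shorter than a
  session, or utterance segmentation.
- Surface phonology is symbolic; template interpolation ignores
  morpho-phonological stem changes by design.
- The child's inventory grows deterministically in frequency-rank
  order; real acquisition orders are noisier.
- Passing recovery tests show the model detects the generator's
  coupling structure; they cannot show that real dyads contain no
  confound (e.g. shared session context) producing similar
  associations — an inferential limit shared with the observational
  design itself.
- Speaker-level random effects (pooling across dyads) are out of
  scope; models are fitted per dyad.
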