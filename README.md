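# morphnet

Dynamic bipartite-network analysis of root-and-pattern verb morphology
in child–parent interaction.

## The problem

Hebrew verbs are built non-linearly: a consonantal **root** (e.g.
*l-m-d* "learn") interdigitates with one of seven **binyan**
conjugations, each a bundle of temporal-category templates (31 defined
templates in all), and the stem is further inflected for
person/number/gender agreement (25 inflection categories for a full
paradigm). A child acquiring Hebrew must learn which roots combine
with which inflected patterns. This package treats that system as a
**bipartite network**: roots and inflected patterns are nodes, and
every attested verb wordform is a link between a root and a pattern.
Each recording session of a child–parent dyad yields two networks, one
per speaker stratum (CS, child speech; CDS, child-directed speech), so
a longitudinal corpus becomes a sequence of network snapshots whose
structure can be measured and modeled over developmental time.

Three measures drive the analysis:

- **degree** `C_D(j) = Σ_i A_ij` — how many partners a construct
  combines with;
- **eigenvector centrality** `x = (1/λ) A x` — a construct's importance
  through the importance of its neighbours (leading eigenvector of the
  symmetrized bipartite adjacency, unit Euclidean norm);
- **density** `d = m / (n(n−1)/2)` — realized links over possible
  links; a *sparse* network is read as having high growth potential.

Adaptation between child and parent is then quantified with lagged
regressions: each measure at recording *N* is modeled from the
partner's measure at *N*, and both parties' measures at *N−1* —
linear mixed models with a random intercept per node name (REML, Wald
intervals) for node-level degree and centrality, and OLS for
session-level density.

Because such dense dyadic recordings are not distributable, the
package ships a **synthetic dyad generator** with the corpus shape
such studies report (47 sessions between ages 664 and 810 days, ~650
CDS and ~100 CS verb tokens per session, ~80% Qal tokens, Zipfian
roots, a growing child inventory) and *known* adaptation couplings, so
the entire pipeline is validated end to end by parameter recovery.

## Worked example

```python
import morphnet as mn

table, truth = mn.simulate_dyad(mn.SimParams(), seed=1)
print(mn.summarize_corpus(table).to_frame().to_string(index=False))

series = mn.build_network_series(table, "dyad1")
net = series.get(3, "CS")
print("session 3 CS network:", net.n, "nodes,", net.m, "links,",
      "density %.3f" % mn.network_density(net))

measures = mn.measure_table(series, include_centrality=False)
frame = mn.assemble_network_frame(measures)
print(mn.fit_density_lm(frame, "density.cs").to_text())
```

prints

```
dyad_id speaker  n_sessions  age_start_days  age_end_days  verb_tokens  verb_types
  dyad1      CS          47             664           810         4841         186
  dyad1     CDS          47             664           810        28155         512
session 3 CS network: 48 nodes, 76 links, density 0.067
Response: density.cs  (OLS, n=46)
Predictors               Estimates                CI         p
(Intercept)                   8.02      3.88 - 12.15     0.000
age                          -0.01     -0.02 - -0.01     0.000
density.cds                  -0.03      -0.18 - 0.12     0.689
prior.density.cs              0.42       0.16 - 0.68     0.003
prior.density.cds            -0.16     -0.30 - -0.01     0.043
Observations  46
R^2/R^2 adj.  0.855/0.841
```

The summary shows the calibrated corpus shape (a child producing ~4.8k
verb tokens over 186 lemmas against a parent's ~28k tokens over 512
lemmas). The child's session-3 network links 48 active constructs
through 76 attested wordforms. In the density model the negative age
coefficient is the child's network becoming sparser — gaining growth
potential — as the inventory grows; at the weak default couplings the
contemporaneous CDS term is not significant in this single replicate,
which is why coupling detection is assessed over many replicates with
`mn.recovery_experiment` rather than from one corpus.

The same pipeline runs from the command line:

```bash
morphnet all --simulate --seed 1 --out runs/demo
```

writing the corpus, edge lists, measure tables, activation timelines,
the six model tables and a machine-readable effect ledger.

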