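# Methods

## The landscape model

The package models a drug–gene landscape as one bipartite multigraph with
two typed edge layers over shared drug and gene universes. A *target* edge
(d, g) asserts that drug d's compound physically binds the protein encoded
by gene g; a *sensitive* edge asserts that treatment with d significantly
changes g's expression. Edges are binary and typed: a pair that is both
bound and sensitive carries two distinct edges, never one weighted edge, so
the two per-gene degree scores

- KDTN(g) — number of distinct drugs binding g,
- KDSN(g) — number of distinct drugs perturbing g,

remain independent sums. Thresholding both at ≥ 1 yields the three-way gene
partition DTG / DSG / DTSG (target-only / sensitive-only / both). Genes with
both scores 0 are unscored background: they are dropped from networks but
retained in score tables.

Identifiers are opaque strings normalized by trimming and uppercasing.
Matching drugs and genes across input tables is therefore purely lexical;
no online identifier resolution is attempted.

## Signature calling

A record (drug, gene, FC, p) is called sensitive iff adjusted p < 0.05 AND
(FC > 2 OR FC < 0.5), all inequalities strict, FC on the linear scale (the
two branches are reciprocal; a non-reciprocal window triggers a warning, not
an error). When inputs carry only raw p-values, Benjamini–Hochberg
adjustment is applied before thresholding, by default **per drug** — each
drug's expression profile is treated as its own testing family, matching how
per-compound contrasts are produced — with a global scope available. Records
absent from a drug's table are simply uncalled; nothing is imputed. Calling
is deterministic, order-independent and monotone in the thresholds; all
three properties are under test.

## Degree statistics

The reverse-cumulative distribution reports P(K ≥ k) at every observed
degree. Power-law tails are fitted with the discrete maximum-likelihood
estimator: for the tail k ≥ x_min, p(k) = k^(−α) / ζ(α, x_min) with ζ the
Hurwitz zeta function; α is found by bounded scalar minimization of the
negative log-likelihood on (1, 25]. With `xmin="auto"` every distinct
observed value that leaves ≥ 2 distinct tail values is tried and the cutoff
with the smallest Kolmogorov–Smirnov distance (sup-norm gap between
empirical and model tail CCDF, evaluated on the observed support) is kept.
A degenerate tail (a single distinct value) is reported as an error, not a
fit. Cross-set "representativeness" is operationalized as a two-sample KS
test; the package reports the statistic and p-value and imposes no pass/fail
threshold. Parameter recovery on exact zeta samples (n = 5,000) keeps the
median |α̂ − α| well under 0.1 across α ∈ {1.8, 2.5, 3.2}.

## m-core peeling

The m-core of a single layer is the maximal subgraph in which every **gene**
keeps a layer degree of at least m. The constraint deliberately applies to
gene nodes only — the quantities being decomposed (KDTN, KDSN) are gene-side
degrees — while drug nodes persist as long as they keep ≥ 1 edge. The
implementation peels iteratively (genes below the bar, then edge-less drugs,
to a fixed point). In this gene-constrained bipartite setting the fixed
point admits a closed form — genes of original degree ≥ m plus their drug
neighbours, since removing a gene can never lower another gene's degree —
which the tests exploit as an independent oracle alongside exhaustive
gene-subset enumeration on small graphs. Peeling is order-independent; cores
are nested in m. All connected components of the fixed point are kept and
counted (maximality holds per component); a largest-component-only mode and
a strict (> m) threshold variant are available as options. The decomposition
runs m = 1, 2, … until the core empties; m_max and per-gene core numbers
(the largest m retaining the gene) are reported. The pipeline decomposes a
layer only when it holds more than 50 genes (smaller layers yield
uninformative profiles); the bound is configurable.

## Enrichment and TF statistics

Over-representation uses the one-sided upper-tail hypergeometric probability
of the observed-or-greater overlap between a query set and each library
term, with terms first restricted to the background universe. BH-FDR is
controlled across all tested terms within one library; libraries are tested
independently. The default universe is the set of scored genes in the
network, since the appropriate background for landscape queries is the
landscape itself; it is configurable. Term-overlap accounting intersects the
significant term lists of ≥ 2 gene sets and reports total and shared term
counts. TF binding frequency counts, per gene of a set, the TF target sets
containing it; the per-gene mean and the distinct TFs touching the set
support cross-set regulation-density comparisons. The package reproduces
these *procedures*; it does not attempt to reproduce term counts from any
specific annotation-database release, which are version-dependent.

## Synthetic landscapes

The generator plants a complete landscape and returns its truth:

- **Roles.** Of n_genes, a target set and a sensitive set are drawn with an
  intersection of `overlap_fraction` × n_target_genes genes. Defaults are a
  ~1/10-scale rendition of the real landscape's shape: 40 drugs, 950 genes,
  72 target genes (64% also sensitive), 923 sensitive genes, so the dual set
  is small against the sensitive set, as observed.
- **Degrees.** Gene-side degree sequences are exact draws from the discrete
  power law (inverse-CDF against the Hurwitz-zeta CCDF; table for the bulk,
  bisection for the far tail), truncated at n_drugs by resampling. Default
  exponents 2.2 (target) and 1.9 (sensitive) make the sensitive layer the
  denser, heavier-tailed one. Incidence is realized by giving each gene a
  distinct-drug neighbour set of exactly its planted degree — a bipartite
  configuration model conditioned on simple edges on the gene side — so
  recomputed scores equal planted degrees exactly. Every drug is guaranteed
  ≥ 1 target (drugs without targets would not enter a landscape); repair
  edges are folded into the returned truth.
- **Reciprocity.** On shared genes, a |anti_correlation| fraction is coupled
  by rank reversal: the strongest target hub gets the smallest sensitive
  degree. Because both marginals put large mass on degree 1, tie blocks
  attenuate rank correlations: full reversal yields Spearman ρ ≈ −0.7 at the
  default exponents and ≤ −0.9 for tails with α ≤ 1.5. The construction
  check therefore uses heavy-tailed marginals; the default −0.5 encodes the
  qualitative reciprocity only.
- **Signatures.** Planted sensitive pairs draw FC from U(2.2, 8) or
  U(0.1, 0.45) and adjusted p from U(0, 0.04); null records draw FC from
  U(0.6, 1.8) and uniform p. Clean mode therefore makes calling lossless
  (planted pairs pass and nulls fail the FC gate with certainty), separating
  logic tests (exact) from statistical tests. Noisy mode narrows the margins
  (planted FC ≥ 2.05, adjusted p < 0.049) and lets null FC straddle the
  window (U(0.3, 3.0)), so the false-call rate is governed by the p
  threshold times the FC-gate escape probability (≈ 0.022 nominal, below
  the 0.05 bound).
- **Libraries.** Annotation/TF terms sample genes without replacement with
  weight `effect` on a named gene set's members and 1 elsewhere; effect 1 is
  the exact null. TF libraries are planted the same way with several
  DSG-enriched terms to emulate denser regulation of sensitive genes.

What the generator does **not** emulate: transcriptome covariance between
genes, cell-line effects and replicate structure, drug–drug chemical
similarity, and annotation-term hierarchy. Passing tests therefore
demonstrate correctness of the scoring, partition, peeling and testing
machinery under the assumed independence structure — not robustness to
correlated noise in real expression data.

## Numerical and design choices

- Determinism: every stochastic component takes an explicit seed
  (numpy `default_rng`); the same spec + seed yields byte-identical files.
- Subnetwork sampling selects round(fraction × #drugs) drugs (half-up,
  floor 1) uniformly and induces the subgraph on them; gene neighbours keep
  only their edges to selected drugs.
- BH adjustment and hypergeometric tails are delegated to statsmodels and
  scipy respectively; tests pin them against hand-derived step-up values and
  an exact combinatorial enumeration oracle (≤ 25-gene universes, 1e-12).
- Strict config schema (unknown keys rejected, all violations reported at
  once): silent config typos are the dominant pipeline failure mode.
- Problem sizes in tests and the acceptance script (e.g. 950-gene default
  landscapes, n = 5,000 power-law samples, 100–200 replicates for rate
  estimates) are chosen to make sampling error small relative to the margins
  being checked while keeping runs fast on a laptop.

## Known limitations

- The m-core semantics hard-wire the gene-side constraint; drug-side or
  all-node cores are out of scope (the classical k-core agrees with the
  gene-constrained core only when drugs incidentally satisfy the bar, a case
  the tests exploit for cross-validation).
- ORA treats terms as flat sets; no parent–child structure or term
  similarity is modelled.
- The signature caller assumes one profile per drug; unifying multiple
  cell-line profiles per compound is left to the caller.
- GraphML round trips preserve node/edge sets and attributes but not file
  byte-identity (attribute ordering is writer-dependent).
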