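# Methods

## Model and procedure

`reporterpath` scores features of a metabolic network — metabolites, then
pathways — by aggregating per-gene differential-expression evidence over
network neighborhoods. The pipeline is:

1. **Gene statistics.** Per gene, a two-sample t-test between the two
   condition groups (pooled variance by default; Welch optional). The
   p-value is mapped to a standard-normal deviate z = Φ⁻¹(1 − p), so small
   p means large positive z regardless of direction; the direction of
   change (sign of the condition − reference mean difference) is carried
   separately. Precomputed p-value tables can be substituted for the
   t-test.
2. **Gene → reaction mapping.** A reaction controlled by several genes is
   represented by the gene with the smallest p-value (ties broken
   lexicographically, for determinism). Reactions whose genes are all
   unmeasured carry no statistic.
3. **Metabolite scores.** A metabolite's neighborhood is the set of
   distinct representative genes over all reactions that consume or
   produce it (direction-agnostic; duplicate genes collapse). With k
   neighbor genes, the raw score is the Stouffer aggregate (Σz)/√k,
   standardized as (raw − μ_k)/σ_k against random size-k gene sets, and
   converted to an upper-tail p-value.
4. **Pathway scores.** Metabolite-centric (RPA^m): aggregate the corrected
   scores of the pathway's n scored metabolites with (Σz)/√n, standardize,
   convert to p. Reaction-centric (RPA^r): aggregate the representative
   gene deviate of each of the pathway's p measured member reactions — one
   term per reaction even when reactions share a gene — standardize
   against random size-p reaction sets, convert to p. Benjamini–Hochberg
   q-values are attached across pathways. Pathways with fewer than
   `min_reactions` (default 3) members are not reported.
5. **Directional runs.** The up (down) variant keeps only genes with
   positive (negative) sign, halves their two-sided p-values into the
   matching one-tailed p, and reruns steps 2–4 (RPA^m only). Restricting
   the gene set discards connectivity, so directional results are always
   reported alongside the undirected run.

Two structural consequences are intended, not incidental: a reaction
catalogued under pathway B but touching a metabolite of pathway A
contributes to A's RPA^m score (cross-talk capture), and a gene whose
reactions touch m metabolites of one pathway contributes m terms to that
pathway's RPA^m evidence (implicit up-weighting of branch-point
neighborhoods).

## Background correction

All aggregates are standardized against empirical null moments (mean and
standard deviation), estimated by Monte-Carlo:

* **Metabolite level** — random size-k subsets (without replacement,
  permutation prefixes) of the measured-gene deviate pool. The pool is the
  deviates of all measured genes associated with the network; sampling
  from measured genes only is deliberate, since unmeasured genes carry no
  deviate.
* **RPA^m pathway level (default: `background="permutation"`)** — the
  gene deviates are permuted over the gene pool and the *entire*
  metabolite → pathway cascade is replayed per permutation, giving each
  pathway its own μ/σ. This is the random-gene-set idea lifted to the
  pathway level while preserving the covariance induced by neighboring
  metabolites sharing genes. The simpler alternative — random size-n sets
  of metabolite scores (`background="pool"`) — ignores that covariance:
  on chain-structured pathways its null corrected scores have a standard
  deviation near 1.4 rather than 1, inflating the p < 0.01 hit rate under
  the null to roughly 5–6%. The permutation null is calibrated (hit rate
  ≈ 1%, corrected scores ≈ N(0,1)); the pool variant is retained as an
  option because it is the more literal transcription of the random-set
  recipe.
* **RPA^r pathway level** — random size-p sets of reaction deviates
  network-wide. With one gene per reaction these terms are exchangeable
  and the null is calibrated.

Whether the pathway aggregate consumes corrected or raw metabolite scores
is switchable (`statistic="corrected"|"raw"`); corrected is the default,
since the corrected score is the reporter-metabolite quantity of interest.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `n_samples` | 10,000 | Monte-Carlo draws per background; relative error of σ_k ≈ (2·n_samples)^(−1/2) ≈ 0.7% |
| `seed` | required | one master seed; fixed offsets derive per-stage streams |
| `min_reactions` | 3 | pathway reporting filter |
| `alpha` | 0.01 | significance cutoff; 0.005 available when RPA^m yields many hits |
| `tail` | two_sided | one-tailed variants feed directional runs |
| `equal_var` | True | pooled-variance t-test; Welch optional |
| p clamp | [1e−15, 1−1e−15] | keeps Φ⁻¹ finite at extreme p |

## Synthetic data

The generator emulates the target study design, not any particular
organism: `n_pathways` (20) chain pathways of `reactions_per_pathway` (8)
reactions each, every reaction carrying `genes_per_reaction` (1) unique
gene(s); `cross_link_fraction` (0.25) of reactions additionally touch one
metabolite of another pathway, realizing inter-pathway reactions. A hub
topology (all reactions around one central metabolite) exercises
branch-point weighting; a shared-isozyme mode exercises the minimum-p
rule. Expression is i.i.d. Gaussian noise (`noise_sd` = 1) with an
additive shift of `effect_size` (3, i.e. 3 standard deviations) on the
condition group of the affected genes — the genes of all reactions
touching the perturbed pathway's metabolites, or only the member /
cross-linking subsets. Five samples per group. Under this model the
t-test is exact and all planted-truth claims are checkable.

What the generator does **not** emulate: correlated gene noise, varying
library size or normalization artifacts, stoichiometry or flux coupling,
compartment structure, and the heavy-tailed degree distribution of real
metabolic networks (currency metabolites). Passing the validation suite
therefore demonstrates the statistical machinery is correct under its own
assumptions, not that real-data p-values are exact.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; backgrounds regenerate bit-identically for a given seed,
  universe, and sample count, and whole-pipeline reruns are byte-identical.
* A background with σ_k below 1e−12 (e.g. an all-constant deviate pool,
  as when every gene sits at p = 0.5 exactly) is refused as degenerate
  rather than silently dividing by ~0.
* Metabolite/pathway features with no measured neighbor are omitted and
  logged, never scored as zero. n and p count *scored* items; nominal
  member counts are reported alongside.
* Ranked reports sort by p-value, then neighbor count (descending), then
  identifier — fully deterministic.
* Compartment-qualified metabolite names are kept verbatim; no cross-
  compartment merging (it would silently change neighborhood sizes). An
  optional exclusion list can drop currency metabolites; off by default
  because cofactor neighborhoods are legitimate signal.
* Validation problem sizes: 25 networks of ≤ 50 reactions for the
  brute-force equivalence check, and 50 replicates of the default
  20-pathway network for the calibration, recovery, discordance and
  directionality checks with 1,000–2,000 background draws per stage —
  sizes at which the Monte-Carlo error of the checks is far below the
  effects being tested.

## Known limitations

* **Background contamination under strong sparse signal.** μ_k/σ_k are
  estimated from the same experiment's deviates, which is what makes the
  score robust to global expression shifts — but it also means a strong
  perturbation concentrated elsewhere in the network slightly deflates
  every other feature's corrected score. On the small synthetic network
  (160 genes) a cross-link-only perturbation shifts the victim's RPA^r
  corrected score by about −0.5 sd through the pool alone, while leaving
  its raw score exactly unchanged; at genome scale the affected fraction
  of the pool, and hence the shift, is an order of magnitude smaller.
* **Minimum-p selection bias.** With many genes per reaction, the min-p
  rule biases reaction deviates upward; the gene-pool background (drawn
  from all measured genes, not selected ones) does not absorb this bias
  at the metabolite level. It is inherent to the mapping rule; directional
  and pathway-level conclusions should rest on the corrected scores, which
  share the bias across features of equal size.
* One-tailed "reporter" semantics: only coordinated *significance* (large
  positive corrected Z) is flagged; coordinated insignificance is not.
* The PADOG-style moderated-t comparison is out of scope; the report
  format leaves room to join externally computed comparator p-values.
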