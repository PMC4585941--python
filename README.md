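# reporterpath

Reporter pathway analysis of transcriptome data on genome-scale metabolic
networks.

When a cell is perturbed — genetically, environmentally, or by disease —
the transcriptional response is rarely confined to single genes. A
practical way to read it is at the level of metabolic pathways, using the
metabolic network as a scaffold: genes map to the reactions they control,
reactions connect metabolites, and coordinated expression changes
accumulate along that connectivity even when no individual gene is
strikingly significant. `reporterpath` implements two complementary
pathway scores on this scaffold:

* **RPA^r (reaction-centric)** — a pathway is scored from the genes of its
  own member reactions only.
* **RPA^m (metabolite-centric)** — a pathway is scored through its
  metabolites, each of which is first scored from *all* reactions that
  consume or produce it — including reactions catalogued under other
  pathways. Cross-pathway reactions are exactly the conduits the
  reaction-centric view misses, so RPA^m captures inter-pathway cross-talk
  that RPA^r cannot.

## The statistic

Per gene *i*, a two-sample t-test p-value is converted to a
standard-normal deviate Z_i = Φ⁻¹(1 − p_i). Each reaction is represented
by its minimum-p gene. A metabolite with k distinct neighbor genes gets
the Stouffer aggregate

    Z_met = ( Σ_{i=1..k} Z_i ) / √k,

standardized against an empirical null (mean μ_k and standard deviation
σ_k of aggregates of random size-k gene sets):

    Z_met_corr = (Z_met − μ_k) / σ_k.

A pathway with n scored metabolites aggregates their corrected scores the
same way (and analogously over its p measured member reactions for RPA^r),
is corrected against its own null, and is converted to an upper-tail
p-value 1 − Φ(Z_corr) with Benjamini–Hochberg q-values across pathways.
For the pathway-level RPA^m null the package permutes the gene deviates
over the network and replays the whole metabolite→pathway cascade, which
preserves the gene sharing between neighboring metabolites (see
`docs/methods.md`). Directional (up/down) variants rerun RPA^m on the
genes changing in one direction only. Pathways with fewer than three
member reactions are filtered; significance is reported at p < 0.01
(a stricter 0.005 is recommended when RPA^m yields many hits).

## Worked example

The package ships a synthetic-data generator that emulates the intended
study design: a multi-pathway network with cross-linking reactions and an
expression matrix in which the genes around one pathway carry a planted
mean shift.

```sh
reporterpath simulate --out-dir sim --seed 11
# network: 180 metabolites, 160 reactions, 160 genes, 20 pathways;
#   perturbed=P01 (16 genes, up, effect 3.0)

reporterpath run --network sim/network.tsv \
    --expression sim/expression.tsv --groups sim/groups.tsv \
    --condition condition --reference reference \
    --seed 11 --out-dir out
# scored 180 metabolites, 20 pathways (RPA^m), 20 pathways (RPA^r);
#   1 significant under RPA^m at alpha=0.01
```

`out/report.tsv` then starts:

```
pathway  n_metabolite_neighbors  p_rpam         q_rpam         n_reaction_neighbors  p_rpar         q_rpar        discordant
P01      10                      2.053300e-16   4.106600e-15   8                     3.015015e-11   6.030030e-10  False
P06      10                      0.01526        0.15263        8                     0.08395        0.83952       False
P18      13                      0.07548        0.46329        8                     0.15438        0.90186       False
```

The planted pathway P01 is the unique significant hit at p < 0.01 under
both scores (the perturbation here covers its whole neighborhood, so both
views see it; a perturbation restricted to cross-linking reactions of
*other* pathways is seen by RPA^m only — the `discordant` column flags
that situation). Columns mirror the standard report layout: neighbor
counts, p-values and BH q-values for both scores. `reporterpath
run-directional --direction both ...` adds up/down-restricted runs and a
`direction_flag` column; `reporterpath compare` joins two reports and
counts discordant pathways. Every run writes a `manifest.yaml` (all
materialized options, seed, versions, network dimensions) from which it
can be replayed byte-for-byte.

Real networks are supplied as tab-separated reaction tables (one row per
reaction; metabolite, gene and pathway lists inside cells, `" // "`
delimited, BioCyc SmartTables style) with configurable column names;
gene statistics come either from a genes × samples expression matrix or a
precomputed gene/p-value table (`--pvalues`).

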