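# magdyn

Functional dynamics of longitudinal, genome-resolved gut-microbiome
studies.

`magdyn` is for microbial ecologists who have a catalogue of
metagenome-assembled genomes (MAGs), a sample × MAG read-count table from
a repeated-measures design (individuals sampled through a sequence of
environmental disturbances), a MAG phylogeny and per-genome gene
annotations — and who want to know not just *whether* the community
changed, but whether it changed *directionally* and what that did to its
functional capacity.

## What it computes

**Genome-inferred functional traits (GIFTs) and metabolic capacity
indices (MCIs).** A pathway is an ordered set of steps, each satisfied by
alternative gene-identifier combinations. A genome's GIFT for a pathway is
the mean over steps of the best fraction-present among alternatives, so a
two-identifier step scores 1 (complete), 0.5 (half-complete) or 0. Raw
scores are corrected for genome completeness *c* by `min(1, GIFT / c)`
and averaged within broader function categories to give per-genome MCIs
in [0, 1].

**Hill-number diversity partitioning at q = 1.** For relative abundances
*p*, neutral diversity is `exp(−Σ pᵢ ln pᵢ)`; phylogenetic diversity
weights branches *b* by length `L_b` and descendant abundance `a_b`, with
`T = Σ L_b a_b`, as `exp(−Σ (L_b/T) a_b ln a_b)`; functional diversity is
the attribute diversity built on Rao's `Q = Σ d_ij p_i p_j` over the Gower
distance matrix `d` of the MCI traits. Beta diversity is `γ/ᾱ` under
equal sample weights and is reported as Sørensen-type turnover:
`(β−1)/(N−1)` for the neutral and phylogenetic components, `(β−1)/(N²−1)`
for the functional component (whose β ranges to N²).

**Functional redundancy.** Uniqueness `U* = Q/D` (Rao over Gini–Simpson)
and redundancy `R* = 1 − U*` per sample, plus the correlation between
`log` neutral diversity and `R*` across samples.

**Directional treatment effects.** One-way PERMANOVA on the turnover
dissimilarity matrices with the unadjusted R² as effect size and
*restricted permutations*: treatment labels are shuffled only within each
individual, respecting the repeated-measures design. CAP (canonical
analysis of principal coordinates) ordination with leave-one-out
selection of the number of retained axes.

**Community-weighted functional trajectories.** After a 0.1% prevalence
filter, the community-weighted mean capacity `CWM_f = Σ pᵢ·MCIᵢf` is
tracked per treatment with percentile-bootstrap 90% intervals that
resample individuals; consecutive treatments with non-overlapping
intervals are flagged as directional shifts.

**Synthetic studies.** A fully seeded generator produces complete study
bundles — two host-species archetypes with contrasting MAG richness, a
Yule phylogeny with phylogenetically autocorrelated gene content,
cage/individual random effects, log-normal abundance noise, multinomial
read sampling, and a designated directional "responder" genome — together
with the ground truth needed for parameter-recovery testing.

## Worked example

```python
from magdyn import Permanova, default_config, generate_study
from magdyn.pipeline import RunConfig, run_all

bundle = generate_study(default_config(seed=1))   # 60-MAG vs 15-MAG archetypes
results = run_all(bundle, RunConfig(seed=1, outdir="out"))
print(results["tables"]["permanova"])
```

```
   species     component   pseudo_F        R2  p_value  n_permutations
0  highdiv       neutral   0.554503  0.038764    0.166             999
1  highdiv  phylogenetic   0.789033  0.054270    0.130             999
2  highdiv    functional   0.517171  0.036249    0.209             999
3   lowdiv       neutral  60.886423  0.815774    0.001             999
4   lowdiv  phylogenetic  87.859849  0.864678    0.001             999
5   lowdiv    functional  65.612206  0.826744    0.001             999
```

The low-richness species, whose dominant responder genome blooms under
heat and collapses under cold, shows treatment R² around 0.82–0.86 —
more than an order of magnitude above the high-richness species
(0.04–0.05), whose individuals drift incoherently. `out/summary.txt`
additionally reports the per-species mean consecutive turnover (e.g.
0.173 vs 0.043 for the neutral component) and the CWM shifts flagged at
the heat→cold transition, which include all three functions enriched in
the responder genome with negative direction.

The same stages are available from the shell:

```sh
magdyn simulate --seed 1 --outdir study
magdyn run --indir study --seed 1 --outdir out
```

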