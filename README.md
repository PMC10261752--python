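# symbionet

Bipartite network analysis of host tissue microbiomes: how environmental
bacteria assemble into the tissue-specific microbiomes of a mosquito host.

Adult mosquitoes acquire most of their bacterial symbionts from the
substrates they contact over their life cycle — standing water, soil, and
plant nectar — and these bacteria then sort among internal tissues (crop,
midgut, Malpighian tubules, ovaries). `symbionet` implements the
ecological-network toolkit used to test this assembly model on 16S ASV
count tables:

* **Nestedness temperature** (Atmar–Patterson style, 0 = perfectly nested,
  100 = random) of packed presence/absence matrices, testing whether
  low-diversity tissue communities are taxonomic subsets of high-diversity
  environmental communities, against connectance-preserving (`vaznull`)
  null matrices;
* **Weighted bipartite modularity** `Q = Σ_ij (A_ij/F − r_i c_j/F²)·δ(m_i, m_j)`
  maximized by simulated annealing (QuanBiMo-style), with an exact
  enumeration oracle for small networks and a vaznull z-test;
* **Network-wide specialization H2′** — the two-dimensional Shannon entropy
  of interaction proportions standardized between the minimum- and
  maximum-entropy integer tables sharing the observed margins
  (0 = generalized, 1 = specialized), tested against fixed-margin
  (Patefield) nulls;
* **Tissue-grouping inference**: every set partition of the four tissues
  (14 models plus an intercept-only null) is fit as a zero-inflated
  negative-binomial mixed model — taxon random intercepts, taxon-by-group
  random interactions, per-taxon random zero-inflation — by a per-taxon
  Laplace approximation, and ranked by AICc with Akaike weights, evidence
  ratios and likelihood-ratio tests;
* **Supporting stages**: ASV-table filtering (control-taxon removal,
  singleton and 5%-prevalence filters, *Wolbachia* exclusion), rarefaction,
  Gini–Simpson diversity and richness, taxon co-occurrence (sharing)
  tables, Bray–Curtis NMDS ordination;
* **A synthetic-data generator** that emulates the field design (20 sites,
  4 pooled tissue samples per site, triplicate environmental samples of 3
  substrates) with planted tissue modules, vertically transmitted
  *Wolbachia*-like taxa, and zero inflation, so every stage is testable
  end-to-end without sequence data.

## Worked example

```python
from symbionet import (PipelineConfig, run_all, scenario_paper_like)

bundle = scenario_paper_like(seed=1)          # 1002 taxa x 260 samples
config = PipelineConfig(n_null_nestedness=200, n_null_h2=200,
                        n_null_modularity=50, anneal_steps=5000,
                        anneal_restarts=3, seed=1)
report = run_all(bundle.counts, bundle.metadata, bundle.taxonomy, config)

for name, r in report["nestedness"].items():
    print(f"{name:14s} T = {r['temperature']:5.1f}  p = {r['p']:.3f}")
print("Q  =", round(report["modularity"]["Q"], 3),
      " p =", round(report["modularity"]["p"], 3),
      " modules:", report["modularity"]["modules"]["columns"])
print("H2' =", round(report["specialization"]["H2prime"], 3),
      " p =", round(report["specialization"]["p"], 3))
print("top grouping model:", report["grouping_models"]["ranking"][0]["model"])
```

prints (seed 1):

```
env_unmerged   T =  35.5  p = 0.005
env_merged     T =  31.8  p = 0.005
tissues_only   T =  43.1  p = 0.990
Q  = 0.488  p = 0.02  modules: {'crop': 2, 'midgut': 2, 'malpighian_tubule': 1, 'ovary': 1}
H2' = 0.497  p = 0.005
top grouping model: cg-mo
```

Read: tissue communities are significantly nested within the environmental
source pools (temperatures well below the null expectation) but show no
nestedness among themselves; instead the tissue network is modular — crop
and midgut form one module, Malpighian tubules and ovaries the other — and
significantly specialized, and the AICc ranking of all tissue groupings
selects exactly that two-module partition (the generator's planted truth).

A command-line interface mirrors the library
(`symbionet simulate | filter | rarefy | nestedness | modularity | h2 |
glmm | nmds | sharing | run-all`).

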