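# mtpopgen

A mitochondrial phylogeography toolkit for haploid, non-recombining
sequence data sampled across localities — the analysis stack used to ask
whether populations of a marine species are connected or structured, and
whether they carry the genetic signature of a past demographic expansion.

Given aligned mtDNA sequences (e.g. COI and/or 16S fragments) and a table
mapping individuals to sampling localities, `mtpopgen` computes:

* **Diversity** — polymorphic sites *S*, haplotypes *H*, Nei's haplotype
  diversity *h*, nucleotide diversity *π*, mean pairwise differences *d*,
  per locality and pooled.
* **Structure** — Tamura–Nei (gamma-corrected) distances, pairwise Φ_ST
  between localities and hierarchical AMOVA (Φ_ST, Φ_SC, Φ_CT) under
  arbitrary grouping schemes, with permutation p-values
  (p = (b+1)/(B+1), B = 10,000 by default) and Benjamini–Hochberg FDR
  correction.
* **Haplotype networks** — median-joining networks with median vectors
  ("mv" nodes) and the inverse-origin weighting rule: a site mutating once
  keeps weight 90, a site mutating on r edges gets 90/r, and the network is
  rebuilt under the new weights.
* **Historical demography** — observed mismatch distributions, least-squares
  fits of the sudden-expansion model (τ, θ₀, θ₁), parametric-bootstrap SSD
  goodness-of-fit tests and 95% τ confidence intervals, Tajima's *D* and
  Fu's *F*s with coalescent-simulation significance, and expansion dating
  via t = τ/2u with u = µs.
* **Haplogroups** — Dirichlet-multinomial model-based clustering of
  haplotypes with per-locality haplogroup frequency tables.
* **Synthetic data** — an msprime-backed structured-coalescent generator
  (island migration, optional sudden expansion, finite-sites mutation) so
  every stage can be validated against known truth.

The key identities the package is built around:

```
h  = n/(n−1) · (1 − Σ pᵢ²)                      π = d / L
Φ_CT = σ²ₐ/σ²_T    Φ_SC = σ²_b/(σ²_b+σ²_c)     Φ_ST = (σ²ₐ+σ²_b)/σ²_T
(1 − Φ_ST) = (1 − Φ_CT)(1 − Φ_SC)
F̂(i,θ) = θ^i/(1+θ)^(i+1)                        t = τ / 2u,  u = µs
```

See `docs/methods.md` for the models, conventions, and limitations.

## Worked example

Simulate a two-deme island model at migration 2Nm = 1 and measure its
differentiation — coalescent theory predicts Φ_ST ≈ 1/(1+2Nm) = 0.5:

```python
from mtpopgen import (SimConfig, simulate_coalescent, SubstitutionModelConfig,
                      pairwise_distance_matrix, amova, diversity_summary)

ds = simulate_coalescent(SimConfig(demes=2, sample_sizes=20, theta=5,
                                   migration=1.0, sequence_length=1000, seed=42))
dm = pairwise_distance_matrix(ds.alignment, SubstitutionModelConfig(model="p-distance"))
res = amova(dm, ds.popmap, n_perm=1000, seed=1)
print(f"Phi_ST = {res.phi_st:.3f}  (p = {res.p_phi_st:.4f})")
print(diversity_summary(ds.alignment, ds.popmap).round(3).to_string(index=False))
```

```
Phi_ST = 0.451  (p = 0.0010)
locality  N  S  H     h    pi      d
      D1 20 24  9 0.874 0.009  8.926
      D2 20 19  8 0.853 0.005  5.184
   total 40 42 17 0.933 0.010 10.031
```

The single-replicate Φ_ST of 0.451 sits near the theoretical 0.5 (across
many replicates the pooled estimate converges to it; see the test suite),
and the permutation test at B = 1000 flags the structure as significant at
the smallest attainable p = 1/1001. The pooled *d* ≈ 10.0 exceeds the
within-deme values because between-deme pairs carry the extra divergence —
the same signal Φ_ST summarises.

The same analyses run from the shell:

```bash
mtpopgen simulate --demes 2 --sample-size 20 --theta 5 --migration 1 \
    --length 1000 --seed 42 --out data/
mtpopgen diversity --fasta data/alignment.fasta --popmap data/popmap.tsv --out div.csv
mtpopgen analyze --config run.yaml     # full pipeline with manifest
```

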