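# sispec

Inference of mutational bias and a GC-favoring fixation force at
*Drosophila* short-intron sites.

## The problem

The 8–30 bp region of introns shorter than 66 bp ("SI sites") is widely used
as a neutral reference in *Drosophila* population genetics. If these sites
really are neutral, their evolution is shaped only by mutation and drift — so
any systematic departure reveals a nonselective directional force, the prime
candidate being GC-biased gene conversion (gBGC), a recombination-associated
transmission bias favoring G/C over A/T alleles that mimics semidominant
selection of scaled strength γ = 4·N<sub>e</sub>·s.

`sispec` implements the two complementary inferences, for users analyzing
polymorphism samples plus multi-species alignments at SI sites:

**Polymorphism side.** Segregating sites are polarized with two outgroups
(est-sfs-style joint ML of per-branch Kimura 2-parameter distances and a free
unfolded-spectrum prior) and sorted into three mutation classes: S>W (G/C →
A/T), W>S and GC-conservative. Under the Poisson random field for a
semidominant force, the expected unfolded SFS of a favored class is

    E[ξ_j] = θ C(n,j) ∫₀¹ (1−e^{−γ(1−x)}) / ((1−e^{−γ}) x(1−x)) · x^j (1−x)^{n−j} dx,

which reduces to θ/j when γ = 0. Nested Poisson models — M0 (γ = 0), M1
(γ free), and starred variants adding a polarization-error probability ε —
share per-frequency demographic distortion nuisances r_j (r₁ ≡ 1) across
classes and are compared by likelihood-ratio tests. The mutational bias is
the derived quantity κ = (θ_SW/L_S)/(θ_WS/L_W), the ratio of per-site S→W
and W→S mutational inputs.

**Divergence side.** On the rooted tree ((ingroup1, ingroup2), outgroup), a
nonstationary GTR model (shared exchangeabilities, free root and per-branch
target compositions) is fitted to site-pattern counts, and the expected
numbers of labelled S>W / W>S / conservative substitutions per lineage are
obtained by expected Markov counting — the closed-form expectation of
labelled events conditional on branch endpoints, averaged over the posterior
of ancestral states, never a single best reconstruction. The rate ratio
R = r_S>W / r_W>S equals κ under neutrality and κ·e^{−γ} under a directional
force; equilibrium GC content is GC* = 1/(1 + κ·e^{−γ}).

Introns are binned into GC quintiles (by one species' GC or the two-species
mean), every statistic is computed per bin, and confidence intervals come
from resampling introns with replacement.

A first-class synthetic-data module generates all inputs (genomes + GFF3,
WGA columns, haplotype samples) with planted γ, κ, demography distortion and
per-branch truth tables, so the whole chain is testable with no downloads;
a forward Wright–Fisher simulator serves as an independent oracle for the
diffusion expectation.

## Worked example

Simulate a dataset with a planted GC-favoring force (γ = 1.5, κ = 3,
n = 21 haplotypes, 600 introns) and run the full pipeline:

```bash
sispec simulate --out demo --n-introns 600 --gamma 1.5 --kappa 3 --seed 2
cat > demo/pipeline.yaml <<EOF
gff_a: demo/annotation_A.gff3
fasta_a: demo/genome_A.fa
gff_b: demo/annotation_B.gff3
fasta_b: demo/genome_B.fa
wga: demo/alignment.wga.bed
haplotypes_a: demo/haplotypes_A.fa
outdir: demo/out
seed: 1
polarize_restarts: 2
fit_restarts: 2
divergence_runs: 2
EOF
sispec run --config demo/pipeline.yaml
```

Summarizing `demo/out/summary.json` per GC bin:

```
bin  n_introns  gc_range       gamma_hat  kappa_hat   DAF(W>S)  DAF(S>W)     R
  1        120  0.000-0.217       1.57       2.72      0.310      0.227   1.27
  2        120  0.217-0.304       1.08       2.97      0.263      0.200   0.99
  3        120  0.304-0.391       1.18       2.77      0.298      0.228   0.71
  4        120  0.391-0.478       1.39       2.89      0.292      0.219   0.52
  5        120  0.478-0.783       1.41       2.48      0.295      0.218   0.37
```

What this shows: γ̂ scatters
around the planted 1.5 and κ̂ around the planted 3 in every bin; the mean
derived allele frequency of W>S mutations exceeds that of S>W mutations —
the diagnostic signature of a GC-favoring force; and R falls with GC content
because high-GC strata offer more S sites to lose and fewer W sites to gain.
`demo/out/per_bin.tsv` holds the same numbers in tabular form, keyed by bin,
strategy and population, and `per_bin.png` / `gamma_kappa.png` plot them.

The library surface mirrors the pipeline: `expected_sfs`, `fit_model`,
`likelihood_ratio_test` (SFS models); `fit_outgroup_model`, `polarize`,
`build_class_sfs` (polarization); `fit_nonstationary`,
`expected_substitution_counts`, `equilibrium_chi2` (divergence);
`gc_equilibrium`, `substitution_ratio_R`, `required_kappa`,
`solve_gamma_for_gc` (equilibrium algebra); `assign_bins`, `bootstrap_ci`;
`diversity_summary`, `mean_daf`, `predict_relative_diversity`.

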