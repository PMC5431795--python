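# Methods

## Problem setting

Given a list of candidate coding indels for one query disease, the package
assigns each candidate a single integrated p-value measuring the statistical
strength of it causing the disease, and ranks candidates ascending by that
value. Evidence comes from up to K = 10 channels per indel: five functional
predictor scores (SIFT, PinPor, CADD, DDIG, VEST), the gene-level
intolerance score RVIS, and four disease–gene association channels computed
in-package (`gexp`, `gobp`, `strg`, `tsfc`). Any subset may be missing.
Indels are classified into four subtypes by allele lengths — deletion if
len(REF) > len(ALT), frameshift if the length change is not a multiple of
3 — giving ND/NI/FD/FI; benchmark control sets are stratified by subtype.

## Empirical null transform

Every raw score is converted to a p-value against an empirical null
collection for its source:

    p = (#{i : s_i ⪰ s} + 1) / (N + 1)

with ⪰ equal to ≥ for sources where larger scores are more damaging (CADD,
DDIG, VEST, and the association scores) and ≤ where smaller scores are more
damaging (SIFT, PinPor, RVIS). Ties count as "at least as extreme". The
add-one pseudo-count bounds p in [1/(N+1), 1]: a strictly positive floor is
required because the integration stage takes log p. Consequences worth
knowing: p-values are granular at resolution 1/(N+1), and querying the null
against itself yields a discrete-uniform p distribution (the calibration
property the tests check). The null cohorts themselves are inputs — one
single-column TSV per source with a damaging-direction header — because the
appropriate reference population is a study-design choice, not something the
package can infer.

## Similarity networks

**Disease layer.** Each disease is a concept vector over phenotype terms
with entry −log h_i for annotated concept i, 0 otherwise, where h_i is the
concept's corpus frequency. When frequencies are not supplied they are
estimated from the annotation table with an add-one denominator,
h_i = (#diseases with concept i)/(n+1), so that even a ubiquitous concept
retains a small positive weight (−log of exactly 1 would erase it; supplied
frequencies are clamped away from 0 and 1 for the same reason). Pairwise
cosine similarity is sparsified to each disease's 10 nearest neighbours.

**Gene layers.** Four kinds, all sparsified to 100 nearest neighbours after
the exponential kernel φ(w) = exp(−((1−w)/σ)²), σ the standard deviation of
the off-diagonal raw similarities of that network:

* `gexp` — Pearson correlation of expression profiles across tissues;
* `gobp` — cosine similarity of binary ontology-term membership vectors;
* `strg` — shortest-path similarity on the PPI graph, w = 1 − δ/max δ with
  max δ over connected pairs and w = 0 for disconnected pairs (the rescaling
  is undefined at infinite distance);
* `tsfc` — cosine similarity of TF binding-site count vectors.

Numerical choices: the kernel is applied to negative Pearson correlations
unclipped (they map to small positive weights, preserving the neighbour
ranking); genes with empty feature vectors are kept as isolated nodes rather
than acquiring the spurious φ(0) > 0 kernel floor; k-NN selection keeps all
edges tied at the k-th position (deterministic, order-independent) and
symmetrizes by union so that no node that had a positive similarity is
disconnected — reachability matters for the random walk. The kernel is
applied to the gene networks only; the disease network keeps raw cosine
weights.

## Random walk with restart on the two-layer network

The heterogeneous network is H = (D, G, A) with m diseases, n genes and
binary associations A. Row-normalizing D, G, A, Aᵀ gives U, V, R, S
(all-zero rows stay zero), composed with layer-switch probability τ into

    T = [[(1−τ)U, τR], [τS, (1−τ)V]]

and row-normalized again into W. A disease with no known gene therefore
redistributes its switch mass within the disease block; a fully isolated
node gets a unit self-loop so that the restart term alone governs it. The
walk iterates

    p(t+1) = (1−π) Wᵀ p(t) + π p(0)

until ‖p(t+1) − p(t)‖₂² < ε. The update is the standard restart-walk form:
it is the unique reading that both uses the network and conserves
probability mass, which the implementation asserts at convergence. The
start vector puts uniform mass on the query disease's direct neighbours in
D (the query itself excluded) and zero on all genes — the genetic basis is
treated as unknown. Defaults τ = 0.5, π = 0.5, ε = 10⁻⁴ follow the
established restart-walk literature for disease-gene inference; exact
agreement with the direct solve π(I − (1−π)Wᵀ)⁻¹p(0) is verified in the
tests with a much smaller ε.

The steady-state gene probability v(∞)_g is the association score of
(query, g). Its p-value is empirical against the null of steady-state
scores of **non-associated** pairs, built separately per gene-network kind
(score scales differ across kinds): all pairs when m·n ≤ 10⁶, otherwise a
seeded sample of 10⁵. When the query pair is itself a known association the
corresponding A entry is zeroed and only the two affected transition rows
are renormalized before a dedicated walk — leave-one-out prevents the known
link from trivially inflating the score. One cached walk per query disease
serves all other genes.

## Integrating the p-values

Fisher's statistic over the K_eff present sources is U = Σ −2 log p_i.
Under independence U ~ χ²(2K_eff); correlated sources inflate its variance,
so U is referred to a scaled chi-squared fitted by moment matching:

    E[U] = 2 K_eff,
    Var[U] = Σ_i Var(V_i) + 2 Σ_{i<j} cov(V_i, V_j),   Var(V_i) = 4,
    ν = 2 E[U]² / Var[U],   c = Var[U] / (2 E[U]),   U/c ~ χ²_ν.

Covariances use the quartic approximation in the adjusted probit
correlation, cov ≈ a₁ρ̃ + a₂ρ̃² + a₃ρ̃³ + a₄ρ̃⁴ with a₁ = 3.263119,
a₂ = 0.709866, a₃ = 0.026589, a₄ = −0.709866/n; ρ̂ is the pairwise-complete
correlation of Z = Φ⁻¹(1−p) across the candidate set of the current run, n
the pairwise-complete sample size, and ρ̃ = ρ̂(1 + (1−ρ̂²)/(2n−1)) its
small-sample adjustment. Pairs sharing fewer than 3 observations get
covariance 0 with a warning. Negative fitted covariances are kept, but
Var[U] is floored at 10% of its independence value so ν stays finite. Under
zero correlation the fit reduces exactly (to 10⁻¹² in the tests) to
textbook Fisher, and a single present source returns its own p-value. A
config flag exposes a literal variant of the moment equations
(η = Σcov/K, ν = 2K/η) for comparison; it is not the default because it
does not recover plain Fisher under independence.

Alternatives, all dropping missing sources and using K_eff:

* **minP** — the minimum p-value, Šidák-corrected by default
  (1 − (1−p_min)^K_eff) so the result is itself a valid p-value; the raw
  minimum (available via `correct=False`) induces the identical ranking but
  is anti-conservative as a p-value, which matters for the calibration
  guarantees below.
* **Stouffer** — Z = Σ Φ⁻¹(1−p_i)/√K_eff, p = 1 − Φ(Z), with p clamped to
  [10⁻¹⁵, 1−10⁻¹⁵] before the probit.
* **RRA** — for sorted p_(1) ≤ … ≤ p_(K), β_m = P(Binomial(K, p_(m)) ≥ m)
  (the exact binomial tail), combined as min(K · min_m β_m, 1).

## Ranking and evaluation

Candidates sort ascending by integrated p; ties break deterministically by
(more present sources first, then input order); candidates with no usable
source at all form a trailing block. Evaluation metrics use the worst rank
within a tie block — a conservative choice — and an all-missing causal indel
is charged the last position. Spike-in experiments insert one causal indel
into a same-subtype control set; MRR is the mean of rank/M over causal
indels (random ranking gives 50%), TOP counts causal indels at rank ≤ 20,
and the rank ROC thresholds rank ratios inclusively (TPR over causal
indels, FPR over the co-ranked neutral ones; AUC by trapezoid).

## Synthetic data: what it does and does not emulate

The generator plants exactly the structure the method assumes: modular
disease and gene similarity in every feature layer, associations linking
matched modules, equicorrelated raw scores through a Gaussian copula (the
dependence-correction model is itself probit-based, so the fixture
exercises the assumed dependence structure), causal score shifts of
`effect_size` standard deviations in each source's damaging direction,
per-source missingness, and frameshift enrichment among causal indels.
Defaults: 50 diseases, 200 genes, 5 modules, 20 causal and 200 neutral
indels (neutral split evenly across subtypes), effect size 3 SD,
source correlation 0.3, missing rate 0.1 per source, null tables of 1000
scores. These sizes keep the full pipeline at a few seconds on one CPU
while leaving ~50 same-subtype controls per spike-in.

What passing on this fixture shows: correct plumbing end to end, calibrated
p-values under the assumed null, dependence correction behaving as designed,
and recovery of planted signal at realistic effect sizes. What it does not
show: performance on real predictor scores (whose score distributions are
neither Gaussian nor equicorrelated), real phenotype ontologies with
hierarchical term dependence, literature-biased association catalogues, or
variant-calling artefacts. Absolute MRR/TOP values on real cohorts are
expected to differ.

## Known limitations

* Coding indels with a host gene only; intergenic candidates are rejected
  at input validation, and genotype quality is ignored.
* The dependence model is estimated on the candidate set of the current
  run; very small candidate sets (< ~10 indels) make ρ̂ noisy, and the
  pipeline falls back to plain Fisher below 3 candidates.
* Empirical p-values are bounded below by 1/(N+1); small null tables limit
  the achievable significance and hence the resolution at the top of the
  ranking.
* One query disease per run; multi-disease queries and alternative
  propagation schemes (heat diffusion, personalized PageRank variants) are
  out of scope.
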