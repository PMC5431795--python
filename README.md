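# indelrank

Phenotype-aware prioritization of disease-causing coding indels.

Exome studies of inherited disease routinely leave tens to hundreds of
candidate micro-insertions/deletions after variant calling and frequency
filtering. `indelrank` ranks such candidates for a **query disease** by fusing
ten heterogeneous evidence channels into a single p-value per indel:

* **five functional prediction scores** (SIFT, PinPor, CADD, DDIG, VEST),
  consumed as pre-computed inputs;
* **four genic association scores** (`gexp`, `gobp`, `strg`, `tsfc`), computed
  in-package by a random walk with restart on a two-layered disease–gene
  network built from phenotype annotations, co-expression, ontology
  annotations, protein–protein interactions and transcription-factor binding
  profiles;
* **one genic intolerance score** (RVIS).

## Method in brief

1. **Empirical p-values.** Each raw score *s* is compared against an
   empirical null collection {s₁,…,s_N} for its source:
   p = (#{i : sᵢ ⪰ s} + 1)/(N + 1), where ⪰ is ≥ or ≤ depending on the
   source's damaging direction. The add-one correction keeps log p finite.
2. **Disease–gene association.** A heterogeneous network H = (D, G, A)
   couples a 10-NN disease similarity network (cosine over −log-frequency
   phenotype-concept vectors) with a 100-NN gene network (Pearson/cosine/
   shortest-path similarity passed through the kernel
   φ = exp(−((1−w)/σ)²)) via known association links A. The row-normalized
   two-layer transition matrix W (layer-switch probability τ) drives
   p⁽ᵗ⁺¹⁾ = (1−π) Wᵀ p⁽ᵗ⁾ + π p⁽⁰⁾ from the query disease's neighbourhood to a
   stationary vector; the gene block v⁽∞⁾ is the association score, referred
   to the empirical null of non-associated pairs (known links are removed
   leave-one-out before scoring). Defaults: τ = 0.5, π = 0.5, ε = 10⁻⁴.
3. **Integration.** The statistic U = Σᵢ −2 log pᵢ over the K ≤ 10 present
   sources is referred to a scaled χ² null fitted by moment matching with the
   Brown/Kost covariance approximation
   cov(Vᵢ,Vⱼ) ≈ a₁ρ̃ + a₂ρ̃² + a₃ρ̃³ + a₄ρ̃⁴ estimated from probit-transformed
   p-values across the candidate set. Missing sources reduce the degrees of
   freedom. minP (Šidák-corrected), Stouffer's Z and robust rank aggregation
   are available as alternatives.
4. **Evaluation.** A spike-in harness inserts each causal indel into a
   same-subtype control set and reports MRR (mean rank ratio), TOP (causal
   indels in the top 20) and rank-ROC/AUC.

A fully tested synthetic-data module generates modular disease/gene worlds
with planted associations and block-correlated indel scores, so the whole
pipeline runs and is validated without any external database.

## Worked example

```python
from indelrank.synthetic import (SyntheticConfig, generate_world, generate_indels,
                                 world_networks, association_scorers)
from indelrank.prioritize import prioritize
from indelrank.evaluation import run_spike_in_grouped

cfg = SyntheticConfig(seed=1)                       # 50 diseases, 200 genes, 5 modules
world = generate_world(cfg)
indels = generate_indels(cfg, world)                # 20 causal + 200 neutral indels
disease_net, gene_nets = world_networks(world)
scorers = association_scorers(world, disease_net, gene_nets, seed=1)

causal = indels.causal[0]
disease = indels.disease_map[causal.label]
result = prioritize(indels.neutral[:50] + [causal], disease, indels.nulls, scorers)
print(result.table[["CHROM", "POS", "GENE", "SUBTYPE",
                    "integrated_p", "rank", "rank_ratio"]].head(3).to_string(index=False))

res = run_spike_in_grouped(indels.causal, indels.neutral,
                           indels.disease_map, indels.nulls, scorers)
s = res.summary(k=20)
print(f"MRR = {100*s['MRR']:.2f}%  TOP20 = {int(s['TOP'])}/{int(s['n_causal'])}")
```

prints

```
CHROM  POS  GENE SUBTYPE  integrated_p  rank  rank_ratio
    1 1000 G0134      NI      0.000415     1    0.019608
    1 3150 G0114      FI      0.026419     2    0.039216
    1 3750 G0009      FI      0.045852     3    0.058824
MRR = 1.96%  TOP20 = 20/20
```

The planted causal indel (hosted in gene G0134, a member of the query
disease's module, with 3-SD-shifted functional scores) ranks first out of 51
candidates; over all 20 spike-ins the mean rank ratio is 1.96% — against the
50% expected from random ranking — and every causal indel lands in the top
20.

The same pipeline is scriptable from a shell:

```bash
indelrank simulate -c cfg.yaml -o fixture/
indelrank build-networks -c cfg.yaml -i fixture/ -o networks/
indelrank prioritize -c cfg.yaml -i fixture/ --networks networks/ \
    --indels fixture/neutral_indels.tsv --disease D0009 -o ranking.tsv
indelrank evaluate -c cfg.yaml -i fixture/ --networks networks/ -o metrics.json
```

All inputs and outputs are plain TSV/JSON with `#` comment headers; candidate
indels can also be read from a VCF with an INFO-tag mapping.

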