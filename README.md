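# dtifuse

Drug–target interaction (DTI) prediction from fused heterogeneous features.

Most approved drugs act on a handful of protein targets, and most
drug–protein pairs have never been assayed. `dtifuse` is a pipeline for
prioritising which untested pairs are worth assaying: it treats the known
interactions as a bipartite network and learns, for every drug and every
protein, a compact descriptor that blends three complementary views:

1. **Interaction-profile similarity.** Each drug's profile is its row of the
   binary interaction matrix A (each target's, its column). The Gaussian
   interaction profile (GIP) kernel scores two profiles as
   `S(i,j) = exp(-τ ||V_i − V_j||²)`, with the bandwidth normalized by the
   mean squared profile norm: `τ = τ′ / ((1/n) Σ_i ||V_i||²)`.
2. **Attributes.** Proteins are represented by k-mer composition vectors
   (overlapping length-k substrings over the 20-letter amino-acid alphabet,
   20^k dimensions, length-normalized); drugs by Morgan/ECFP circular
   fingerprints folded to a fixed bit length (precomputed binary
   fingerprints are also accepted, bypassing the chemistry backend).
3. **Network topology.** A joint Graph Factorization (GF) embedding of the
   bipartite graph minimizes
   `ε = ½ Σ_{(i,j)∈E} (P_ij − ⟨Q_i,Q_j⟩)² + (λ/2) Σ_i ||Q_i||²`
   by full-batch gradient descent, giving one low-dimensional vector per
   node.

Per side, a stacked autoencoder (affine + ReLU layers, trained by greedy
layer-wise pretraining then joint fine-tuning on mean squared reconstruction
error) compresses the `[GIP row | attribute vector]` block to a bottleneck
code; the fused descriptor is `[code | GF embedding row]`. A drug–protein
pair is the concatenation of the two fused descriptors, classified by a 1-D
convolutional network (convolution → ReLU → max-pool → dense → softmax)
trained with cross-entropy. Everything is plain numpy with hand-written
backprop, deterministic given a seed.

The package also ships a synthetic benchmark generator that plants a
latent-factor structure (clustered drug/target factors; interaction
probability `sigmoid(a·U_i·V_j + b)` with the offset calibrated to a target
density; attributes informative of the clusters), so the full pipeline is
exercisable and measurable offline, plus leakage-safe five-fold
cross-validation, candidate ranking, and a 60/30/10 %-weighted neighbor
construction for cold-start entities.

## Worked example

```bash
# 1. generate a synthetic benchmark: 100 drugs x 80 targets, 5% density
dtifuse simulate --out bench --seed 7 --n-drugs 100 --n-targets 80 \
    --density 0.05 --label-noise 0.0

# 2. leakage-safe five-fold cross-validation
dtifuse cv --edges bench/edges.tsv --fasta bench/proteins.fasta \
    --drugs bench/drugs.tsv --out bench/cv --seed 7

# 3. rank unknown pairs
dtifuse predict --edges bench/edges.tsv --fasta bench/proteins.fasta \
    --drugs bench/drugs.tsv --out bench/pred --seed 7 --top-n 20
```

The `cv` step logs a line like

```
cv: mean AUC 0.8771 in 74.1s
```

and writes `cv_report.json` with per-fold and mean AUC / AUPR / accuracy /
precision / recall / F1. On this noise-free benchmark the mean AUC is 0.88
(AUPR 0.85, accuracy 0.80):
the pipeline recovers most of the planted latent structure from the masked
network plus attributes (held-out edges are zeroed before any feature is
computed, so nothing leaks). `predictions.csv` lists the top-scoring unknown
pairs with columns `drug_id,protein_id,score,rank`; the score is the
softmax probability of the interaction class, and known interactions never
appear.

With `--label-noise 0.05` (every matrix entry flipped independently with
probability 0.05) the same run yields mean AUC 0.66 against 0.51 for a
label-shuffled null. That drop is a property of the noise model, not the
method: at 5 % density a 5 % symmetric flip rate makes about half of all
positive labels pure noise, which caps the attainable AUC near 0.75 for any
scorer — see `docs/methods.md` for the argument.

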