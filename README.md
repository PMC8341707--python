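# elate

**Encoder-based local T-cell receptor density.**

`elate` turns the clones of a T-cell receptor (TCR) repertoire — CDR3
amino-acid sequence, optionally V gene and clone size — into 30-dimensional
real vectors with an autoencoder, and builds repertoire analyses on that
projection: local clone density by kernel density estimation (KDE),
sample-by-sample similarity and hierarchical clustering, descriptive
statistics (publicity, radius, residue-content density), and one-vs-all
clone classification. It is written for immunologists and computational
biologists who work with rep-seq clone tables and want a single real-valued
representation that unifies sequence, V usage and clone size.

## The method

Each clone is one-hot encoded: every CDR3 position is a 21-block (20 amino
acids + a stop symbol), the sequence is terminated by a stop block and
right zero-padded to the corpus maximum length m, and the V gene is an
optional one-hot block, giving n = 21·(m+1) + n_V dimensions. A symmetric
autoencoder (encoder 300 → 100 → 30, Elu, dropout 0.1; decoder mirrored
with a per-block softmax) is trained with MSE loss (Adam, lr 1e-4). The
family has four flavors: **E** (basic), **VE** (+V gene), **EM** and
**VEM**, which add a distance-maintenance loss

    loss_dis = Σ_{i<j} ( ‖z_i − z_j‖ − D_ij )²

pulling Euclidean distances between embeddings z toward the distances D
between the one-hot inputs, so that the projection supports geometric
analyses. On the embeddings, the density of a clone x against a reference
sample {y_i} is the Gaussian KDE

    f_h(x) = 1/(R·h) Σ_i w_i K((x − y_i)/h),   h = 1.06·STD(S)·|S|^(−1/5),

optionally weighted by clone sizes w_i. Cross-densities averaged over a
constant-size subsample define a directional sample similarity; KL
divergence of V usage and mean nearest-neighbour Levenshtein distance are
provided as baselines. A four-layer head (30/15/10/1, Tanh + sigmoid) on
the frozen encoder classifies single clones one-vs-all.

A synthetic-repertoire generator (V/D/J-mosaic CDR3s, rank-biased V usage,
power-law clone sizes, host-shared public pools, motif-defined specificity
classes) makes every analysis testable without any external dataset.

## Worked example

```python
from elate import (AEConfig, GeneratorConfig, build_scheme, generate_repertoire,
                   train, embed, reconstruction_accuracy, distance_correlation,
                   kde_similarity_matrix, hierarchical_cluster, cluster_entropy)

samples = generate_repertoire(GeneratorConfig(n_samples=4, clones_per_sample=500, seed=7))
scheme = build_scheme(samples)

model = train(samples, scheme, AEConfig.for_model("EM", epochs=60, seed=0))
print("held-out style 2-mismatch accuracy:",
      round(reconstruction_accuracy(model, samples[0].clones[:200], k=2), 3))
rho, p = distance_correlation(model, samples[0].clones[:150])
print("distance correlation rho:", round(rho, 3))

m = kde_similarity_matrix(samples, model, r=100, seed=0)
labels = {s.sample_id: s.category for s in samples}
per_label, mean_entropy = cluster_entropy(hierarchical_cluster(m, k=2), labels)
print("host entropies:", per_label, "mean:", round(mean_entropy, 3))
```

Output:

```
held-out style 2-mismatch accuracy: 0.37
distance correlation rho: 0.795
host entropies: {'host0': 0.0, 'host1': 0.0} mean: 0.0
```

After only 60 epochs the distance-regularized model already embeds clones
with a strong rank correlation (0.80) between one-hot and embedded
distances — reconstruction is still rough at this budget, which is the
expected trade-off of the distance-maintaining flavor — and the KDE
similarity matrix clusters the four samples perfectly into their two host
groups (entropy 0 for both hosts).

The same pipeline is available from the shell:

```
elate simulate --seed 1 --out sim/
elate train --model EM --epochs 60 --seed 0 --out model/ \
      --input sim/host0_s0.tsv --input sim/host0_s1.tsv \
      --input sim/host1_s0.tsv --input sim/host1_s1.tsv
elate embed --model-dir model/ --input sim/host0_s0.tsv --out emb.tsv
elate compare --model-dir model/ --method kde --out matrix.tsv \
      --inputs sim/host0_s0.tsv --inputs sim/host0_s1.tsv \
      --inputs sim/host1_s0.tsv --inputs sim/host1_s1.tsv
elate cluster --matrix matrix.tsv --k 2 --out clusters.tsv
```

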