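# phenotrace

Unsupervised phenotyping of single-cell, multi-channel fluorescence time
series from impacted articular cartilage.

After a mechanical impact, chondrocytes display a spectrum of behaviors —
viable cells with slowly decaying mitochondrial polarity, cells with elevated
or transient calcium, and several modes of death signalled by rising nuclear
membrane permeability (NMP). `phenotrace` turns per-cell three-channel traces
(calcium, TMRM mitochondrial polarity, NMP; ~3 h at ~12 s/frame, resampled to
750 points) into behavioral phenotypes and spatial/biological conclusions:

1. a **convolutional variational autoencoder** compresses each 3 × 750 trace
   into a 32-dimensional diagonal-Gaussian posterior
   q_φ(z|x) = N(μ_φ(x), σ_φ(x)), trained by minimising the negative ELBO
   −E[log p_θ(x|z)] + D_KL(q_φ(z|x) ‖ N(0, I));
2. **PCA on the latent means** with decoder traversal along each component
   (α from −3 to 3 in per-component SD units) visualises what the latent
   space encodes, and spatial maps localise it in the tissue;
3. **symmetrized Kullback–Leibler divergences**
   D_sKL = ½(KL(P‖Q) + KL(Q‖P)) between the per-cell latent Gaussians feed
   average-linkage agglomerative clustering, cut by threshold or count into
   behavioral phenotypes;
4. **hypothesis tests** connect phenotypes to biology: a PCA-derived
   sharpness score of the peracute (60 s, 40 fps) impact calcium peak tested
   against cell fate (two-sample KS), late-death timing regressed on distance
   to the impact site (F-test), and mitochondrial polarity vs distance (KS);
5. a **synthetic-data module** generates traces, impact calcium pulses,
   spatial layouts, and rendered 512×512 frames with known ground truth,
   standing in for the microscopy data; STL timescale decomposition
   quantifies reconstruction error on short and long timescales.

The VAE (encoder 3→4→8→16 stride-2 convolutions to 16×94 = 1504 features,
1504→256 trunk, twin 256→128→32 heads; mirrored decoder) is a compact NumPy
implementation with hand-written backpropagation — see `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from phenotrace.synthetic import GeneratorConfig, SIX_PHENOTYPES, generate_dataset
from phenotrace.preprocess import assemble
from phenotrace.vae import TrainConfig, train, embed
from phenotrace.cluster import pairwise, agglomerate, cut, summarize
from phenotrace.hypotheses import label_fate, sharpness_fate_test

cfg = GeneratorConfig(n_cells=600, phenotype_names=SIX_PHENOTYPES, seed=11)
ds = generate_dataset(cfg)
matrix = assemble(ds.traces, labels=ds.labels)          # (600, 3, 750)
trained = train(matrix.data, config=TrainConfig(epochs=20, seed=11))
table = embed(trained.vae, matrix.data, cell_ids=matrix.cell_ids)
assignment = cut(agglomerate(pairwise(table)), k=6)
print("cluster sizes:", assignment.counts)
print("ARI vs ground truth:",
      round(adjusted_rand_score(ds.labels, assignment.labels), 3))

fate, _ = label_fate(summarize(assignment, matrix), assignment)
dead_at_impact = fate[ds.impact_cell_ids] == "dead"
rep = sharpness_fate_test(ds.impact_calcium, dead_at_impact)
print(f"sharpness vs fate: KS D={rep.statistic:.3f}, p={rep.p_value:.2e}")
```

Output:

```
cluster sizes: {1: 12, 2: 175, 3: 175, 4: 187, 5: 31, 6: 20}
ARI vs ground truth: 1.0
sharpness vs fate: KS D=0.909, p=1.03e-07
```

The six sKL clusters recover the six generator phenotypes exactly
(adjusted Rand index 1.0), and the sharpness score of the impact calcium
peak separates the cells whose clusters show high NMP ("dead") from the
rest: dead cells carry sharp, early, fast-decaying peaks, viable cells broad
plateaus.

The same workflow is available as a CLI:

```bash
phenotrace simulate  --out-dir run --n-cells 1200 --seed 1
phenotrace preprocess --out-dir run
phenotrace train     --out-dir run --epochs 20 --seed 1
phenotrace embed     --out-dir run
phenotrace analyze   --out-dir run
phenotrace cluster   --out-dir run --k 6
phenotrace test      --out-dir run
```

Each stage records a content fingerprint of its inputs and refuses
artifacts from a different run.

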