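# gacnn

Severity grading of diabetic-retinopathy (DR) fundus photographs with a
hybrid classifier that fuses a convolutional branch and an attention
graph-convolution branch, trained semi-supervised with pseudo labels.

## Who this is for

Researchers experimenting with graph-based representations of retinal
lesions and with pseudo-label semi-supervision on small labeled budgets.
The package reads the APTOS-2019 dialect (a directory of RGB fundus
images plus a `train.csv` with columns `id_code,diagnosis`, diagnosis in
0..4) and ships a seeded synthetic-fundus generator so the entire
pipeline — preprocessing, graph construction, training, evaluation — runs
end-to-end on one CPU without any download.

## The model

**CNN branch.** A modified VGG-19: the 16 convolutional layers are kept
(blocks of 2, 2, 4, 4, 4 convolutions with 64, 128, 256, 512, 512
channels, all 3×3 stride 1), the max-pool after the last block is
removed, and the fully connected layers are replaced by a global
max-pool, so a 224×224×3 input gives a 14×14×512 final map and a
length-512 feature vector f_k. A width multiplier scales the channel
counts for desk-scale work.

**Graph branch.** A blob detector proposes candidate-lesion regions
{m, n, w, h} with centres y_i = (m + w/2, n + h/2). Nodes i, j are
connected when each is among the other's K = 8 nearest neighbours, with
Gaussian weight

    w_ij = exp(−‖y_i − y_j‖² / 2ω²),   ω = 1.6.

Stacked graph convolutions H⁽ʲ⁺¹⁾ = f(Â H⁽ʲ⁾ W_j) over the renormalised
adjacency Â = D̃^(−1/2)(A + I)D̃^(−1/2) produce per-hop node features,
aggregated with attention weights a_i on the probability simplex,
γ_v = Σ_i a_i H_v⁽ⁱ⁾, and pooled (mean‖max over nodes) into a graph
vector h_k.

**Fusion and loss.** z_k = ρ(f_k) + μ·σ(h_k) with μ = 1 by default,
followed by a 5-way classifier. Training splits the train set into a
labeled part S and an unlabeled part U by a labeling rate; U's targets
are the model's own one-hot argmax predictions (pseudo labels), refreshed
each epoch, and the objective is L = L_label + λ·L_unl with λ = 0.1,
where both terms are binary cross-entropy summed over the K classes.
Metrics are accuracy, micro/macro precision and recall, and Cohen's
kappa (p₀ − p_e)/(1 − p_e).

The tensor engine (autodiff, convolutions, SGD/Adam) is implemented in
NumPy inside the package — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from gacnn import (SyntheticSpec, generate_dataset, GraphBuildConfig,
                   build_graph, BackboneConfig, GCNConfig, FusionConfig,
                   TrainConfig, fit)

train = generate_dataset(SyntheticSpec(image_side=64, n_per_class=20, seed=1))
graphs = [build_graph(im, GraphBuildConfig(max_nodes=32)) for im in train.images]
result = fit(train, TrainConfig.desk_scale(epochs=12, seed=0, eval_every=4),
             backbone_cfg=BackboneConfig(input_side=64, width_multiplier=1/8),
             gcn_cfg=GCNConfig(hidden=16), fusion_cfg=FusionConfig(fused_dim=64),
             graphs=graphs)
print(result.history[["epoch", "train_loss", "train_accuracy"]].dropna())
```

prints (examples/04_train_desk_scale.py)

```
 epoch    lr  train_loss  train_accuracy  train_kappa
     4 0.001    2.684267            0.41       0.2625
     8 0.001    2.113929            0.48       0.3500
    12 0.001    1.795515            0.56       0.4500
```

— the loss falls and train accuracy climbs from chance (0.20) to 0.56
within twelve epochs on 100 images; longer runs at 60 images/class reach
≥ 0.93 train accuracy in 30 epochs. The `examples/` directory has one
short script per capability (synthesis, preprocessing, graph building,
training, metrics); each prints what it computes and what the numbers
mean.

There is also a thin CLI mirroring the pipeline stages:

```bash
gacnn simulate --out data --n-per-class 10 --seed 1
gacnn preprocess --in data --csv data/train.csv --out prep --side 64
gacnn build-graph --in prep --out graphs --k 8 --omega 1.6 --detector log
gacnn train --data prep --csv prep/train.csv --labeling-rate 0.25 --epochs 20 --out run
gacnn evaluate --model run.npz --data prep --csv prep/train.csv --out report.csv
```

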