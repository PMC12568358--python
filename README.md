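# udrnet

Unsupervised deformable registration of 3D CT volumes with a hybrid
spatial/channel attention fusion module (scHAF) at the skip connections of a
VoxelMorph-style encoder–decoder.

## The problem

Lung CT scans of the same patient taken at different breathing phases (or on
different scanners) disagree by a large, smooth, non-rigid deformation.
Deformable registration finds, for every voxel `i` of a fixed image `I_f`, a
displacement `DVF(i)` such that the warped moving image

```
I_w(i) = I_m(i + DVF(i))
```

aligns with `I_f` (pull convention; non-integer positions are sampled by
trilinear interpolation).  Classical iterative methods solve this per pair
and are slow; a registration *network* predicts the dense displacement field
`DVF` in a single forward pass.  Because ground-truth deformation fields do
not exist for clinical data, training is **unsupervised**: the network
parameters are optimized to minimize an image-similarity loss — here
`1 − NCC(I_f, I_w)` (normalized cross-correlation) or mean squared error —
through a differentiable spatial-transformer warp.

The architecture is an encoder–decoder U-Net that takes the channel-
concatenated `(I_m, I_f)` pair and emits a 3-channel displacement field at
full resolution.  At every skip connection, the **scHAF** block filters the
shallow encoder features before fusion with the decoder:

* a 1×1×1 convolution collapses channels into one spatial attention map,
  broadcast over channels and multiplied with the features (`F_channel`);
* global max- and average-pooled per-channel vectors pass through a
  two-layer MLP (2C → C → C) to per-channel weights, broadcast over space
  and multiplied with the features (`F_space`);
* the elementwise product, sum and maximum of `F_channel` and `F_space` are
  concatenated (3C channels) and mapped back to C channels by a 3×3×3
  convolution.

Turning scHAF off yields the plain VoxelMorph-style baseline with strictly
fewer parameters — the ablation contrast.

Evaluation uses the standard registration metrics, reported on a percentage
scale: Dice overlap `2|A∩B| / (|A|+|B|)` of region masks, `1 − MSE`, and
global NCC.

Everything runs on CPU with NumPy: the network, the differentiable warp and
the training loop are built on a small reverse-mode autodiff core
(`udrnet._autodiff`, numba-accelerated convolutions), so no deep-learning
framework is required.  A synthetic generator of lung-like phantoms with
smooth ground-truth deformations makes the entire pipeline runnable and
testable with zero downloads.

## Worked example

```python
import udrnet

pairs = udrnet.make_dataset(12, base_seed=7)          # 32^3 lung-like phantoms
study = udrnet.UnsupervisedRegistration(
    pairs[:8], pairs[8:],
    network=udrnet.NetworkConfig.desk_scale(),
    train_config=udrnet.TrainConfig.desk_scale(epochs=10),
)
results = study.fit()
print(results.summary())
```

prints (about one minute on one CPU core):

```
Unsupervised deformable registration — fit summary
====================================================
epochs run:        10
best epoch:        6 (test loss 0.07832)
final train loss:  0.06864
parameters:        39522

Test-set metrics (mean over pairs):
      1-MSE (%)  NCC (%)  Dice (%)  MSE (raw)
mean     99.508   92.168     86.68      0.005

Pre-registration baseline (identity transform):
      1-MSE (%)  NCC (%)  Dice (%)  MSE (raw)
mean     99.389   90.078    85.214      0.006
```

Ten epochs on eight pairs already lift held-out NCC from 90.1 % to 92.2 %
and Dice from 85.2 % to 86.7 % relative to the unregistered baseline; the
full desk-scale protocol (30 epochs on 20 pairs, see below) gains several
Dice points more.  `results.register_pair(pair)` returns the predicted
displacement field and warped volume for any pair;
`results.plot_history("loss.png")` plots the loss curves.

The command-line interface mirrors the library:

```bash
udrnet simulate --out data/ --n 30 --split 20,10 --seed 666
udrnet train --data data/ --out ckpt/ --desk-scale
udrnet register --model ckpt/ --moving m.nii.gz --fixed f.nii.gz \
                --out-warped w.nii.gz --out-dvf d.nii.gz
udrnet evaluate --model ckpt/ --data data/ --out metrics.csv --top-k 5
udrnet preprocess --in raw.nii.gz --out prep.nii.gz --wl -600 --ww 1500 \
                  --crop-depth 192
```

`preprocess` applies the CT chain: Hounsfield windowing (width/level ramp
clipped to [0, 255]), min-max normalization to [0, 1], and cropping of the
leading/trailing slices of the axial sequence.

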