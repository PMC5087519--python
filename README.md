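# skinspeckle

Recognition of **skinning injury** — the superficial excoriation of potato
periderm that strips the protective phellem (skin) — from two complementary
CCD-based imaging channels:

- **Biospeckle imaging.** Living tissue illuminated by coherent light
  produces a time-varying granular interference pattern; the speed of that
  variation reflects biological activity. Fresh wounds (< 1 day) are
  metabolically violent and show high activity; it subsides as a suberized
  closing layer forms.
- **Visible imaging.** With time, wound suberization darkens the injured
  skin, so the mean-gray contrast between a sound-skin (SS) and an
  injured-skin (IS) region grows; color and texture features of 65×65-pixel
  ROI patches then separate the classes.

The package is aimed at postharvest machine-vision researchers who want a
tested, reproducible implementation of the THSP/inertia-moment activity
measure and the companion visible-feature classification stage, plus
synthetic generators that stand in for the (undeposited) potato data.

## The activity statistic

From a stack of `T` speckle frames, one spatial column is tracked through
time to form the THSP (time history of the speckle pattern), an `H × T`
matrix whose rows are pixels and columns are time. Consecutive-in-time
gray-level pairs are counted into a co-occurrence matrix

    COM = [N_ij],    M_ij = N_ij / Σ_j N_ij,

and the **biospeckle activity** is the inertia moment of `M` about its
diagonal:

    BA = IM = Σ_ij M_ij (i − j)².

A static surface puts every transition on the diagonal (`BA = 0`); active
tissue spreads transitions out and inflates `BA`. Prefix windows of
10/20/30/40 s (125–500 frames at 12.5 Hz) let capture time shrink without
losing the signal: short-window and full-recording BA stay highly
correlated.

Classification uses a least-squares SVM (RBF kernel; training is one exact
KKT linear solve) on the visible features, and a binary logistic regression
(IRLS) on scalar BA, both evaluated with stratified repeated random 2:1
train/prediction splits.

## Worked example

```python
from skinspeckle import (SpeckleSimParams, PatchSimParams,
                         simulate_speckle_sequence, simulate_skin_patch_pair,
                         ba_over_windows, contrast_con)

sound = simulate_speckle_sequence(SpeckleSimParams(rho=0.95, seed=1))
wound = simulate_speckle_sequence(SpeckleSimParams(rho=0.5, seed=2))
for name, seq in [("sound skin", sound), ("fresh injury", wound)]:
    for res in ba_over_windows(seq, [10.0, "all"]):
        print(f"{name:13s} window {res.window_seconds:5.1f} s "
              f"({res.n_frames_used:3d} frames): BA = {res.ba:9.1f}")

ss, injured = simulate_skin_patch_pair(PatchSimParams(con=30.9, seed=0))
print(f"realized contrast Con = {contrast_con(ss, injured):.2f}")
```

prints

```
sound skin    window  10.0 s (125 frames): BA =   18669.9
sound skin    window  41.0 s (512 frames): BA =   23914.3
fresh injury  window  10.0 s (125 frames): BA =  264579.2
fresh injury  window  41.0 s (512 frames): BA =  425622.3
realized contrast Con = 30.90
```

The fresh injury's field decorrelates faster (`rho = 0.5` vs `0.95`), so
its BA is an order of magnitude above sound skin in every window — the
separation the logistic-regression channel exploits. The patch pair
realizes the requested 1-day contrast regime (`Con ≈ 30.9` gray levels,
SS brighter than IS) to within 8-bit quantization.

A command-line interface mirrors the library
(`skinspeckle simulate|ba|feats|clf|stats|pipeline`, see `--help`), and
`skinspeckle pipeline --mode both` runs the whole synthetic study into a
versioned run directory.

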