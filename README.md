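# chinpaint

Cahn–Hilliard image inpainting for damaged binary images, with a
classification benchmark that quantifies how much restoration helps
label prediction.

Scratches, lost scan lines or dead pixels destroy part of an image before
it reaches a downstream model. When the damaged region is known
(non-blind inpainting), a phase-field PDE can rebuild the missing
structure from its surroundings: the image's two colours are the two
minima of a double-well potential, and the modified Cahn–Hilliard
equation

    ∂φ/∂t = −∇²(ε²∇²φ − H′(φ)) + λ(x)·(φ⁰ − φ),   H(φ) = (φ²−1)²/4,

interpolates edges across the damage (where λ = 0) while the fidelity
term λ₀(φ⁰ − φ) pins the rest of the image to the input φ⁰. The package
is aimed at researchers in image restoration and phase-field methods, and
at anyone who wants a quantitative answer to "does inpainting actually
help my classifier?".

What it provides:

- an energy-stable, semi-implicit upwind **finite-volume solver** (convex
  splitting, Newton with a sparse 13-point Jacobian, no-flux ghost
  cells), in a coupled 2-D form and a cheaper dimensional-splitting form
  that solves rows then columns with N×N Jacobians;
- the **two-step method**: a first stage with large interface width
  ε₁ = 1.5 reconnects shapes across the damage, a second with ε₂ = 0.5
  sharpens the edges;
- **damage simulators** (line damages A–D, random rows, random pixels —
  all returning explicit masks), the classic cross-line calibration
  image, and a synthetic digit-glyph dataset so every test and example
  runs without downloads;
- a deterministic numpy **dense classifier** (784-64-64-10, ReLU/softmax,
  Adam) and an **experiment pipeline** that damages a test set, inpaints
  it, classifies both arms with the same frozen model and reports the
  relative improvement 100·(acc_with − acc_without)/acc_without;
- IDX and PGM I/O plus a thin `chinpaint` command-line interface
  (`fixtures`, `damage`, `inpaint`, `train`, `experiment`).

See `docs/methods.md` for the discretization, stability properties and
parameter rationale.

## Worked example

Restoring the 50×50 cross-line image (a vertical bar crossed by a
mid-grey damage band) with the production settings:

```sh
python examples/inpaint_crossline.py
```

prints

```
solver steps: stage 1 (reconnect) 1169, stage 2 (sharpen) 472
masked-region mean |phi| before: 0.0039
masked-region mean |phi| after:  0.9825
mean phi on the bar inside the band: 0.9279
```

Before inpainting the damaged band sits at phase ≈ 0 (mid-grey, neither
colour). After the two stages the masked cells average |φ| ≈ 0.98 — the
band has been replaced by sharp black/white phases — and the bar cells
inside the band average φ ≈ +0.93, i.e. the ink bar is reconnected
through the damage instead of being erased.

The end-to-end benchmark on synthetic glyphs
(`python examples/train_and_evaluate.py`, a minute or two):

```
baseline accuracy on clean test glyphs: 0.8750
rows k=10: accuracy without filter 0.5250
rows k=10: accuracy with filter    0.8250
improvement: +57%
```

With 10 of 28 rows destroyed, classifying the restored images recovers
most of the accuracy lost to the damage — the low-to-moderate damage
regime where the filter pays off.

Other examples: `energy_decay.py` (free energy is non-increasing even at
100× the production time step), `dimensional_splitting.py` (the split/full
gap halves with Δt), `damage_gallery.py` (every damage simulator on one
glyph).

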