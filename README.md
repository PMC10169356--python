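# simplexgrad

Gradient-based attribution maps (saliency, integrated gradients,
SmoothGrad, expected gradients) for deep models of one-hot encoded
sequences contain a structural noise source: one-hot DNA/RNA/protein lives
on a per-position probability simplex (Σ_a x_a = 1), and the trained
network is unconstrained *off* that simplex, so the component of the input
gradient along the simplex normal n = (1/√A)(1,…,1) is arbitrary.
`simplexgrad` removes it:

    G_corrected[l, a] = G[l, a] − (1/A) Σ_a G[l, a]

— an orthogonal projection of each position's gradient onto the zero-sum
hyperplane, one line of numpy in practice. The package is for researchers
in regulatory genomics (and anyone attributing models over categorical
inputs) who want the correction itself, diagnostics for how far their
model's gradients stray off-simplex (signed angles
sin α = (G·n)/‖G‖, exceedance fractions), and a self-contained synthetic
benchmark that quantifies what the correction buys against base-resolution
ground truth.

The package ships:

* `GradientCorrector` — an sklearn-style transformer implementing the
  projection, angle profiles, and exceedance summaries; plus the functions
  `correct_attribution`, `orthogonal_magnitude`, `gradient_angles`,
  `angle_exceedance`, `off_simplex_penalty`.
* A billboard-model synthetic dataset generator (200-nt sequences,
  3–5 embedded transcription-factor motifs from a CEBPB/GABPA/MAX/SP1/YY1
  core pool plus reverse complements, equiprobable background, exact
  per-position ground-truth probabilities), with FASTA/BED/array output.
* `SequenceCNN` — shallow and deep CNN classifiers (ReLU or exponential
  first-layer activations) in a plain-numpy network stack whose backward
  pass provides exact input gradients; includes an optional off-simplex
  training penalty.
* The four attribution methods, interpretability scoring (cosine
  similarity to centered ground truth, grad-times-input AUROC/AUPR,
  ensemble difference reduction), and a CLI pipeline
  (`generate / train / attribute / correct / angles / evaluate / benchmark`).

## Worked example

```python
>>> import numpy as np, simplexgrad as sg
>>> g = np.array([[1.0, 0.0, 0.0, 0.0]])     # one position's gradient row
>>> sg.correct_attribution(g)
array([[ 0.75, -0.25, -0.25, -0.25]])
>>> sg.orthogonal_magnitude(g)
array([0.5])
>>> sg.gradient_angles(g).angles
array([30.])
```

The row (1, 0, 0, 0) sits 30° off the simplex plane: its projection on the
normal ½(1,1,1,1) has length 0.5, sin α = 0.5/1.0, and the corrected row
(0.75, −0.25, −0.25, −0.25) is what survives in the data-supported plane —
its norm √0.75 = cos 30°.

End-to-end on the synthetic benchmark:

```python
import simplexgrad as sg
from simplexgrad.models import ModelSpec, TrainConfig, build_model, train

data = sg.generate_dataset(n=20_000, seed=0)          # 14,000/2,000/4,000 split
model = train(build_model(ModelSpec(architecture="deep"), seed=0),
              data, TrainConfig(seed=0))              # val AUC ≈ 0.95 in ~9 min on 1 CPU
X, y, M = data.arrays("test")
maps = model.input_gradient(X[:500])                  # saliency maps
corrector = sg.GradientCorrector().fit(maps)
print(corrector.exceedance_summary(maps))             # {30.0: ~0.31, 45.0: ~0.13, 60.0: ~0.04}
```

i.e. for this trained model roughly 31% / 13% / 4% of positions per map
have gradient angles beyond 30°/45°/60° — positions whose scores the
projection then changes most. The same run from the shell:

```bash
simplexgrad benchmark --smoke --seed 0 --out-dir runs/smoke
```

writes per-sequence before/after metric tables (`report.tsv`), angle
summaries (`angles.tsv`), and a JSON digest.

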