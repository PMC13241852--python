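# ibdmil

Weakly supervised grading of inflammatory bowel disease (IBD) activity
from whole-slide images of H&E-stained biopsies, scored on the Nancy
Histological Index (NHI, 0–4). The package is aimed at computational
pathology groups who have slide-level grades but no region-level
annotation: it turns a scanned biopsy into an interpretable grade
prediction, and a quantitative tissue profile a pathologist can read
without any ML background.

## What it does

The pipeline has two complementary arms built on the same tissue
segmentation maps:

1. **Quantitative histology statistics.** Per-slide densities of each
   nuclear type, tissue-class area fractions, gland density and
   circularity (4πA/P²), surface-epithelium area and the
   epithelial-to-stromal nuclear ratio — the measurable hallmarks of
   IBD progression (gland depletion, epithelial erosion, inflammatory
   infiltration, stromal expansion) — plus a gradient-boosting
   baseline classifier over these features.

2. **Region-filtered attention MIL.** Tiles are kept when they hold at
   least 10% reference tissue (stroma + normal epithelium) and any
   pixel of abnormal epithelium, inflammation or debris; kept tiles
   split into 25 patches of 250 px, patches ≥ 60% background are
   dropped, and a frozen foundation-model encoder turns the survivors
   into embedding *bags*. A gated attention MIL network grades each
   bag: instance encoder (2 FC layers → 256-d with ReLU, dropout,
   layer norm), attention pooling
   s_k = wᵀ(tanh(V h_k) ⊙ σ(U h_k)) with masked softmax over real
   patches, and a linear head to 2/3/5 classes. Training uses focal
   loss with epoch-wise inverse-frequency class weights, Adam, and
   early stopping on validation macro F1. Attention weights render
   into slide-space heatmaps showing *where* the evidence sits.

NHI groupings supported: five-class, conventional three-class (0–1 /
2 / 3–4), remission-separating three-class (0 / 1–2 / 3–4) and binary
(< 2 vs ≥ 2). All splits are patient-level and stratified, so no
patient's slides ever straddle train and test.

Because the clinical cohorts this method targets are private, the
package includes first-class synthetic generators for every input kind
(annotation bundles with exact ground-truth ledgers, slide-like
rasters, embedding bags with planted diagnostic instances), making the
entire pipeline runnable and testable offline. See `docs/methods.md`
for the full model description and design rationale.

## Worked example

Train on a synthetic cohort where each diseased slide contains ~10%
planted "lesion" patches and grade labels follow the conventional
three-class grouping:

```python
import numpy as np
from ibdmil.synthetic import BagSpec, gen_bags, split_bags
from ibdmil.train import TrainConfig, train_mil, predict_bags
from ibdmil.grouping import get_grouping

spec = BagSpec(n_classes=3, n_per_class=67, bag_size=(30, 60),
               signal_rate=0.1, dim=32)
bags, ledger = gen_bags(spec, seed=1)
split = split_bags(bags, seed=1)
cfg = TrainConfig(lr=1e-3, max_epochs=150, patience=40, weight_decay=3e-3)
state = train_mil([bags[i] for i in split["train"]],
                  [bags[i] for i in split["val"]], "type_A", cfg, seed=1)

scheme = get_grouping("type_A")
test = [bags[i] for i in split["test"]]
probs, preds, attn = predict_bags(state, test)
truth = np.array([scheme.map_nhi(b.label) for b in test])
print(f"held-out accuracy: {(preds == truth).mean():.3f}")

idx = {b.slide_id: i for i, b in enumerate(bags)}
ratios = [a[ledger.signal_masks[idx[b.slide_id]]].mean() * b.n
          for b, a in zip(test, attn)
          if ledger.signal_masks[idx[b.slide_id]].any()]
print(f"attention on planted lesions vs uniform: {np.mean(ratios):.1f}x")
```

Output:

```
held-out accuracy: 1.000
attention on planted lesions vs uniform: 11.8x
```

A held-out accuracy of 1.0 on 39 test bags means the model separates
the three planted severity classes cleanly; the 11.8× ratio says the
attention mechanism concentrates its weight on the planted lesion
patches rather than spreading it uniformly — the behavior that makes
the heatmaps diagnostically meaningful.

A command-line interface mirrors the library
(`ibdmil fixtures|tile|filter|stats|baseline|embed|train|evaluate|ablate|report`);
`ibdmil fixtures --out cohort/` emits a complete miniature synthetic
cohort to experiment with.

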