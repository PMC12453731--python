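# cardiofuse

Binary cardiac-state classification (normal vs. abnormal) from
**synchronized ECG and PCG signals**, using a progressive
attention-based cross-modal fusion network, together with the full
pipeline around it: beat-to-beat preprocessing, class-imbalance-aware
training, ablation variants and missing-modality evaluation.

The package is aimed at researchers working on multimodal
cardiovascular screening: the ECG carries the heart's electrical
activity (P-QRS-T morphology), the PCG its mechanical activity (S1/S2
heart sounds, murmurs), and the two are complementary — some
pathologies show up mainly in one modality.

## Model

Input is one cardiac cycle: a pair of 1-second, 2,000-sample waveforms
cut at consecutive S1 onsets (S1 marks the start of systole, shortly
after the ECG R wave) and z-scored per record.

Three branches:

1. **Two modality encoders** (identical architecture, independent
   weights). Each of four levels is a CBR block (conv k=7 →
   batch norm → ReLU, the level's stride-5 downsampling) followed by two
   SE-ResNet blocks, with channels 64 → 128 → 192 → 256 and lengths
   2000 → 400 → 80 → 16. The squeeze-and-excitation gate is
   `X ⊙ σ(W₂ δ(W₁ GAP(X)))`. At levels 3–4 the raw signal,
   average-pooled by 5 and 25 to the level-input length, is added to
   the level input (broadcast over channels).
2. **Progressive fusion**: at each level `l` a SACMF module computes
   `V_s = SAM(concat(f_l^ECG, f_l^PCG))` — a spatial-attention block
   (1×1 conv → ReLU → k=16 conv → ReLU → 1×1 conv → sigmoid) producing
   one weight map per modality — then SE-style channel attention, and
   fuses with the previous level's output (average-pooled by 5) through
   BN → conv(k=7) → ReLU: `f_l = C₂(f_{l-1}, CAM(V_s))`.
3. **Classifier head**: conv(k=3, s=2) → global average pooling →
   dense 128/64/32 with ReLU and dropout 0.5 → dense 2 → softmax.

Training protocol: Adam from lr 0.01, ×0.1 decay
after 5 epochs without a train-loss decrease, early stop after 20,
at most 100 epochs, batch 32 (train) / 128 (eval), L2 regularization,
He initialization, and cross-entropy weighted inversely to class
frequency. Evaluation reports accuracy, sensitivity, specificity, FPR,
precision, F1 and ROC-AUC; missing-modality robustness is probed by
zeroing one input channel at inference.

Nine architecture variants are buildable for ablations: `full`,
`single_ecg`, `single_pcg`, `early_fusion`, `late_fusion`,
`only_last_sacmf`, `concat_only`, `sa_only`, `ca_only`.

Everything runs on plain numpy: the package ships a small reverse-mode
autodiff engine (`cardiofuse.nn`) whose gradients are verified against
finite differences in the test suite.

## Worked example

```python
from sklearn.model_selection import train_test_split
from cardiofuse import PRESETS, build_dataset, synth_dataset
from cardiofuse import CrossModalFusionClassifier
from cardiofuse.evaluation import evaluate_missing_modality, metrics_report

# 40 synthetic records (20 normal / 20 abnormal), each 10 heartbeats of
# synchronized ECG+PCG with ground-truth S1 annotations
records = synth_dataset(20, PRESETS["easy"], seed=42)
X, y = build_dataset(records).arrays(500)   # (360, 2, 500): ECG ch 0, PCG ch 1

Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.25,
                                      stratify=y, random_state=0)
clf = CrossModalFusionClassifier(
    variant="full", input_len=500, channels=(8, 16, 24, 32),
    se_ratio=4, channel_ratio=4, head_hidden=(32, 16, 8),
    max_epochs=5, random_state=0)
clf.fit(Xtr, ytr)
print(metrics_report(yte, clf.predict_proba(Xte)[:, 1]).to_json())
```

prints (reduced-width model, 5 epochs on one CPU):

```json
{
  "tp": 45, "fp": 0, "tn": 45, "fn": 0,
  "accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0,
  "fpr": 0.0, "precision": 1.0, "f1": 1.0, "auc": 1.0,
  "undefined": []
}
```

i.e. on strongly class-separated synthetic beats the fused model
separates the held-out segments perfectly within a few epochs. On
*complementary* data, where half the abnormal records are abnormal only
in the ECG and half only in the PCG, each single-modality branch tops
out near 75 % while the fused model stays near 100 % — the ordering the
fusion design is meant to produce.

The same pipeline is scriptable from the shell:

```bash
cardiofuse simulate   --out-dir data --n-per-class 10 --preset easy --seed 0
cardiofuse preprocess --data-dir data --out-dir work --k-folds 5 --seed 0
cardiofuse train      --archive work/segments.npz --variant full --out-dir runs --seed 0
cardiofuse evaluate   --archive work/segments.npz --drop-modality pcg --out-dir runs --seed 0
cardiofuse ablate     --archive work/segments.npz --out-dir runs --seed 0
```

Real data in WFDB format (header + signal files, one PCG and one ECG
channel at 2,000 Hz, a `REFERENCE.csv` with `record,-1|1` labels, and
per-record S1 annotation CSVs) is read by the same
`preprocess`/`train`/`evaluate` commands.

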