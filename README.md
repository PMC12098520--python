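# adgsleep

Adversarial domain-generalized sleep staging from multichannel
polysomnography (PSG) spectrograms.

Automatic sleep staging assigns one of the five AASM stages — W, N1, N2,
N3, REM — to every 30-second epoch of an overnight recording. Models
trained on a fixed set of subjects routinely lose accuracy on new ones,
because physiological signals differ systematically between people.
`adgsleep` implements a domain-generalization classifier for this
problem: a residual channel-attention feature extractor (Res_CAB blocks
with squeeze-and-excitation, a U-shaped encoder–decoder with skip
connections, and a bidirectional GRU) feeds two heads — a 5-way stage
predictor and an `n`-way subject (domain) discriminator reached through
a gradient reversal layer (GRL). Training minimizes

    L_all = L_cla − λ · L_d

so the discriminator learns to identify the source subject while the
extractor, receiving the sign-reversed domain gradient, learns features
that stage sleep but do not identify the subject. Evaluation follows
leave-one-subject-out (LOSO) cross-validation with accuracy, per-class
precision/recall/F1, macro-F1, Cohen's κ, and bootstrap confidence
intervals.

The package is aimed at methods researchers: it ships a synthetic
multi-subject PSG generator (stage-specific spectra + per-subject domain
shift) so the whole pipeline — preprocessing, adversarial training,
LOSO evaluation, ablations — runs and is tested on one CPU without any
external dataset. Reading real EDF recordings is supported through the
optional `mne` dependency. The network and its gradients (including the
GRL) are implemented as a small reverse-mode autodiff on numpy inside
the package.

## Worked example

Train and evaluate the desk-scale LOSO experiment (3 synthetic
subjects × 40 epochs, reduced model) from the shipped preset:

```bash
adgsleep run --config configs/desk.yaml --seed 1 --out runs/demo
```

which prints (identically reproducible for this seed):

```json
{
  "accuracy": 0.7333333333333334,
  "macro_f1": 0.63607294265189,
  "kappa": 0.6636298871616501
}
```

Here `accuracy` is the mean over the three LOSO folds of the held-out
subject's epoch-level staging accuracy (0.2 would be chance at the
uniform stage distribution), `macro_f1` the mean over folds of the
unweighted five-class F1 average, and `kappa` the mean chance-corrected
agreement. `runs/demo/` contains one JSON report per fold (confusion
matrix, per-class metrics, bootstrap CI), per-epoch training-history
logs, the aggregate `summary.json`, and the resolved configuration.

The same pipeline is available as a library, sklearn-style:

```python
from adgsleep import AdversarialSleepStager, SyntheticCohortConfig, generate_cohort
from adgsleep.experiment import preprocess_cohort

cohort = generate_cohort(SyntheticCohortConfig(n_subjects=3, epochs_per_subject=40))
tensors, labels = preprocess_cohort(cohort, size=32)

model = AdversarialSleepStager(input_size=32, encoder_widths=(8, 16, 32),
                               decoder_channels=32, gru_hidden=16,
                               head_hidden=(32, 16), epochs=5,
                               learning_rate=1e-3)
import numpy as np
x = np.concatenate([tensors[0], tensors[1]])
y = np.concatenate([labels[0], labels[1]])
d = np.concatenate([np.zeros(len(labels[0])), np.ones(len(labels[1]))])
model.fit(x, y, domains=d)
probs = model.predict_proba(tensors[2])   # (n_epochs, 5) stage probabilities
```

Subcommands `simulate`, `preprocess`, `train` and `evaluate` expose the
individual stages on disk files and compose to the same results as
`run`. The `configs/reference.yaml` preset keeps the full-size architecture
(128×128×10 inputs, encoder bottleneck 8×8×256, 32×256 feature
sequences) and the reference hyperparameters (150 epochs, batch 16,
Adam at 2e-5); it is GPU-scale work and not meant for a laptop CPU.

Ablation flags `use_se` (channel attention off) and `use_discriminator`
(adversarial branch off) reproduce the two ablation variants as
configuration changes.

See `docs/methods.md` for the model, the preprocessing contract, the
synthetic generator's design and its limits, and all numerical choices.

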