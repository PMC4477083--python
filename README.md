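# mrsmil

Minimum-reference-set multiple-instance learning (MRS-MIL) for multi-label
symptom–syndrome differentiation.

## The problem

In syndrome differentiation — the diagnostic step of mapping a patient's
symptom list onto one or more syndrome classes — each patient typically
carries several syndromes, different syndromes share symptoms, and the
number of patients labeled with any single syndrome is small relative to
the rest of the cohort. `mrsmil` treats this as multiple-instance learning:
a patient is a *bag*, each presented symptom is an *instance* (a one-hot
vector over the symptom vocabulary), and the bag's label set holds its
syndrome classes. The package is for biostatisticians and method developers
who want an interpretable, small-sample-robust multi-label classifier that
also *explains* each class by an explicit list of representative symptoms.

## The method

For each class `c` (one-vs-rest):

1. **Representative-symptom selection.** A candidate prototype set `P`
   maps every bag `B` into a similarity space,
   `e_j(B) = max_{x∈B} exp(−‖x − p_j‖²/σ²)`. The set is scored by the size
   of the **minimum reference set** it induces: the smallest-found subset of
   labeled bags that, used as the seeds `Y` of a manifold-ranking classifier
   `F = (I − αS)⁻¹Y` on the embedded-bag affinity graph, classifies all
   labeled bags correctly. Candidates are ranked by positive/negative
   frequency lift; the prefix of that ranking with the smallest MRS is the
   class's symptom signature. Small MRS ⇒ few labeled bags suffice to
   separate the class ⇒ good expected generalisation.
2. **Class model.** The positive bags are embedded on the selected
   prototypes and a Gaussian mixture `p(e|c) = Σ_k w_k N(e; μ_k, Σ_k)` is
   fitted by EM; the component count is chosen by minimum description
   length, `MDL(k) = −loglik + (P/2)·ln(nm)`.
3. **Differentiation.** For a test bag, `posterior(c) ∝ prior(c)·p(e_c|c)`
   (Bayes' rule); the top-K classes (K = 3 by default) are assigned.
   Evaluation uses the per-class counts A/B/C with precision = B/A and
   recall = B/C.

A synthetic cohort generator with planted per-class symptom signatures
(88 symptoms, 7 classes, 1–3 labels per bag, configurable overlap and
noise) makes every stage testable against known ground truth. See
`docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import dataclasses
from mrsmil import MRSMIL, generate, presets, selected_precision

cfg = dataclasses.replace(presets()["paper-like"], n_bags=200, seed=42)
dataset, truth = generate(cfg)

results = MRSMIL(dataset).fit(seed=0)
print(results.summary())
```

```
MRS-MIL results (7 classes, 200 bags, seed=0)
class  n_prototypes  mrs_size  gmm_k  prior                                              prototypes
   C1             8        15      1  0.255                         S66;S13;S67;S14;S78;S37;S48;S09
   C2             6        11      1  0.295                                 S42;S12;S20;S23;S65;S79
   C3             8         9      1  0.210                         S07;S31;S77;S35;S55;S50;S19;S04
   C4            14         4      1  0.275 S47;S49;S17;S45;S71;S81;S63;S03;S84;S04;S83;S59;S08;S62
   C5             7        12      1  0.255                             S86;S16;S85;S32;S46;S24;S57
   C6             5         9      1  0.240                                     S76;S82;S60;S72;S21
   C7             8         5      1  0.280                         S75;S38;S44;S51;S06;S56;S02;S11
```

Each row is one class: the selected symptom signature, the reference-set
size it achieved (smaller = more separable), the mixture order picked by
MDL, and the class prior. Against the generator's planted signatures:

```python
precisions = {c: selected_precision(results.representatives[c].symptom_ids,
                                    truth.signatures[c])
              for c in results.fitted_classes}
print({c: round(p, 2) for c, p in precisions.items()})
report = results.evaluate()
print(f"training macro precision {report.macro_precision:.3f}, "
      f"recall {report.macro_recall:.3f}")
```

```
{'C1': 1.0, 'C2': 1.0, 'C3': 0.88, 'C4': 0.71, 'C5': 1.0, 'C6': 1.0, 'C7': 1.0}
training macro precision 0.669, recall 1.000
```

Most selected symptoms are planted signature members (selected precision
0.71–1.0 per class here). Macro precision at top-3 is bounded by
mean-labels/3 ≈ 0.55–0.66 on this generator — every bag receives exactly
three of seven classes while carrying 1.66 on average — so 0.669 with
recall 1.0 is near the structural ceiling, not a weak fit.

## Command line

```bash
mrsmil simulate --preset paper-like --n-bags 300 --seed 1 --out cohort.json
mrsmil select   --dataset cohort.json --target-class C1 --out c1.json
mrsmil fit      --dataset cohort.json --seed 1 --out model.json
mrsmil classify --model model.json --dataset cohort.json --out pred.json
mrsmil evaluate --predictions pred.json --truth cohort.json --out eval.json
mrsmil run-experiment --preset paper-like --repeats 10 --seed 1 --baseline --out report.json
```

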