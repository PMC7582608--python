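# hrvprint

Imminent ventricular tachyarrhythmia (sudden-cardiac-death) risk analysis
from short, beat-annotated RR-interval recordings.

Patients wearing an implantable cardioverter-defibrillator (ICD) produce
short RR-interval captures — roughly the last 1000 beats before a
ventricular tachycardia/fibrillation episode, plus control recordings from
follow-up visits. `hrvprint` asks whether those final ~15 minutes already
look different from a quiet baseline, and answers it with a classifier
over two families of indices:

* **11 heart-rate-variability (HRV) indices** on the sinus-only (NN)
  series: meanNN, SDNN, RMSSD, pNN50; Welch-based band powers LF
  (0.04–0.15 Hz) and HF (0.15–0.4 Hz) with LFnu, HFnu and the LF/HF ratio,
  averaged over 5-minute segments; and meanNN/SDNN over the final minute
  (meanNN l.m., SDNN l.m.).
* **5 heartprint indices** describing premature ventricular complexes
  (PVCs): PVCs/hour, mean and SD of the coupling interval (meanCI, SDCI),
  the modal number of intervening sinus beats between PVCs (NIBmax) and
  the count of NIB entries at that mode (sNIB).

All 16 indices are min–max scaled with training-set factors,
x ↦ (x − min)/(max − min), and fed to a support vector machine with the
radial-basis-function kernel K(x_i, x_j) = exp(−γ‖x_i − x_j‖²). The index
combination and the hyperparameters (C, γ) are chosen jointly by a greedy
forward search under **patient-paired 10-fold cross-validation**: one
pre-event/control pair per patient, both recordings of a patient in the
same fold, so every fold's class prevalence is exactly 0.5. C ranges over
0.5–10 in steps of 0.5 and γ over 2^e for e = −15, −14.5, …, 3. Held-out
recordings are ranked by the SVM decision margin; performance is the ROC
AUC (Hanley–McNeil 95% CI) and accuracy at the margin-0 threshold
(Wilson 95% CI).

Because the clinical recordings are not redistributable, the package ships
a synthetic generator of paired pre-event/control cohorts (two-sinusoid NN
model with controllable LF/HF, plus PVC insertion with controllable rate,
coupling-interval distribution and NIB pattern) so the entire pipeline is
testable end to end.

## Worked example

```python
from hrvprint import CohortSpec, HeartprintSVM, build_feature_table, generate_cohort
from hrvprint.selection import REDUCED_COSTS, REDUCED_GAMMAS

cohort = generate_cohort(CohortSpec(n_patients=20, rng_seed=11))   # 20 paired patients
model = HeartprintSVM.from_recordings(cohort)
res = model.fit(k=10, seed=0, cost_values=REDUCED_COSTS,
                gamma_values=REDUCED_GAMMAS, max_size=4)
print(res.summary())
```

```
Paired 10-fold cross-validation, greedy forward index search
folds: 10   paired patients: 20   fold seed: 0

size                AUC       Accuracy (%)      C     gamma  indices
   2  1.0000 ± 0.0000     92.50 ± 16.87    0.5    0.0078  meanNN l.m., SDCI *
   3  1.0000 ± 0.0000     95.00 ± 15.81    0.5    0.0078  meanNN l.m., SDCI, meanNN &
   4  1.0000 ± 0.0000     92.50 ± 16.87    0.5    0.0078  meanNN l.m., SDCI, meanNN, meanCI

* best AUC; & best accuracy
```

Each row is the best combination found at that size: the mean ± SD of the
ROC AUC and accuracy across the 10 folds, and the grid-optimal cost and
kernel width. On this synthetic cohort the planted group differences
(shorter meanNN, more PVCs/hour, shorter meanCI, larger LF/HF before an
episode) are strong, so the search saturates quickly; `res.evaluate(test_table)`
then scores an independent cohort with the final model trained on all rows.
(Numbers vary with the cohort seed; the table above is from an actual run.)

A thin CLI wraps the same functions:

```bash
hrvprint simulate --n-patients 20 --seed 1 --out cohort/
hrvprint extract cohort/*.rr --out features.csv
hrvprint select --features features.csv --k 10 --seed 1 --reduced-grid
```

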