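# cholarray

Cholinergic drug–target-interaction (DTI) classifier grids and array-type
meta-predictors for chemical-threat-likeness detection.

The pipeline has two stages:

1. **DTI grid.** Activity records (ChEMBL-export-style CSV) are cleaned,
   deduplicated (median aggregation) and binarized against a potency
   threshold (default 10 µM) into per-target labeled sets for five
   cholinergic targets (nAChR, mAChR, AChE, BuChE, VAChT). Compounds are
   encoded as 1024-bit circular fingerprints (ECFP/FCFP, diameters
   0/2/4/6 — eight configurations). A grid of binary classifiers is
   trained over 5 targets × 4 algorithms (RF, DT, SVM, KNN) × 10 seeds
   (each seed drives its own stratified 70:30 split), i.e. 200 models,
   validated by 10-fold CV and held-out metrics, with best models picked
   by ensemble-AUC (mean of seed-wise held-out ROC-AUCs by default).
2. **Array detector.** Out-of-set compounds are scored by all 200 models
   into an ordered 200-slot array (slow axis = target, middle = seed,
   fast = algorithm; encodings: binary 0/1, binary 1/2, or probability).
   Arrays are reshaped losslessly to [50×4], [40×5], [5×10×4] or
   [10×5×4], optionally resampled (Model 01 native, Model 02 duplicate
   removal, Model 03/04 SMOTE), and fed to a small CNN
   (conv→pool→flatten→dense→softmax; Adam, lr 0.01, batch 32, ≤100
   epochs, early stopping on validation loss) that outputs the
   probability of the threat class. An equal-depth MLP baseline is
   included. Evaluation covers ACC, precision, recall/TPR, TNR, F1 (per
   class), MCC, threshold-based "paper AUC" = (TPR+TNR)/2, ranking
   ROC-AUC, and AUPR.

The CNN/MLP are implemented in numpy (`cholarray._nn`) because the
runtime environment ships no deep-learning framework; gradients are
verified against finite differences in the test suite. SMOTE is likewise
implemented directly (convex minority-neighbor interpolation).

A synthetic-data module generates planted-signal fixtures (disjoint
informative fingerprint bits per target, latent activity profiles, and a
configurable profile→label rule) so the whole pipeline is testable
offline with known ground truth. No hazardous structure is embedded or
generated anywhere; the only embedded SMILES are well-known innocuous
drugs.

## CLI

```bash
# synthetic fixtures in the exact input formats the readers consume
cholarray simulate --seed 3 --out sim/

# train the grid (YAML config: activity_csv, threshold_nM, fingerprint,
# targets, algorithms, seeds, cv_folds)
cholarray train-dti --config dti.yaml --out grid/

# score a labeled SMILES file into a persisted array dataset
cholarray predict-array --models grid/ --input sim/meta_stage.smi --out arrays.tsv

# train the detector (add --baseline for the MLP)
cholarray train-cnn --arrays arrays.tsv --shape 50x4 --sampling model03 --out cnn/

# evaluate a saved detector
cholarray evaluate --model cnn/ --arrays arrays.tsv
```

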