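# dtipred

Predicting drug–target interactions (DTIs) from sequence-derived features.

Experimental identification of protein–compound interactions is slow and
expensive, so candidate interactions are routinely prioritized in silico.
`dtipred` implements a feature-based (chemogenomic) predictor for
bipartite DTI datasets — the setting of the classic gold-standard
collections of enzymes, ion channels, GPCRs and nuclear receptors, where
every known interacting (target, drug) pair is a positive and *every*
remaining grid pair is a negative. It is aimed at computational biologists
who have PSI-BLAST profiles for their proteins and path fingerprints for
their compounds and want a reproducible, leakage-aware evaluation and a
ranked list of novel candidate pairs.

## Method

**Protein features.** Each protein's PSI-BLAST evolutionary profile
(L×20 integer log-odds matrix E, entries typically in [−9, 11]) is
normalized elementwise with the logistic function E′ = 1/(1+e^(−E)) and
summarized by two fixed-length descriptors:

- *pseudo-PSSM* (lag parameter λ, default 3): the 20 column means
  Ē_j = (1/L) Σ_i E′_ij followed, for each lag λ′ = 1..λ, by
  θ_j^{λ′} = (1/(L−λ′)) Σ_i (E′_ij − E′_{i+λ′,j})², giving 20 + 20λ = 80
  features that capture composition plus sequence-order fluctuation;
- *DCCA coefficients* (window parameter s, default 36): for each of the
  C(20,2) = 190 column pairs, the detrended cross-correlation coefficient
  ρ_DCCA(s) = f²_xy(s) / (f_xx(s) f_yy(s)) ∈ [−1, 1], computed from the
  least-squares-detrended cumulative profiles over the L−s sliding
  windows of s+1 points.

**Drug features.** A 1024-bit FP2 path fingerprint consumed as 256
hexadecimal nibbles, each a feature in 0..15.

**Pipeline.** Pair vectors (80 + 190 + 256 = 526 features) are reduced by
squared-error Lasso (penalty chosen by internal cross-validation),
rebalanced with SMOTE using the DMwR parameter convention
(perc.over = 500, perc.under = 120, k = 5 — exact class balance at 6m/6m
for m minority rows), and classified by a 500-tree random forest.
Evaluation is 5-fold cross-validation over pairs with ACC/SE/SP/F and
ROC/PR curves (AUC, AUPR); by default selection and balancing happen
inside each training fold (`balance_scope="train_only"`); the historical
`"global"` protocol, which balances before splitting and therefore leaks
synthetic rows into test folds, is available for comparison and is always
named in reports.

## Worked example

`examples/04_cross_validation.py` builds a synthetic dataset of 8 targets
× 12 drugs with 16 positives and a planted 5-SD activity signal, then
cross-validates the full stack:

```
balance scope: train_only
mean over 5 folds:
  ACC   0.958
  SE    0.883
  SP    0.973
  F     0.888
  P     0.910
  R     0.883
  AUC   0.978
  AUPR  0.906
```

AUC/AUPR near 1 mean the Lasso + SMOTE + forest stack recovers the planted
separation from held-out pairs; ACC/SE/SP are threshold-0.5 calls.
`examples/05_smote_leakage.py` repeats this on *null* data (no signal) and
prints `train_only ≈ 0.56` vs `global ≈ 0.95` mean AUC — the gap is pure
protocol artefact, which is why train-only balancing is the default. The
other examples cover descriptors, fingerprints, dataset assembly, and
ranked inference; each prints what it computes and what the numbers mean.

A thin CLI mirrors the library (`dtipred fixture | features | cv |
scan-lambda | scan-s | predict`); every run writes a `manifest.json` with
the config, seed, balance mode and input digests.

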