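# epiclock

DNA-methylation age prediction for forensic and aging applications:
genome-scale scanning for age-associated CpG sites, calibration and quality
control of mass-spectrometric (Sequenom/EpiTYPER-style) methylation data,
four competing regression families behind one fit/predict contract, and
exhaustive leave-one-out subset selection of a minimal marker panel.

## The problem

The fraction of methylated alleles at a CpG site (the *beta value*,
β ∈ [0, 1]) drifts with age at thousands of loci in human blood: some sites
gain methylation, others lose it. A small panel of such sites can estimate
the chronological age of the donor of a blood trace — valuable in forensic
casework when no database match identifies a suspect. The pipeline this
package implements has two stages:

1. **Discovery.** On a BeadChip-scale beta matrix from a small twin cohort,
   each site is regressed on age; values with detection p > 0.01 are first
   set missing and imputed from the 10 nearest sites (row-KNN). Sites pass
   a loose filter (*P* < 0.01 and R² > 0.5) or a strict one
   (Benjamini–Hochberg FDR q < 0.01), and CpG-island enrichment of the hits
   is tested by Fisher's exact test.
2. **Validation and modelling.** Candidate sites are re-measured in a
   larger unrelated cohort on a Sequenom-style platform. Measurements are
   corrected by a linear calibration fitted to a 0–100 % methylation
   standard series (in the study conditions this line is
   y = 2.285 x − 1.2176), values with confidence score ≤ 1.9 and sites or
   samples with > 70 % missingness are dropped, and sites with |Pearson R|
   > 0.5 against age are kept. Age models are then fit on the surviving
   panel and scored by the mean absolute deviation (MAD, years) between
   predicted and chronological age under leave-one-out cross-validation
   (LOO); *every* subset of the panel is scored to find the smallest panel
   whose minimal LOO MAD is within tolerance of the global minimum.

## The core model

The headline regressor is ε-insensitive support vector regression with an
RBF kernel, f(x) = Σᵢ βᵢ K(xᵢ, x) + b with K(u, v) = exp(−γ‖u − v‖²).
Residuals inside the ε-tube cost nothing; excess slack ξ is penalized
linearly with weight C (defaults C = 2, γ = 0.1, ε = 0.1 on standardized
features and response). The dual

    min ½ zᵀQ̄z + pᵀz   s.t.  sᵀz = 0,  0 ≤ z ≤ C,
    z = (α, α*),  p = (ε − y, ε + y),  Q̄ = [[K, −K], [−K, K]]

is solved by SMO with maximal-violating-pair selection to a KKT gap below
10⁻⁶; the solver is validated against a dense convex-QP solve in the test
suite. Competing families: multivariate linear regression, quadratic
(pure-squares) regression, and a single-hidden-layer back-propagation
neural network trained for 1000 cycles. All four expose
scikit-learn-style `fit`/`predict`/`get_params`/`set_params`.

A synthetic-methylome module generates every input the pipeline consumes —
twin cohorts, age-trending bounded beta values, detection p-values,
platform distortion with standard series, confidence scores, missingness,
and heavy-tailed inter-individual age acceleration — so the full analysis
is testable without any external download.

## Worked example

```python
import pandas as pd
from epiclock import (RBFSupportVectorRegression, LinearAgeModel, loo_cv,
                      mad, simulate_panel, exhaustive_subset_search,
                      choose_final_subset)

X, ages = simulate_panel(seed=1)          # 49 adults, 11 CpG sites
svr = RBFSupportVectorRegression().fit(X, ages)
print(f"train MAD (SVR, 11 sites): {mad(svr.predict(X), ages):.2f} years")
print(f"LOO   MAD (SVR, 11 sites): {loo_cv(RBFSupportVectorRegression(), X, ages).mad:.2f} years")
print(f"LOO   MAD (linear, 11 sites): {loo_cv(LinearAgeModel(), X, ages).mad:.2f} years")

frame = pd.DataFrame(X[:, :6], columns=[f"X{i+21}" for i in range(6)])
result = exhaustive_subset_search(frame, ages, RBFSupportVectorRegression(),
                                  sizes=[1, 2, 3, 4, 5, 6])
k, subset = choose_final_subset(result)
print("chosen panel:", k, subset)
```

prints

```
train MAD (SVR, 11 sites): 2.83 years
LOO   MAD (SVR, 11 sites): 5.87 years
LOO   MAD (linear, 11 sites): 6.32 years
chosen panel: 3 ('X21', 'X23', 'X25')
```

The gap between the 2.8-year training MAD and the 5.9-year LOO MAD is the
over-fitting effect the subset search exists to control: resubstitution
error flatters a kernel model, and honest (leave-one-out) error prefers a
smaller panel. `choose_final_subset` picks the smallest panel within 0.05
years of the best LOO MAD over all sizes.

## Command line

The same pipeline is scriptable from the shell:

```sh
epiclock simulate --seed 1 --out-dir sim/
epiclock scan --betas sim/betas.tsv --meta sim/metadata.csv \
              --detection sim/detection_p.tsv --out records.tsv --summary scan.json
epiclock qc --epityper validation.csv --standards standards.csv \
            --meta meta.csv --out qc_matrix.tsv --report qc.json
epiclock select --betas qc_matrix.tsv --meta meta.csv --sizes 1-6 --out search.tsv
epiclock train --family svr --betas qc_matrix.tsv --meta meta.csv \
               --sites panel.txt --model model.json
epiclock predict --model model.json --betas new_samples.tsv --out ages.tsv
epiclock run --seed 1 --out-dir run/      # all stages + provenance manifest
```

Beta matrices are dense TSV (rows = sites, columns = samples, `NA` for
missing), EpiTYPER data long-format CSV, metadata CSV; `epiclock run`
writes a manifest with content hashes, seeds and library versions so
deterministic stages re-run bit-identically.

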