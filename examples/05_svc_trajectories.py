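"""Stage-varying network-memory association with the sparse
varying-coefficient model.

Participants of one pathology group are ordered along the severity
pseudo-axis and binned (10/bin); memory is regressed on all network
scores plus nuisance predictors with B-spline coefficient functions
under a group-lasso penalty; lambda is tuned by fivefold CV and the fit
repeated over CV randomisations to obtain selection frequencies and
coefficient-curve bands.
"""

import numpy as np
import pandas as pd

from netstage import (
    SimConfig,
    build_basis,
    generate_cohort,
    repeat_and_summarize,
    standardize_inputs,
)
from netstage.pipeline import svc_design
from netstage.staging import order_and_bin

cohort = generate_cohort(SimConfig(n_per_cell=100, grid_dims=(8, 8, 8),
                                   voxel_size_mm=12.0, rng_seed=0))
phen = cohort.phenotypes
sub = phen[phen["pathology"] == "A+"]  # amyloid-pathology group, n=300
ordered = order_and_bin(sub, bin_size=10)
X = svc_design(ordered.set_index("subject_id"),
               cohort.truth["loadings"].loc[ordered["subject_id"]])
y, Xs = standardize_inputs(ordered["memory"].to_numpy(), X,
                           np.full(len(ordered), "A+"))
Xs = pd.DataFrame(Xs, columns=X.columns)
K = int(ordered["bin"].max())
basis = build_basis(K, 6)

summary = repeat_and_summarize(y, Xs, ordered["bin"].to_numpy(), basis,
                               n_rep=25, threshold=22, n_lambda=15,
                               base_seed=0)
print(f"{K} bins, {Xs.shape[1]} predictors, 25 repetitions")
print("\nselection frequencies (nonzero only):")
print(summary.frequency[summary.frequency > 0].to_string())
print("\nkept (frequency > 22/25):", summary.kept)

truth = cohort.truth["beta_truth"]["HIP_GMV"]
curve = summary.curve_mean.loc["HIP_GMV"]
print("\nrecovered HIP_GMV coefficient curve vs planted truth:")
print(pd.DataFrame({"bin": range(1, K + 1), "recovered": curve.round(2).values,
                    "truth": truth.round(2)}).iloc[::6].to_string(index=False))
print("curve-truth correlation:",
      round(float(np.corrcoef(curve, truth)[0, 1]), 3))
# Only the planted HIP structural predictor is kept; its recovered
# coefficient declines across bins, mirroring the planted early-stage
# dominance of the hippocampal network on memory.
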