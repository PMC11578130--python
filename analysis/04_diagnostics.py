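"""Model qualification: bootstrap precision, VPC and residual diagnostics.

Re-fits the final model, runs a study-level nonparametric bootstrap for
percentile confidence intervals, a 1000-replicate visual predictive check,
and writes the residual table (PRED/IPRED/IWRES/CWRES).
"""

import json
from pathlib import Path

import numpy as np

from cocbtb.datamodel import impute_low_information_observations, \
    read_dataset
from cocbtb.diagnostics import compute_residuals, plot_vpc, run_vpc
from cocbtb.estimation import (FitConfig, bootstrap_fit, ee_dose_term,
                               fit_model, molar_dose_term)
from cocbtb.reference import BASELINE

DATA = Path("results/data")
OUT = Path("results/diagnostics")
N_BOOT = 100      # 1000 in a full run; 100 keeps this driver interactive
N_VPC = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = read_dataset(DATA / "btb_observations.csv",
                           DATA / "demographics.csv")
    dataset = impute_low_information_observations(dataset, BASELINE)
    cfg = FitConfig(covariate_terms=(molar_dose_term(), ee_dose_term()),
                    restarts=2, seed=1)
    fit = fit_model(dataset, config=cfg)
    print(f"OFV {fit.ofv:.2f}")

    boot = bootstrap_fit(dataset, N_BOOT, seed=11, base_fit=fit,
                         config=FitConfig(covariate_terms=cfg.covariate_terms,
                                          restarts=1, maxfun=400, seed=1))
    boot.replicates.to_csv(OUT / "bootstrap_replicates.csv", index=False)
    print(f"bootstrap: {N_BOOT - boot.n_failed_replicates} converged, "
          f"{boot.n_failed_replicates} excluded")
    print(f"{'parameter':22s} {'estimate':>9s} {'boot med':>9s} "
          f"{'2.5%':>9s} {'97.5%':>9s}")
    for k, v in fit.params.items():
        print(f"{k:22s} {v:9.4f} {boot.median.get(k, float('nan')):9.4f} "
              f"{boot.ci_lower.get(k, float('nan')):9.4f} "
              f"{boot.ci_upper.get(k, float('nan')):9.4f}")

    vpc = run_vpc(fit, dataset, n_replicates=N_VPC, seed=21)
    vpc.to_frame().to_csv(OUT / "vpc.csv", index=False)
    plot_vpc(vpc, OUT / "vpc.png")
    cov = vpc.coverage().to_numpy()
    print(f"VPC: observed percentiles inside 95% bands in "
          f"{100 * cov.mean():.0f}% of bins")

    resid = compute_residuals(fit, dataset)
    resid.to_csv(OUT / "residuals.csv", index=False)
    print(f"IWRES variance {np.var(resid['IWRES']):.2f} "
          f"(1 expected under the model); CWRES variance "
          f"{np.var(resid['CWRES']):.2f}")
    with open(OUT / "summary.json", "w") as fh:
        json.dump({"ofv": fit.ofv, "vpc_coverage": float(cov.mean()),
                   "bootstrap_failed": boot.n_failed_replicates,
                   "iwres_var": float(np.var(resid["IWRES"]))}, fh, indent=1)
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
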