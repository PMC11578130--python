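"""End-to-end pipeline: impute -> initial estimates -> fit -> (optional
covariate search) -> bootstrap -> VPC -> product simulation.

Every stage draws its randomness from a named sub-stream spawned from the
single pipeline seed, so a re-run with the same configuration reproduces
identical outputs.  Each run writes its resolved configuration next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .datamodel import (BaselineSpec,
                        impute_low_information_observations, read_dataset,
                        write_dataset)
from .estimation import (FitConfig, bootstrap_fit, ee_dose_term, fit_model,
                         molar_dose_term)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

#: order defines the seed sub-stream of each stage
STAGES = ("generate", "fit", "scm", "bootstrap", "vpc", "simulate")


def stage_seeds(seed: int) -> dict[str, int]:
    """One independent 31-bit seed per pipeline stage."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


@dataclass
class PipelineConfig:
    """Everything a run needs; validated before any computation."""

    out_dir: str = "results/run"
    seed: int = 0
    # data: either paths to CSVs or a synthetic-generation request
    dataset_path: str | None = None
    demographics_path: str | None = None
    generate_n_studies: int = 25
    # model
    n_compartments: int = 2
    use_final_covariates: bool = True   # EE dose on B, molar dose on alpha
    run_scm: bool = False
    # estimation
    restarts: int = 3
    maxfun: int = 2000
    # diagnostics / uncertainty
    n_boot: int = 0
    n_vpc: int = 1000
    # simulation
    n_draws: int = 1000
    months: tuple[float, ...] = (1.0, 3.0, 4.0)
    baseline_fraction: float = 0.0168
    make_plots: bool = False

    def validate(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if not 0 < self.baseline_fraction < 1:
            raise ValueError("baseline_fraction must be in (0, 1)")
        for name in ("generate_n_studies", "restarts", "maxfun", "n_vpc",
                     "n_draws"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _dump_config(config: PipelineConfig, out: Path) -> None:
    d = dataclasses.asdict(config)
    d["months"] = list(d["months"])
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a record of artifact paths and
    headline numbers.  Any stage failure raises with the stage name; partial
    outputs remain on disk."""
    from .reference import BASELINE
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_config(config, out)
    seeds = stage_seeds(config.seed)
    record: dict = {"out_dir": str(out), "seeds": seeds}

    # ---- data -------------------------------------------------------------
    if config.dataset_path is not None:
        dataset = read_dataset(config.dataset_path,
                               config.demographics_path)
    else:
        from .synthetic import GeneratorConfig, generate_dataset, \
            write_ground_truth
        gen = GeneratorConfig(n_studies=config.generate_n_studies,
                              seed=seeds["generate"])
        dataset, truth = generate_dataset(gen)
        write_ground_truth(truth, out / "ground_truth.json")
    baseline = BaselineSpec(
        baseline_fraction=config.baseline_fraction,
        imputation_fraction=config.baseline_fraction / 2.0)
    dataset = impute_low_information_observations(dataset, baseline)
    write_dataset(dataset, out / "dataset.csv", out / "demographics.csv")
    record["n_arms"] = len(dataset.arms)
    record["n_observations"] = dataset.n_observations

    # ---- fit --------------------------------------------------------------
    terms = (molar_dose_term(), ee_dose_term()) \
        if (config.use_final_covariates and config.n_compartments == 2) \
        else ()
    eta_mask = (True,) * (2 * config.n_compartments)
    fit_cfg = FitConfig(covariate_terms=terms, eta_mask=eta_mask,
                        n_phases=config.n_compartments,
                        restarts=config.restarts, maxfun=config.maxfun,
                        seed=seeds["fit"])
    try:
        fit = fit_model(dataset, config=fit_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    fit.estimates_frame().to_csv(out / "estimates.csv", index=False)
    record["ofv"] = fit.ofv
    record["converged"] = fit.converged
    record["params"] = fit.params

    # ---- optional covariate search ----------------------------------------
    if config.run_scm and config.n_compartments == 2:
        from .covariates import CovariateCandidate, stepwise_covariate_search
        cands = [CovariateCandidate(ee_dose_term()),
                 CovariateCandidate(molar_dose_term())]
        base_cfg = dataclasses.replace(fit_cfg, covariate_terms=())
        try:
            scm = stepwise_covariate_search(dataset, cands, config=base_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'scm' failed: {exc}") from exc
        scm.step_log().to_csv(out / "scm_steps.csv", index=False)
        record["scm_selected"] = [c.name for c in scm.selected]

    # ---- bootstrap ---------------------------------------------------------
    if config.n_boot > 0:
        try:
            boot = bootstrap_fit(dataset, config.n_boot, seeds["bootstrap"],
                                 fit)
        except Exception as exc:
            raise RuntimeError(f"stage 'bootstrap' failed: {exc}") from exc
        boot.replicates.to_csv(out / "bootstrap_replicates.csv", index=False)
        summary = {k: {"median": boot.median.get(k),
                       "ci95_lower": boot.ci_lower.get(k),
                       "ci95_upper": boot.ci_upper.get(k)}
                   for k in boot.median}
        with open(out / "bootstrap_summary.json", "w") as fh:
            json.dump({"n_failed": boot.n_failed_replicates, **summary},
                      fh, indent=1)
        record["bootstrap_failed"] = boot.n_failed_replicates

    # ---- VPC ---------------------------------------------------------------
    if config.n_vpc > 0:
        from .diagnostics import compute_residuals, plot_vpc, run_vpc
        try:
            vpc = run_vpc(fit, dataset, n_replicates=config.n_vpc,
                          seed=seeds["vpc"])
        except Exception as exc:
            raise RuntimeError(f"stage 'vpc' failed: {exc}") from exc
        vpc.to_frame().to_csv(out / "vpc.csv", index=False)
        compute_residuals(fit, dataset).to_csv(out / "residuals.csv",
                                               index=False)
        record["vpc_coverage"] = float(
            vpc.coverage().to_numpy().mean())
        if config.make_plots:
            plot_vpc(vpc, out / "vpc.png")

    # ---- product simulation -------------------------------------------------
    if config.n_draws > 0:
        from .products import registry_summary_frame, simulate_registry
        try:
            sims = simulate_registry(
                fit.fixed_effects,
                _full_omega_diag(fit), n_draws=config.n_draws,
                seed=seeds["simulate"], baseline=baseline,
                months=config.months)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
        frame = registry_summary_frame(sims)
        frame.to_csv(out / "product_summaries.csv", index=False)
        record["product_month1_median_pct"] = {
            s.product.label: 100.0 * s.stats[1.0]["median"] for s in sims}
        record["product_time_to_baseline_months"] = {
            s.product.label: s.median_time_to_baseline for s in sims}
        if config.make_plots:
            _plot_products(sims, out / "product_boxplot.png", baseline)

    with open(out / "run_record.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=1, default=str)
    return record


def _full_omega_diag(fit) -> np.ndarray:
    """ISV variances padded to the 4 macro-parameters (zero where the
    random effect was inactive)."""
    m = fit.model
    full = np.zeros(4)
    for name, var in zip(fit.omega.names, fit.omega.variances):
        full[("A", "alpha", "B", "beta").index(name)] = var
    return full


def _plot_products(summaries, path, baseline: BaselineSpec) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    months = summaries[0].months
    fig, axes = plt.subplots(1, len(months), figsize=(4 * len(months), 4),
                             sharey=True)
    for ax, mth in zip(np.atleast_1d(axes), months):
        labels, boxes = [], []
        for s in summaries:
            st = s.stats[mth]
            boxes.append({
                "med": 100 * st["median"], "q1": 100 * st["q25"],
                "q3": 100 * st["q75"], "whislo": 100 * st["min"],
                "whishi": 100 * st["max"], "fliers": []})
            labels.append(s.product.label)
        ax.bxp(boxes, showfliers=False)
        ax.axhline(100 * baseline.baseline_fraction, color="red",
                   linestyle="--", linewidth=1, label="baseline")
        ax.set_xticklabels(labels, rotation=75, fontsize=7)
        ax.set_title(f"month {mth:g}")
        ax.set_ylabel("women with BTB (%)")
        ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
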