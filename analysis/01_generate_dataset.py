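"""Generate the working dataset.

The trial-level data behind the meta-analysis are not public, so the
analysis runs on a synthetic dataset that mirrors the trial overview: 25
studies, 33 arms over ten progestin/EE dose combinations, monthly
observation schedules, log-normal inter-study variability and arm-size
weighted residual noise, plus study-level demographics with realistic
missingness.  Ground truth goes to a JSON sidecar for later checks.
"""

from pathlib import Path

from cocbtb.datamodel import write_dataset
from cocbtb.synthetic import GeneratorConfig, generate_dataset, \
    write_ground_truth

OUT = Path("results/data")
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(n_studies=25, seed=SEED)
    dataset, truth = generate_dataset(config)
    write_dataset(dataset, OUT / "btb_observations.csv",
                  OUT / "demographics.csv")
    write_ground_truth(truth, OUT / "ground_truth.json")

    n_missing = sum(
        v is None
        for d in dataset.demographics
        for v in (d.mean_age, d.mean_weight, d.mean_height, d.mean_bmi))
    print(f"studies: {len(dataset.study_ids)}  arms: {len(dataset.arms)}  "
          f"observations: {dataset.n_observations}")
    print(f"progestins: {sorted({a.progestin for a in dataset.arms})}")
    print(f"truncated-at-zero observations: {truth['n_truncated']} "
          f"({100 * truth['n_truncated'] / truth['n_observations']:.1f}%)")
    print(f"missing demographic cells: {n_missing} / "
          f"{4 * len(dataset.demographics)}")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
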