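"""Generate the synthetic study cohort.

Writes a seeded cohort of 100 two-sample patients — coding reference,
MAF-like mutation table, per-sample metadata, censored survival with drug
exposures, and the generative ground truth — under results/cohort/.  The
later sample of each patient is drawn with its selection strength contracted
halfway toward neutrality (kappa = 0.5), the regime treated resistant
cohorts exhibit.
"""

from pathlib import Path

from tumordnds.simulate import SimulationConfig, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20240901


def main() -> None:
    config = SimulationConfig(seed=SEED)
    paths = write_cohort(config, OUT)
    print(f"cohort written to {OUT}")
    for name, path in paths.items():
        print(f"  {name:11s} {path.name}")
    print(f"patients: {config.n_patients}, kappa: {config.kappa}, "
          f"pair noise sd: {config.pair_noise_sd}")


if __name__ == "__main__":
    main()
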