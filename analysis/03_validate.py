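"""Validate the fitted model: per-metabolite lack-of-fit F-test against the
replicate pure error, and leave-one-out-metabolite PGD2 cross-validation.

Reads results/data/ and results/fit.json; writes results/f_test.csv and
results/loo_pgd2.json.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

import cyberlipid as cl
from cyberlipid import io as cio
from cyberlipid.estimation import FitConfig
from cyberlipid.synth import _perturbed_start

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--budget", type=int, default=800,
                    help="stage-1 budget of the leave-one-out refit")
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    network = cl.build_default_network("EPA")
    datasets = cio.read_timeseries(args.data / "measurements.csv")
    profiles = cio.read_profiles(args.data / "profiles.csv")
    params = cio.read_params_json(args.out / "fit.json")
    with open(args.data / "truth.json") as fh:
        truth = cl.KineticParameters(json.load(fh)["parameters"])

    class Fitted:
        trajectories = {
            c: cl.simulate(network, params, profiles[c], t_eval=datasets[c].times)
            for c in datasets
        }

    report = cl.f_test_report(Fitted, datasets)
    report.to_frame().to_csv(args.out / "f_test.csv", index=False)
    crit = report.table["critical"].iloc[0]
    print(f"F-test (alpha=0.05): critical value "
          f"F({report.table['df1'].iloc[0]}, {report.table['df2'].iloc[0]}) "
          f"= {crit:.3f}")
    print(report.to_frame().to_string(index=False))
    print(f"all metabolites below critical: {report.all_passed}")

    start = _perturbed_start(truth, network, np.random.default_rng(args.seed))
    config = FitConfig(budget=args.budget, start=start)
    refit, held_out, fitted_errors = cl.loo_metabolite_cv(
        datasets, network, profiles, config=config,
        metabolite="PGD2", seed=args.seed,
    )
    median_err = float(np.median(list(fitted_errors.values())))
    with open(args.out / "loo_pgd2.json", "w") as fh:
        json.dump(
            {
                "held_out_metabolite": "PGD2",
                "held_out_scaled_error": held_out,
                "fitted_species_errors": fitted_errors,
                "refit_cost": refit.cost,
                "seed": args.seed,
            },
            fh, indent=2, sort_keys=True,
        )
    print(f"\nLOO-CV: predicted PGD2 scaled error {held_out:.4g} vs median "
          f"fitted-species error {median_err:.4g}")


if __name__ == "__main__":
    main()
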