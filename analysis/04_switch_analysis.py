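"""Switch analysis of the fitted activity controls.

The matching-law activities depend only on the weighted concentrations
kPGH2*[AA] and kPGH3*[EPA]; the shared eCOX level cancels.  This script
evaluates the simplified activity surfaces over an (AA, EPA) grid at the
fitted rate constants and reports the analytic switch ratio
[AA]switch/[EPA]switch = kPGH3/kPGH2.

Reads results/fit.json; writes results/switch_surface.csv.
"""

import argparse
from pathlib import Path

import numpy as np

import cyberlipid as cl
from cyberlipid import io as cio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--grid-max", type=float, default=80.0)
    ap.add_argument("--grid-n", type=int, default=41)
    args = ap.parse_args()

    params = cio.read_params_json(args.out / "fit.json")
    k2, k3 = params["kPGH2"], params["kPGH3"]
    grid = np.linspace(0.0, args.grid_max, args.grid_n)
    analysis = cl.switch_surface(grid, grid, k2, k3)
    analysis.to_frame().to_csv(args.out / "switch_surface.csv", index=False)

    print(f"fitted kPGH2 = {k2:.5f}, kPGH3 = {k3:.5f}")
    print(f"switch ratio [AA]switch/[EPA]switch = kPGH3/kPGH2 = "
          f"{analysis.ratio:.4f}")
    print("above this AA:EPA ratio the 2-series activity vPGH2 is fully on "
          "(proinflammatory dominance); below it the 3-series activity "
          "vPGH3 dominates (antiinflammatory dominance)")
    print(f"surface written to {args.out / 'switch_surface.csv'}")


if __name__ == "__main__":
    main()
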