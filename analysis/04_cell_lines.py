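"""Cell-number calibration for the two breast cell lines.

Expected accepted counts are generated from the published per-line response
lines (MB-231: N = 58.046·log10(cells) − 120.14; MCF10A:
N = 59.976·log10(cells) − 45.627) over 100–100,000 cells; the pipeline
recovers each line.  The MCF10A line sits above the MB-231 line throughout,
i.e. the control cells express more of the tumor-suppressive target per cell
than the cancer line.

Usage: python analysis/04_cell_lines.py [--seed 0]
"""

import argparse
import json
from pathlib import Path

from mirspot.experiments import MB231_LINE, MCF10A_LINE, run_cell_series
from mirspot.quantify import plot_calibration

LINES = {"MB-231": MB231_LINE, "MCF10A": MCF10A_LINE}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    payload = {}
    for name, line in LINES.items():
        fit, per_sample = run_cell_series(line, seed=args.seed)
        print(f"{name}: N = {fit.slope:.2f}·log10(cells) + {fit.intercept:.2f}"
              f"  (configured {line[0]}·log10(cells) + {line[1]}; R² = {fit.r_squared:.4f})")
        for rc in per_sample:
            print(f"    {rc.label:>12s}: {rc.mean:7.1f} ± {rc.sd:.1f} spots/region")
        plot_calibration(
            fit, [100, 1_000, 10_000, 100_000], [rc.mean for rc in per_sample],
            args.out / f"cell_line_{name}.png", sds=[rc.sd for rc in per_sample],
        )
        payload[name] = {
            "configured": {"slope": line[0], "intercept": line[1]},
            "fit": {"slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared},
            "mean_counts": {rc.label: [rc.mean, rc.sd] for rc in per_sample},
        }

    (args.out / "cell_lines.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    print(f"\nwrote {args.out / 'cell_lines.json'}")


if __name__ == "__main__":
    main()
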