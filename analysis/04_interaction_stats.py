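#!/usr/bin/env python
"""Statistical analysis of the synthetic interaction experiment.

Consumes the tables written by 03_simulate_interaction.py and reproduces the
analysis battery on them: the binomial GLM deviance test of cannibalism
across treatments with Tjur's r², one-way ANOVAs of growth and of initial /
final sizes and intrinsic mortality, and the per-container size-variance
regression. Writes the report JSON to results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import thermvar as tv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=str, default=str(RESULTS / "sim"))
    args = ap.parse_args()

    simdir = Path(args.simdir)
    census = pd.read_csv(simdir / "census.csv")
    measurements = pd.read_csv(simdir / "measurements.csv")
    report = tv.analyze_interaction(census, measurements, duration_days=56.0)

    out = RESULTS / "interaction_report.json"
    out.write_text(json.dumps(report, indent=2) + "\n")

    glm = report["cannibalism_glm"]
    reg = report["size_variance_regression"]
    print(f"cannibalism ~ treatment: deviance χ²({glm['df'][0]}) = "
          f"{glm['statistic']:.2f}, p = {glm['p_value']:.3f}, "
          f"Tjur r² = {report['tjur_r2']:.3f}")
    print(f"growth ANOVA: F{tuple(report['growth_anova']['df'])} = "
          f"{report['growth_anova']['statistic']:.2f}, "
          f"p = {report['growth_anova']['p_value']:.3f}")
    print(f"cannibalism ~ size variance: slope = {reg['effect']['slope']:.2f}, "
          f"r² = {reg['effect']['r2']:.3f}, "
          f"F{tuple(reg['df'])} = {reg['statistic']:.1f}, p = {reg['p_value']:.2e}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
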