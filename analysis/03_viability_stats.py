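"""Gated cytotoxicity statistics on the synthetic viability plates.

Runs the full pipeline — Shapiro–Wilk and Levene assumption checks, one-way
ANOVA with partial eta squared, Kruskal–Wallis validation when normality
fails, Dunnett and Tukey HSD post hocs, Hedges' g — on each plate generated
by 01_simulate_inputs.py, and writes one JSON report per plate plus a
summary table to results/.
"""

import json
import pathlib

import pandas as pd

from nanoscreen.viability import read_plate_csv, run_viability_pipeline

ROOT = pathlib.Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    summary = []
    for path in sorted(DATA.glob("plate_*.csv")):
        plate = read_plate_csv(path, control_label="control")
        report = run_viability_pipeline(plate)
        om = report.omnibus
        name = path.stem
        print(
            f"{name}: F({om.df_between},{om.df_within}) = {om.F:.2f}, "
            f"p = {om.p_anova:.3g}, partial eta^2 = {om.partial_eta_sq:.4f}, "
            f"H = {om.H:.3f} (KW validation {'run' if om.kw_run else 'not required'})"
        )
        n_sig = int((report.posthoc.dunnett["p_adjusted"] < 0.05).sum())
        print(
            f"  Dunnett: {n_sig}/{len(report.posthoc.dunnett)} treatments differ "
            f"from control; min |g| = "
            f"{report.effects.comparisons['hedges_g'].abs().min():.2f}"
        )
        out = ROOT / "results" / f"{name}_report.json"
        out.write_text(json.dumps(report.to_dict(), indent=2, default=float) + "\n")
        summary.append(
            {
                "plate": name,
                "F": om.F,
                "p_anova": om.p_anova,
                "partial_eta_sq": om.partial_eta_sq,
                "H": om.H,
                "kw_run": om.kw_run,
                "dunnett_significant": n_sig,
            }
        )
    if not summary:
        print("no plates found: run 01_simulate_inputs.py first")
        return
    pd.DataFrame(summary).to_csv(ROOT / "results" / "viability_summary.csv", index=False)
    print("wrote results/viability_summary.csv")


if __name__ == "__main__":
    main()
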