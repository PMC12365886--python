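"""Hill-equation IC50 fits on the synthetic dose-response sets.

Each set was generated around one of the four reported mean inhibitory
concentrations (65.74, 37.44, 65.24 and 42.25 µM); the fit should recover
the generating value within a few percent.  Writes results/ic50_fits.csv.
"""

import pathlib

import pandas as pd

from nanoscreen.doseresponse import DoseResponseData, fit_ic50

ROOT = pathlib.Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"

TRUE_IC50 = {
    "dose_mdamb231_odida": 65.74,
    "dose_mdamb231_aunp": 37.44,
    "dose_mcf7_odida": 65.24,
    "dose_mcf7_aunp": 42.25,
}


def main() -> None:
    rows = []
    for name, truth in TRUE_IC50.items():
        path = DATA / f"{name}.csv"
        if not path.exists():
            print(f"skipping {name}: run 01_simulate_inputs.py first")
            continue
        df = pd.read_csv(path)
        fit = fit_ic50(
            DoseResponseData(
                df["concentration_uM"].to_numpy(float),
                df["viability_pct"].to_numpy(float),
            )
        )
        print(
            f"{name}: IC50 = {fit.ic50_uM:.2f} +/- {fit.ic50_se:.2f} uM "
            f"(true {truth}), h = {fit.hill_coefficient:.2f}, "
            f"R^2 = {fit.r_squared:.4f}"
        )
        rows.append(
            {
                "dataset": name,
                "true_ic50_uM": truth,
                "ic50_uM": round(fit.ic50_uM, 2),
                "ic50_se": round(fit.ic50_se, 2),
                "hill_coefficient": round(fit.hill_coefficient, 3),
                "r_squared": round(fit.r_squared, 4),
                "converged": fit.converged,
            }
        )
    if rows:
        pd.DataFrame(rows).to_csv(ROOT / "results" / "ic50_fits.csv", index=False)
        print("wrote results/ic50_fits.csv")


if __name__ == "__main__":
    main()
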