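"""Generate the synthetic study inputs.

The raw instrument data behind the study — UV–Vis scans of the colloid at
two timepoints, XTT viability plates for two cell lines x two treatments,
and the dose–response replicates behind the IC50 table — are not published.
This script generates seeded stand-ins with the same structure: spectra with
the two measured optical gaps (1.97 eV at 8 min, 1.92 eV at 105 days), a
plasmon band at 520 nm and 0.5% noise; plates with a monotone dose effect
over the control/10/25/50/75/100 µM ladder (9 replicates); and Hill-shaped
dose–response data at the four reported IC50s.

Outputs go to results/data/ as plain CSV.
"""

import pathlib

import pandas as pd

from nanoscreen.simulate import (
    PlateSpec,
    SpectrumSpec,
    generate_dose_response,
    generate_plate,
    generate_spectrum,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

SPECTRA = {
    "spectrum_8min": SpectrumSpec(eg_eV=1.97, seed=101, time_annotation="8 min"),
    "spectrum_105days": SpectrumSpec(eg_eV=1.92, seed=102, time_annotation="105 days"),
}

# plate means chosen to mimic a strong monotone cytotoxic response
PLATES = {
    "plate_mdamb231_odida": PlateSpec(
        group_means_pct=(100.0, 92.0, 80.0, 62.0, 45.0, 32.0), seed=201
    ),
    "plate_mdamb231_aunp": PlateSpec(
        group_means_pct=(100.0, 85.0, 65.0, 45.0, 32.0, 22.0), seed=202
    ),
}

# the four reported IC50s (MDA-MB-231 and MCF-7, compound and nanoparticles)
DOSE_SETS = {
    "dose_mdamb231_odida": (65.74, 1.2, 301),
    "dose_mdamb231_aunp": (37.44, 1.2, 302),
    "dose_mcf7_odida": (65.24, 1.2, 303),
    "dose_mcf7_aunp": (42.25, 1.2, 304),
}


def main() -> None:
    for name, spec in SPECTRA.items():
        generate_spectrum(spec).to_frame().to_csv(OUT / f"{name}.csv", index=False)
        print(f"wrote {name}.csv (Eg = {spec.eg_eV} eV)")
    for name, spec in PLATES.items():
        generate_plate(spec).to_frame().to_csv(OUT / f"{name}.csv", index=False)
        print(f"wrote {name}.csv (means {spec.group_means_pct})")
    for name, (ic50, hill, seed) in DOSE_SETS.items():
        data = generate_dose_response(ic50, hill, seed=seed)
        pd.DataFrame(
            {
                "concentration_uM": data.concentrations_uM,
                "viability_pct": data.viability_pct,
            }
        ).to_csv(OUT / f"{name}.csv", index=False)
        print(f"wrote {name}.csv (true IC50 = {ic50} uM)")


if __name__ == "__main__":
    main()
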