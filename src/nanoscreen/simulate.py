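"""Seeded synthetic inputs with the structure each pipeline stage assumes.

The study's raw instrument files (UV–Vis scans, 96-well absorbances,
dose–response replicates) are not published, so these generators emulate
them:

* a colloidal gold absorption spectrum — a direct-allowed Tauc edge with a
  known optical gap, a Gaussian localized-surface-plasmon band near 520 nm,
  and proportional Gaussian noise;
* a viability plate — a control at 100% plus concentration groups with
  i.i.d. normal replicates around specified means;
* Hill-shaped dose–response data with a known IC50.

Every generator is a pure function of its spec including the seed:
identical specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from nanoscreen.doseresponse import DoseResponseData, hill_model
from nanoscreen.spectra import EV_NM, Spectrum
from nanoscreen.viability import ViabilityGroup, ViabilityPlate

__all__ = [
    "SpectrumSpec",
    "PlateSpec",
    "generate_spectrum",
    "generate_plate",
    "generate_dose_response",
    "DEFAULT_CONCENTRATIONS_UM",
]

#: Concentration ladder of the cytotoxicity design: untreated control plus
#: five doses, 10-100 µM (six groups, i.e. 5 between-group degrees of freedom).
DEFAULT_CONCENTRATIONS_UM: Tuple[Optional[float], ...] = (None, 10.0, 25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of one synthetic UV–Vis spectrum.

    The absorption edge obeys (alpha*E)^2 = tauc_prefactor * (E - eg_eV) for
    photon energies above the gap; the plasmon band is a Gaussian in
    wavelength centred near 520 nm; noise is zero-mean Gaussian with standard
    deviation ``noise_sd_fraction`` of the spectrum peak.
    """

    eg_eV: float = 1.97
    tauc_prefactor: float = 8.0
    plasmon_center_nm: float = 520.0
    plasmon_width_nm: float = 30.0
    plasmon_amplitude: float = 0.30
    noise_sd_fraction: float = 0.005
    wavelength_range_nm: Tuple[float, float] = (350.0, 800.0)
    n_points: int = 451
    seed: int = 0
    label: str = ""
    time_annotation: str = ""

    def __post_init__(self) -> None:
        if self.eg_eV <= 0:
            raise ValueError("eg_eV must be positive")
        lo, hi = self.wavelength_range_nm
        if not 0 < lo < hi:
            raise ValueError("wavelength range must be positive and increasing")
        if EV_NM / lo <= self.eg_eV:
            raise ValueError(
                "wavelength range must reach energies above the band gap"
            )
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be non-negative")


def generate_spectrum(spec: SpectrumSpec) -> Spectrum:
    """Simulate edge + plasmon + noise absorbance on a wavelength grid."""
    lo, hi = spec.wavelength_range_nm
    wl = np.linspace(lo, hi, spec.n_points)
    energy = EV_NM / wl
    edge = np.zeros_like(wl)
    above = energy > spec.eg_eV
    edge[above] = np.sqrt(spec.tauc_prefactor * (energy[above] - spec.eg_eV)) / energy[above]
    plasmon = spec.plasmon_amplitude * np.exp(
        -0.5 * ((wl - spec.plasmon_center_nm) / spec.plasmon_width_nm) ** 2
    )
    clean = edge + plasmon
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd_fraction * clean.max(), size=wl.size)
    absorbance = np.clip(clean + noise, 0.0, None)
    return Spectrum(
        wavelength_nm=wl,
        absorbance=absorbance,
        label=spec.label,
        time_annotation=spec.time_annotation,
    )


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of one synthetic viability plate.

    ``group_means_pct`` lists the control first (must be 100) followed by the
    treatment-group means along the default 10-100 µM concentration ladder;
    each group gets ``n_replicates`` i.i.d. normal draws with common
    ``sd_pct``.  The default means encode a monotone dose-dependent loss of
    viability typical of a cytotoxic treatment.
    """

    group_means_pct: Tuple[float, ...] = (100.0, 90.0, 75.0, 60.0, 45.0, 35.0)
    sd_pct: float = 3.0
    n_replicates: int = 9
    seed: int = 0
    concentrations_uM: Tuple[Optional[float], ...] = DEFAULT_CONCENTRATIONS_UM
    control_label: str = "control"

    def __post_init__(self) -> None:
        if self.group_means_pct[0] != 100.0:
            raise ValueError("control mean (first entry) must be 100")
        if len(self.group_means_pct) != len(self.concentrations_uM):
            raise ValueError("one concentration per group mean required")
        if self.sd_pct < 0:
            raise ValueError("sd_pct must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")


def generate_plate(spec: PlateSpec) -> ViabilityPlate:
    """Simulate replicate viability percentages for each concentration group."""
    rng = np.random.default_rng(spec.seed)
    groups = []
    for mean, conc in zip(spec.group_means_pct, spec.concentrations_uM):
        values = rng.normal(mean, spec.sd_pct, size=spec.n_replicates)
        values = np.clip(values, 0.0, None)
        label = spec.control_label if conc is None else f"{conc:g} uM"
        groups.append(ViabilityGroup(label, conc, values))
    return ViabilityPlate(tuple(groups), spec.control_label)


def generate_dose_response(
    ic50_uM: float,
    hill_coefficient: float,
    concentrations_uM: Sequence[float] = (10.0, 25.0, 50.0, 75.0, 100.0),
    sd_pct: float = 3.0,
    n_replicates: int = 9,
    seed: int = 0,
    top_pct: float = 100.0,
    bottom_pct: float = 0.0,
) -> DoseResponseData:
    """Simulate replicated viabilities around a Hill curve with known IC50."""
    if ic50_uM <= 0 or hill_coefficient <= 0:
        raise ValueError("ic50 and hill coefficient must be positive")
    rng = np.random.default_rng(seed)
    conc = np.repeat(np.asarray(concentrations_uM, dtype=float), n_replicates)
    truth = hill_model(conc, ic50_uM, hill_coefficient, top_pct, bottom_pct)
    noisy = truth + rng.normal(0.0, sd_pct, size=conc.size)
    return DoseResponseData(conc, np.clip(noisy, 0.0, None))
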