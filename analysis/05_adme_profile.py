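"""Descriptor and drug-likeness profile of oDIDA.

Profiles the diimide-diacid from its structure: molecular weight, H-bond
counts, Ertl TPSA, Moriguchi and Wildman–Crippen logP, Lipinski violations,
BOILED-Egg absorption/permeation classes and the six radar-range flags.
Writes results/adme_profile.csv.
"""

import pathlib

import pandas as pd

from nanoscreen.adme import ODIDA_SMILES, profile_molecule

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    profile = profile_molecule(ODIDA_SMILES)
    print(f"oDIDA ({profile.formula}, MW {profile.mw_gmol:.2f} g/mol)")
    print(f"  TPSA           {profile.tpsa_A2:.2f} A^2")
    print(f"  polar atoms    {profile.polar_atoms_NO} (N+O)")
    print(f"  HBD / HBA      {profile.hbd} / {profile.hba}")
    print(f"  MLOGP / WLOGP  {profile.mlogp:.2f} / {profile.wlogp:.2f}")
    print(f"  Lipinski       {profile.lipinski_violations} violation(s)")
    print(f"  GI absorption  {profile.gi_absorption}")
    print(f"  BBB permeant   {profile.bbb_permeant}")
    flags = profile.radar_flags
    out_of_range = [
        k
        for k in ("lipophilicity", "size", "polarity", "solubility", "saturation", "flexibility")
        if not getattr(flags, k)
    ]
    print(f"  radar axes out of drug-like range: {', '.join(out_of_range) or 'none'}")

    out = ROOT / "results" / "adme_profile.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([profile.to_dict()]).to_csv(out, index=False)
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
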