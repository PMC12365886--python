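"""Structure-derived physicochemical descriptors and drug-likeness.

Profiles a small molecule from its SMILES: molecular weight, H-bond donors
and acceptors (rule-of-five N+O convention), Ertl topological polar surface
area, rotatable bonds, sp3 fraction, Wildman–Crippen logP (WLOGP) and the
Moriguchi regression logP (MLOGP).  Classification layers on top:

* Lipinski's rule of five counted over {MW > 500, HBD > 5, HBA > 10,
  MLOGP > 4.15} — the MLOGP arm is the convention of the common web
  profilers and is configurable.
* BOILED-Egg: point-in-ellipse tests in the (TPSA, WLOGP) plane decide
  passive gastrointestinal absorption (white region) and blood–brain-barrier
  permeation (yolk).
* A six-axis drug-likeness radar (lipophilicity, size, polarity, solubility,
  saturation, flexibility) flags whether each descriptor sits in its
  drug-like range.

The worked example throughout the package is oDIDA,
N,N'-(1,2-phenylene)bis(phthalimide-5-carboxylic acid), the aromatic
diimide-diacid used as reducing/stabilising agent for ultrasmall gold
nanoparticles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "ODIDA_SMILES",
    "MoleculeProfile",
    "RadarFlags",
    "DrugLikeness",
    "Ellipse",
    "WHITE_ELLIPSE",
    "YOLK_ELLIPSE",
    "RADAR_RANGES",
    "SmilesParseError",
    "UnsupportedFeatureError",
    "profile_molecule",
    "drug_likeness",
    "moriguchi_logp",
    "esol_log_s",
]

#: N,N'-(1,2-phenylene)bis(phthalimide-5-carboxylic acid): two N-aryl
#: phthalimide units, each bearing one carboxylic acid on the benzo ring,
#: bridged by an ortho-phenylene.  Molecular formula C24H12N2O8.
ODIDA_SMILES = "OC(=O)c1ccc2c(c1)C(=O)N(c1ccccc1N1C(=O)c3ccc(C(=O)O)cc3C1=O)C2=O"


class SmilesParseError(ValueError):
    """The SMILES string could not be parsed into a valence-sane molecule."""


class UnsupportedFeatureError(ValueError):
    """Radicals and isotopic labels are outside the descriptor model."""


@dataclass(frozen=True)
class RadarFlags:
    """Whether each of the six radar descriptors is inside its drug-like range."""

    lipophilicity: bool
    size: bool
    polarity: bool
    solubility: bool
    saturation: bool
    flexibility: bool

    def all_in_range(self) -> bool:
        return all(
            (
                self.lipophilicity,
                self.size,
                self.polarity,
                self.solubility,
                self.saturation,
                self.flexibility,
            )
        )


@dataclass(frozen=True)
class DrugLikeness:
    lipinski_violations: int
    gi_absorption: str  # "high" | "low"
    bbb_permeant: bool
    radar_flags: RadarFlags


@dataclass(frozen=True)
class MoleculeProfile:
    """Descriptor bundle for one structure."""

    smiles: str
    formula: str
    mw_gmol: float
    hbd: int
    hba: int
    polar_atoms_NO: int
    tpsa_A2: float
    rotatable_bonds: int
    fraction_csp3: float
    mlogp: float
    wlogp: float
    esol_log_s: float
    lipinski_violations: int
    gi_absorption: str
    bbb_permeant: bool
    radar_flags: RadarFlags

    def to_dict(self) -> dict:
        d = {
            "smiles": self.smiles,
            "formula": self.formula,
            "mw_gmol": self.mw_gmol,
            "hbd": self.hbd,
            "hba": self.hba,
            "polar_atoms_NO": self.polar_atoms_NO,
            "tpsa_A2": self.tpsa_A2,
            "rotatable_bonds": self.rotatable_bonds,
            "fraction_csp3": self.fraction_csp3,
            "mlogp": self.mlogp,
            "wlogp": self.wlogp,
            "esol_log_s": self.esol_log_s,
            "lipinski_violations": self.lipinski_violations,
            "gi_absorption": self.gi_absorption,
            "bbb_permeant": self.bbb_permeant,
        }
        for k in (
            "lipophilicity",
            "size",
            "polarity",
            "solubility",
            "saturation",
            "flexibility",
        ):
            d[f"radar_{k}"] = getattr(self.radar_flags, k)
        return d


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in the (TPSA, WLOGP) plane."""

    center_tpsa: float
    center_wlogp: float
    semi_tpsa: float
    semi_wlogp: float

    def contains(self, tpsa: float, wlogp: float) -> bool:
        dx = (tpsa - self.center_tpsa) / self.semi_tpsa
        dy = (wlogp - self.center_wlogp) / self.semi_wlogp
        return dx * dx + dy * dy <= 1.0


# BOILED-Egg regions, reconstructed from the published boundary extents of
# the model: passive GI absorption (white) spans TPSA 0–142 and WLOGP
# -2.18–6.82; BBB permeation (yolk) spans TPSA up to 79.4 and WLOGP 0.4–6.0.
WHITE_ELLIPSE = Ellipse(center_tpsa=71.0, center_wlogp=2.32, semi_tpsa=71.0, semi_wlogp=4.50)
YOLK_ELLIPSE = Ellipse(center_tpsa=38.1, center_wlogp=3.20, semi_tpsa=41.3, semi_wlogp=2.81)

#: Drug-like ranges for the six radar axes (inclusive bounds).
RADAR_RANGES: Dict[str, Tuple[float, float]] = {
    "lipophilicity": (-0.7, 5.0),  # logP estimate (WLOGP here)
    "size": (150.0, 500.0),  # MW, g/mol
    "polarity": (20.0, 130.0),  # TPSA, A^2
    "solubility": (-6.0, 0.0),  # ESOL log S
    "saturation": (0.25, 1.0),  # fraction Csp3
    "flexibility": (0.0, 9.0),  # rotatable bonds
}

#: Lipinski rule-of-five thresholds; the logP arm uses MLOGP.
LIPINSKI_THRESHOLDS = {"mw": 500.0, "hbd": 5, "hba": 10, "mlogp": 4.15}


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() > 0:
            raise UnsupportedFeatureError(
                f"radical at atom index {atom.GetIdx()} is not supported"
            )
        if atom.GetIsotope() != 0:
            raise UnsupportedFeatureError(
                f"isotopic label at atom index {atom.GetIdx()} is not supported"
            )
    return mol


# --- Moriguchi logP -------------------------------------------------------

_HALOGEN_WEIGHT = {9: 0.5, 17: 1.0, 35: 1.5, 53: 2.0}

_SMARTS = {
    "amide": Chem.MolFromSmarts("[CX3](=O)[#7]"),
    "sulfonamide": Chem.MolFromSmarts("[SX4](=O)(=O)[#7]"),
    "nitro": Chem.MolFromSmarts("[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    "quaternary_n": Chem.MolFromSmarts("[NX4+,NX4]"),
    "n_oxide": Chem.MolFromSmarts("[#7+][O-]"),
    "ncs": Chem.MolFromSmarts("N=C=S"),
    "scn": Chem.MolFromSmarts("SC#N"),
    "beta_lactam": Chem.MolFromSmarts("O=C1CCN1"),
    "alpha_amino_acid": Chem.MolFromSmarts("[NX3;H2,H1][CX4][CX3](=O)[OX2H1]"),
    "amino_benzoic": Chem.MolFromSmarts("[NX3;H2,H1]c1ccccc1[CX3](=O)[OX2H1]"),
    "pyridine_carboxylic": Chem.MolFromSmarts("[OX2H1][CX3](=O)c1ccncc1"),
    "hb_donor": Chem.MolFromSmarts("[OX2H,NX3;H1,H2]"),
}


def _unsaturated_bonds(mol: Chem.Mol) -> int:
    """Double + triple bonds in a Kekulé structure, excluding nitro N=O."""
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro_atoms = set()
    for match in kek.GetSubstructMatches(_SMARTS["nitro"]):
        nitro_atoms.update(match)
    count = 0
    for bond in kek.GetBonds():
        if bond.GetBondType() not in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if {a.GetIdx(), b.GetIdx()} <= nitro_atoms and {
            a.GetAtomicNum(),
            b.GetAtomicNum(),
        } == {7, 8}:
            continue
        count += 1
    return count


def _proximity(mol: Chem.Mol) -> float:
    """N/O proximity: +2 per bonded N/O pair, +1 per N/O pair bridged by one
    C/S/P atom, with -1 per carboxamide or sulfonamide group."""
    polar = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    dmat = Chem.GetDistanceMatrix(mol)
    prx = 0.0
    for i, ai in enumerate(polar):
        for aj in polar[i + 1 :]:
            d = dmat[ai][aj]
            if d == 1:
                prx += 2.0
            elif d == 2:
                path = Chem.GetShortestPath(mol, ai, aj)
                if mol.GetAtomWithIdx(path[1]).GetAtomicNum() in (6, 16, 15):
                    prx += 1.0
    n_amide = len(mol.GetSubstructMatches(_SMARTS["amide"]))
    n_sulfonamide = len(mol.GetSubstructMatches(_SMARTS["sulfonamide"]))
    return prx - (n_amide + n_sulfonamide)


def _aromatic_polar_substituents(mol: Chem.Mol) -> int:
    """Substituent attachments on aromatic carbons whose group is polar.

    Polar means the first substituent atom is N or O, or is a carbon with an
    N/O within two bonds of the attachment (carboxyl, carbonyl, amide...).
    """
    count = 0
    for atom in mol.GetAtoms():
        if not atom.GetIsAromatic() or atom.GetAtomicNum() != 6:
            continue
        for nb in atom.GetNeighbors():
            bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx())
            if bond.GetIsAromatic():
                continue
            if nb.GetIsAromatic() and nb.IsInRing():
                continue  # biaryl link, not a substituent group
            z = nb.GetAtomicNum()
            if z in (7, 8):
                count += 1
            elif z == 6:
                if any(
                    nb2.GetAtomicNum() in (7, 8)
                    for nb2 in nb.GetNeighbors()
                    if nb2.GetIdx() != atom.GetIdx()
                ):
                    count += 1
    return count


def _intramolecular_hbond(mol: Chem.Mol) -> bool:
    """Ortho donor/acceptor pairs on an aromatic ring (salicylate-like)."""
    donors = {m[0] for m in mol.GetSubstructMatches(_SMARTS["hb_donor"])}
    if not donors:
        return False
    for bond in mol.GetBonds():
        if not bond.GetIsAromatic():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for first, second in ((a, b), (b, a)):
            has_donor = any(
                nb.GetIdx() in donors and not nb.GetIsAromatic()
                for nb in first.GetNeighbors()
            )
            if not has_donor:
                continue
            for nb in second.GetNeighbors():
                if nb.GetIsAromatic():
                    continue
                if nb.GetAtomicNum() in (7, 8):
                    return True
                if nb.GetAtomicNum() == 6 and any(
                    nb2.GetAtomicNum() == 8 for nb2 in nb.GetNeighbors()
                ):
                    return True
    return False


def moriguchi_logp(mol_or_smiles) -> float:
    """Moriguchi regression logP (MLOGP).

    MLOGP = -1.014 + 1.244*CX^0.6 - 1.017*NO^0.9 + 0.406*PRX - 0.145*UB^0.8
            + 0.511*HB + 0.268*POL - 2.215*AMP + 0.912*ALK - 0.392*RNG
            - 3.684*QN + 0.474*NO2 + 1.582*NCS + 0.773*BLM

    where CX weights carbons and halogens (F 0.5, Cl 1, Br 1.5, I 2), NO is
    the nitrogen+oxygen count, PRX the N/O proximity term, UB the number of
    unsaturated bonds, and the remaining terms are structural indicators
    (intramolecular H-bond, aromatic polar substituents, amphoteric motifs,
    pure hydrocarbons, non-benzenoid rings, quaternary N, nitro, thiocyanate,
    beta-lactam).
    """
    mol = _parse(mol_or_smiles) if isinstance(mol_or_smiles, str) else mol_or_smiles

    cx = 0.0
    no = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 6:
            cx += 1.0
        elif z in _HALOGEN_WEIGHT:
            cx += _HALOGEN_WEIGHT[z]
        elif z in (7, 8):
            no += 1

    prx = _proximity(mol)
    ub = _unsaturated_bonds(mol)
    hb = 1.0 if _intramolecular_hbond(mol) else 0.0
    pol = _aromatic_polar_substituents(mol)

    amp = 0.0
    if mol.HasSubstructMatch(_SMARTS["alpha_amino_acid"]):
        amp = 1.0
    elif mol.HasSubstructMatch(_SMARTS["amino_benzoic"]) or mol.HasSubstructMatch(
        _SMARTS["pyridine_carboxylic"]
    ):
        amp = 0.5

    only_ch = all(a.GetAtomicNum() in (1, 6) for a in mol.GetAtoms())
    aromatic = any(a.GetIsAromatic() for a in mol.GetAtoms())
    alk = 1.0 if (only_ch and not aromatic and ub <= 1) else 0.0

    ring_info = mol.GetRingInfo()
    rng = 0.0
    for ring in ring_info.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() and a.GetAtomicNum() == 6 for a in atoms):
            rng = 1.0
            break

    qn = 0.0
    if mol.HasSubstructMatch(_SMARTS["quaternary_n"]):
        qn = 1.0
    elif mol.HasSubstructMatch(_SMARTS["n_oxide"]):
        qn = 0.5
    no2 = len(mol.GetSubstructMatches(_SMARTS["nitro"]))
    ncs = 0.0
    if mol.HasSubstructMatch(_SMARTS["ncs"]):
        ncs = 1.0
    elif mol.HasSubstructMatch(_SMARTS["scn"]):
        ncs = 0.5
    blm = 1.0 if mol.HasSubstructMatch(_SMARTS["beta_lactam"]) else 0.0

    return (
        -1.014
        + 1.244 * cx**0.6
        - 1.017 * no**0.9
        + 0.406 * prx
        - 0.145 * ub**0.8
        + 0.511 * hb
        + 0.268 * pol
        - 2.215 * amp
        + 0.912 * alk
        - 0.392 * rng
        - 3.684 * qn
        + 0.474 * no2
        + 1.582 * ncs
        + 0.773 * blm
    )


def esol_log_s(mol: Chem.Mol, wlogp: Optional[float] = None) -> float:
    """ESOL aqueous solubility estimate (log mol/L), used as the radar
    solubility proxy:  log S = 0.16 - 0.63 logP - 0.0062 MW + 0.066 RB
    - 0.74 AP, with AP the aromatic heavy-atom proportion."""
    if wlogp is None:
        wlogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Lipinski.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = (
        sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    )
    return 0.16 - 0.63 * wlogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


# --- Profiling ------------------------------------------------------------


def _in_range(value: float, key: str) -> bool:
    lo, hi = RADAR_RANGES[key]
    return lo <= value <= hi


def _classify(
    mw: float, hbd: int, hba: int, mlogp: float, wlogp: float, tpsa: float,
    log_s: float, fsp3: float, rotb: int,
) -> DrugLikeness:
    violations = sum(
        (
            mw > LIPINSKI_THRESHOLDS["mw"],
            hbd > LIPINSKI_THRESHOLDS["hbd"],
            hba > LIPINSKI_THRESHOLDS["hba"],
            mlogp > LIPINSKI_THRESHOLDS["mlogp"],
        )
    )
    gi = "high" if WHITE_ELLIPSE.contains(tpsa, wlogp) else "low"
    bbb = YOLK_ELLIPSE.contains(tpsa, wlogp)
    flags = RadarFlags(
        lipophilicity=_in_range(wlogp, "lipophilicity"),
        size=_in_range(mw, "size"),
        polarity=_in_range(tpsa, "polarity"),
        solubility=_in_range(log_s, "solubility"),
        saturation=_in_range(fsp3, "saturation"),
        flexibility=_in_range(rotb, "flexibility"),
    )
    return DrugLikeness(
        lipinski_violations=int(violations),
        gi_absorption=gi,
        bbb_permeant=bool(bbb),
        radar_flags=flags,
    )


def profile_molecule(smiles: str) -> MoleculeProfile:
    """Compute the full descriptor and drug-likeness profile for one SMILES.

    Raises :class:`SmilesParseError` for unparsable input and
    :class:`UnsupportedFeatureError` for radicals or isotopic labels.
    """
    mol = _parse(smiles)
    mw = float(Descriptors.MolWt(mol))
    hbd = int(Lipinski.NHOHCount(mol))
    polar_no = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    hba = polar_no  # rule-of-five N+O acceptor convention
    tpsa = float(Descriptors.TPSA(mol))
    rotb = int(Lipinski.NumRotatableBonds(mol))
    fsp3 = float(rdMolDescriptors.CalcFractionCSP3(mol))
    wlogp = float(Crippen.MolLogP(mol))
    mlogp = float(moriguchi_logp(mol))
    log_s = float(esol_log_s(mol, wlogp))
    dl = _classify(mw, hbd, hba, mlogp, wlogp, tpsa, log_s, fsp3, rotb)
    return MoleculeProfile(
        smiles=smiles,
        formula=rdMolDescriptors.CalcMolFormula(mol),
        mw_gmol=mw,
        hbd=hbd,
        hba=hba,
        polar_atoms_NO=polar_no,
        tpsa_A2=tpsa,
        rotatable_bonds=rotb,
        fraction_csp3=fsp3,
        mlogp=mlogp,
        wlogp=wlogp,
        esol_log_s=log_s,
        lipinski_violations=dl.lipinski_violations,
        gi_absorption=dl.gi_absorption,
        bbb_permeant=dl.bbb_permeant,
        radar_flags=dl.radar_flags,
    )


def drug_likeness(profile: MoleculeProfile) -> DrugLikeness:
    """Re-derive the classification layer from an existing descriptor profile."""
    return _classify(
        profile.mw_gmol,
        profile.hbd,
        profile.hba,
        profile.mlogp,
        profile.wlogp,
        profile.tpsa_A2,
        profile.esol_log_s,
        profile.fraction_csp3,
        profile.rotatable_bonds,
    )
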