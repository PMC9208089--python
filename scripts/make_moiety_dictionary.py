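"""Build src/panmoiety/data/moieties.tsv and validate it with RDKit."""
import csv
from pathlib import Path

from rdkit import Chem

# Functional-group block f-1..f-204 (Checkmol-style names; best-effort SMARTS
# for common groups, placeholders elsewhere).
FG = {
    1: ("alkene", "[CX3]=[CX3]"),
    2: ("alkyne", "[CX2]#[CX2]"),
    3: ("carbonyl group", "[CX3]=[OX1]"),
    4: ("aldehyde", "[CX3H1](=O)[#6]"),
    5: ("ketone", "[#6][CX3](=O)[#6]"),
    6: ("thiocarbonyl group", "[#6X3]=[SX1]"),
    7: ("imine", "[CX3]=[NX2]"),
    9: ("oxime", "[CX3]=[NX2][OX2H]"),
    12: ("acetal", "[CX4]([OX2][#6])[OX2][#6]"),
    15: ("alcohol", "[OX2H][CX4]"),
    16: ("primary alcohol", "[OX2H][CX4H2]"),
    17: ("secondary alcohol", "[OX2H][CX4H1]"),
    18: ("tertiary alcohol", "[OX2H][CX4D4]"),
    20: ("phenol", "[OX2H]c"),
    22: ("enol", "[OX2H][CX3]=[CX3]"),
    27: ("carboxylic acid", "[CX3](=O)[OX2H1]"),
    30: ("carboxylic acid ester", "[CX3](=O)[OX2H0][#6]"),
    32: ("lactone", "[CX3]1(=O)[OX2][#6][#6]1"),
    37: ("ether", "[OD2]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]"),
    40: ("peroxide", "[OX2][OX2]"),
    43: ("thiol", "[SX2H][#6]"),
    44: ("thioether", "[SX2]([#6])[#6]"),
    45: ("disulfide", "[SX2][SX2]"),
    47: ("amine", "[NX3;!$([NX3][CX3]=[OX1]);!$([NX3]=*)]"),
    48: ("primary aliphatic amine", "[NX3;H2][CX4]"),
    50: ("primary aromatic amine", "[NX3;H2]c"),
    51: ("secondary aliphatic amine", "[NX3;H1]([CX4])[CX4]"),
    54: ("secondary amine", "[NX3;H1]([#6])[#6]"),
    56: ("tertiary amine", "[NX3;H0;!$([NX3][CX3]=[OX1]);!$([NX3]=*)]([#6])([#6])[#6]"),
    58: ("quaternary ammonium", "[NX4+]"),
    60: ("hydroxylamine", "[NX3][OX2H]"),
    61: ("hydrazine derivative", "[NX3][NX3]"),
    63: ("nitrile", "[CX2]#[NX1]"),
    65: ("nitro group", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    67: ("aryl chloride", "c[Cl]"),
    68: ("alkyl halide", "[CX4][F,Cl,Br,I]"),
    69: ("aryl halide", "c[F,Cl,Br,I]"),
    70: ("aryl fluoride", "c[F]"),
    75: ("azide", "[NX2]=[NX2+]=[NX1-]"),
    78: ("azo group", "[#6][NX2]=[NX2][#6]"),
    82: ("carboxamide", "[CX3](=[OX1])[NX3]"),
    84: ("primary amide", "[CX3](=[OX1])[NX3H2]"),
    87: ("secondary amide", "[CX3](=[OX1])[NX3;H1]"),
    88: ("tertiary amide", "[CX3](=[OX1])[NX3;H0]"),
    90: ("lactam", "[NX3]1[CX3](=[OX1])[#6][#6]1"),
    93: ("carbamate", "[NX3][CX3](=[OX1])[OX2][#6]"),
    96: ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    99: ("thiourea", "[NX3][CX3](=[SX1])[NX3]"),
    102: ("amidine", "[NX3][CX3]=[NX2]"),
    110: ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    118: ("sulfonic acid", "[SX4](=[OX1])(=[OX1])[OX2H]"),
    120: ("sulfonamide", "[SX4](=[OX1])(=[OX1])[NX3]"),
    122: ("sulfone", "[#6][SX4](=[OX1])(=[OX1])[#6]"),
    124: ("sulfoxide", "[#6][SX3](=[OX1])[#6]"),
    130: ("phosphoric acid ester", "[PX4](=[OX1])([OX2])([OX2])[OX2]"),
    140: ("boronic acid", "[BX3]([OX2H])[OX2H]"),
    150: ("trifluoromethyl group", "[CX4](F)(F)F"),
}

# Ring-moiety block f-205..f-238, classed by typical ATP-site interaction.
RINGS = [
    ("benzene", "c1ccccc1", "vdW", "c1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1", "vdW", "c1ccc2ccccc2c1"),
    ("cyclopropane", "C1CC1", "vdW", "C1CC1"),
    ("cyclopentane", "C1CCCC1", "vdW", "C1CCCC1"),
    ("cyclohexane", "C1CCCCC1", "vdW", "C1CCCCC1"),
    ("cycloheptane", "C1CCCCCC1", "vdW", "C1CCCCCC1"),
    ("thiophene", "c1ccsc1", "vdW", "c1ccsc1"),
    ("benzothiophene", "c1ccc2sccc2c1", "vdW", "c1ccc2sccc2c1"),
    ("pyrrole", "c1cc[nH]c1", "hydrogen-bonding", "c1cc[nH]c1"),
    ("furan", "c1ccoc1", "hydrogen-bonding", "c1ccoc1"),
    ("imidazole", "c1c[nH]cn1", "hydrogen-bonding", "c1c[nH]cn1"),
    ("pyrazole", "c1cc[nH]n1", "hydrogen-bonding", "c1cc[nH]n1"),
    ("oxazole", "c1ocnc1", "hydrogen-bonding", "c1ocnc1"),
    ("isoxazole", "c1conc1", "hydrogen-bonding", "c1conc1"),
    ("thiazole", "c1cscn1", "hydrogen-bonding", "c1cscn1"),
    ("1,2,3-triazole", "c1c[nH]nn1", "hydrogen-bonding", "c1c[nH]nn1"),
    ("tetrazole", "c1nnn[nH]1", "electrostatic", "c1nnn[nH]1"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]", "electrostatic", "NC(=N)N"),
    ("carboxylate", "[CX3](=[OX1])[OX1-]", "electrostatic", "CC(=O)[O-]"),
    ("pyridine", "c1ccncc1", "hydrogen-bonding", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1", "hydrogen-bonding", "c1cncnc1"),
    ("pyrazine", "c1cnccn1", "hydrogen-bonding", "c1cnccn1"),
    ("pyridazine", "c1ccnnc1", "hydrogen-bonding", "c1ccnnc1"),
    ("morpholine", "C1COCCN1", "hydrogen-bonding", "C1COCCN1"),
    ("indole", "c1ccc2[nH]ccc2c1", "hydrogen-bonding+vdW", "c1ccc2[nH]ccc2c1"),
    ("7-azaindole", "c1ccc2cc[nH]c2n1", "hydrogen-bonding+vdW", "c1ccc2cc[nH]c2n1"),
    ("benzimidazole", "c1ccc2[nH]cnc2c1", "hydrogen-bonding+vdW", "c1ccc2[nH]cnc2c1"),
    ("indazole", "c1ccc2[nH]ncc2c1", "hydrogen-bonding+vdW", "c1ccc2[nH]ncc2c1"),
    ("purine", "c1ncc2[nH]cnc2n1", "hydrogen-bonding+vdW", "c1ncc2[nH]cnc2n1"),
    ("quinoline", "c1ccc2ncccc2c1", "hydrogen-bonding+vdW", "c1ccc2ncccc2c1"),
    ("isoquinoline", "c1ccc2cnccc2c1", "hydrogen-bonding+vdW", "c1ccc2cnccc2c1"),
    ("quinazoline", "c1ccc2ncncc2c1", "hydrogen-bonding+vdW", "c1ccc2ncncc2c1"),
    ("benzofuran", "c1ccc2occc2c1", "hydrogen-bonding+vdW", "c1ccc2occc2c1"),
    ("pteridine", "c1cnc2ncncc2n1", "hydrogen-bonding+vdW", "c1cnc2ncncc2n1"),
]
assert len(RINGS) == 34

rows = []
for i in range(1, 205):
    if i in FG:
        name, smarts = FG[i]
        pat = Chem.MolFromSmarts(smarts)
        assert pat is not None, (i, smarts)
        rows.append((f"f-{i}", name, smarts, "unclassified"))
    else:
        rows.append((f"f-{i}", f"functional group {i} (Checkmol only)", "", "unclassified"))
for k, (name, smarts, klass, exemplar) in enumerate(RINGS):
    fid = f"f-{205 + k}"
    pat = Chem.MolFromSmarts(smarts)
    assert pat is not None, (fid, smarts)
    mol = Chem.MolFromSmiles(exemplar)
    assert mol is not None, (fid, exemplar)
    assert mol.HasSubstructMatch(pat), f"{fid} {name}: exemplar does not match"
    rows.append((fid, name, smarts, klass))

assert rows[223][0] == "f-224" and rows[223][1] == "pyridine"
assert rows[224][0] == "f-225" and rows[224][1] == "pyrimidine"

# cross-checks: exemplars of the 6-membered single-heteroring patterns are
# mutually exclusive
azines = [r for r in RINGS if r[0] in ("benzene", "pyridine", "pyrimidine", "pyrazine", "pyridazine")]
for n1, s1, _, e1 in azines:
    for n2, s2, _, _ in azines:
        m = Chem.MolFromSmiles(e1)
        hit = m.HasSubstructMatch(Chem.MolFromSmarts(s2))
        assert hit == (n1 == n2), (n1, n2, hit)

out = Path(__file__).resolve().parents[1] / "src" / "panmoiety" / "data" / "moieties.tsv"
out.parent.mkdir(parents=True, exist_ok=True)
with out.open("w", newline="") as fh:
    w = csv.writer(fh, delimiter="\t")
    w.writerow(["feature_id", "name", "smarts", "interaction_class"])
    w.writerows(rows)
print(f"wrote {out} with {len(rows)} entries")
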