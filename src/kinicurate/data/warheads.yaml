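# Default covalent-warhead registry: 14 reactive-group classes commonly used
# for targeted covalent inhibition, each with the nucleophilic residue side
# chains it typically engages.  The registry is editable data, not code:
# patterns can be tightened or extended without touching the scanner.
# positive_control / negative_control are minimal example molecules used by
# the self-test panel (the negative is the matched saturated/blocked analogue).
- name: acrylamide
  smarts: "[CX3;!R]=[CX3;!R][CX3](=[OX1])[NX3]"
  residues: [Cys, Lys, Ser, Thr]
  positive_control: "C=CC(=O)Nc1ccccc1"
  negative_control: "CCC(=O)Nc1ccccc1"
- name: heterocyclic urea
  smarts: "[NX3;R][CX3;!R](=[OX1])[NX3]"
  residues: [Ser, Thr]
  positive_control: "O=C(Nc1ccccc1)N1CCCCC1"
  negative_control: "CNC(=O)Nc1ccccc1"
- name: vinyl sulfone
  smarts: "[CX3;!R]=[CX3][SX4](=[OX1])(=[OX1])"
  residues: [Cys]
  positive_control: "C=CS(=O)(=O)c1ccccc1"
  negative_control: "CCS(=O)(=O)c1ccccc1"
- name: propiolamide
  smarts: "[CX2]#[CX2][CX3](=[OX1])[NX3]"
  residues: [Cys]
  positive_control: "C#CC(=O)Nc1ccccc1"
  negative_control: "CC(=O)Nc1ccccc1"
- name: chloroacetamide
  smarts: "[Cl,Br,I][CH2X4][CX3](=[OX1])[NX3]"
  residues: [Cys]
  positive_control: "ClCC(=O)Nc1ccccc1"
  negative_control: "ClCCC(=O)Nc1ccccc1"
- name: alpha-haloketone
  smarts: "[Cl,Br,I][CH2X4][CX3](=[OX1])[#6]"
  residues: [Cys, His]
  positive_control: "ClCC(=O)c1ccccc1"
  negative_control: "CC(=O)c1ccccc1"
- name: epoxide
  smarts: "[CX4]1[OX2][CX4]1"
  residues: [Cys, Asp, Glu]
  positive_control: "c1ccccc1OCC1CO1"
  negative_control: "c1ccccc1OCC1CCO1"
- name: aziridine
  smarts: "[CX4]1[NX3][CX4]1"
  residues: [Cys, Asp, Glu]
  positive_control: "C1CN1Cc1ccccc1"
  negative_control: "C1CCN(Cc2ccccc2)C1"
- name: maleimide
  smarts: "[OX1]=[CX3]1[CX3]=[CX3][CX3](=[OX1])[NX3]1"
  residues: [Cys]
  positive_control: "O=C1C=CC(=O)N1c1ccccc1"
  negative_control: "O=C1CCC(=O)N1c1ccccc1"
- name: aldehyde
  smarts: "[CX3H1](=[OX1])[#6]"
  residues: [Cys, Ser, Lys]
  positive_control: "O=Cc1ccccc1"
  negative_control: "COC(=O)c1ccccc1"
- name: nitrile
  smarts: "[#6][CX2]#[NX1]"
  residues: [Cys, Ser]
  positive_control: "N#Cc1ccccc1"
  negative_control: "NCc1ccccc1"
- name: boronic acid
  smarts: "[BX3]([OX2H])[OX2H]"
  residues: [Ser]
  positive_control: "OB(O)c1ccccc1"
  negative_control: "COB(OC)c1ccccc1"
- name: sulfonyl fluoride
  smarts: "[SX4](=[OX1])(=[OX1])[FX1]"
  residues: [Ser, Thr, Tyr, Lys]
  positive_control: "O=S(=O)(F)c1ccccc1"
  negative_control: "CS(=O)(=O)Nc1ccccc1"
- name: haloheteroarene
  smarts: "[F,Cl,Br][c;$(c[n])]"
  residues: [Cys]
  positive_control: "Clc1ccccn1"
  negative_control: "Clc1ccccc1"
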