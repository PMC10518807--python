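# Building blocks for the synthetic corpus generator.
#
# cores: drug-like kinase-inhibitor scaffolds with numbered attachment points
#   ([*:1], [*:2]) placed on aromatic carbons.  Every substituent below binds
#   through an atom (N, O or aromatic C) whose bond to the scaffold matches one
#   of the shipped retrosynthetic fragmentation rules, so a planted series is
#   always recoverable by the compound-core relationship engine.
# substituents: chemically benign R-groups (no reactive warhead environments).
#   "H" caps a site with hydrogen.
# warhead_substituents: R-groups that carry a registry warhead; the generator
#   uses these to plant covalent inhibitors and records the class planted.
# singletons: standalone molecules structurally unrelated to every core, used
#   to plant compounds without analogues.
cores:
  - "[*:1]c1ccc(Nc2ncnc3cc([*:2])ccc23)cc1"
  - "[*:1]c1ccc(Nc2nccc(-c3cccc([*:2])c3)n2)cc1"
  - "[*:1]c1ccc2[nH]c(-c3ccc([*:2])cc3)nc2c1"
  - "[*:1]c1ccc2[nH]nc(-c3ccc([*:2])cc3)c2c1"
  - "O=C(Nc1ccc([*:1])cc1)c1ccc([*:2])cc1"
  - "[*:1]c1ccc(CN2CCN(c3ccc([*:2])cc3)CC2)cc1"
  - "[*:1]c1ccc2nc(-c3ccc([*:2])cc3)ccc2c1"
  - "Nc1ncnc2c1ncn2-c1ccc([*:1])cc1"
  - "Cc1nc([*:1])sc1-c1ccc([*:2])cc1"
  - "[*:1]c1ccc(Oc2ccc(NC(=O)C3CC3)cc2)cc1"
  - "[*:1]c1ccc(-c2nnc(NC3CCCCC3)s2)cc1"
  - "[*:1]c1ccc(C(=O)N2CCC(O)CC2)cc1[*:2]"
  - "[*:1]c1cnc2ccc(NC(=O)C3CCC3)cc2c1"
  - "[*:1]c1ccc(-n2ccc3cc([*:2])ccc32)cc1"
  - "[*:1]c1ccc(S(=O)(=O)N2CCOCC2)cc1[*:2]"
  - "[*:1]c1ccc(-c2csc(NC(C)=O)n2)cc1"
  - "[*:1]c1ccc(NC(=O)c2ccc3ccccc3c2)cc1"
  - "[*:1]c1ccc2oc(-c3ccc([*:2])cc3)nc2c1"
  - "[*:1]c1ccc(-c2nc3ccccc3s2)cc1"
  - "[*:1]c1ccc(C(=O)Nc2ccc3ncccc3c2)cc1"
  - "[*:1]c1ccc(-c2cc3ccccc3[nH]2)cc1"
  - "[*:1]c1ccc(Nc2ncccc2C(N)=O)cc1"
  - "[*:1]c1ccc(-c2noc(C3CCOCC3)n2)cc1"
  - "[*:1]c1ccc(N2CCN(C(=O)C3CC3)CC2)cc1"
substituents:
  - "[*]N(C)C"
  - "[*]NC"
  - "[*]NCC"
  - "[*]NC(C)C"
  - "[*]NC(C)CC"
  - "[*]NCCO"
  - "[*]NC1CC1"
  - "[*]N1CCCC1"
  - "[*]N1CCOCC1"
  - "[*]NC(=O)C"
  - "[*]NC(C)=O"
  - "[*]OC"
  - "[*]OCC"
  - "[*]OC(C)C"
  - "[*]OC(C)CC"
  - "[*]OCCOC"
  - "[*]OCCN(C)C"
  - "[*]OCCC"
  - "[*]c1ccccc1"
  - "[*]c1ccc(C)cc1"
  - "[*]c1ccc(OC)cc1"
  - "[*]c1ccncc1"
  - "[*]c1cccnc1"
  - "[*]c1ccco1"
  - "[*]c1cccs1"
  - "[*]c1ccc(N(C)C)cc1"
  - "[*]c1ccc(CC)cc1"
  - "[*]N(CC)CC"
  - "[*]NCC(C)C"
  - "H"
warhead_substituents:
  - smiles: "[*]NC(=O)C=C"
    warhead: acrylamide
  - smiles: "[*]NC(=O)CCl"
    warhead: chloroacetamide
  - smiles: "[*]NC(=O)C#C"
    warhead: propiolamide
  - smiles: "[*]N1CC1"
    warhead: aziridine
  - smiles: "[*]NS(=O)(=O)C=C"
    warhead: vinyl sulfone
  - smiles: "[*]NC(=O)N1CCCC1"
    warhead: heterocyclic urea
singletons:
  - "CC(C)Cc1ccc(C(C)C(=O)O)cc1"
  - "CC(=O)Oc1ccccc1C(=O)O"
  - "Cn1c(=O)c2c(ncn2C)n(C)c1=O"
  - "OCC1OC(O)C(O)C(O)C1O"
  - "NC12CC3CC(CC(C3)C1)C2"
  - "O=C1CCCCCN1"
  - "c1ccc2c(c1)ccc1ccccc12"
  - "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O"
  - "OC(=O)C1CCCCC1"
  - "c1ccc(-c2ccccc2)cc1"
  - "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1"
  - "OCCN1CCN(CCO)CC1"
  - "CC1(C)OC(=O)N(c2ccccc2)C1=O"
  - "C1CCC2(CC1)OCCO2"
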