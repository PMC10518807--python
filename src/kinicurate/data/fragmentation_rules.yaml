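# Retrosynthetic bond environments used by the compound-core relationship
# fragmenter.  Each rule is a SMARTS pattern plus the (0-based) indices of the
# two matched atoms whose connecting bond is cleaved.  Only acyclic single
# bonds between heavy atoms are ever cut; that constraint is enforced by the
# engine, so the patterns here only describe the chemical environment.
- name: amide
  smarts: "[CX3](=[OX1])[NX3]"
  bond: [0, 2]
- name: ester
  smarts: "[CX3](=[OX1])[OX2][#6]"
  bond: [0, 2]
- name: aliphatic amine
  smarts: "[NX3;!$([NX3][CX3]=[OX1]);!$([NX3][SX4](=[OX1])=[OX1])][CX4]"
  bond: [0, 1]
- name: aryl nitrogen
  smarts: "[c][NX3]"
  bond: [0, 1]
- name: ether
  smarts: "[#6][OX2;!$([OX2][CX3]=[OX1])][#6]"
  bond: [0, 1]
- name: sulfonamide
  smarts: "[SX4](=[OX1])(=[OX1])[NX3]"
  bond: [0, 3]
- name: biaryl
  smarts: "[c;R]-[c;R]"
  bond: [0, 1]
- name: aromatic nitrogen to aliphatic carbon
  smarts: "[n][CX4]"
  bond: [0, 1]
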