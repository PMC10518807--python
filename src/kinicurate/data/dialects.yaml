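# Column-mapping presets for the two supported export dialects.
# Keys on the left are the pipeline's internal field names; values are the
# column headers expected in the input TSV.  Both presets are frozen here
# rather than hard-coded so that locally customized exports can be ingested
# by pointing --dialect-config at an edited copy.
chembl:
  record_id: activity_id
  smiles: canonical_smiles
  uniprot: accession
  target_category: target_type
  confidence_score: confidence_score
  measurement_type: standard_type
  relation: standard_relation
  value: standard_value
  units: standard_units
  activity_comment: activity_comment
  activity_label: activity_label

bindingdb:
  record_id: reactant_set_id
  smiles: ligand_smiles
  uniprot: uniprot_id
  measurement_type: measurement_type
  relation: relation
  value: value_nM
  n_chains: n_protein_chains
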