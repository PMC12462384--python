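# Default descriptor configuration (dimension 8831).
blocks: [AAC, DPC, TPC, CKSAAGP, PHYSCHEM, ATOMIC, LENGTH]
cksaagp_grouping:
  ALI: GAVLMI     # aliphatic
  ARO: FYW        # aromatic
  PC: KRH         # positively charged
  NC: DE          # negatively charged
  PNC: STCPNQ    # polar non-charged
cksaagp_max_gap: 15
pka_table:
  n_term: 8.6
  c_term: 3.6
  side_chains: {K: 10.8, R: 12.5, H: 6.5, D: 3.9, E: 4.1, C: 8.5, Y: 10.1}
gravy_scale: kyte-doolittle
hydrophobicity_scale: eisenberg
net_charge_ph: 7.0
normalize_by: length
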