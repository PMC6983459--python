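# ACMG/AMP 2015 evidence-combining rules, transcribed as data so rule
# provenance is auditable.  Each rule gives MINIMUM counts per evidence
# category (PVS = very strong pathogenic, PS = strong, PM = moderate,
# PP = supporting; BA = stand-alone benign, BS = strong, BP = supporting).
# Rules are checked in order within each class list; the first match is
# reported.  "1-2 moderate" style ranges reduce to a minimum of 1 under
# min-count semantics.
pathogenic:
  - {id: P-ia,   PVS: 1, PS: 1}
  - {id: P-ib,   PVS: 1, PM: 2}
  - {id: P-ic,   PVS: 1, PM: 1, PP: 1}
  - {id: P-id,   PVS: 1, PP: 2}
  - {id: P-ii,   PS: 2}
  - {id: P-iiia, PS: 1, PM: 3}
  - {id: P-iiib, PS: 1, PM: 2, PP: 2}
  - {id: P-iiic, PS: 1, PM: 1, PP: 4}
likely_pathogenic:
  - {id: LP-i,   PVS: 1, PM: 1}
  - {id: LP-ii,  PS: 1, PM: 1}
  - {id: LP-iii, PS: 1, PP: 2}
  - {id: LP-iv,  PM: 3}
  - {id: LP-v,   PM: 2, PP: 2}
  - {id: LP-vi,  PM: 1, PP: 4}
benign:
  - {id: B-i,  BA: 1}
  - {id: B-ii, BS: 2}
likely_benign:
  - {id: LB-i,  BS: 1, BP: 1}
  - {id: LB-ii, BP: 2}
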