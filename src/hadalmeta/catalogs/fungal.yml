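# Fungal trait catalog (nitrogen/sulfur pathway logic for eukaryotic
# community analysis).  Same schema and engine as the prokaryote catalog;
# no fungal-specific code path exists.
pathways:
  - name: fungal_carbohydrate_degradation
    category: carbohydrate_degradation
    key_genes: [GH, PL, CE, GT, AA, CBM]
  - name: dissim_nitrate_reduction
    category: "anaerobic:DNRA"
    key_genes: [narG, narH, narI, napA, napB, nirB_f, nirD_f]
  - name: assim_nitrate_reduction
    category: "anaerobic:assim_nitrate_reduction"
    key_genes: [NR, nasA, nasB, NIT-6]
  - name: fungal_denitrification
    category: "anaerobic:denitrification"
    key_genes: [nirK_f, norB, norC_f]
  - name: fungal_assim_sulfate_reduction
    category: "anaerobic:assim_sulfate_reduction"
    key_genes: [sat_f, cysC, cysH, cysJ]
  - name: fungal_sulfide_oxidation
    category: "chemolithotrophy:sulfide_oxidation"
    key_genes: [dsrA_f, dsrB_f, aprA_f, APR]
  - name: taurine_utilization
    category: "chemolithotrophy:organic_sulfur"
    key_genes: [tauD, ssuD]
  - name: sox_system
    category: "chemolithotrophy:thiosulfate_oxidation"
    key_genes: [soxC]
  - name: sulfide_quinone_oxidation
    category: "chemolithotrophy:H2S_oxidation"
    key_genes: [SQOR]
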