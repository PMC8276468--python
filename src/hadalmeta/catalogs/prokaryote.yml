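# Default prokaryote trait catalog: key marker genes per pathway/trait.
#
# Category grammar (drives lifestyle flags):
#   *_degradation           -> heterotrophy
#   co2_fixation:<pathway>   -> autotrophy (mixotroph = both)
#   aerobic_respiration      -> aerobic
#   anaerobic:<pathway>      -> anaerobic (facultative = aerobic + anaerobic)
#   chemolithotrophy:<type>  -> chemolithotrophy, by subtype
#
# Marker labels are namespaced at the symbol level to stay unambiguous:
# coxA is the aerobic cytochrome c oxidase subunit, coxL the CO
# dehydrogenase large subunit (the bare name "cox" is used for both in the
# literature and is deliberately absent here).
#
# NOTE on sulfate reduction: source annotations in this field sometimes put
# sat/aprAB/dsrAB under assimilatory reduction even though aprAB and dsrAB
# are classically dissimilatory markers.  To keep every marker in exactly
# one entry, assimilatory carries {sat, dsrA, dsrB} and dissimilatory
# {aprA, aprB} by default; edit to taste.
#
# Marker lists for 3-HP, 3-HP/4-HB, methanogenesis, hydrocarbon/aromatic
# degradation and H2 oxidation are editable field-standard defaults.
pathways:
  - name: carbohydrate_degradation
    category: carbohydrate_degradation
    key_genes: [GH, PL, CE, GT, AA, CBM]
  - name: hydrocarbon_degradation
    category: hydrocarbon_degradation
    key_genes: [alkB, almA, ladA]
  - name: aromatic_degradation
    category: aromatic_degradation
    key_genes: [benA, catA, pcaG, bphA]
  - name: CBB
    category: "co2_fixation:CBB"
    key_genes: [rbcS, prkB]
    min_markers_present: 2
  - name: rTCA
    category: "co2_fixation:rTCA"
    key_genes: [aclA, aclB]
  - name: WL
    category: "co2_fixation:WL"
    key_genes: [cdhD, acsB, cooS, cooF, acsE]
  - name: 3-HP
    category: "co2_fixation:3-HP"
    key_genes: [mcr, pcs]
  - name: 3-HP/4-HB
    category: "co2_fixation:3-HP/4-HB"
    key_genes: [4hbd, ech]
  - name: methanogenesis
    category: "co2_fixation:methanogenesis"
    key_genes: [mcrA, mcrB, mtrA]
  - name: aerobic_respiration
    category: aerobic_respiration
    key_genes: [coxA, cydA, qoxA, ccoN, cyoA]
  - name: DNRA
    category: "anaerobic:DNRA"
    key_genes: [nirB, nirD]
  - name: denitrification
    category: "anaerobic:denitrification"
    key_genes: [nirK, norC]
  - name: assim_sulfate_reduction
    category: "anaerobic:assim_sulfate_reduction"
    key_genes: [sat, dsrA, dsrB]
  - name: dissim_sulfate_reduction
    category: "anaerobic:dissim_sulfate_reduction"
    key_genes: [aprA, aprB]
  - name: nitrification
    category: "chemolithotrophy:nitrification"
    key_genes: [amoA, amoB, amoC, hao, nxrA]
  - name: CO_oxidation
    category: "chemolithotrophy:CO_oxidation"
    key_genes: [coxL]
  - name: sulfide_oxidation
    category: "chemolithotrophy:sulfide_oxidation"
    key_genes: [sqr, fccB]
  - name: H2_oxidation
    category: "chemolithotrophy:H2_oxidation"
    key_genes: [hyaB, hybC, hoxH]
  - name: iron_oxidation
    category: "chemolithotrophy:iron_oxidation"
    key_genes: [cyc2]
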