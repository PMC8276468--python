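# Orthology ids / gene symbols whose presence on a viral ORF flags a
# nitrogen- or sulfur-metabolism auxiliary metabolic gene (AMG).
# Deliberately minimal: nitrite reductase (NirK) and ATP sulphurylase
# (CysN/NodQ) are the explicitly supported defaults; extend with a fuller
# KO list as a drop-in.
nitrogen:
  - nirK
  - K00368        # nirK, copper-containing nitrite reductase
sulfur:
  - cysN
  - nodQ
  - cysN/nodQ
  - K00956        # cysN, sulfate adenylyltransferase subunit 1
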