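# Editable default roster of universal single-copy protein-coding marker
# genes for concatenated genome phylogenies (the classic 40-COG universal
# set).  Replace with the marker set matching your annotation database.
COG0012
COG0016
COG0018
COG0048
COG0049
COG0052
COG0080
COG0081
COG0085
COG0087
COG0088
COG0090
COG0091
COG0092
COG0093
COG0094
COG0096
COG0097
COG0098
COG0099
COG0100
COG0102
COG0103
COG0124
COG0172
COG0184
COG0185
COG0186
COG0197
COG0200
COG0201
COG0202
COG0215
COG0256
COG0495
COG0522
COG0525
COG0533
COG0541
COG0552
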