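# Standard 15 syntenic ribosomal proteins used for concatenated
# phylogenies of draft genomes.  One marker name per line.
L2
L3
L4
L5
L6
L14
L15
L16
L18
L22
L24
S3
S8
S17
S19
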