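MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.250000 C 0.250000 G 0.250000 T 0.250000

MOTIF BmMamoS_printed
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 0
 0.010000 0.010000 0.970000 0.010000
 0.010000 0.010000 0.010000 0.970000
 0.010000 0.010000 0.970000 0.010000
 0.010000 0.970000 0.010000 0.010000
 0.010000 0.010000 0.970000 0.010000
 0.010000 0.010000 0.010000 0.970000
 0.010000 0.010000 0.970000 0.010000
 0.010000 0.010000 0.970000 0.010000
 0.010000 0.970000 0.010000 0.010000

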