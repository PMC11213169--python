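MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.3 C 0.2 G 0.2 T 0.3

MOTIF heptamer
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
0.066667 0.800000 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.066667 0.800000 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.066667 0.066667 0.800000 0.066667
0.066667 0.066667 0.066667 0.800000
0.066667 0.066667 0.800000 0.066667

MOTIF nonamer
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 0
0.800000 0.066667 0.066667 0.066667
0.066667 0.800000 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.800000 0.066667 0.066667 0.066667
0.066667 0.800000 0.066667 0.066667
0.066667 0.800000 0.066667 0.066667

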