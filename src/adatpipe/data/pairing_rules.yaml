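# Wobble pairing rules: anticodon position-34 base -> codon third bases it can
# read. DNA alphabet (T stands for U). "I" is inosine, the edited state of A34.
# Positions 35/36 always pair strict Watson-Crick with codon positions 2/1.
A: [T]
I: [A, T, C]
G: [C, T]
C: [G]
T: [A, G]
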