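# IMGT amino-acid property classes (one record per residue).
# Columns: residue, hydropathy class (3), volume class (5),
# physicochemical class (11).  Transcribed from the standard IMGT
# classification of the 20 common amino acids.
A	hydrophobic	very_small	aliphatic
C	hydrophobic	small	cysteine
D	hydrophilic	small	acidic
E	hydrophilic	medium	acidic
F	hydrophobic	very_large	aromatic
G	neutral	very_small	glycine
H	neutral	medium	histidine
I	hydrophobic	large	aliphatic
K	hydrophilic	large	basic
L	hydrophobic	large	aliphatic
M	hydrophobic	large	methionine
N	hydrophilic	small	amide
P	neutral	small	proline
Q	hydrophilic	medium	amide
R	hydrophilic	large	basic
S	neutral	very_small	hydroxyl
T	neutral	small	hydroxyl
V	hydrophobic	medium	aliphatic
W	hydrophobic	very_large	aromatic
Y	neutral	very_large	aromatic
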