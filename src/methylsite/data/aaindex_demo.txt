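# AAindex-style physicochemical property table.
# Columns: property id, then 20 values in alphabetical one-letter order
# A C D E F G H I K L M N P Q R S T V W Y
# KYTJ820101: Kyte-Doolittle hydropathy; GRAR740102: Grantham polarity;
# BIGC670101: Zamyatnin residue volume (A^3).
KYTJ820101 1.8 2.5 -3.5 -3.5 2.8 -0.4 -3.2 4.5 -3.9 3.8 1.9 -3.5 -1.6 -3.5 -4.5 -0.8 -0.7 4.2 -0.9 -1.3
GRAR740102 8.1 5.5 13.0 12.3 5.2 9.0 10.4 5.2 11.3 4.9 5.7 11.6 8.0 10.5 10.5 9.2 8.6 5.9 5.4 6.2
BIGC670101 52.6 68.3 68.4 84.7 113.9 36.3 91.9 102.0 105.1 102.0 97.7 75.7 73.6 89.7 109.1 54.9 71.2 85.1 135.4 116.2
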