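H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H GRAR740102
D Polarity (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.1    10.5    11.6    13.0     5.5    10.5    12.3     9.0    10.4     5.2
     4.9    11.3     5.7     5.2     8.0     9.2     8.6     5.4     6.2     5.9
//
H GRAR740103
D Volume (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    31.0   124.0    56.0    54.0    55.0    85.0    83.0     3.0    96.0   111.0
   111.0   119.0   105.0   132.0    32.5    32.0    61.0   170.0   136.0    84.0
//
H SYNNA0001
D Synthetic incomplete per-residue record (parser/filter check; not a real index)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.1     0.2      NA     0.4     0.5     0.6     0.7     0.8     0.9     1.0
     1.1     1.2     1.3     1.4     1.5     1.6     1.7     1.8     1.9     2.0
//
H SYNMAT001
D Synthetic symmetric lower-triangular matrix (parser check; not a real index)
M rows = ARNDCQEGHILKMFPSTWYV, cols = ARNDCQEGHILKMFPSTWYV
      1.
      0.    1.
      0.    0.    1.
      0.    0.    0.    1.
      0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    2.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
      0.    0.    0.    0.    0.    0.    0.    0.    3.    0.    0.    0.    0.    0.    0.    0.    0.    0.    0.    1.
//
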