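H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.800  -4.500  -3.500  -3.500   2.500  -3.500  -3.500  -0.400  -3.200   4.500
   3.800  -3.900   1.900   2.800  -1.600  -0.800  -0.700  -0.900  -1.300   4.200
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.500   3.000   0.200   3.000  -1.000   0.200   3.000   0.000  -0.500  -1.800
  -1.800   3.000  -1.300  -2.500   0.000   0.300  -0.400  -3.400  -2.300  -1.500
//
H EISD840101
D Consensus normalized hydrophobicity scale (Eisenberg, 1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.620  -2.530  -0.780  -0.900   0.290  -0.850  -0.740   0.480  -0.400   1.380
   1.060  -1.500   0.640   1.190   0.120  -0.180  -0.050   0.810   0.260   1.080
//
H GRAR740101
D Composition (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.000   0.650   1.330   1.380   2.750   0.890   0.920   0.740   0.580   0.000
   0.000   0.330   0.000   0.000   0.390   1.420   0.710   0.130   0.200   0.000
//
H GRAR740102
D Polarity (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   8.100  10.500  11.600  13.000   5.500  10.500  12.300   9.000  10.400   5.200
   4.900  11.300   5.700   5.200   8.000   9.200   8.600   5.400   6.200   5.900
//
H GRAR740103
D Volume (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  31.000 124.000  56.000  54.000  55.000  85.000  83.000   3.000  96.000 111.000
 111.000 119.000 105.000 132.000  32.500  32.000  61.000 170.000 136.000  84.000
//
H ZIMJ680104
D Isoelectric point (Zimmerman et al., 1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   6.000  10.760   5.410   2.770   5.050   5.650   3.220   5.970   7.590   6.020
   5.980   9.740   5.740   5.480   6.300   5.680   5.660   5.890   5.660   5.960
//
H FASG760101
D Molecular weight (Fasman, 1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  89.090 174.200 132.120 133.100 121.150 146.150 147.130  75.070 155.160 131.170
 131.170 146.190 149.210 165.190 115.130 105.090 119.120 204.240 181.190 117.150
//
H KLEP840101
D Net charge (Klein et al., 1984)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.000   1.000   0.000  -1.000   0.000   0.000  -1.000   0.000   0.000   0.000
   0.000   1.000   0.000   0.000   0.000   0.000   0.000   0.000   0.000   0.000
//
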