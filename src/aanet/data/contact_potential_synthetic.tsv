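# SYNTHETIC stand-in inter-residue contact-energy table (RT units).
# Deterministic surrogate anchored at the published extremes -1.19 / 0.76;
# see aanet.potentials.build_synthetic_table for the construction.
#      ALA    ARG    ASN    ASP    CYS    GLN    GLU    GLY    HIS    ILE    LEU    LYS    MET    PHE    PRO    SER    THR    TRP    TYR    VAL
ALA   0.02   0.25   0.18   0.21  -0.20   0.11   0.19   0.07   0.05  -0.25  -0.23   0.25  -0.15  -0.25  -0.06   0.08   0.03  -0.33  -0.10  -0.15
ARG   0.25   0.76   0.25  -0.25   0.25   0.25  -0.25   0.25   0.51   0.25   0.25   0.76   0.25   0.25   0.25   0.25   0.25   0.25   0.25   0.25
ASN   0.18   0.25   0.23   0.24   0.11   0.21   0.23   0.20   0.19   0.10   0.10   0.25   0.13   0.10   0.16   0.20   0.18   0.07   0.14   0.13
ASP   0.21  -0.25   0.24   0.75   0.17   0.23   0.75   0.22  -0.04   0.16   0.17  -0.25   0.18   0.16   0.20   0.22   0.21   0.15   0.19   0.18
CYS  -0.20   0.25   0.11   0.17  -0.63  -0.02   0.13  -0.10  -0.14  -0.72  -0.68   0.25  -0.52  -0.72  -0.35  -0.08  -0.19  -0.88  -0.43  -0.52
GLN   0.11   0.25   0.21   0.23  -0.02   0.17   0.21   0.15   0.13  -0.05  -0.04   0.25   0.01  -0.05   0.07   0.15   0.12  -0.10   0.04   0.02
GLU   0.19  -0.25   0.23   0.75   0.13   0.21   0.74   0.20  -0.06   0.11   0.12  -0.25   0.14   0.11   0.17   0.21   0.19   0.09   0.16   0.14
GLY   0.07   0.25   0.20   0.22  -0.10   0.15   0.20   0.12   0.10  -0.13  -0.12   0.25  -0.05  -0.13   0.02   0.12   0.08  -0.19  -0.02  -0.05
HIS   0.05   0.51   0.19  -0.04  -0.14   0.13  -0.06   0.10   0.20  -0.18  -0.17   0.50  -0.09  -0.18  -0.01   0.10   0.06  -0.25  -0.05  -0.09
ILE  -0.25   0.25   0.10   0.16  -0.72  -0.05   0.11  -0.13  -0.18  -0.82  -0.78   0.25  -0.60  -0.81  -0.41  -0.12  -0.23  -0.99  -0.50  -0.60
LEU  -0.23   0.25   0.10   0.17  -0.68  -0.04   0.12  -0.12  -0.17  -0.78  -0.74   0.25  -0.57  -0.78  -0.38  -0.10  -0.21  -0.95  -0.47  -0.57
LYS   0.25   0.76   0.25  -0.25   0.25   0.25  -0.25   0.25   0.50   0.25   0.25   0.76   0.25   0.25   0.25   0.25   0.25   0.25   0.25   0.25
MET  -0.15   0.25   0.13   0.18  -0.52   0.01   0.14  -0.05  -0.09  -0.60  -0.57   0.25  -0.43  -0.60  -0.27  -0.04  -0.13  -0.74  -0.35  -0.42
PHE  -0.25   0.25   0.10   0.16  -0.72  -0.05   0.11  -0.13  -0.18  -0.81  -0.78   0.25  -0.60  -0.81  -0.40  -0.11  -0.23  -0.99  -0.50  -0.59
PRO  -0.06   0.25   0.16   0.20  -0.35   0.07   0.17   0.02  -0.01  -0.41  -0.38   0.25  -0.27  -0.40  -0.15   0.03  -0.04  -0.51  -0.21  -0.27
SER   0.08   0.25   0.20   0.22  -0.08   0.15   0.21   0.12   0.10  -0.12  -0.10   0.25  -0.04  -0.11   0.03   0.13   0.09  -0.18  -0.01  -0.04
THR   0.03   0.25   0.18   0.21  -0.19   0.12   0.19   0.08   0.06  -0.23  -0.21   0.25  -0.13  -0.23  -0.04   0.09   0.04  -0.31  -0.09  -0.13
TRP  -0.33   0.25   0.07   0.15  -0.88  -0.10   0.09  -0.19  -0.25  -0.99  -0.95   0.25  -0.74  -0.99  -0.51  -0.18  -0.31  -1.19  -0.62  -0.73
TYR  -0.10   0.25   0.14   0.19  -0.43   0.04   0.16  -0.02  -0.05  -0.50  -0.47   0.25  -0.35  -0.50  -0.21  -0.01  -0.09  -0.62  -0.27  -0.34
VAL  -0.15   0.25   0.13   0.18  -0.52   0.02   0.14  -0.05  -0.09  -0.60  -0.57   0.25  -0.42  -0.59  -0.27  -0.04  -0.13  -0.73  -0.34  -0.42
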