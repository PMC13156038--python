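gene	signaling_class
CHRND	ionotropic
GRIA1	ionotropic
CHRNA1	ionotropic
HTR3A	ionotropic
GRIK1	ionotropic
CHRNG	ionotropic
GABRG1	ionotropic
GABRA1	ionotropic
CHRNE	ionotropic
GRIN1	ionotropic
GABRA2	ionotropic
GABRG2	ionotropic
CHRNB1	ionotropic
GABBR1	metabotropic
HRH2	metabotropic
DRD2	metabotropic
ADRB2	metabotropic
CHRM2	metabotropic
DRD4	metabotropic
HRH4	metabotropic
ADRA1A	metabotropic
CHRM1	metabotropic
ADRB1	metabotropic
MTNR1A	metabotropic
HTR4	metabotropic
HTR2A	metabotropic
HRH1	metabotropic
DRD1	metabotropic
GABBR2	metabotropic
GRM1	metabotropic
ADRB3	metabotropic
CHRM3	metabotropic
ADRA2A	metabotropic
HTR1A	metabotropic
DRD3	metabotropic
HRH3	metabotropic
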