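source,sv,iv,du,mufa_percent,pufa_percent,lcsf,cfpp,cn,os
Jatropha,190.98,105.42,122.1,37.3,42.4,4.54,-2.21,51.16,5.37
Karanja,184.05,94.22,105.2,65.6,19.8,2.64,-8.18,54.76,8.55
Mahua,191.58,67.72,78.62,39.1,19.76,11.65,20.12,59.55,8.56
Palm,194.82,48.05,55.7,37.04,9.33,6.91,5.22,63.5,15.23
Rapeseed,188.61,115.07,125.46,64.4,30.53,0.77,-14.05,49.35,6.45
Dunaliella salina DSTA20,171.39,169.05,122.92,4.4,59.26,2.37,-9.03,35.04,8.7
Dunaliella salina LIMS-PS-1511,121.29,95.41,78.3,3.7,37.3,2.73,-7.9,69.83,5.75
Asterarcys quadricellulare AQYS21,205.11,171.65,134.04,13.3,60.37,2.99,-7.08,34.29,4.54
Chlamydomonas hedleyi MM0020,95.6,62.09,55.0,2.6,26.2,2.43,-8.84,89.42,7.09
Chlorella salina MM0063,132.19,100.26,85.0,2.6,41.2,2.75,-7.84,65.03,5.45
Coelastrum microporum IBL-C119,181.83,82.61,84.64,45.24,19.7,4.02,-3.84,57.73,8.58
Graesiella emersonii GEGS21,204.86,131.06,121.3,22.5,49.4,3.05,-6.89,43.45,4.98
Haematococcus lacustris,162.7,98.86,95.81,20.13,37.84,3.82,-4.46,57.6,5.75
Microglena monadina NFW3,188.54,166.15,138.24,3.28,67.48,2.71,-7.97,37.86,4.34
Mychonastes homosphaera UTEX 2341,142.74,162.79,98.9,23.9,37.5,1.45,-11.92,47.91,23.28
Jaagichlorella luteoviridis MM0014,157.6,109.69,110.7,7.1,51.8,2.77,-7.77,56.25,4.87
Tetradesmus obliquus MM0026,138.92,98.63,85.4,18.4,33.5,2.45,-8.78,63.4,6.11
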