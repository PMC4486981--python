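# CIAAW 2021 representative abundances; AME2020 atomic masses (Da).
# version: ciaaw2021-ame2020
element,isotope,mass_da,abundance
H,1H,1.0078250319,0.999885
H,2H,2.0141017779,0.000115
C,12C,12.0,0.9893
C,13C,13.0033548351,0.0107
N,14N,14.0030740042,0.99636
N,15N,15.0001088989,0.00364
O,16O,15.9949146196,0.99757
O,17O,16.9991317565,0.00038
O,18O,17.9991596129,0.00205
P,31P,30.9737619984,1.0
S,32S,31.9720711744,0.9499
S,33S,32.9714589098,0.0075
S,34S,33.9678670120,0.0425
S,36S,35.9670806990,0.0001
Cl,35Cl,34.9688526820,0.7576
Cl,37Cl,36.9659026020,0.2424
Br,79Br,78.9183376010,0.5069
Br,81Br,80.9162897150,0.4931
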