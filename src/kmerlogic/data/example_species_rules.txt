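# Example species-level classification rules for bacterial genomes.
# f(W) is the relative frequency of the 4-mer W in a genome, multiplied
# by 1e5 for readability. Conditions are half-open: lo<=f(W)<hi.
A. baumannii: f(GTAC)>=229.10 & f(TGCA)>=515.63
B. cereus: 384.04<=f(CTCA)<490.11 & 819.04<=f(TCCA)<875.80
B. animalis: 762.28<=f(TCCA)<819.04 & 469.35<=f(TGCA)<515.63
B. longum: f(GTAC)>=229.10 & 330.52<=f(TGCA)<376.80
B. aphidicola: 57.77<=f(AGGC)<182.81
C. jejuni: 490.11<=f(CTCA)<596.17 & 353.97<=f(CTGA)<451.85
C. trachomatis: 305.55<=f(GGAC)<393.10 & 875.80<=f(TCCA)<932.56
C. botulinum: 371.77<=f(ACTC)<434.37 & 112.00<=f(GCAC)<261.71
C. diphtheriae: 819.04<=f(TCCA)<875.80 & 423.07<=f(TGCA)<469.35
C. pseudotuberculosis: 875.80<=f(TCCA)<932.56 & 423.07<=f(TGCA)<469.35
E. coli: 710.86<=f(GCAC)<860.58 & 415.84<=f(GCTA)<525.98
F. tularensis: 592.00<=f(TCCA)<648.76 & 330.52<=f(TGCA)<376.80
H. influenzae: 549.73<=f(CTGA)<647.60 & 130.47<=f(GGAC)<218.01
H. pylori: 5.56<=f(GTAC)<42.82
L. monocytogenes: 411.43<=f(GCAC)<561.15 & 305.55<=f(GGAC)<393.10
M. tuberculosis: 649.71<=f(ATCA)<772.78
N. meningitidis: 590.29<=f(GATA)<754.27 & 376.80<=f(TGCA)<423.07
P. marinus: (f(AGGA)<602.46 | f(AGGA)>=706.28) & f(GCTA)<856.37 & 117.33<=f(GTAC)<154.58
S. enterica: 525.98<=f(GCTA)<636.11 & 393.10<=f(GGAC)<480.64
S. aureus: 1082.23<=f(GATA)<1246.22 & f(GTAC)>=229.10
S. pneumoniae: 393.10<=f(GGAC)<480.64 & 154.58<=f(GTAC)<191.84
S. pyogenes: 596.06<=f(AGTA)<733.86 & 1082.23<=f(GATA)<1246.22
S. suis: 918.25<=f(GATA)<1082.23 & 330.52<=f(TGCA)<376.80
S. islandicus: 218.01<=f(GGAC)<305.55 & 284.24<=f(TGCA)<330.52
Y. pestis: 596.17<=f(CTCA)<702.24 & f(CTGA)>=941.24
default: other
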