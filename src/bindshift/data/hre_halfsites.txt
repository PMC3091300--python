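# Curated accepted nuclear-receptor HRE half-site sequences (6-mers).
# Assembled from published accepted half-sites of the NHRscan database of
# confirmed hormone response elements; an approximation of the original
# alignment-derived scoring model, bundled for convenience.
TGACCT
TGACCC
TGAACT
TGTCCT
TGCCCT
TGAACC
TGGCCT
TGTCCC
TGATCT
TGACCA
TGACCG
TGCCCC
TGTACT
GGACCT
AGACCT
TGGCCC
TGAGCT
TCACCT
TGATCC
TAACCT
TGGACT
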