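# Interior-loop initiation dG37 (kcal/mol) by total unpaired size.
# RNA: Turner 2004; DNA: SantaLucia-Hicks 2004 internal loops (size-2 loops are pure NN mismatches, penalty 0),
# Jacobson-Stockmayer extrapolation beyond size 9.
kind	size	dG
RNA:RNA	2	1.00
RNA:RNA	3	1.00
RNA:RNA	4	1.10
RNA:RNA	5	2.00
RNA:RNA	6	2.00
RNA:RNA	7	2.10
RNA:RNA	8	2.30
RNA:RNA	9	2.40
RNA:RNA	10	2.50
RNA:RNA	11	2.60
RNA:RNA	12	2.70
DNA:DNA	2	0.00
DNA:DNA	3	3.20
DNA:DNA	4	3.60
DNA:DNA	5	4.00
DNA:DNA	6	4.40
DNA:DNA	7	4.60
DNA:DNA	8	4.80
DNA:DNA	9	4.90
DNA:DNA	10	5.10
DNA:DNA	11	5.20
DNA:DNA	12	5.30
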