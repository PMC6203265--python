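# Nearest-neighbor stack dG37 (kcal/mol), top strand 5'->3', bottom 3'->5' (antiparallel).
# WC/WC stacks: Xia 1998 (RNA:RNA), SantaLucia 1998 unified (DNA:DNA), Sugimoto 1995 (RNA:DNA measured subset).
# Mismatch-containing stacks: Turner 2004 interior mismatch terms (RNA:RNA); Allawi/SantaLucia 1997-1998 + Peyret 1999 (DNA:DNA).
kind	top	bottom	dG
RNA:RNA	AA	UU	-0.93
RNA:RNA	AC	UG	-2.24
RNA:RNA	AG	UC	-2.08
RNA:RNA	AU	UA	-1.10
RNA:RNA	CA	GU	-2.11
RNA:RNA	CC	GG	-3.26
RNA:RNA	CG	GC	-2.36
RNA:RNA	CU	GA	-2.08
RNA:RNA	GA	CU	-2.35
RNA:RNA	GC	CG	-3.42
RNA:RNA	GG	CC	-3.26
RNA:RNA	GU	CA	-2.24
RNA:RNA	UA	AU	-1.33
RNA:RNA	UC	AG	-2.35
RNA:RNA	UG	AC	-2.11
RNA:RNA	UU	AA	-0.93
RNA:RNA	AA	AU	0.00
RNA:RNA	AA	CU	0.00
RNA:RNA	AA	GU	-1.00
RNA:RNA	AA	UA	0.00
RNA:RNA	AA	UC	0.00
RNA:RNA	AA	UG	-0.80
RNA:RNA	AC	AG	0.00
RNA:RNA	AC	CG	0.00
RNA:RNA	AC	GG	-1.00
RNA:RNA	AC	UA	0.00
RNA:RNA	AC	UC	0.00
RNA:RNA	AC	UU	0.00
RNA:RNA	AG	AC	0.00
RNA:RNA	AG	CC	0.00
RNA:RNA	AG	GC	-1.00
RNA:RNA	AG	UA	-1.00
RNA:RNA	AG	UG	-1.00
RNA:RNA	AG	UU	0.00
RNA:RNA	AU	AA	0.00
RNA:RNA	AU	CA	0.00
RNA:RNA	AU	GA	-1.00
RNA:RNA	AU	UC	0.00
RNA:RNA	AU	UG	0.00
RNA:RNA	AU	UU	-0.60
RNA:RNA	CA	AU	0.00
RNA:RNA	CA	CU	0.00
RNA:RNA	CA	GA	0.00
RNA:RNA	CA	GC	0.00
RNA:RNA	CA	GG	-0.80
RNA:RNA	CA	UU	0.00
RNA:RNA	CC	AG	0.00
RNA:RNA	CC	CG	0.00
RNA:RNA	CC	GA	0.00
RNA:RNA	CC	GC	0.00
RNA:RNA	CC	GU	0.00
RNA:RNA	CC	UG	0.00
RNA:RNA	CG	AC	0.00
RNA:RNA	CG	CC	0.00
RNA:RNA	CG	GA	-1.00
RNA:RNA	CG	GG	-1.00
RNA:RNA	CG	GU	0.00
RNA:RNA	CG	UC	0.00
RNA:RNA	CU	AA	0.00
RNA:RNA	CU	CA	0.00
RNA:RNA	CU	GC	0.00
RNA:RNA	CU	GG	0.00
RNA:RNA	CU	GU	-0.60
RNA:RNA	CU	UA	0.00
RNA:RNA	GA	AU	-0.80
RNA:RNA	GA	CA	0.00
RNA:RNA	GA	CC	0.00
RNA:RNA	GA	CG	-0.80
RNA:RNA	GA	GU	-1.00
RNA:RNA	GA	UU	0.00
RNA:RNA	GC	AG	-0.80
RNA:RNA	GC	CA	0.00
RNA:RNA	GC	CC	0.00
RNA:RNA	GC	CU	0.00
RNA:RNA	GC	GG	-1.00
RNA:RNA	GC	UG	0.00
RNA:RNA	GG	AC	-0.80
RNA:RNA	GG	CA	-1.00
RNA:RNA	GG	CG	-1.00
RNA:RNA	GG	CU	0.00
RNA:RNA	GG	GC	-1.00
RNA:RNA	GG	UC	0.00
RNA:RNA	GU	AA	-0.80
RNA:RNA	GU	CC	0.00
RNA:RNA	GU	CG	0.00
RNA:RNA	GU	CU	-0.60
RNA:RNA	GU	GA	-1.00
RNA:RNA	GU	UA	0.00
RNA:RNA	UA	AA	0.00
RNA:RNA	UA	AC	0.00
RNA:RNA	UA	AG	-0.80
RNA:RNA	UA	CU	0.00
RNA:RNA	UA	GU	0.00
RNA:RNA	UA	UU	-0.60
RNA:RNA	UC	AA	0.00
RNA:RNA	UC	AC	0.00
RNA:RNA	UC	AU	0.00
RNA:RNA	UC	CG	0.00
RNA:RNA	UC	GG	0.00
RNA:RNA	UC	UG	-0.60
RNA:RNA	UG	AA	-1.00
RNA:RNA	UG	AG	-1.00
RNA:RNA	UG	AU	0.00
RNA:RNA	UG	CC	0.00
RNA:RNA	UG	GC	0.00
RNA:RNA	UG	UC	-0.60
RNA:RNA	UU	AC	0.00
RNA:RNA	UU	AG	0.00
RNA:RNA	UU	AU	-0.60
RNA:RNA	UU	CA	0.00
RNA:RNA	UU	GA	0.00
RNA:RNA	UU	UA	-0.60
DNA:DNA	AA	TT	-1.00
DNA:DNA	AC	TG	-1.44
DNA:DNA	AG	TC	-1.28
DNA:DNA	AT	TA	-0.88
DNA:DNA	CA	GT	-1.45
DNA:DNA	CC	GG	-1.84
DNA:DNA	CG	GC	-2.17
DNA:DNA	CT	GA	-1.28
DNA:DNA	GA	CT	-1.30
DNA:DNA	GC	CG	-2.24
DNA:DNA	GG	CC	-1.84
DNA:DNA	GT	CA	-1.44
DNA:DNA	TA	AT	-0.58
DNA:DNA	TC	AG	-1.30
DNA:DNA	TG	AC	-1.45
DNA:DNA	TT	AA	-1.00
DNA:DNA	AA	AT	0.70
DNA:DNA	AA	CT	1.33
DNA:DNA	AA	GT	0.70
DNA:DNA	AA	TA	0.67
DNA:DNA	AA	TC	0.87
DNA:DNA	AA	TG	0.11
DNA:DNA	AC	AG	0.14
DNA:DNA	AC	CG	0.48
DNA:DNA	AC	GG	-0.49
DNA:DNA	AC	TA	0.77
DNA:DNA	AC	TC	1.36
DNA:DNA	AC	TT	0.64
DNA:DNA	AG	AC	0.40
DNA:DNA	AG	CC	0.79
DNA:DNA	AG	GC	0.09
DNA:DNA	AG	TA	0.01
DNA:DNA	AG	TG	-0.15
DNA:DNA	AG	TT	0.72
DNA:DNA	AT	AA	0.67
DNA:DNA	AT	CA	0.77
DNA:DNA	AT	GA	0.01
DNA:DNA	AT	TC	0.72
DNA:DNA	AT	TG	0.07
DNA:DNA	AT	TT	0.65
DNA:DNA	CA	AT	0.92
DNA:DNA	CA	CT	1.01
DNA:DNA	CA	GA	0.40
DNA:DNA	CA	GC	0.75
DNA:DNA	CA	GG	0.01
DNA:DNA	CA	TT	0.78
DNA:DNA	CC	AG	0.80
DNA:DNA	CC	CG	0.84
DNA:DNA	CC	GA	0.79
DNA:DNA	CC	GC	0.73
DNA:DNA	CC	GT	0.60
DNA:DNA	CC	TG	1.01
DNA:DNA	CG	AC	0.75
DNA:DNA	CG	CC	0.73
DNA:DNA	CG	GA	0.09
DNA:DNA	CG	GG	-0.15
DNA:DNA	CG	GT	-0.47
DNA:DNA	CG	TC	0.39
DNA:DNA	CT	AA	0.87
DNA:DNA	CT	CA	1.36
DNA:DNA	CT	GC	0.39
DNA:DNA	CT	GG	-0.32
DNA:DNA	CT	GT	-0.10
DNA:DNA	CT	TA	0.72
DNA:DNA	GA	AT	0.48
DNA:DNA	GA	CA	0.14
DNA:DNA	GA	CC	0.80
DNA:DNA	GA	CG	-0.29
DNA:DNA	GA	GT	0.48
DNA:DNA	GA	TT	0.34
DNA:DNA	GC	AG	-0.29
DNA:DNA	GC	CA	0.48
DNA:DNA	GC	CC	0.84
DNA:DNA	GC	CT	0.63
DNA:DNA	GC	GG	-1.10
DNA:DNA	GC	TG	-0.59
DNA:DNA	GG	AC	0.01
DNA:DNA	GG	CA	-0.49
DNA:DNA	GG	CG	-1.10
DNA:DNA	GG	CT	0.07
DNA:DNA	GG	GC	-0.15
DNA:DNA	GG	TC	-0.32
DNA:DNA	GT	AA	0.11
DNA:DNA	GT	CC	1.01
DNA:DNA	GT	CG	-0.59
DNA:DNA	GT	CT	0.41
DNA:DNA	GT	GA	-0.15
DNA:DNA	GT	TA	0.07
DNA:DNA	TA	AA	0.70
DNA:DNA	TA	AC	0.92
DNA:DNA	TA	AG	0.48
DNA:DNA	TA	CT	0.98
DNA:DNA	TA	GT	0.43
DNA:DNA	TA	TT	0.67
DNA:DNA	TC	AA	1.33
DNA:DNA	TC	AC	1.01
DNA:DNA	TC	AT	0.98
DNA:DNA	TC	CG	0.63
DNA:DNA	TC	GG	0.07
DNA:DNA	TC	TG	0.41
DNA:DNA	TG	AA	0.70
DNA:DNA	TG	AG	0.48
DNA:DNA	TG	AT	0.43
DNA:DNA	TG	CC	0.60
DNA:DNA	TG	GC	-0.47
DNA:DNA	TG	TC	-0.10
DNA:DNA	TT	AC	0.78
DNA:DNA	TT	AG	0.34
DNA:DNA	TT	AT	0.67
DNA:DNA	TT	CA	0.64
DNA:DNA	TT	GA	0.72
DNA:DNA	TT	TA	0.65
RNA:DNA	AA	TT	-1.00
RNA:DNA	AC	TG	-2.10
RNA:DNA	AG	TC	-1.80
RNA:DNA	AU	TA	-0.90
RNA:DNA	CA	GT	-0.90
RNA:DNA	CC	GG	-2.10
RNA:DNA	CG	GC	-1.70
RNA:DNA	CU	GA	-0.90
RNA:DNA	GA	CT	-1.30
RNA:DNA	GC	CG	-2.70
RNA:DNA	GG	CC	-2.90
RNA:DNA	GU	CA	-1.10
RNA:DNA	UA	AT	-0.60
RNA:DNA	UC	AG	-1.50
RNA:DNA	UG	AC	-1.60
RNA:DNA	UU	AA	-0.20
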