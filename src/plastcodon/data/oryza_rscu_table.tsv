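codon	O_rufipogon_delta	O_rufipogon_rscu	O_officinalis_delta	O_officinalis_rscu	O_granulata_delta	O_granulata_rscu	O_sativa_delta	O_sativa_rscu
AAA	0.66	1.47	0.32	1.46	0.35	1.47	0.66	1.46
AAC	0.49	0.53	0.57	0.53	0.66	0.53	0.49	0.53
AAG	-0.66	0.53	-0.32	0.54	-0.35	0.53	-0.66	0.54
AAU	-0.49	1.47	-0.57	1.47	-0.66	1.47	-0.49	1.47
ACA	-0.06	1.06	0.03	1.09	0.09	1.06	-0.06	1.11
ACC	-0.21	0.78	-0.12	0.76	-0.54	0.76	-0.21	0.73
ACG	-0.76	0.45	-0.94	0.47	-0.72	0.47	-0.76	0.45
ACU	1.03	1.71	1.03	1.68	1.17	1.71	1.03	1.70
AGA	0.14	1.69	0.45	1.68	0.18	1.64	0.14	1.69
AGC	-0.47	0.39	-0.18	0.38	-0.03	0.39	-0.47	0.41
AGG	-0.37	0.63	-0.35	0.59	-0.35	0.64	-0.37	0.61
AGU	0.60	1.28	0.22	1.27	0.42	1.26	0.60	1.28
AUA	-0.11	0.90	-0.30	0.91	-0.21	0.90	-0.11	0.91
AUC	-0.05	0.59	-0.05	0.59	-0.13	0.59	-0.05	0.58
AUG	0.00	1.00	0.00	1.00	0.00	1.00	0.00	1.00
AUU	0.17	1.51	0.35	1.51	0.34	1.50	0.17	1.51
CAA	0.19	1.51	0.16	1.52	0.30	1.52	0.19	1.51
CAC	0.01	0.52	0.04	0.55	0.16	0.52	0.01	0.51
CAG	-0.19	0.49	-0.16	0.48	-0.29	0.48	-0.19	0.49
CAU	-0.01	1.48	-0.04	1.45	-0.16	1.48	-0.01	1.49
CCA	-0.05	1.06	-0.17	1.08	-0.07	1.08	-0.05	1.06
CCC	-0.74	0.88	-0.49	0.95	-0.37	0.88	-0.74	0.90
CCG	-0.48	0.47	-0.64	0.46	-0.86	0.46	-0.48	0.46
CCU	1.28	1.59	1.30	1.51	1.30	1.59	1.28	1.58
CGA	-0.41	1.27	-0.12	1.32	-0.02	1.32	-0.41	1.32
CGC	-0.38	0.57	-0.22	0.54	-0.31	0.56	-0.38	0.58
CGG	-0.09	0.50	-0.47	0.49	-0.22	0.46	-0.09	0.49
CGU	1.11	1.34	0.71	1.39	0.72	1.39	1.11	1.30
CUA	-0.31	0.82	-0.07	0.82	-0.27	0.83	-0.31	0.80
CUC	-0.46	0.41	-0.48	0.42	-0.29	0.40	-0.46	0.40
CUG	-0.19	0.35	-0.36	0.35	-0.13	0.35	-0.19	0.34
CUU	-0.07	1.30	-0.09	1.29	-0.41	1.30	-0.07	1.31
GAA	-0.41	1.47	-0.27	1.48	-0.32	1.47	-0.41	1.48
GAC	-0.07	0.44	0.34	0.46	0.09	0.44	-0.07	0.42
GAG	0.41	0.53	0.27	0.52	0.32	0.53	0.41	0.52
GAU	0.07	1.56	-0.33	1.54	-0.09	1.56	0.07	1.58
GCA	-0.02	1.19	-0.11	1.19	-0.52	1.18	-0.02	1.18
GCC	-0.11	0.56	-0.14	0.56	-0.05	0.56	-0.11	0.56
GCG	-0.22	0.51	-0.26	0.48	-0.14	0.50	-0.22	0.51
GCU	0.34	1.75	0.51	1.77	0.71	1.76	0.34	1.75
GGA	-0.47	1.53	-0.19	1.53	-0.65	1.52	-0.47	1.55
GGC	-0.17	0.43	0.07	0.43	0.20	0.44	-0.17	0.40
GGG	-0.46	0.76	-0.61	0.77	-0.48	0.77	-0.46	0.77
GGU	1.09	1.28	0.73	1.27	0.93	1.27	1.09	1.28
GUA	0.66	1.47	0.63	1.47	0.60	1.45	0.66	1.46
GUC	-0.29	0.45	-0.34	0.46	-0.45	0.44	-0.29	0.45
GUG	-0.04	0.53	-0.34	0.53	-0.16	0.54	-0.04	0.52
GUU	-0.34	1.55	0.05	1.54	0.01	1.57	-0.34	1.57
UAA	1.20	1.50	0.60	1.44	0.60	1.50	1.20	1.50
UAC	0.34	0.45	0.23	0.44	0.18	0.44	0.34	0.44
UAG	-1.20	0.75	-0.60	0.84	-1.20	0.78	-1.20	0.75
UAU	-0.34	1.55	-0.23	1.56	-0.18	1.56	-0.34	1.56
UCA	-0.43	1.04	-0.94	1.03	-0.91	1.06	-0.43	1.06
UCC	0.40	1.20	0.55	1.20	0.26	1.17	0.40	1.17
UCG	-0.18	0.52	-0.44	0.53	-0.38	0.53	-0.18	0.54
UCU	0.05	1.56	0.77	1.60	0.64	1.59	0.05	1.54
UGA	0.00	0.75	0.00	0.72	0.60	0.72	0.00	0.75
UGC	-0.47	0.51	0.29	0.53	-0.75	0.52	-0.47	0.51
UGG	0.00	1.00	0.00	1.00	0.00	1.00	0.00	1.00
UGU	0.47	1.49	-0.29	1.47	0.75	1.48	0.47	1.49
UUA	1.36	2.01	0.73	2.00	1.21	2.01	1.36	2.05
UUC	0.16	0.70	0.21	0.70	0.43	0.70	0.16	0.69
UUG	-0.34	1.11	0.28	1.13	-0.11	1.12	-0.34	1.10
UUU	-0.16	1.30	-0.21	1.30	-0.43	1.30	-0.16	1.31
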