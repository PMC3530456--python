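gene_symbol	mean_ctrl	sem_ctrl	mean_case	sem_case	p_printed	fold_printed	microarray_fc	confirmed
CTSZ	1.10	0.07	2.06	0.23	0.001	1.9	2.2	yes
STAT5A	1.10	0.12	1.58	0.20	0.05	1.4	1.6	yes
TREM2	1.20	0.17	3.18	0.72	0.05	2.6	2.9	yes
FCER1G	1.10	0.11	2.30	0.19	0.001	2.1	2.4	yes
CHI3L2	1.32	0.29	3.13	0.48	0.01	1.6	2.1	yes
SLC11A1	1.34	0.23	17.00	3.38	0.001	12.7	3.1	yes
NRN1	1.19	0.18	0.49	0.05	0.001	-2.4	-2.5	yes
NNAT	1.14	0.20	0.52	0.06	0.05	-2.2	-2.2	yes
FMO1	1.41	0.40	0.38	0.07	0.001	-3.7	-1.5	yes
GJB2	1.38	0.27	0.35	0.07	0.001	-3.9	-4.7	yes
FURIN	1.11	0.16	0.83	0.13	0.17	-1.3	1.6	no
H19	1.28	0.15	0.68	0.20	0.05	-1.9	-2.3	yes
PEG10	1.08	0.08	0.79	0.07	0.01	-1.4	-1.8	yes
LUM	1.40	0.29	0.32	0.13	0.01	-4.4	-4.1	yes
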