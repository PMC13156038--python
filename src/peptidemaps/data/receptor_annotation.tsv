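gene	full_name	family	mean_intensity	rnaseq_correlation	differential_stability	mean_expr_cortex	mean_expr_hypothalamus	mean_expr_subcortex
ADCYAP1R1	ADCYAP receptor type I	Glucagon/secretin	0.97	0.45	0.35	0.35	0.81	0.64
ADIPOR2	Adiponectin receptor 2	Adipose	0.95	0.54	0.14	0.52	0.42	0.60
APLNR	Apelin receptor	Unclassified	0.75	0.62	0.30	0.49	0.75	0.56
BDKRB2	Bradykinin receptor B2	Kinin/tensin	0.39	0.66	0.40	0.45	0.11	0.32
CALCRL	Calcitonin receptor-like receptor	Calcitonin	0.79	0.39	0.18	0.47	0.46	0.44
CCKBR	Cholecystokinin B receptor	CCK/gastrin	0.61	0.66	0.54	0.87	0.16	0.28
EDNRA	Endothelin receptor type A	Endothelin	0.42	0.60	0.32	0.53	0.32	0.41
EDNRB	Endothelin receptor type B	Endothelin	0.96	0.78	0.54	0.40	0.86	0.81
GALR1	Galanin receptor 1	Galanin	0.37	0.48	0.38	0.53	0.68	0.37
GHR	Growth hormone receptor	Unclassified	0.63	0.70	0.44	0.42	0.69	0.54
GIPR	Gastric inhibitory polypeptide receptor	Glucagon/secretin	0.97	0.20	0.15	0.39	0.51	0.56
GLP2R	Glucagon-like peptide 2 receptor	Glucagon/secretin	0.31	0.73	0.59	0.67	0.28	0.26
GRPR	Gastrin-releasing peptide receptor	Bombesin-like	0.28	0.25	0.27	0.54	0.45	0.21
HCRTR1	Hypocretin receptor 1	Unclassified	0.38	0.58	0.18	0.48	0.65	0.50
LEPR	Leptin receptor	Adipose	0.76	0.20	0.26	0.37	0.72	0.64
MCHR1	Melanin-concentrating hormone receptor 1	Unclassified	0.34	0.58	0.35	0.60	0.19	0.17
MCHR2	Melanin-concentrating hormone receptor 2	Unclassified	0.45	0.75	0.42	0.60	0.09	0.10
NPFFR2	Neuropeptide FF receptor 2	F-amide/Y-amide	0.51	0.42	0.36	0.49	0.49	0.18
NPR2	Natriuretic peptide receptor 2	Natriuretic factor	0.99	0.23	0.19	0.45	0.70	0.51
NPR3	Natriuretic peptide receptor 3	Natriuretic factor	0.25	0.42	0.34	0.50	0.53	0.31
NPY1R	Neuropeptide Y receptor Y1	F-amide/Y-amide	0.69	0.80	0.66	0.60	0.55	0.45
NPY2R	Neuropeptide Y receptor Y2	F-amide/Y-amide	0.29	0.60	0.16	0.47	0.42	0.21
NPY5R	Neuropeptide Y receptor Y5	F-amide/Y-amide	0.53	0.45	0.41	0.56	0.54	0.60
NTSR1	Neurotensin receptor 1	Kinin/tensin	0.22	0.81	0.67	0.46	0.48	0.31
NTSR2	Neurotensin receptor 2	Kinin/tensin	0.98	0.83	0.44	0.44	0.89	0.73
OPRK1	Opioid receptor kappa 1	Opioid	0.43	0.71	0.54	0.48	0.53	0.59
OPRL1	Opioid-related nociceptin receptor 1	Opioid	0.90	0.65	0.15	0.65	0.57	0.44
OPRM1	Mu-opioid receptor 1	Opioid	0.60	0.55	0.62	0.38	0.66	0.58
OXTR	Oxytocin receptor	Vasopressin/oxytocin	0.68	0.61	0.44	0.38	0.93	0.66
RAMP1	Receptor activity-modifying protein 1	Calcitonin	1.00	0.50	0.21	0.46	0.70	0.72
RAMP3	Receptor activity-modifying protein 3	Calcitonin	0.72	0.68	0.51	0.50	0.56	0.36
RXFP1	Relaxin/insulin-like family peptide receptor 1	Insulin	0.52	0.67	0.51	0.74	0.12	0.17
SORT1	Sortilin 1	Kinin/tensin	1.00	0.46	0.34	0.55	0.16	0.43
SSTR1	Somatostatin receptor 1	Somatostatin	0.50	0.86	0.75	0.59	0.66	0.28
SSTR2	Somatostatin receptor 2	Somatostatin	0.98	0.80	0.49	0.66	0.31	0.35
TACR2	Tachykinin receptor 2	Kinin/tensin	0.71	0.29	0.18	0.49	0.39	0.37
VIPR1	Vasoactive intestinal peptide receptor 1	Glucagon/secretin	0.40	0.47	0.35	0.82	0.15	0.32
VIPR2	Vasoactive intestinal peptide receptor 2	Glucagon/secretin	0.51	0.85	0.58	0.67	0.29	0.27
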