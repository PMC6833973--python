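# Local flexibility vs voltage dependence and temperature coefficients
# for selected VGIC-superfamily channels, compiled from published
# electrophysiology literature.  Flexibility indices are 1/mBf values
# for the S3, S3-S4 and S1-S4 windows (larger = more flexible).
# charge_e0: total gating charge per channel (elementary charges);
# q10_act / q10_inact: temperature coefficients of the activation /
# inactivation (or deactivation) time constants.  Ranges use "a to b";
# "n.d." = not determined; "-" = not applicable/reported.
channel	domain	s3_index	s3s4_index	s1s4_index	charge_e0	q10_act	q10_inact	notes
Shaker Kv1	-	1.48	1.96	1.87	12 to 16	~ 4	7.2	-
Kv1.2	-	1.61	1.86	1.82	10	n.d.	n.d.	-
Na-channel (frog muscle)	-	-	-	-	~ 12	2.4	3 to 5.3	-
Na-channel (muscle)	-	-	-	-	~ 12	2.3	3.4 to 9.1	-
Nav1.5	DI	1.56	1.69	1.67	~ 12	1.25	4 to 5.8	Q10 at -70 or -50 mV
Nav1.5	DIV	1.51	1.62	1.68	~ 12	1.25	4 to 5.8	Q10 at -70 or -50 mV
Ca-channel (muscle)	-	-	-	-	8.6 to 15	~ 3	n.d.	charge depends on beta subunit
Cav1.2	DII	1.58	1.70	1.67	~ 9	n.d.	3	inactivation weakly T-dependent
Cav1.2	DIV	1.62	1.90	1.70	~ 9	n.d.	3	inactivation weakly T-dependent
Cav1.4	DII	1.66	1.68	1.65	~ 9	n.d.	~ 19	-
Cav1.4	DIV	1.62	1.97	1.75	~ 9	n.d.	~ 19	-
Kv7.4 (KCNQ4)	-	1.53	1.62	1.58	~ 8	8.3	n.d.	-
Kv11.3	-	1.56	1.84	1.81	8	3.8	2.6	-
Kv11.1 (hERG)	-	1.51	1.80	1.74	6 to 8	4.7	2.9	-
HCN2	-	1.63	1.73	1.80	5 to 8	n.d.	n.d.	cAMP reduces charge ~8 to ~5
HCN1	-	1.62	1.73	1.78	3.75	2.9	3.1	Q10 for deactivation
hHv1	-	1.40	1.49	1.50	6	6 to 9	-	-
mHv1	-	1.40	1.46	1.49	4	6 to 9	-	-
BK (Slo1)	-	1.55	1.67	1.64	2.4 to 4.4	n.d.	n.d.	-
ciVSP	-	1.52	1.63	1.66	~ 1.25	1.4	1.7	Q10 for deactivation
mTRPM8	-	1.51	1.59	1.60	0.9	1.2	5.2 to 9.4	Q10 for deactivation
mTRPA1	-	1.50	1.45	1.69	n.d.	2.8	-	-
DmTRPA1	-	1.47	1.54	1.72	n.d.	11	-	-
TRPV1	-	1.44	1.52	1.66	0.5 to 0.7	~ 15 to 40	1.35	Q10 for deactivation
TRPV2	-	1.49	1.52	1.55	n.d.	> 100	-	-
CNGA1	-	1.77	1.93	1.82	~ 0.22	n.d.	-	-
CNGA2	-	1.64	1.78	1.68	n.d.	2 to 6	-	Q10 max ~6 near [cGMP]/EC50 = 0.1
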