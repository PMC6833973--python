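# S3 flexibility vs stretch-induced shifts of the half-activation
# voltage, compiled from published electrophysiology literature.
# dv12_shift in mV under membrane stretch; ranges use "a to b",
# "x ± y" denotes mean ± sem; ";" separates independently reported
# conditions (parsed as the overall envelope).
channel	domain	s3_index	s3s4_index	charge_e0	mechanosensitive	dv12_shift	notes
Nav1.5	DI	1.61	1.71	~ 12	true	-5 to -35	pressures -10 to -50 mmHg
BK (Slo1)	-	1.55	1.67	2.4 to 4.4	true	-4 to -20	depends on conditions
Nav1.5	DIV	1.55	1.64	~ 12	true	-5 to -35	pressures -10 to -50 mmHg
Shaker Kv1	-	1.48	1.96	12 to 16	true	-8.8 ± 1.3	-
Cav1.2	DI	1.48	1.79	~ 9	true	-1.4 ± 0.4	-
Nav1.5	DIII	1.45	1.73	~ 12	true	-5 to -35	pressures -10 to -50 mmHg
Cav2.2	DIII	1.44	1.92	~ 9	true	0 ; -7 to -18	activation ~0; inactivation shifted
Kv7.1 (KCNQ1)	-	1.41	1.61	~ 8	true	-13 ± 1.9	-
hHv1	-	1.40	1.49	6	true	-14.4	-10 mmHg pipette pressure
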