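# SYNTHETIC stand-in S3 consensus sequences used as the scale
# calibration reference set.  These are NOT curated family consensus
# sequences: each is a constructed S3-length sequence (NxxD anchor to
# helix C-end) whose residue composition reflects the published
# character of the family segment — Hv1-like: aromatic/aliphatic-rich
# and rigid; Kv1-like: intermediate, with the paddle-motif proline and
# the S4-facing acidic/basic residues; CNG-like: polar/charged-rich
# and flexible, with the P-T-D paddle start.  reference_index is the
# family's S3 flexibility index (1/mBf) from the packaged functional
# table; calibrate_scale() fits the affine mBf calibration to these
# pairs.  Substitute curated consensus sequences here to recalibrate
# against real family data.
family_id	s3_sequence	reference_index
hHv1	NIFDFFVVFVGLWIV	1.40
Kv1.2	NPLDIVSEAMTRLIQ	1.61
CNGA1	NSGDKEQSTPTDSGE	1.77
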