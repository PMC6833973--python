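# Methods

## Consensus and logo construction

A family alignment (FASTA or Clustal, `-` gaps, `X` unknown) is reduced
to per-column counts.  Gaps and `X` are excluded from residue
frequencies and counted in a per-column gap fraction; columns with gap
fraction ≥ 0.5 are flagged and excluded from consensus segments
(majority-occupancy, the standard logo practice).  The rank-r consensus
takes the r-th most frequent residue per column, ties broken
alphabetically by one-letter code so the result is deterministic and
independent of record order.  A rank that does not exist (fewer distinct
residues than ranks) is written as the sentinel `.` and excluded from
all downstream averaging.

Logo information content is Shannon information in bits,
IC = log2(20) − H(column), with letter heights frequency·IC.  No
small-sample correction is applied; the correction depends on alignment
depth and is omitted so that identical column compositions always give
identical logos.

## Segment windows

Coordinates are 1-based; windows are half-open `[start, end)`.  The
anchor is the NxxD motif (variants FxxD and C/S-x-x-D for the families
that use them); position 4 of every pattern is the conserved CTC
aspartate.  When several matches occur, the match closest to the
annotated S3 N-terminus is taken (the motif is the unique S3a anchor);
without an S3-start annotation the earliest match compatible with the
S3 C-end is used.  Windows: S3 = [anchor, s3_end+1), S3–S4 =
[anchor, s4_end+1), S1–S4 = [s1_start, s4_end+1).  Segment boundaries
are always inputs (curated from sequence databases and the literature),
never inferred, and an anchor outside the annotated S3 is an error, not
a silent correction.

## Flexibility profiling

Two normalized B-factor scales ship as TSV files with provenance
headers so exact published values can be substituted:

* `bnorm-vihinen` (default) — Vihinen-type normalized flexibility
  averages; per-residue mean ≈ 0.99.
* `bnorm-karplus-schulz` — the classic Karplus–Schulz normalized
  backbone B-values; per-residue mean ≈ 1.03.

Both score flexible side chains high.  Smoothing uses a 9-residue
window with symmetric triangular weights 1 2 3 4 5 4 3 2 1 (normalized),
reflecting that a side chain's mobility depends on its sequence
neighbours.  At the sequence ends the window is truncated and the
remaining weights renormalized; this (rather than mirroring or
dropping edge positions) keeps the homopolymer profile exactly
constant.  Sentinel/gap positions are removed before smoothing.

mBf is the arithmetic mean of the smoothed values and the flexibility
index is exactly 1/mBf.  The per-family dispersion is the population
standard deviation of the indices of the (up to three) consensus
ranks — the rank-2/rank-3 sequences enter the analysis only through
this spread.

### Calibration and orientation

Raw 1/mBf of a mean-1 scale is *lower* for flexible segments, while the
reported family indices follow the field convention larger = more
flexible, on a 1.40–1.77 span.  The package therefore separates the
scale (residue values, mean ≈ 1, auditable) from an affine calibration
of mBf: `mBf_cal = u·mBf_raw + w`, index = 1/mBf_cal.  Because the
index is a reciprocal, fitting u, w is an ordinary linear least squares
of 1/target-index on raw mBf — deterministic, no iteration.  A negative
slope u flips the orientation.

The packaged calibration reference set
(`data/synthetic_s3_consensus.tsv`) contains three **synthetic
stand-in** S3 consensus sequences — curated family consensus sequences
are not redistributable here — constructed from the published
compositional character of the families: Hv1-like
(aromatic/aliphatic-rich, rigid), Kv1-like (intermediate, with the
paddle proline and S4-facing charges) and CNG-like (polar/charged-rich
with the P-T-D paddle start).  Their reference indices are the
corresponding values of the packaged functional table (1.40, 1.61,
1.77).  With this calibration the three indices are reproduced at
one-decimal precision and the ordering CNGA1 > Kv1.2 > hHv1 holds under
either packaged scale; users with curated consensus sequences should
substitute them in that file and recalibrate.

Mean relative solvent accessibility (RSA) values are a typical
per-residue exposure set (fractions in [0, 1], polar/charged exposed,
aliphatic/aromatic buried) used as a secondary stability-oriented
index.

### Classification

Tertile mode splits the supplied indices at their 1/3 and 2/3 quantiles
(linear interpolation); a value exactly at a boundary goes to the lower
(more rigid) class.  Explicit thresholds are also accepted.  At least
three families are required for tertiles.

## Charge-transfer-center geometry

First model only, hydrogens dropped, one conformer per atom (highest
occupancy; ties to the alphabetically first altloc), no symmetry mates.
Donors: Lys NZ; Arg NE/NH1/NH2 — the guanidinium nitrogens; some
descriptions label them Nζ/Nη1/Nη2, which is an alias (arginine has no
Nζ) and is documented rather than silently corrected.  Acceptors: Asp
OD1/OD2 and Glu OE1/OE2 (Glu is accepted because TRPV-family CTCs use a
glutamate in the equivalent position).  A salt bridge is a
donor-nitrogen/acceptor-oxygen pair at distance ≤ 4.0 Å, inclusive
exactly as the criterion is stated.  Superposition RMSD uses the Kabsch
algorithm on Cα atoms of ≥ 3 corresponding residues, with the
determinant correction against improper rotations; tests cross-check it
against an independent quaternion (Horn) implementation.

## Functional table and correlation

The packaged fixture transcribes per-channel annotations compiled from
the electrophysiology literature: S3/S3–S4/S1–S4 indices, gating charge
e₀, Q₁₀ of activation and inactivation kinetics, stretch-induced ΔV₁/₂.
Cells keep their printed character: ranges (`12 to 16`), approximations
(`~ 4`), bounds (`> 100`), mean ± sem, `n.d.`.  Ranges are represented
as intervals and reduced to midpoints for fitting (the least-assumption
point estimate); the interval is retained for reporting.  The same
channel may appear in both tables with slightly different transcribed
indices; both rows are kept, tagged by source table.  Cross-table joins
use the voltage/temperature table.

The trend fit f(x) = a·exp[b/(x + c)] is nonlinear least squares
(trust-region reflective) with c bounded below so x + c > 0 over the
data — the unconstrained optimum can run to a pole outside the domain.
Default initialization: a = max(y), c = 1 (plus two data-scaled
alternatives), b from the log-ratio of the endpoint values; the best of
the small deterministic multi-start is returned, with
R² = 1 − SSres/SStot.  The x-variable of the published family-trend is
ambiguous, so both candidates are computed: family rank (families
ordered by decreasing index; the primary, matching the per-family
distribution layout) and gating-charge midpoint.  On the packaged table
these give R² = 0.94 (n = 24) and 0.32 (n = 20) respectively — the
package computes both at run time; the numbers here are what the tests
and acceptance script print.

Spearman correlations use exact permutation p-values (all n!
permutations) for n ≤ 8 and a seeded Monte-Carlo estimate (default seed
20190, 10,000 draws) above.  Class-vs-trait association uses the
Fisher–Freeman–Halton exact test: full enumeration of 2×k tables with
the observed margins, p = Σ of probabilities of tables at most as
probable as the observed one.

## Synthetic data

Family generator: per-column categorical sampling (explicit
distributions, or two-residue rigid/flexible mixtures hitting a target
mean raw B-value per region), motif implanted at a fixed column in
every sequence, optional substitution noise that never touches motif
columns.  Sequences are sampled independently (star topology): the
generator does not emulate phylogenetic correlation between sequences,
so tests passing on synthetic families show correctness of the
computation, not robustness to tree-structured redundancy in real
alignments.  Toy structures place donor/acceptor residue pairs with the
prescribed distance between their functional atoms, side-chain atoms
oriented away from the partner and jitter restricted to rotation about
the pair axis so the prescribed distance is also the set-minimum;
B-factor columns carry the residue's raw scale value.  All generators
are pure functions of spec and seed.

## Problem sizes and numerics

The test suite runs family alignments of 30–200 sequences and 1,000
random-column property sweeps; null calibration of the association test
uses 200 seeded replicates of 12 channels.  These sizes give stable
pass/fail behaviour on a single CPU in well under a minute per module.
Tolerances: frequency/logo identities at 1e-9; fit parameter recovery
at 1e-6 on exactly generated data; superposition vs the quaternion
oracle at 1e-6; toy-structure distance round trips at PDB coordinate
precision (1e-3 Å).

## Known limitations

* The exact published flexibility scales behind the transcribed family
  indices are not identifiable from their citations alone; the packaged
  scales are the field's standard normalized B-factor sets and the
  calibration absorbs the affine uncertainty.  Bit-exact reproduction
  of every transcribed index is therefore out of reach by design;
  calibration targets are matched at one-decimal precision.
* The calibration reference sequences are synthetic stand-ins (see
  above), not curated consensus sequences.
* Structural distance checks need the published coordinate entries,
  which are not redistributable with the package
  (`data/structures/<id>.pdb`).
* Boundary annotations are trusted inputs; the package never predicts
  transmembrane segments.
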