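# Methods

This note documents the models, conventions and numerical choices behind
`nucsox`, in the order the pipeline uses them.

## Coordinate conventions

Nucleosomal DNA positions are indexed two ways. *Dyad-relative* indices are
integers with 0 at the dyad nucleotide of the forward strand, negative
toward its 5' end; motif windows are inclusive on both ends (the
triple-insert design places the consensus at −4..7, 16..27 and 37..48).
*Superhelical locations* divide the dyad-relative index by the helical
period (default 10.0 bp — the canonical value is "about 10", so it is a
parameter, not a constant) and round to the nearest integer with
half-period ties toward zero. Author residue numbers (1-based) are used in
every user-facing selection; insertion codes are rejected rather than
silently reinterpreted, because neither the engineered constructs nor the
reference structures need them.

A duplex map is inferred, not assumed: strands are paired by strict
Watson–Crick complementarity (A–T, G–C; wobble rejected, since the
constructs are designed WC duplexes) plus two geometric gates — a C1′–C1′
distance of 9–12 Å, and alignment of each base's glycosidic direction
(C1′ → N9/N1) with the inter-C1′ vector (cosine ≥ 0.5). The second gate is
what makes pairing unambiguous: in helical geometry a complementary base a
few steps along the *other* strand can sit at a WC-like C1′–C1′ distance,
but its base points the wrong way. Antiparallel ordering of the partners
is then verified, and inference fails loudly if fewer than half the
forward nucleotides pair.

## Trajectories and equilibration

A trajectory is an ordered list of structures on one atom roster (identity
triple chain/residue/atom). Frames with permuted rosters are accepted and
canonically re-ordered; genuinely differing rosters are an error naming
the first mismatch. Frame *i* carries time (i+1)·Δt with Δt the recording
interval (default 0.5 ns). Equilibration is metadata: frames with
t ≤ burn-in are flagged and excluded from every analysis operation but
never deleted, so raw data survive round-trips. With 1000 frames at 0.5 ns
and a 200 ns burn-in this yields the canonical 600 analyzed frames per
replica.

## Superposition and P-RMSD

Rigid superposition is least-squares Kabsch restricted to proper rotations
(reflections are never allowed — DNA is chiral), computed via
`scipy.spatial.transform.Rotation.align_vectors`. Collinear or coincident
point sets raise a conditioning error instead of returning an arbitrary
rotation. The test suite cross-checks the implementation against an
independently coded quaternion-eigenvalue (Horn) solver; agreement is at
machine precision, and the numerical identity floor is ~1e−7 Å, which is
why "zero" assertions use a 1e−6 Å bound.

P-RMSD fits and evaluates on the phosphorus atoms of a 7-nucleotide
recognition window (the consensus core `GACAATG`; windows −3..3, 17..23
and 38..44 for the dyad, SHL2 and SHL4 sites). Fitting on the RMSD atoms
themselves is the default, matching the common behavior of structure-fit
tools; `fit_selection` makes the anchor configurable. That choice matters:
a smooth local groove deformation is largely absorbable by a rigid fit of
the deformed atoms themselves, so analyses that want to resolve the *local*
deformation against the nucleosomal frame should anchor the fit on
flanking phosphates (the end-to-end tests do exactly this and document the
magnitudes both ways). Bound-compatibility is summarized as the fraction
of analyzed frames with P-RMSD inside the inclusive 0.7–2.2 Å band.

## Minor-groove widths

The raw width at forward position *i* is the minimum over offsets
k ∈ {2, 3, 4} of the distance from P_forward(i) to the reverse-strand
phosphate paired with position i+k, ties to the smaller k. The offset
window tracks the groove across bending without fixing a single register;
on an ideal fiber duplex the minimizer is k = 3 and the profile agrees
exactly with an exhaustive cross-strand P–P scan. Raw phosphate–phosphate
distances are the default convention because the 22.5 Å Sox-bound
fingerprint is a raw P–P magnitude; the refined convention (raw − 5.8 Å,
two phosphate-group radii, floored at 0) is available by flag. Positions
whose offset window leaves the duplex, or whose phosphates are missing
(5′-terminal nucleotides carry none), are flagged undefined — never
zero-filled; more than 10% unexpectedly missing phosphates is an error.

## Thermal fluctuations

RMSF is computed after superposing every analyzed frame onto the first
analyzed frame on a fit selection (default: the profiled atoms), then
B = (8π²/3)·RMSF² per atom. A rigid-body fit absorbs 6 of the 3N
displacement degrees of freedom, biasing RMSF low by a factor
√(1 − 2/N); the closed-form recovery tests therefore use ≥120 fitted
atoms, where the bias is under 1%.

## Contacts and barcodes

Three classes are detected per frame with auditable geometric criteria:
hydrogen bonds (donor–acceptor heavy-atom distance ≤ 3.5 Å; the D–H…A
angle ≥ 120° is enforced only when explicit hydrogens exist, since
crystal-derived and reduced synthetic structures lack them), hydrophobic
contacts (apolar carbon–carbon ≤ 4.4 Å, apolar meaning not bonded to N/O
per residue template), and ionic contacts (Arg/Lys/His side-chain
nitrogens to phosphate oxygens ≤ 4.0 Å). All thresholds are parameters of
`ContactCriteria`. A contact is *base-specific* when the DNA-side atom
belongs to the nucleobase template (sugar and phosphate atoms are
backbone) — the dichotomy separating sequence reading from backbone
binding. Events are deduplicated per (residue pair, class, base-specific
flag, frame), which is the granularity of barcode plots; persistence is
the row mean of the presence matrix. The default residues of interest are
Arg51, Asn54, Phe56, Met57 and Tyr118 in the reference Sox numbering. The
KD-tree pair search is checked against an O(n²) all-pairs loop for exact
set equality.

## Conformer selection and restraints

The bound-compatible conformer is the analyzed frame with the lowest
P-RMSD to the Sox-bound DNA reference, ties to the earliest frame.
Restraints pair the FM-wedge residues (56, 57 by default) with the site
anchor nucleotides (dyad-relative 0, 20, 41); the target distance is the
*minimum heavy-atom distance* between the pair in the reference complex —
a minimal-assumption stand-in, since crystal-derived distance lists rarely
state their anchor atoms — with a ±0.5 Å default tolerance. Output (TSV or
CNS/AIR `assign` statements) is byte-stable; running docking itself is out
of scope by design, the contract ends at a valid restraint file.

## Titration quantification

Band intensities are normalized per lane against internal-standard bands
and then against the zero-concentration lane, making the series invariant
to exposure scaling. Curves are fitted to f1(x) = a·e^(bx) + c·e^(dx) by
Levenberg–Marquardt least squares from 16 starts (log-spaced |b|, |d| in
[1e−5, 1e−1], a = f(0), c small, 1% seeded jitter) — the biexponential is
multimodal and symmetric under term exchange, so the best-of-starts fit is
reported with the dominant-amplitude term first. R² = 1 − SSres/SStot
(undefined and flagged for constant series), RMSE = √(SSres/n). No sign
constraints are imposed on b and d: published fits mix signs, and with
d > 0 the curve has no finite asymptote. Consequently the "half-level of
the signal change" must be bounded by the assay range: Kd_app solves
f1(x) = (f1(0) + f1(x_max))/2 on [0, x_max] by bracketed root finding
(first crossing, 0.01 nM tolerance), with x_max the maximal assayed
concentration (1000 nM for naked DNA, 3000 nM for nucleosomes in the
dilution protocol, step 1.5). Non-monotone fitted curves warn; increasing
curves are an extraction error. Kd_app is operational and must not be read
as the thermodynamic Kd.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the analysis layer needs, from a single
seed fanned out into per-operation substreams (CRC of the operation name),
so all fixtures are reproducible and mutually independent.

*Fiber B-DNA*: rise 3.38 Å, twist 36°/bp, phosphate radius 9.4 Å, strand
phase offset 154°, reduced nucleotides (phosphate group, C1′/C2′,
glycosidic nitrogen, ring and WC-edge atoms). This gives a uniform
interior minor groove of ≈12.5 Å raw P–P — a sensible relaxed baseline —
but is deliberately not sequence-dependent and has no histone core,
no backbone torsional detail and no sugars beyond two carbons.

*Groove deformation*: phosphate groups are displaced along the local
cross-groove axis (the P_f(i) → P_r(pair(i+3)) direction of the undeformed
duplex) under a cosine window, with the amplitude calibrated by bisection
so the measured raw width at the window center hits the requested target
(22.5 Å for the Sox-bound fingerprint) within 0.3 Å; atoms outside the
window move < 1e−6 Å and disjoint deformations commute. Displacement along
the groove axis rather than radially is essential: some cross-strand
phosphate pairs are nearly parallel in azimuth, so radial displacement
cannot separate them.

*Trajectories*: frame coordinates are an optional linear (or scheduled)
interpolation toward a target conformation plus i.i.d. per-axis Gaussian
noise. This emulates drift and thermal fluctuation amplitudes only — there
is no inertia, no correlated motion, no force field. Passing tests on
these fixtures validates the *measurement* layer, not any claim about real
nucleosome dynamics.

*Contact probes*: single-atom pseudo-residues (labeled with the Sox
residues of interest) placed at planned distances from base or backbone
atoms, refusing placements within 1.5 Å of DNA atoms.

*Titrations*: exact biexponential curves with seeded multiplicative
Gaussian noise.

Study-condition defaults mirror the experimental protocol where one
exists: 0.5 ns frame interval, 200 ns burn-in, 600 analyzed frames per
replica, dilution step 1.5 with 1000/3000 nM maxima, 2% multiplicative
gel noise as a realistic densitometry error. Problem sizes in the test and
acceptance runs (31-bp duplexes, 20–150-frame drift trajectories, 10,000
frames for RMSF closed-form checks) are chosen so every statistical
tolerance is comfortably resolved on a single CPU.

## Known limitations

- The duplex pairer assumes B-form-like geometry; strongly melted or
  flipped-out bases would fail the glycosidic gate (by design, loudly).
- Hydrogen-bond detection without hydrogens is distance-plus-typing only;
  donor geometry is not inferred.
- The groove-width offset window {2, 3, 4} targets the minor groove of
  near-canonical duplexes; extreme unwinding could shift the true register
  outside it (the exhaustive-scan oracle in the tests guards the regime
  the package is used in).
- Biexponential parameters are reported as fitted; when a term is
  negligible (c ≈ 0) the individual parameters of that term are not
  identifiable, and only function-space recovery is meaningful.
- The apparent-Kd convention (assay-range midpoint) is one declared choice
  among several possible readings of "half signal change"; values are only
  comparable under the same convention and the same x_max.
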