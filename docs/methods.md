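# Methods

## Temperature-coefficient hydrogen-bond inference

The amide ¹H shift of each residue is regressed on temperature by ordinary
least squares after converting shifts to ppb (1 ppm = 1000 ppb), so the slope
is in ppb/K with the field's sign convention (more negative = more exposed).
The intercept is reported as the predicted shift at the 298 K reference
temperature. The standard error of the slope comes from the residual
variance; an exactly constant series is returned with slope 0 and zero
uncertainty rather than an undefined correlation.

Classification uses the empirical −4.6 ppb/K threshold: slopes strictly above
it are hydrogen bonded, strictly below exposed. Two refinements handle the
boundary honestly:

* when the symmetric normal band `slope ± ci_multiplier × SE` (default 1.96,
  i.e. 95%) contains the threshold, the residue is *unclassified* — the
  literature rule quantifies no error range, so the multiplier is
  configurable and the band can be disabled;
* an exact tie is unclassified, because the strict >/< rule covers neither.

Prolines have no amide proton and are excluded before fitting; they are
carried through every table and summary as their own class so totals always
partition the residue count. Fitting requires at least `min_points = 3`
temperatures (configurable, ≥ 2). Curved temperature dependence and
¹⁵N-based coefficients are out of scope; ¹⁵N shifts are carried for
bookkeeping only.

## Geometric hydrogen-bond detection and consensus

Crystal reference models lack amide hydrogens, so they are rebuilt in the
peptide plane: H sits 1.02 Å from N along the direction opposing the bisector
of the C(i−1)→N and CA(i)→N bonds, which places it coplanar with C(i−1), N,
CA and trans to both — the standard idealized amide geometry. Chain-initial
residues and prolines receive no H; residues missing a backbone atom are
skipped with a warning.

A backbone N–H···O=C contact is accepted as a hydrogen bond under
conventional Baker–Hubbard-style distance/angle criteria — d(H···O) ≤ 2.5 Å,
d(N···O) ≤ 3.5 Å, ∠(N–H···O) ≥ 120° — all three configurable, since the
source workflow states no explicit geometry. Pairs closer than two residues
in sequence are excluded, and by default each donor keeps only its closest
(smallest H···O) acceptor so the derived restraints are unambiguous; a
multi-acceptor mode exists for diagnostics. Side-chain and bifurcated bonds,
and DSSP-style electrostatic scoring, are deliberately out of scope.

Consensus over reference monomers retains a (donor, acceptor) residue pair
when it appears in at least `min_fraction` (default 0.5 — a majority) of the
monomers; the tally is a straight per-model count from the detector.

## Restraint derivation and the CYANA dialect

Each residue classified hydrogen bonded *and* possessing a consensus acceptor
contributes one bond, encoded as the conventional two-restraint pair: upper
bounds H–O ≤ 2.0 Å and N–O ≤ 3.0 Å, lower bounds 1.8 and 2.7 Å (all four
configurable). Ties between acceptors break toward higher support, then lower
residue number, deterministically. Hydrogen-bonded residues without a
consensus partner are returned explicitly — they are the gap between
CSTC-positive and restrainable residues, and a real workflow should inspect
them rather than lose them.

Restraints are written as fixed-column text, one line per bound
(`resnum resname atom resnum resname atom distance`, distance at 2 decimals),
upper bounds to `.upl` and lower bounds to `.lol`; the exact byte layout is
locked by a golden-file test and round-trips through the bundled parser.
Writing rejects any atom pair whose lower bound exceeds its upper bound.

Reference monomers are mapped onto the analysis numbering frame only through
an explicit per-file offset (default 0, matching the near-identical numbering
of the mouse/human stomatin domains); nothing is renumbered silently, and a
disjoint numbering frame between classes and consensus raises an error
instead of yielding zero restraints.

## Chemical-shift perturbation

`Δδ_H,N = sqrt(Δδ_H² + (Δδ_N/s)²)` with nitrogen scale s = 5 (configurable
for other nuclei conventions). Tier thresholds are inclusive (≥ 0.015 ppm
moderate, ≥ 0.020 ppm strong). Differences are table A minus table B; the
combined delta is symmetric under swapping the tables and scales linearly.
Residues present in only one table — in practice exchange-broadened or
overlapped signals — are reported as unmatched, never dropped, since "how
many signals moved" is itself a result. The patch statistic (centroid and
max pairwise Cα distance) supports the qualitative claim that perturbed
residues form a contiguous surface: a planted patch is compared against
random same-size residue subsets, a property test rather than a fixed
threshold.

## Superposition and precision statistics

Superposition is least-squares optimal over proper rotations (Kabsch, via
scipy's `Rotation.align_vectors`); a determinant of +1 is asserted on every
call, and collinear or undersized point sets are rejected because the
rotation is underdetermined. Ensemble precision is the iterative fit-to-mean
statistic: all models are superposed on the current mean, the mean is
recomputed, and the loop runs until the mean moves < 1e-6 Å (max 100
iterations), initialized deterministically from model 1. The reported value
is the mean ± sample sd of per-model r.m.s.d. to the converged mean. The
crystal-monomer spread uses mean pairwise superposed r.m.s.d. instead,
matching that context's convention; both are exposed.

`BACKBONE` is {N, CA, C} — the common NMR-precision convention; the carbonyl
O is excluded. `HEAVY` is all non-hydrogen atoms, and a `SIDECHAIN_HEAVY`
selection is also provided because precision figures are quoted under both
conventions in the literature; at the sd printed alongside such figures the
distinction is absorbed by the uncertainty.

## Synthetic data: what it emulates and what it does not

* **Ideal helix**: poly-alanine backbone (plus CB) from ideal bond geometry
  and α-helical dihedrals (φ = −57°, ψ = −47°, ω = 180°), giving known
  i+4 → i hydrogen bonds with d(H···O) ≈ 2.1 Å. Optional Gaussian coordinate
  noise turns it into a multi-model ensemble; 0.15 Å per coordinate is used
  as a representative well-defined-NMR-ensemble scatter and 0.30 Å as a
  representative crystal-monomer scatter.
* **Temperature series**: four temperatures (288–303 K), per-residue slopes
  drawn uniformly from [−4.0, −1.0] ppb/K (bonded) or [−9.0, −5.2] ppb/K
  (exposed) — both clear of −4.6 so noiseless recovery must be exact — base
  ¹H shifts in 7.5–9.5 ppm, measurement noise default 2 ppb. A hard mode
  draws slopes spanning the threshold to exercise the unclassified band.
  The default scale (113 residues, 56% bonded, 3 prolines) mirrors a typical
  SPFH-domain-sized analysis.
* **CSP pair**: condition B equals condition A plus a (0.03 ppm ¹H,
  0.20 ppm ¹⁵N) effect on a planted patch — a combined delta of exactly
  0.05 ppm — with independent measurement noise on both tables.

One integer seed drives all randomness; identical seed and parameters
reproduce bit-identical files. The generators do **not** emulate peak
overlap, exchange broadening, curved temperature dependence, or correlated
coordinate error, so green synthetic tests establish the correctness of the
computations and the recoverability of planted signals under iid noise — not
performance on crowded real spectra.

## Verification strategy

Every computation is checked against an independent route: OLS against the
closed-form normal equations (to 1e-9), bond detection against an exhaustive
all-pairs search on random structures, superposition against a numeric
rigid-body minimizer and 100 random rigid motions, fit-to-mean precision
against a vectorized Monte-Carlo expectation (10⁴ replicates), consensus
against a hand tally, and the end-to-end pipeline against byte-identical
reruns. Checks on the deposited coordinates (20-model ensemble precision over
residues 98–195; pairwise spread over the 11 crystal monomer chains) run
whenever the entries are present under `data/reference/`; they are fetched on
demand rather than redistributed with the package.

## Numerical choices and limitations

Output precision is fixed (shifts 3 decimals ppm, distances 2 decimals Å) so
pipeline outputs are byte-stable. Altloc resolution keeps the highest
occupancy (ties keep the first encountered) and is logged. Models within one
file that disagree in atom content are harmonized to their common skeleton
with a warning. Known limitations: no side-chain donors/acceptors, no
bifurcated bonds, no Kd estimation from titrations, no flexible or partial
superposition, and the residue window for cross-species monomer comparisons
must be chosen by the user (the shared structured core is a reasonable
default and is what the acceptance checks use).
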