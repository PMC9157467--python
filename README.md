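# hbondnmr

NMR-driven backbone hydrogen-bond analysis for small protein domains, built
around the workflow used to solve solution structures when hydrogen-exchange
data are unavailable (for example, the SPFH domain of human stomatin, whose
lyophilized sample dissolves too slowly in D₂O for a conventional H/D exchange
experiment).

## What it computes

**Amide-proton temperature coefficients (CSTC).** For each residue, the amide
¹H chemical shift δ_H is measured at several temperatures and fit by ordinary
least squares:

    δ_H(T) = δ₀ + m·T,   m in ppb/K

A shallow slope, m > −4.6 ppb/K, indicates the amide proton is protected in an
intramolecular hydrogen bond; a steeper slope indicates a solvent-exposed
amide. Residues whose confidence band m ± 1.96·SE straddles the threshold are
left unclassified; prolines (no amide proton) are tallied separately.

**Hydrogen-bond restraint derivation.** Acceptors for the CSTC-positive
donors are located geometrically in reference coordinates (e.g. independent
crystal monomers of a homologous domain): a backbone N–H···O=C contact counts
as a bond when d(H···O) ≤ 2.5 Å, d(N···O) ≤ 3.5 Å and ∠(N–H···O) ≥ 120°, and
a donor–acceptor pair is kept when it recurs in at least half of the
monomers. Each matched donor yields one hydrogen bond encoded as two upper
bounds (H–O ≤ 2.0 Å, N–O ≤ 3.0 Å) plus two lower bounds (1.8 / 2.7 Å) in
CYANA `.upl`/`.lol` text format — e.g. 52 matched donors → 104 upper-bound
restraints.

**Chemical-shift perturbation (CSP) mapping.** Between two buffer conditions
(e.g. phosphate present/absent), the combined amide perturbation per residue is

    Δδ_H,N = sqrt( Δδ_H² + (Δδ_N / 5)² )   [ppm]

tiered inclusively at Δδ ≥ 0.015 (moderate) and Δδ ≥ 0.020 ppm (strong), and
mapped onto a structure through the B-factor column for coloring. A patch
statistic (max pairwise Cα distance) shows whether the hits cluster into a
plausible binding surface.

**Ensemble precision.** Kabsch superposition (proper rotations only) feeds
two statistics: iterative fit-to-mean r.m.s.d. (the NMR ensemble precision
figure, e.g. backbone over a chosen residue window) and mean pairwise
r.m.s.d. (the spread among crystal monomers).

A seeded synthetic-data module generates every input with planted ground
truth — ideal α-helices with known i+4→i bonds, four-temperature shift tables
with slopes drawn from the bonded/exposed populations, two-condition tables
with a planted perturbation patch — so the full pipeline is testable without
spectrometer data.

## Worked example

```sh
python examples/temperature_coefficients.py
```

```
residues analysed:        113
hydrogen bonded (> -4.6): 59
exposed (< -4.6):         51
unclassified (CI band):   0
prolines (no amide H):    3
agreement with planted truth: 100.0%
e.g. residue 1: slope -8.07 +/- 0.19 ppb/K (r^2 = 0.999)
```

A 113-residue domain is simulated at 288/293/298/303 K with 2 ppb measurement
noise; the per-residue OLS slope classifies 59 residues as hydrogen bonded
(slope above −4.6 ppb/K), 51 as exposed, and recovers every planted class.

```sh
python examples/hbond_restraints.py
```

```
consensus hydrogen bonds in reference: 56
CSTC-positive donors with a partner:   52
upper-bound restraints written (.upl): 104  (2 per hydrogen bond)
lower-bound restraints written (.lol): 104
hydrogen bonded but unrestrained:      0
first line:    5 ALA  H       1 ALA  O        2.00
```

The 52 CSTC-positive donors with consensus acceptors yield 104 upper-bound
restraints — two (H–O and N–O) per hydrogen bond. `examples/csp_mapping.py`
and `examples/ensemble_precision.py` demonstrate the other two capabilities;
the `hbondnmr` command exposes the same stages as shell subcommands
(`simulate`, `cstc`, `hbond`, `csp`, `ensemble`, `run`), with `run` driving
the full pipeline from a YAML config and writing a machine-readable report.

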