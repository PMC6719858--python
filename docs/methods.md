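# Methods

`ssbkit` packages the quantitative analyses that surround a case study of
the mitochondrial single-stranded DNA-binding protein (SSBP1, mtSSB): a
heterozygous E27K substitution in the nuclear *SSBP1* gene co-occurring
with a single large-scale mtDNA deletion (SLSMD), m.8629_14068del5440.
The raw instrument and simulation outputs behind such a study (Amber
trajectories, plate-reader melt curves, fluorometer titrations, droplet
counts) are rarely deposited, so the package pairs every estimator with a
seeded synthetic generator whose ground truth is known, making each
analysis stage testable end to end.

## Trajectory statistics

A trajectory is an ordered stack of coordinate frames over a fixed atom
roster (multi-model PDB in, `TrajectoryEnsemble` in memory). Supported
statistics:

* **Superposition / RMSD.** Kabsch least-squares rigid superposition (SVD
  with the determinant correction for the reflection case; collinear or
  <3-point inputs are rejected). `rmsd_series` superposes every frame on
  the reference before taking the RMSD; `convergence_check` declares a
  series converged when its trailing-window range falls below a tolerance
  (default 0.5 Å; window must hold ≥ 10 points).
* **Cα deviation maps.** Δ_ij = ⟨d_ij(t)⟩_window − d_ij(frame 0), signed:
  negative means the residue pair moved closer, positive farther. Pairwise
  distances are rigid-motion invariant, so no superposition enters the
  map. The "initial" frame defaults to frame 0 of the provided ensemble
  (configurable). Default window: trailing third of the frames, mirroring
  the convention of analysing the equilibrated final third of a
  production run; every frame in the window is used.
* **Pair mobility fraction.** The share of residue pairs (i<j, diagonal
  excluded) with |Δ_ij| ≤ threshold (default 2 Å, applied to the absolute
  deviation), split by scope: intra-monomer (same chain), inter-monomer,
  or overall. It is non-decreasing in the threshold by construction.
* **RMSF / B-factors.** RMSF_i = √⟨|r_i(t) − r̄_i|²⟩ after optional
  per-frame Kabsch alignment; B_i = (8π²/3)·RMSF_i²; the *normalized*
  B-factor is B_i / mean(B), a choice documented here because the field
  uses several conventions — mean(normalized B) is exactly 1, and a
  numerically static profile is reported as uniformly 1. Alignment
  removes six rigid degrees of freedom and therefore shrinks apparent
  fluctuations by a factor ≈ (1 − 2/N_atoms); with the 48-atom test
  system this stays inside the 5% recovery tolerance.

## Solvent-accessible surface area and charges

Shrake–Rupley SASA with a deterministic golden-spiral point lattice
(default 960 points, 1.4 Å water probe): per-atom area is the accessible
fraction of the solvent-expanded sphere 4π(r+probe)². No RNG is involved,
so results are bit-reproducible. Radii come from a Bondi-style van der
Waals table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å); a coarse
`ca_spheres` mode (uniform 3.0 Å) makes Cα-only toy structures testable.
The charged-surface decomposition sums per-residue areas over Lys/Arg
(positive) and Glu/Asp (negative) and reports net = positive − negative;
histidine is treated as neutral, and decomposition is keyed by residue
name, not titration state. Trajectory-averaged decompositions report mean
± SD over a trailing window. Absolute SASA values depend on engine and
radius choices, so only the decomposition arithmetic, orderings and
analytic-sphere limits are asserted, never absolute areas.

Formal charges use the unit-charge model K/R = +1, E/D = −1, others 0.
An E→K substitution therefore changes a monomer by +2e, and a tetramer by
+2e per mutated monomer (+8e when all four are). For the canonical human
SSBP1 construct modelled in such studies (precursor residues 26–140, the
crystallographically ordered core), the four chains carry 68 K/R against
52 E/D residues — a net +16e. Salt bridges are basic/acidic residue pairs
whose charged-group atoms (Lys NZ; Arg NH1/NH2/NE; Glu OE1/OE2; Asp
OD1/OD2) approach within 4 Å (all-atom) or whose Cα atoms approach within
8 Å (coarse mode); detection is an exhaustive pair scan, tested against
an independent brute-force enumeration.

## Binding and thermal-stability assays

**Anisotropy titrations.** At 20 nM labelled DNA the protein–DNA complex
consumes a non-trivial share of total protein, so the fit uses the
quadratic ligand-depletion (Morrison) closed form

    FB = ((P + D + Kd) − √((P + D + Kd)² − 4 P D)) / (2 D)

with the discriminant clamped at zero against rounding, composed with
A(P) = a_free + (a_bound − a_free)·FB. P is the **tetramer**
concentration — monomer/tetramer confusion is a 4× error in Kd.
Stoichiometry is fixed at one tetramer per DNA molecule (the study's gel
shift control supports 1:1 binding). Fitting is unweighted least squares
by default (1/SD² weighting optional), initialized from the first point
(a_free), last point (a_bound) and the concentration nearest
half-amplitude (Kd), with Kd bounded positive and bounded restarts on
failure. With ≥ 3 replicate curves the reported Kd SD is the
replicate-level standard deviation, matching how triplicate experiments
are usually summarised; otherwise it comes from the covariance diagonal.

**DSF melt curves.** The melting temperature is the peak of the smoothed
first derivative dF/dT (Savitzky–Golay window 7, quadratic — the
instrument ramp of ~1.6 °C/s implies dense sampling; configurable).
Peaks with prominence ≥ 5% of the maximum derivative qualify; the highest
is *major*, the rest *minor*; positions are refined by parabolic
interpolation through the peak and its neighbours, which can move a peak
by at most one grid step. Flat or baseline-only curves raise a
no-transition error rather than returning a spurious Tm.

## mtDNA quantification

**Deletion arithmetic.** rCRS coordinates, 1-based inclusive; the genome
is a 16,569-bp circle so a span with end < start wraps the origin:
length = end − start + 1, or L − start + 1 + end when wrapped. Labels
"m.<start>_<end>del<len>" are parsed and the embedded length is validated
(m.8629_14068del5440 → 5,440 bp).

**ddPCR heteroplasmy.** Two probes: one inside the deletion (sees only
non-deleted genomes) and one outside (sees all), run in triplicate.
Heteroplasmy = 1 − λ_in/λ_ref with per-well λ = −ln(1 − positives/total)
(Poisson occupancy correction, the field's standard; a `raw_ratio` mode
reproduces the literal positive-droplet ratio, and the method used is
always recorded). Saturated wells are rejected with advice to dilute.
The 95% CI is a normal interval, het ± 1.96·SE, with SE obtained by
propagating the analytic per-well variance var(λ̂) = p/(n(1−p)) through
the ratio by the delta method; this matches commercial ddPCR practice
and gives nominal coverage, whereas an interval built from n = 3
replicate sample variances with a normal quantile under-covers (the
pivot is t-like with few degrees of freedom), so the replicate-variance
variant is provided as an option rather than the default. Estimates and
CI ends are clamped to [0, 1] with a flag.

**Coverage scanning.** Candidate deletions are maximal circular runs
(≥ 1,000 bp by default) of bases whose depth falls below
(1 − drop_fraction) of the baseline, with the mean in-run/baseline depth
ratio as a heteroplasmy proxy. The baseline defaults to the global
circular median depth: a rolling median (available via
`baseline_window`) is only uncontaminated when its window exceeds about
twice the deletion length, which cannot be guaranteed a priori for
multi-kilobase deletions on a 16.6-kb circle.

**Copy number.** Relative mtDNA:nDNA ratio by 2^−ΔΔCt with amplification
efficiency fixed at 2.0 (no standard curves are modelled); replicate Ct
spreads above one cycle raise a warning.

## Synthetic data

Every generator is a pure function of (spec, seed) using a
`SeedSequence`-spawned substream per replicate (adding replicates does
not shift other draws), and attaches a provenance record (generator,
seed, truth) that recovery tests treat as the only source of truth.
Defaults mirror the study's conditions: 20 nM DNA with 15 log-spaced
titration points from 0.1× to 50× the DNA concentration and triplicate
σ = 0.002 anisotropy noise; 25–95 °C melt ramps; triplicate ddPCR wells
of 15,000 droplets at about one reference copy per droplet; ~20,000×
mtDNA coverage with the 8629–14068 deletion at 68% heteroplasmy.

The harmonic trajectory generator draws *memoryless* isotropic Gaussian
displacements, so RMSF has the exact expectation √3·σ — deliberately not
physical MD (no correlated modes, solvent or kinetics). Passing recovery
tests therefore demonstrates estimator correctness under known
fluctuation statistics, not agreement with real force-field dynamics;
published trajectory-dependent numbers (absolute SASA tables, the
71%/77% intra-monomer mobility contrast, 3–4.5 Å RMSD plateaus) require
the original simulations and are treated as context, not targets.

## Pipeline

One YAML config drives all blocks (`ssbkit run`); `ssbkit demo`
generates every synthetic input and runs the full pipeline in a few
seconds on one CPU. Blocks fail independently; every table carries a
`#`-prefixed metadata header with a path-independent config hash,
package version and seed, and with a fixed seed a demo bundle is
byte-identical across runs. Problem sizes used by the test-suite
simulation studies — 100 seeded titrations, 200 seeded ddPCR assays,
10⁴-frame RMSF ensembles on a 48-residue toy tetramer — were chosen as
the smallest sizes at which the estimators' asymptotic behaviour is
visible at the stated tolerances.

## Known limitations

* PDB support is the fixed-column ATOM/HETATM/MODEL subset: no mmCIF,
  insertion codes, bond perception or protonation; trajectories are
  multi-model PDB only.
* The binding model is 1:1 and non-cooperative; no G-factor photophysics.
* No thermodynamic (ΔH/ΔG) fitting of melt curves; Tm only.
* The coverage scanner assumes a single dominant depth baseline; nested
  or overlapping deletions merge into one candidate.
* Charge accounting is formal (integer) charge, not titration-state or
  Poisson–Boltzmann electrostatics.
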