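# Methods

This note records the models implemented in `idrpep`, the defaults and the
reasoning behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Contact-energy model (`mj_energy`)

The pairwise binding energy of residues *a* and *b* is
E(a,b) = e_ab + e_rr − e_ar − e_br, where e_ab is a statistical contact
energy in RT units and the *r* subscript denotes averaging over residue
types. The reference terms make E invariant under adding a constant to
every e_ab, and identically zero for any additive table e_ab = f_a + f_b;
both identities are enforced by property tests. Energies are treated as
dimensionless RT multiples throughout; no temperature conversion is
attempted.

**Matrix variant.** The packaged default (`data/mj1996.txt`) is the
Miyazawa & Jernigan 1996 effective contact-energy table e_ij
(J Mol Biol 256:623, Table 5 upper triangle), transcribed by hand; its
identity is recorded in the matrix `provenance` field and propagated into
every design report. Other tables (the 1985 variant, reduced alphabets for
testing) can be supplied as plain-text files; asymmetric input is rejected,
never silently symmetrized.

**Averaging convention.** e_ar is the unweighted mean of e_aj over the
residue *types* j (including j = a), and e_rr the grand mean (equal to the
mean of the e_ar). Composition-weighted averaging would require a
composition that is not part of the model; users wanting it can bake it
into a custom matrix.

## Peptide design (`design`)

Each peptide position p faces target residue `window_start + p − 1`
(parallel; an antiparallel flag reverses the mapping — which orientation is
"right" is not determined by the model, so both are exposed and parallel is
the default). With contact width k = 1 a candidate residue is scored
against the facing residue only; with k = 3 the two sequence neighbors
contribute with equal weight (no weighting scheme favoring the facing
residue is applied; none is implied by the contact picture). At sequence
edges, neighbors that do not exist are skipped, so edge positions sum fewer
terms; when the design window sits inside a longer supplied sequence the
real flanking residues are used — this uses all available sequence
information and degrades gracefully.

Because the total energy is separable over positions, the greedy
per-position argmin is the exact global optimum of the 20^L candidate
space; `exhaustive_design` (capped at 10^6 candidates) exists purely as an
independent oracle and the equivalence is asserted over hundreds of random
instances.

**Tie-breaking and tolerance.** Argmin ties resolve to the alphabetically
first residue code, and exhaustive enumeration keeps the lexicographically
smallest tied candidate. Energies within 1e-9 RT are treated as tied:
small alphabets produce *algebraically* equal position energies (on a
2-letter matrix E(a,a) = E(b,b) = −E(a,b)) whose floating-point values
differ only by summation order, and without a shared tolerance the two
designers could disagree on which tied sequence to report.

**Curation.** The ranked window scan is reported in full (ascending total
energy, ties by ascending window start). Selecting a design for reasons
other than minimal energy — as was done for some of the packaged reference
peptides — is left to the user.

**Reference data.** `data/reference_peptides.tsv` packages the sequences
and anisotropy-measured K_d values of six designed peptides (DP1–DP6) and
three natural-protein peptides binding the p53 CT peptide; the
`data/p53_ct.fasta` file carries the CT peptide (367–393) and the 313–393
fragment with UniProt numbering. A note on composition: the net charge of
DP6 computed from its sequence (8 Glu + 4 Asp → −12) and of the Lys/Arg-rich
CT peptide (+4) have the opposite signs to some published descriptions of
the same molecules; `net_charge` reports the composition-based value and
makes no attempt to match any other convention.

## Two-state binding (`binding_model`)

The complex concentration is the smaller root of the mass-action quadratic,
evaluated in the cancellation-free form
c_AB = 2 c_A c_B / (s + √(s² − 4 c_A c_B)), s = c_A + c_B + K_D, which
stays accurate when 4 c_A c_B ≪ s² (the weak-binding tail of a titration).
Against an independent bracketing root-finder the result agrees to better
than 1e-12 relative across nM–mM concentration grids. One caveat: at
extreme saturation (c_B/K_D ≳ 1e6) the quantity c_A − c_AB is itself a
cancellation of two nearly equal doubles, so *any* double-precision c_AB
leaves a residual in the mass-action identity above 1e-10 relative there;
accuracy in that corner is established by the root-finder comparison, not
the identity residual.

`fit_titration` does unweighted (optionally per-point-SD-weighted)
nonlinear least squares over (K_D, r_A, r_AB) with bounds K_D > 0, initial
guesses r_A = first point, r_AB = last point, K_D = titrant concentration
at the half-change point, and SEMs from the scaled covariance at the
optimum. Curves whose total anisotropy change is below a floor (default
1e-3) are rejected as non-identifiable rather than fitted. Coverage
calibration on synthetic data (noise SD 0.002): the true K_D lies within
±2 SEM in ~93% of 500 replicates.

Tetrameric constructs are handled by a concentration helper (monomer/4),
not a new model. Competitor effects are analyzed the way the titrations
are actually run: independent two-state fits at each fixed competitor
concentration yielding apparent K_D, with `salt_series_summary` providing
the descriptive log–log slope of K_D versus salt; no explicit ternary
competition model is fitted.

## Sliding analysis (`diffusion`)

The ensemble MSD uses every overlapping pair within each trajectory
(time-averaged), then averages across trajectories weighted by pair counts,
with across-trajectory SEMs per lag. The average diffusion coefficient is
slope/2 of a weighted linear fit MSD = 2Dδt + b; the intercept absorbs
localization noise (2σ_loc² for independent Gaussian noise) and is never
forced to zero.

**MSD error model.** Time-averaged MSD values at different lags share
displacement pairs and are strongly correlated, so the independent-error
covariance of the linear fit understates the uncertainty of D roughly
tenfold. When per-lag SEMs are available, the SEM of D is propagated under
a fully-correlated model — an ensemble-wide fluctuation scales the per-lag
SEM profile, so the slope of that profile bounds the slope error.
Empirically this is well calibrated: over 25 simulated replicates at
D = 0.3 μm²/s the reported SEM (0.0065) matches the observed spread
(0.0069).

**Drift.** The mixture model carries per-mode drift v_i explicitly (buffer
flow moves molecules along the DNA), but drift makes the raw MSD
superlinear. The MSD is therefore computed on drift-corrected positions by
default — the pooled mean velocity (total displacement over total time) is
subtracted — with a flag to disable the correction. The displacement
mixture is always fitted on raw displacements, where drift is a fitted
parameter.

**Two-mode fit.** Displacements pooled at a fixed lag (165 ms default; the
lag must be commensurate with the frame interval) are histogrammed with
Freedman–Diaconis bin width (overridable) on edges symmetric about zero,
and the density is fitted by weighted least squares with per-bin bootstrap
SEMs (1,000 resamples, seeded) as weights; empty-bin SEMs are floored at
the smallest positive SEM. Parameters are bounded A_i ≥ 0, D_i > 0; modes
are relabeled so D_1 ≤ D_2. Localization noise is not modeled separately —
it inflates each apparent D by σ_loc²/δt (≈ 0.0024 μm²/s at the default
σ_loc = 0.02 μm and δt = 165 ms, i.e. ~5% of the slow mode and ~0.5% of the
fast mode), matching how such fits are conventionally reported. A
single-Gaussian fit is always computed alongside; if the two fitted D agree
within their combined SEM the result is flagged degenerate. Modes are
treated as trajectory-level populations; no mode-switching (hidden-state)
model is fitted.

## Synthetic data (`synthetic_data`)

Generators are pure functions of their spec including the seed.

*Titration*: r_obs from the two-state model plus i.i.d. Gaussian noise
(default SD 0.002 anisotropy units) on a 12-point log-spaced titrant grid
spanning 10 nM–100 μM around a 1 μM K_D, with c_A = 5 nM — the sampling
density, probe concentration and noise floor of a fluorometer titration.

*Sliding*: 250 trajectories (the scale of a single-molecule sliding
dataset) of 100 frames at 33 ms, each assigned slow (D = 0.05 μm²/s) or
fast (D = 0.5 μm²/s) at the trajectory level with fraction_fast = 0.5,
drift-free by default, with 20 nm localization noise added to reported
positions. The two D values are the canonical slow/fast sliding
coefficients; the equal split is the maximally informative mixing fraction
and is a free parameter. Optional per-frame mode switching exists for
robustness studies but is off by default, matching the
populations-not-switching reading of the mixture model.

What the simulators deliberately omit: photophysics (blinking,
bleaching-limited trajectory lengths are optional only via fixed length),
DNA-end effects and confinement, camera motion blur, and any correlation
between mode and trajectory length. Passing the recovery tests therefore
shows the estimators are correct for the assumed generative model, not
that real microscopy data meet those assumptions.

## Problem sizes used in the automated checks

The test suite and the acceptance script size their simulations to be
informative at interactive runtimes: 200 random design instances for the
greedy/exhaustive equivalence, a 10^4-point grid for the mass-action
numerics, 500 noisy titration replicates for SEM coverage, and 20
replicates of the 250-trajectory sliding simulation (≈ 23,000 pooled
displacements each) for mode recovery. These sizes reproduce the stated
tolerances with margin; larger runs only sharpen them.

## Known limitations

- The contact model is sequence-local: no long-range, conformational or
  cooperative effects, no solubility or synthesizability objectives.
- Affinity ranking across designs is a soft, monotone expectation (the
  packaged reference set gives Spearman ρ = +0.6), not a calibrated
  energy-to-K_D mapping; it also depends on the matrix variant chosen.
- The titration model is two-state and single-site; Hill-type
  cooperativity and explicit competition are out of scope.
- The two-mode fit assumes Gaussian displacement mixtures; anomalous
  diffusion or heavy-tailed localization error would bias it.
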