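# idrpep

Sequence-only design of peptide binders for intrinsically disordered
regions (IDRs), with the ensemble and single-molecule analytics used to
validate such designs.

IDRs have no stable tertiary structure, so structure-based (pocket-docking)
drug design does not apply to them. `idrpep` implements a design route that
needs nothing but the target's primary sequence: candidate peptide residues
are scored against the IDR with a knowledge-based residue–residue contact
potential (Miyazawa–Jernigan, MJ), and the peptide is built by per-position
energy minimization. The package was built around the canonical test case
for this approach — the disordered C-terminal (CT) domain of the tumor
suppressor p53 (CT peptide, residues 367–393) — and ships those target
sequences plus the measured dissociation constants of the peptides designed
against them as reference data.

## The model

**Design.** The binding energy of peptide residue *j* facing target residue
*i* is the solvent-referenced contact energy

&nbsp;&nbsp;&nbsp;&nbsp;*E(i, j) = e<sub>ij</sub> + e<sub>rr</sub> − e<sub>ir</sub> − e<sub>jr</sub>*&nbsp;&nbsp;(RT units),

where *e<sub>ij</sub>* are MJ contact energies and the subscript *r* denotes
averaging over all 20 amino acid types. In the **one-by-one** scheme (contact
width k = 1) a peptide position contacts only its facing residue; in
**one-by-three** (k = 3) the two sequence neighbors of the facing residue
contribute equally. For a window of length *L* the candidate space is
20<sup>L</sup> (≈ 6.6 × 10<sup>20</sup> for a 16-mer), but the total energy
is a sum of independent per-position terms, so the per-position argmin is
the exact global optimum — the package verifies this against brute-force
enumeration on small alphabets.

**Titration fitting.** Designed binders are characterized by fluorescence
anisotropy titrations. With a labeled species A at total concentration
c<sub>A</sub> titrated by B (total c<sub>B</sub>), mass action gives the
complex concentration as the smaller quadratic root

&nbsp;&nbsp;&nbsp;&nbsp;c<sub>AB</sub> = [(c<sub>A</sub>+c<sub>B</sub>+K<sub>D</sub>) − √((c<sub>A</sub>+c<sub>B</sub>+K<sub>D</sub>)² − 4c<sub>A</sub>c<sub>B</sub>)] / 2,

and the observed anisotropy is r<sub>obs</sub> = r<sub>A</sub>(c<sub>A</sub>−c<sub>AB</sub>)/c<sub>A</sub> + r<sub>AB</sub>c<sub>AB</sub>/c<sub>A</sub>.
`fit_titration` estimates (K<sub>D</sub>, r<sub>A</sub>, r<sub>AB</sub>) by
nonlinear least squares with SEMs from the fit covariance.

**Sliding analysis.** DNA-binding proteins such as p53 locate targets by 1D
sliding; a binder occupying the DNA-binding IDR changes that motion. From
single-molecule trajectories the package computes the ensemble mean-square
displacement (MSD = 2Dδt + b in 1D, intercept retained as the
localization-noise offset) and fits the displacement distribution at a
fixed lag (165 ms by default) with a two-mode Gaussian mixture

&nbsp;&nbsp;&nbsp;&nbsp;P(δx) = Σ<sub>i=1,2</sub> A<sub>i</sub>/√(4πD<sub>i</sub>δt) · exp(−(δx + v<sub>i</sub>δt)²/(4D<sub>i</sub>δt)),

resolving slow and fast sliding modes with per-mode drift; per-bin
histogram errors come from bootstrap resampling (1,000 iterations by
default). Seeded simulators for both data types make the full
simulate → fit → recover loop testable offline.

## Worked example

Design a one-by-three 16-mer against the p53 CT region starting at residue
369 (the packaged FASTA carries the UniProt numbering):

```bash
idrpep design --target src/idrpep/data/p53_ct.fasta --record p53_CT_peptide \
    --start 369 --length 16 --contact-width 3
```

prints (abridged):

```json
{
  "peptide": "EEEEDDNDDDDEEEFF",
  "window_start": 369,
  "window_end": 384,
  "total_energy": -23.367,
  "net_charge": -13,
  "matrix_provenance": "Miyazawa-Jernigan 1996 Table 5 (e_ij, RT units)"
}
```

The designed sequence is strongly acidic with an aromatic tail — the
favorable Glu/Asp–Lys/Arg and aromatic–hydrophobic contact energies pick
out the complementary chemistry of the Lys/Arg-rich CT window — and the
total binding energy of −23.4 RT is the sum of the 16 per-position minima.
Sliding the six packaged designed peptides (DP1–DP6) along the CT peptide
with `binding_energy_profile` and rank-correlating each profile minimum
with its measured K<sub>d</sub> gives a positive Spearman correlation
(ρ = +0.6, n = 6): lower computed binding energy tracks tighter measured
binding.

The same CLI exposes `scan` (rank all windows), `profile` (slide a fixed
peptide), `fit-titration`, `msd`, `fit-displacement` and
`simulate titration|sliding`; every command is also a plain library
function.

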