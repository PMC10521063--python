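# Methods

This note records the models implemented in `mqsar`, the conventions and
defaults chosen where the underlying methodology left them open, and what
the synthetic test bed does and does not demonstrate.

## Promolecular densities and quantum similarity

A molecule's electron density is approximated promolecularly: one
normalized s-Gaussian per atom, carrying the atom's full electron count,

ρ(r) = Σ_a N_a (α_a/π)^{3/2} exp(−α_a |r − c_a|²),

so total electrons are conserved exactly. No published parameterization is
adopted for the exponents; they derive from covalent radii as
α = (c/r_cov)² with a single calibration constant c = 1.5 (configurable),
and multi-shell per-element JSON tables (element → [(exponent, electrons)])
can be dropped in unchanged. The similarity *indices* are ratios of
overlap-type integrals and are insensitive to this choice; the absolute
`Z` values are not, and should not be compared across parameterizations.

Similarity measures use the closed Gaussian forms per shell pair:

- overlap: `N₁N₂ (α₁α₂/(π(α₁+α₂)))^{3/2} exp(−μR²)`, μ = α₁α₂/(α₁+α₂);
- Coulomb: `N₁N₂ erf(√μ·R)/R`, switching to the analytic limit
  `2N₁N₂√(μ/π)` below R = 1e−9 Å to avoid 0/0.

Both are validated against an independent trapezoidal-grid quadrature
oracle (relative error ≤ 1e−6 overlap, ≤ 1e−4 Coulomb in the tests; in
practice agreement is near machine precision because trapezoidal sums
converge super-algebraically on Gaussians). The infinite-order distance is
implemented as `max(Z_II, Z_JJ)` — the only symmetric reading of the
defining expression. Matrix exports use 4 decimals with full precision
kept internally.

## Rigid superposition (TGSA)

Hydrogens are excluded throughout. Duos are bonded heavy-atom pairs; triads
are bonded extensions of duos (not all atom triples), which caps the
combinatorics while preserving the common-skeleton logic. Triads match when
their element triples agree position-wise and all three corresponding side
lengths differ by ≤ `tol` (default 0.30 Å — no published value exists;
configurable). Each matched triad seeds a 3-point least-squares (Kabsch)
transform, greedily extended to all heavy atoms (nearest same-element atom
within `tol`, one-to-one), refit, re-extended and refit once more. The
winning seed maximizes matched atoms, then minimizes RMSD, then takes the
lexicographically smallest atom-id triple — a fully deterministic
tie-break. Inputs are never mutated (rigid-body assumption); the rotation
always has det +1.

The alignment quality score is a Gaussian-kernel cross-correlation
`C_IJ = d_IJ/√(d_II·d_JJ)` with `d_XY = ΣΣ exp(−|x_i − y_j|²)` over
superposed heavy atoms. This reconstruction was chosen because it satisfies
every property asserted of the original cost — range [0, 1] by
Cauchy–Schwarz, exactly 1 at structural identity — while being computable;
it is a declared reconstruction, not a claim about any particular published
formula. Flexible (torsional) alignment is out of scope; molecules are
rigid bodies.

For structures read from bond-less formats (XYZ), connectivity can be
perceived by a covalent-radius criterion (bond if r ≤ 1.25·(r_i + r_j));
the CLI does this automatically before alignment.

## Conceptual-DFT descriptors

Global descriptors from frontier-orbital energies in eV:
μ = (E_LUMO + E_HOMO)/2, η = E_LUMO − E_HOMO, S = 1/η, ω = μ²/(2η).
S = 1/η (rather than 1/(2η)) is used because it reproduces the published
descriptor table for this compound series exactly. Condensed Fukui
functions interpret `q_k` as atomic *electron populations*, not net
charges (with net-charge input the signs invert); when the table conserves
charge, Σf⁺ = Σf⁻ = 1 exactly. Presentation rounding is decimal half-up to
4 places, matching printed-table conventions; full precision is available
by passing `decimals=None`.

Note on published-table fidelity: recomputing S and ω from the printed μ
and η reproduces every cell of the 10-compound reference table to within
1e−4 (the printed precision), but the table's own last-digit rounding is
internally inconsistent (some cells round half-up, some truncate), so
exact rounded equality holds for most but not all cells.

## Interaction-energy decomposition

`I.E = E_AM − E_L − E_M` per ligand–residue pair, all energies from tables
in one unit (default kcal/mol — the source workflow never states its unit,
so it is carried as metadata and checked for uniformity, never converted).
Complex rows are keyed `"<ligand>|<residue>"`. Missing rows raise with the
offending system named; nothing is silently dropped. "Critical" residues
are operationalized as the `top_n = 4` most negative mean-I.E residues
across the ligand series — a pure ranking, threshold-free, with ties broken
by residue name. Decimal commas in pasted literature values are normalized
on ingest.

## CoMFA-style fields and PLS

Field conventions follow standard published CoMFA practice, since the
commercial implementation's exact functional forms are proprietary:
sp³-carbon probe with +1.0 e charge, 2.0 Å grid spacing with 4 Å margin,
steric = Lennard-Jones 6-12 with ε = 0.1 kcal/mol and contact distances
from van der Waals radii, electrostatic = 332.0636·q₁q₂/(ε(r)·r) with
distance-dependent dielectric ε(r) = r, both capped at ±30 kcal/mol.
Near-constant columns (std < 0.05) are dropped before regression. All of
these are configurable.

PLS is centered, with optional block scaling that equalizes total variance
between the steric and electrostatic blocks. Reported statistics: training
R²; leave-one-out q² = 1 − PRESS/SS_total with *full per-fold refits*
(including per-fold column filtering) rather than a shortcut approximation;
and the field-type contribution split Σ|coefficient·std| per block
normalized to 100 %. Contribution contours partition grid points per field
type at the 80th/20th percentiles of the signed coefficient·std product.
The three alignment provenances (structure-based, docked poses, rescored
poses) are pipeline configurations sharing one fields/PLS code path.

## Synthetic test bed

The generator emulates, with exact ground truth and full determinism per
seed:

- a rigid 12-membered ring scaffold (identical coordinates in every series
  member, as for a conformationally locked macrocycle) with two opposite
  substitution sites drawing from a small library of common groups (H, F,
  OH, OMe, NH₂, Me, keto, OAc) with template geometry and partial charges;
- a pocket of net-neutral amide-like pseudo-residues (N–H donor head aimed
  at the ring, C=O tail) placed 3.5–7.5 Å from the ring circle, energized
  by an additive toy Hamiltonian (LJ 6-12, ε = 0.1 kcal/mol, σ = 3.4 Å,
  plus Coulomb with k = 332.0636); E_AM = E_L + E_M + inter by
  construction, so the decomposition has an exact pairwise oracle.
  Intramolecular sums exclude bonded pairs, whose constant LJ-wall terms
  would otherwise dominate the supermolecular differences numerically;
- activities y = Xβ + N(0, σ²) with the coefficient vector planted in the
  span of the top-3 principal directions of the centred field matrix —
  i.e. a generating model whose latent dimension genuinely equals the PLS
  component count being tested — normalized to unit signal variance,
  σ = 0.1 by default, and affinely rescaled into the observed pIC50 span
  [5.57, 8.04] (recovery tests use the pre-scaling linear truth);
- orbital tables with gaps drawn in [4, 7] eV and population tables that
  conserve exactly ±1 electron between charge states.

Default sizes are 40 ligands and 10 residues — the scale of the modelled
analogue series — and every quantity in the tests is computed at that
scale.

What passing these tests shows: the integrals, the alignment, the
decomposition and the regression machinery are correct against independent
oracles under known-truth conditions. What it does not show: agreement
with any published similarity matrix, q²/R² table or absolute
interaction-energy profile — those depend on unpublished 3D structures,
proprietary field implementations and a specific semi-empirical engine,
and are explicitly not reproduced here. Real ligand series also exhibit
conformational flexibility, correlated noise and charge-model sensitivity
that the rigid, additive, homoscedastic generator does not emulate.

## Numerical choices and degenerate inputs

- Coulomb similarity R→0 branch at 1e−9 Å; field 1/r floored at 1e−6 Å
  (the ±30 cap dominates long before).
- Generalized distance rejects negative radicands beyond −1e−12 and clips
  the rest to 0.
- Similarity matrices leave failed alignment pairs as NaN and record them,
  never zero them.
- Single-atom and hydrogen-only molecules yield empty duo/triad lists (not
  errors); superposition then fails loudly with an `AlignmentError`.
- Ranking and triad selection are deterministic under ties (documented
  tie-breaks); reruns of the pipeline with one seed are byte-identical.

## Known limitations

- Promolecular single-Gaussian densities are crude near nuclei; only
  index-level comparisons are meaningful.
- The TGSA score reconstruction is one defensible reading of an
  ambiguously printed cost function.
- PDB parsing keeps altLoc blank/'A' and the first model only; mmCIF and
  MOL2 are unsupported.
- LOO (not k-fold or SAMPLS) cross-validation; for very small series LOO
  q² is noisy.
- The pipeline's user-data path expects pre-posed structures; no docking
  or semi-empirical engine is invoked.
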