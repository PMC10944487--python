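# Methods

## Scope and model

`eetkit` computes excitation energy transfer (EET) in chlorophyll networks in
the weak-coupling (Förster) limit. Three physical layers are composed:

1. **Electronic couplings.** The coupling between pigments is the Coulomb
   interaction of their Qy transition densities, represented as atomic point
   charges (TrEsp). The full screened sum is
   V = f(R)·Σ q_l q_l′ / R_ll′ with charges in units of e, distances in Å and
   V in cm⁻¹. The environmental screening f is a piecewise function of the
   Mg–Mg distance: 1 up to 6.6 Å (inclusive), A·exp(−βR)+0.54 between 6.6 and
   20 Å, and 0.54 beyond (inclusive). One factor multiplies the whole sum —
   per-atom screening is deliberately not attempted, matching the form of the
   published screening rule. The exponential-branch constants default to
   A = 2.68 and β = 0.27 Å⁻¹, the standard distance-dependent screening fit
   consistent with these cutoffs and asymptote; the branch is then continuous
   to within 1% at the inner cutoff (f(6.6⁺) ≈ 0.99). Both are configurable
   and stamped into output metadata.
2. **Lineshapes.** Each pigment's emission and absorption bands are unit-area
   Gaussians; emission is red-shifted by the Stokes shift S. The overlap
   integral has the closed form
   J = exp(−Δ²/2(σ_m²+σ_n²)) / √(2π(σ_m²+σ_n²)), Δ = ω_m − S_m − ω_n,
   and a Simpson-quadrature route (8193 points over the peaks ±6σ) retained
   purely as a cross-check; the two agree to better than 1e-6 relative across
   the tested parameter space.
3. **Rates.** T = (2π/ħ)|V|²J for pigment pairs; for aggregates, the
   generalized Förster sum over Boltzmann-weighted donor excitons and all
   acceptor excitons, with exciton couplings from the coefficient transform
   V_αβ = Σ c_iα c_jβ V_ij. Thermal equilibration within the donor aggregate
   is assumed instantaneous; no back-transfer kinetics or master-equation
   propagation is modeled.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| screening A, β | –, Å⁻¹ | 2.68, 0.27 | literature screening fit for the 6.6/20 Å cutoffs and 0.54 asymptote |
| width interpretation | – | FWHM_CONVERT | printed widths treated as true FWHM, σ = FWHM/(2√(2 ln 2)); a literal-σ mode reproduces the alternative reading |
| Chl a Stokes shift, FWHM | cm⁻¹ | 160, 240 | standard Chl a Qy band parameters |
| site energies ω₀ | cm⁻¹ | **mandatory input** | not derivable from structure; shipped 14,900 (Chl a) / 15,750 (Chl c) are round documentation examples only |
| temperature | K | 300 | k_B = 0.695035 cm⁻¹ K⁻¹; both recorded in outputs |
| time-constant bins | ps | 1, 10, 20 | <1 ps fast, 1–10 ps mid, 10–20 ps slow, ≥20 ps omitted; half-open on the left |
| grouping cutoff | ps | 20 | antenna domains group when the better direction of a pair transfers within the omission threshold |
| export rate floor | ps⁻¹ | 1e-6 | sparse exports drop pairs slower than 10⁶ ps; the dense matrix keeps them |

All conversion factors (e²/4πε₀Å → cm⁻¹ ≈ 1.1614×10⁵; e·Å → Debye ≈ 4.8032;
2π/ħ scaled so (cm⁻¹)²·(cm⁻¹)⁻¹ → ps⁻¹ ≈ 1.1835) are derived once from
CODATA values via `scipy.constants` in `eetkit.constants`; output files embed
the constants version.

## Design choices where the design was open

- **Qy axis**: unit vector from ring nitrogen NB to ND (the common convention
  for the chlorophyll Qy transition); NA→NC selectable. Pigment center: Mg,
  falling back to the mean of the four ring nitrogens.
- **Altloc policy**: highest occupancy wins, ties broken by altloc id order.
- **Measured-overlap override**: the overlap table is *directional* — an
  experimental donor→acceptor overlap (e.g. Chl c → Chl a) replaces only
  that ordered type pair; it applies at the pairwise-rate level, while
  exciton-state overlaps always use the Gaussian model (exciton states have
  no type pair).
- **Exciton lineshapes**: the generalized theory needs lineshapes for exciton
  states, which the rate expression alone does not define. The adopted model
  is a Gaussian at the exciton eigenenergy with FWHM and Stokes shift given
  by the c²-weighted mix of the member pigments' parameters (donor emission
  red-shifted by the weighted Stokes shift). A no-mixing alternative (first
  member's monomer width for every state) is selectable. For single-pigment
  aggregates both reduce exactly to the monomer lineshape, which is what
  makes the generalized ≡ classical reduction hold to machine precision —
  the suite's primary oracle.
- **Degenerate eigenvalues**: eigenvectors are used as returned by the
  symmetric eigensolver. Every reported quantity depends only on |V_αβ|²
  summed within a degenerate level and is therefore invariant to the
  arbitrary basis inside the subspace (tested on a symmetric homotrimer via
  member reordering).
- **Numerical conditioning**: Boltzmann factors are computed after shifting
  eigenvalues by the ground state, so partition functions stay in range for
  any absolute energy scale. Site-energy magnitudes (~1.5×10⁴ cm⁻¹) would
  otherwise underflow exp(−ε/k_BT).
- **Route score**: routes are ranked by bottleneck (slowest-step) τ, the
  quantity that limits a mediated pathway; summed τ is available behind a
  flag. Ties break by path length, then lexicographic ids.
- **Binning boundaries**: half-open on the left ([1,10) ps etc.), so τ
  exactly 1 ps falls in the mid class; the screening-factor boundaries are
  inclusive per the printed inequalities of the piecewise rule.

## The synthetic generator

`eetkit.synthetic` plants networks with exact ground truth: pigments carry
pseudo-atoms MG/NB/ND (center and axis) and P1/P2 — two point charges ±q
separated by 0.8 Å whose dipole q·sep equals the requested magnitude (4 D
default, the usual in-protein effective Qy dipole of Chl a) exactly.
Clusters of pigments on a 12 Å-spaced lattice, with centroids ~70–80 Å
apart, reproduce at reduced scale the regime of an antenna system with
inter-antenna gaps: intra-cluster transfer in the sub-ps–10 ps range,
inter-cluster transfer far beyond the 20 ps omission threshold. Planted
transfer groups are derived analytically from the closest inter-cluster
pigment pair via the point-dipole formula — independent of the TrEsp
summation path the pipeline uses, so group recovery is a genuine end-to-end
oracle.

What the generator does **not** emulate: real chlorin geometry (the
transition density spread over ~50 atoms, which strengthens short-range
deviations from the dipole limit), site-energy disorder from the protein
environment, correlated orientations within an antenna fold, and carotenoid
or quenching channels. Passing tests therefore validate the mathematics of
the pipeline — couplings, overlaps, rate expressions, network reductions —
not the spectroscopic accuracy of any particular charge set or site-energy
assignment, which remain the user's inputs.

Problem sizes used in the suite: clusters of 3–4 pigments (10–16 total),
domains of up to 5 pigments, route graphs of up to 6 domains, 100–1000
randomized draws per property — sizes at which every oracle (brute-force
double sums, characteristic-polynomial eigenvalues, exhaustive path
enumeration) is exact and fast.

## Numerical tolerances

- Generalized↔classical reduction: 1e-10 relative.
- Quadrature vs closed-form overlap: 1e-6 relative.
- Far-field TrEsp vs point-dipole: 2% with a mixed tolerance (2% relative
  plus 2% of the coupling scale K·μ²/R³). The dipole coupling crosses zero
  at magic-angle orientations, where a purely relative comparison is
  undefined; the mixed form bounds the deviation everywhere, in the same way
  `numpy.isclose` treats quantities near zero.
- PDB fixture round-trip: 1e-3 Å (fixed-width coordinate format).
- Degenerate/eigenbasis invariances: 1e-10 relative.

## Known limitations

- Chlorophyll *c* charge sets, experimental Chl c→a overlap values and real
  site energies are not shipped; the pipeline consumes them as inputs.
- No vibronic or spectral-density lineshapes, no temperature-dependent
  broadening, no modified-Redfield intra-domain relaxation, no
  polarizable-embedding screening.
- Carotenoids and other non-chlorophyll cofactors are parsed but never enter
  the EET computation.
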