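# eetkit

Excitation-energy-transfer (EET) analysis for chlorophyll networks in
pigment–protein complexes — built for structural biologists and
photosynthesis modelers who have a cryo-EM or crystallographic model of a
light-harvesting supercomplex (e.g. a photosystem I core ringed by antenna
proteins) and want the map of how excitation flows through it.

The pipeline goes from a structural model to:

1. **pigments** — chlorophylls extracted from mmCIF/PDB with centers (Mg) and
   Qy axes (NB→ND);
2. **couplings** — electronic couplings from transition charges (TrEsp) with
   distance-dependent environmental screening;
3. **rates** — Förster rates between all chlorophyll pairs and
   generalized-Förster rates between exciton domains (antenna ↔ antenna,
   antenna ↔ core);
4. **network** — time-constant classes, antenna transfer groups, and ranked
   (possibly mediated) transfer routes.

## The model

The transfer rate from donor pigment *m* to acceptor *n* is

$$T_{mn} = \frac{2\pi}{\hbar}\,|V_{mn}|^2 \int d\omega\, F_m(\omega)\,A_n(\omega)$$

in ps⁻¹, with the coupling from the TrEsp sum over transition charges
$q^T_l$ (in units of *e*),

$$V_{mn} = f(R)\sum_{l\in m,\,l'\in n} \frac{q^T_l\,q^T_{l'}}{|R_{l,l'}|},$$

screened by a piecewise function of the center–center (Mg–Mg) distance *R*
in Å:

$$f(R)=\begin{cases}1 & R\le 6.6\\ A\,e^{-\beta R}+0.54 & 6.6<R<20\\ 0.54 & R\ge 20.\end{cases}$$

Emission and absorption bands are unit-area Gaussians; emission is
red-shifted by the Stokes shift *S*, so the overlap integral has the
Gaussian-product closed form. Between multi-pigment aggregates *D* and *A*
the generalized Förster rate sums over thermally weighted exciton pairs,

$$k_{DA} = \frac{2\pi}{\hbar}\sum_{\alpha\in D}\sum_{\beta\in A}
\frac{e^{-\varepsilon^D_\alpha/k_BT}}{Z}\,|V^{DA}_{\alpha\beta}|^2
\int d\omega\, S^D_\alpha(\omega)\,S^A_\beta(\omega),$$

with $V_{\alpha\beta} = \sum_{ij} c_{i\alpha}c_{j\beta}V_{ij}$ the exciton
transform of the site couplings. Time constants τ = 1/T (ps) are classified
as <1 ps, 1–10 ps, 10–20 ps, or omitted (≥20 ps); antenna domains are grouped
by mutual transfer reach and routes to the core are ranked by their
bottleneck (slowest-step) τ. All physical constants derive from CODATA in one
constants unit (charges in *e*, distances in Å, energies in cm⁻¹, dipoles in
Debye, rates in ps⁻¹).

Transition charges are **inputs** (TSV per pigment type); site energies and
lineshape parameters are inputs too. Built-in example values (Chl *a* Stokes
shift 160 cm⁻¹, FWHM 240 cm⁻¹; site energies 14,900 / 15,750 cm⁻¹ for
Chl *a*/*c*) are illustrative defaults for synthetic studies, not fitted
constants.

## Worked example

Two stacked Chl *a* pigments 15 Å apart, each modeled as a 4 D two-point
transition dipole:

```python
from eetkit import (LineshapeParams, PigmentType, coupling_matrix,
                    overlap_integral, pairwise_rate)
from eetkit.synthetic import make_charge_set, make_dimer

pigments = make_dimer(15.0, "STACKED")                    # parallel axes, 15 A
charges = {PigmentType.CHL_A: make_charge_set(4.0, 0.8)}  # 4 D point pair
cm = coupling_matrix(pigments, charges)

chl_a = LineshapeParams(omega0=14900.0, fwhm=240.0, stokes=160.0)
J = overlap_integral(chl_a, chl_a)
V = cm.V[0, 1]
T = pairwise_rate(V, J)
print(f"f(R=15 A)  = {cm.f[0,1]:.3f}")
print(f"V          = {V:.2f} cm^-1")
print(f"J          = {J:.3e} (cm^-1)^-1")
print(f"T          = {T:.3f} ps^-1  (tau = {1/T:.2f} ps)")
```

prints

```
f(R=15 A)  = 0.587
V          = 13.97 cm^-1
J          = 1.495e-03 (cm^-1)^-1
T          = 0.345 ps^-1  (tau = 2.90 ps)
```

The screening factor 0.587 sits on the exponential branch between the
unscreened contact regime and the 0.54 asymptote; the resulting ~14 cm⁻¹
coupling and self-overlap of the Chl *a* band give a 2.9 ps hop — squarely in
the 1–10 ps class typical of inter-pigment transfer at this distance.

The same analysis runs from the shell on any structure:

```sh
eet synth --spec spec.json --out scratch/net.pdb         # planted test network
eet run --structure model.cif --charges chl_a.tsv \
        --site-energies sites.tsv --out outdir/          # full pipeline
```

`eet run` writes `pigments.tsv`, `couplings.csv`, `rates.csv`,
`domain_rates.csv` and a `network/` folder with the edge classes, GraphML
graph and grouping summary.

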