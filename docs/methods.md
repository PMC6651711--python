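# Methods

This note records the estimator definitions, conventions, numerical
choices, and the assumptions behind the synthetic fixtures. Units are
nm, ps, kJ/mol, and K internally; outward-facing permeation results are
converted to cm²/s, s/cm², and cm/s.

## Conventions

- The bilayer normal is the z axis; all orientational averages are taken
  against it. Depth z is measured from the membrane center of mass.
- Carbon indexing is head-to-tail along each chain; the "plateau" used
  for phase calls is carbons 4 to n−4 (1-based), the mid-segment where
  alkyl order profiles are flat.
- k<sub>B</sub>T is computed from R = 8.314462618×10⁻³ kJ/(mol·K);
  at 298 K, k<sub>B</sub>T ≈ 2.478 kJ/mol.

## Chain structure

**|S<sub>CD</sub>|.** For every C–H bond, S = ½(3 cos²θ − 1) with θ the
angle to z, averaged over both hydrogens, all chains, and all frames;
the reported profile is |⟨S⟩| per carbon with a 5-block standard error
over frames. With united-atom input (`ch_bonds: reconstruct`),
hydrogens are placed by ideal geometry: interior CH₂ hydrogens
perpendicular to the local C(i−1)→C(i+1) direction about the bisector,
terminal CH₃ on a tetrahedral cone. For a perfectly z-aligned all-trans
chain this yields the textbook |S<sub>CD</sub>| = 0.5 exactly.

**Gauche fraction.** Backbone dihedrals are gauche when the signed
angle φ lies strictly inside (−120°, 120°); trans (±180°) is the
complement. Degenerate dihedrals (collinear triples) are excluded and
counted in `n_excluded`.

**Cavity density.** Each frame, a cubic grid (default 0.05 nm) is laid
over the box; a cell is occupied if any atom center falls inside it
(point occupancy, no atomic radii). P<sub>cav</sub>(z) is the empty
fraction of each z slab, COM-centered and mirrored about z = 0.
Frames are aggregated on a common integer grid by shifting each frame's
slabs a whole number of cells (the COM is located to within half a
cell); this keeps the slab-to-bin map exact and injective.

**Phase call.** S requires plateau |S<sub>CD</sub>| > 0.3 *and* plateau
gauche < 0.15; L<sub>d</sub> requires both reversed; anything else is
reported as `conflicting` — K<sub>A</sub> > 700 mN/m and
χ > 13 k<sub>B</sub>T/rad² are attached as corroborating flags but
never break ties silently.

## Mechanics

**K<sub>A</sub>** = k<sub>B</sub>T⟨A⟩/(N var A) over the per-molecule
area series; block standard error from 5 contiguous blocks. A
zero-variance series returns K<sub>A</sub> = ∞ (rigid) rather than an
error; fewer than 100 frames triggers a warning.

**Tilt modulus.** Chain tilt is the angle between the first→second-last
carbon vector and z, folded to [0, π/2] via |v<sub>z</sub>| so both
leaflets pool. F(α) = −k<sub>B</sub>T ln[P(α)/sin α] is computed on a
72-bin histogram and a quadratic is fitted (weights √count) over the
window F ≤ F<sub>min</sub> + 2 k<sub>B</sub>T; χ is twice the leading
coefficient. Degenerate (zero-width) inputs and windows with fewer than
5 usable bins raise instead of extrapolating.

**Height spectrum.** Surfaces are gridded (for trajectories: the
mid-surface is the mean of per-leaflet truncated-Fourier fits to
headgroup positions, 18 basis functions, modes m,n ≤ 2). With the
convention h<sub>q</sub> = FFT2(h)/N², equal-|q| modes are pooled into
shells and ⟨|h<sub>q</sub>|²⟩ = k<sub>B</sub>T/(A(K<sub>C</sub>q⁴ + χ<sub>s</sub>q²))
is fitted by weighted least squares below q = 2π/1.5 nm⁻¹, excluding
shorter wavelengths where molecular protrusions dominate. Single-frame
spectra are flagged unreliable (infinite per-shell error) and refuse
the modulus fit.

**Bending energy.** E = (K<sub>C</sub>/2)∮(c₁+c₂)² dA by 32×32
Gauss–Legendre quadrature over the periodic cell, with c₁+c₂ = ∇²h
(small slope, default) or the full Monge-gauge mean curvature. The
quadrature is re-run at double resolution; a >1% change warns and
reports the refined value. For a single mode h = a sin(2πx/L) the
closed form (K<sub>C</sub>/2)a²(2π/L)⁴L²/2 is matched to <0.1%.

## Permeation (inhomogeneous solubility–diffusion)

**Thermodynamic integration.** Replicate windows at equal z are pooled
(grand mean force; between-replicate scatter sets the error bar) after
discarding a 10% burn-in. ΔG(z) = +∫<sub>z</sub><sup>z_max</sup>⟨f⟩dz′
with ΔG = 0 at the outermost (bulk) window. The default integrator is
the antiderivative of the cubic-spline interpolant of ⟨f⟩(z); on the
typical 0.2 nm window grid the trapezoid rule biases a ~30 kJ/mol
Gaussian barrier by several tenths of a kJ/mol, which the spline
removes. `method="trapezoid"` is retained for comparison, and error
propagation uses trapezoid weights in both cases (per-depth weights, so
the bulk reference carries zero uncertainty by construction).

**Diffusivity.** D(z) = (RT)²/∫₀^τc ⟨δf(t)δf(0)⟩dt. The ACF is
computed with an unbiased, zero-padded FFT (verified against the O(n²)
direct sum to machine precision). The cutoff τc is the first local
maximum of the 5-point-smoothed running integral within the first third
of the series, with a plateau fallback for monotone-but-flat integrals;
an integral that never decays raises. Replicate ACFs at the same depth
are averaged before integration. A correlation time under 2Δt warns
that the white-noise limit is unresolved.

**Resistance and permeability.** R(z) = exp(ΔG/k<sub>B</sub>T)/D(z) on
the free-energy grid (D interpolated linearly if the grids differ,
logged). P = 1/∫R dz; a one-sided profile starting at z ≥ 0 is treated
as a half membrane and mirrored (integral doubled). The depth of
maximum local resistance is reported alongside P.

## Synthetic fixtures: what they emulate, and what they don't

| Generator | Parameter | Default | Rationale |
|---|---|---|---|
| chains | n_chains / leaflet | 64 | common small-bilayer leaflet size |
| chains | n_carbons | 16 | palmitoyl-length tail |
| chains | order_param_target | 0.45 | ordered-phase plateau value |
| chains | gauche_prob | 0.10 | ordered-phase dihedral disorder |
| chains | C–C bond, angle | 0.153 nm, 111° | alkane geometry |
| areas | ⟨A⟩ per molecule | 0.25 nm² | condensed bilayer area |
| areas | K<sub>A</sub> | 700 mN/m | ordered-phase threshold scale |
| tilt | χ, α₀ | 13 k<sub>B</sub>T/rad², 0.35 rad | ordered-phase tilt well |
| surfaces | K<sub>C</sub>, χ<sub>s</sub> | 20 k<sub>B</sub>T, 0 | typical bilayer rigidity |
| surfaces | L, grid | 20 nm, 16² | resolves the q⁻⁴ window |
| forces | z grid | 0–2.8 nm, 0.2 nm step | 15-window half-membrane PMF layout |
| forces | σ², τ | 400 (kJ/mol/nm)², 0.5 ps | see caveat below |
| forces | Δt, steps, replicates | 0.05 ps, 10⁴, 10 | 500 ps per window, 10 replicates |

- Chain fixtures sample chain axes from a Watson-type axial
  distribution solved to hit the target ⟨P₂⟩, then build ideal-geometry
  backbones with Bernoulli gauche dihedrals. Realized (not just target)
  gauche fractions are recorded, so estimator checks can be exact.
- Height fields draw independent Gaussian mode amplitudes from the
  target spectrum — a harmonic membrane with no anharmonicity,
  protrusions, or leaflet asymmetry.
- Constraint forces are the exact mean-force profile plus a discretely
  exact Ornstein–Uhlenbeck process, so D = (RT)²/(σ²τ) is the exact
  ground truth. **Caveat:** real constraint-force variances are of
  order 10⁵–10⁶ (kJ/mol/nm)² with sub-0.1 ps memory; the default
  (σ² = 400, τ = 0.5 ps) is chosen so that a 10 × 500 ps protocol
  resolves a 30 kJ/mol barrier with sub-kJ/mol noise at desk scale.
  The estimator itself is agnostic to this choice — only the
  signal-to-noise of the fixture is idealized, and the recovered D
  spans the same 10⁻⁴–10⁻³ cm²/s decade seen for small permeants.

## Degenerate inputs and failure behavior

Estimators raise typed exceptions (`ParameterError` for bad arguments,
`EstimatorError` for data the method cannot support, `ParseError` for
malformed files) rather than returning silent defaults: missing box
vectors, truncated trajectories (the last complete frame is named),
rank-deficient surface fits, zero-variance forces, non-decaying ACFs,
single-window TI. The pipeline runner confines a stage failure to that
stage and its dependents and records it in the manifest.

## Limitations

- Leaflet assignment is taken from the topology, not inferred.
- The surface fit truncates at |m|,|n| ≤ 2; wavelengths shorter than
  L/2 alias into the fitted modes.
- Cavity density uses point occupancy; with atomic radii the profile
  shifts toward lower P<sub>cav</sub> everywhere.
- The tilt estimator assumes a single-well tilt distribution; strongly
  bimodal (coexisting-phase) inputs will fit the deeper well only.
- Permeability error bars propagate ΔG and D uncertainties to first
  order and ignore the covariance between them (both derive from the
  same force series), so they are mildly optimistic.
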