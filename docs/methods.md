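# Methods

This note documents the estimators implemented in `kbsolv`, the choices made
where conventions genuinely differ between tools, and what the synthetic
validation data does and does not establish.

## Kirkwood–Buff route

**Pair correlation.** `compute_rdf` histograms minimum-image pair distances
between two site selections (atoms or molecule centres of mass) over frames,
normalizing each bin by the exact shell volume (4π/3)(r³_out − r³_in) times
the ideal j-site density N_j/V. Self pairs are excluded when the selections
coincide, so a uniform closed system shows the expected (N−1)/N tail
depression — deliberately left in place for the correction step to remove.
Site search uses a periodic k-d tree; r_max is capped at half the smallest
box edge (orthorhombic boxes only).

**Closed-system correction.** `vdv_correct` applies the Ganguly/van der Vegt
rescaling

    g′(r) = g(r) · N_j (1 − V_sph/V) / (N_j (1 − V_sph/V) − ΔN_ij(r) − δ_ij)

with ΔN_ij(r) the cumulative excess of j sites around an i site computed from
the raw curve and V_sph evaluated at the bin's outer edge, consistently with
the cumulative sums. With this pairing the correction is *exact* for a
uniform closed system (the corrected tail is identically 1), which the
ideal-gas tests exploit. A denominator crossing zero (possible for
pathological short curves) raises an error naming the bin.

**Integration.** Binned g(r) is a piecewise-constant function, so both KBI
estimators integrate the geometric factor exactly per bin rather than using
a midpoint product: the running integral accumulates (g−1) times shell
volumes, and the Krüger finite-volume integral uses the closed-form
antiderivative of 4πr²·w(r/R), w(x) = 1 − (3/2)x + (1/2)x³, per bin and per
truncation radius R (one row of an O(n²) triangular evaluation per R). This
makes the hard-step fixture machine-exact when the step lies on a bin edge
and removes the O(Δr²) quadrature bias everywhere else; bin width remains
the accuracy knob for how well the histogram itself resolves g.

**Extrapolation.** G_V(R) from the Krüger weight approaches the
thermodynamic-limit G∞ linearly in 1/R, so the estimator fits G against 1/R
over a linear regime and reports the intercept; a fit against R is available
behind a flag for diagnostic comparison. Replicates (independent-seed runs)
are fitted separately; the estimate is the mean of intercepts and its sigma
the sample standard deviation (0 for a single replicate).

**Linear-regime selection.** Two selection routes exist, and choosing
between them is a statistics question, not a correctness question:

* `detect_linear_regime` implements a dual slope-cutoff rule: the regime
  opens at the last point of the first run of seven successive grid points
  whose corrected-g slope magnitude stays within a threshold, and closes
  where the slope of G first drifts from its opening value by more than a
  second threshold. Both thresholds default to 0.1 in curve units per nm and
  are configurable — the natural units of the rule are not fixed by any
  convention we know of, so they are exposed rather than asserted. Slopes
  are forward differences attached to the lower grid point.
* `LinearRegime.from_range` is an explicitly chosen window. The cutoff rule
  presumes slope noise well below its threshold, which holds for
  production-scale averaging (it auto-triggers on the N = 1000 ideal-gas
  fixture at 60 frames) but not for small-N desk-scale statistics, where the
  g-slope noise alone exceeds 0.1/nm by factors of several. The shipped
  experiments therefore fit over the outer 40 % of the accessible R range,
  selected once and applied uniformly — the same practice as choosing an MSD
  fit window by eye.

A subtlety worth recording: at finite R the Krüger value is *not* a better
point estimate of G∞ than the truncated integral — for a compactly supported
integrand the truncated integral is already exact beyond the support, while
G_V carries its designed finite-volume bias ~3σ⁴/(8R). Krüger's virtue is
the *shape* of its convergence (linear in 1/R), which is what makes the
extrapolation well posed. Tests assert exactly that.

## Solubility-derivative decompositions

Concentrations enter as number densities (molecules/nm³; 1 mol/L =
0.602214076 nm⁻³) so c·G is dimensionless, and are treated as exact — only
KBIs carry uncertainty. The binary derivative is the preferential-interaction
numerator over the cosolvent self-clustering denominator; the ternary bracket
for a water + buffer primary solvent is

    c_cos ΔG₁ − c_buf ΔG₂ · c_cos ΔG₃ / (1 + c_buf ΔG₄)

with ΔG₁ = G_s-cos − G_s-w, ΔG₂ = G_s-buf − G_s-w, ΔG₃ = G_cos-buf − G_buf-w,
ΔG₄ = G_buf-buf − G_buf-w. The printed form of this expression is
typographically ambiguous about whether the buffer denominator divides only
the second product or the whole difference; the default follows the
per-term reading above, the alternative (`grouping="shared-fraction"`) is
provided, and no claim is made about which any particular source intended.
The full derivative additionally carries a factor (∂μ_cos/∂c_cos)/kT that
simulation studies rarely evaluate; the bracket is reported by default, and
the factor is applied only when supplied.

Uncertainty propagation: simple differences use the quadrature rule
σ = √(σ₁₂² + σ₁₃²); composite expressions are propagated to first order
through a numerically evaluated gradient with respect to *every* KBI, which
keeps the correlation induced by shared terms (G_s-w appears in both ΔG₁ and
ΔG₂) consistent with full Monte-Carlo propagation — verified to 2 % at
10⁵ samples in the tests, valid while the sigmas are small against the
curvature scale of the bracket.

## Hydrogen bonds

A triple (donor-heavy D, hydrogen H, acceptor A) is bonded when the interior
angle at H is within [150°, 180°] (180° = linear) and the H···A
minimum-image distance is ≤ 250 pm. The 250 pm threshold is physically a
hydrogen–acceptor criterion; tools that measure the donor-heavy–acceptor
distance instead are matched with `distance_mode="donor-acceptor"`. Atoms
that both donate and accept (hydroxyl oxygens) take the role
`donor-acceptor`. Inter- and intramolecular searches are separate modes.

Lifetimes are interval (run) statistics rather than autocorrelation decays,
because the stability statistic is defined through them: τ_existence is the
mean maximal bonded-run length, τ_formation the mean unbonded run strictly
between two bonded runs (leading/trailing unbonded stretches are censored —
their full length was not observed), and %bonded = 100·τ_e/(τ_e + τ_f).
A single unbonded frame breaks a run by default; `gap_tolerance=k` forgives
interruptions up to k frames. Degenerate series are flagged rather than
silently averaged: no bonded run → lifetimes undefined; no interior gap →
τ_formation = 0 with flag, %bonded = 100. Bonds-per-ps is the total number
of bonded triple-frames divided by the spanned time, i.e. the mean number of
bonds present per frame over the frame spacing. Counts and lifetimes here
come from one detector and one run-statistics definition — pipelines that
mix two analysis tools with differing internal definitions will not match
exactly.

## Diffusion and SASA

The MSD is a multiple-time-origin average over unwrapped coordinates;
wrapped-only input is refused rather than unwrapped heuristically, because
wrapped frames do not determine true displacements. D = slope/(2d) over a
caller-chosen window [t₀, t₁] (a window heuristic exists but is never
applied silently); nm²/ps converts to m²/s with the factor 10⁻⁶.

SASA is Shrake–Rupley sampling on a deterministic Fibonacci point set
(default 960 points, probe 0.14 nm — common choices, both configurable) with
periodic neighbour occlusion. Points falling exactly on another expanded
sphere's surface are kept only by the lower-indexed atom, so exactly
coincident spheres count once instead of twice or zero times; the tie has
measure zero for generic geometries. The equidistribution error of a single
geometry fluctuates with the point count; convergence is monotone in the
mean over geometries, which is how the tests assert it.

## Combined distribution functions

Per-frame (distance, angle) samples — distance in pm, angle in degrees, the
angle either an interior three-site angle or the angle between best-fit
plane normals of two rings (SVD of centred ring coordinates, rings made
whole across the boundary first) — are histogrammed on a caller-defined grid
and normalized to unit mass over in-grid samples. The hydrogen-bond
rectangle occupancy prorates partially covered boundary bins by their area
overlap, which assumes in-bin uniformity; aligning bin edges with the
criteria avoids prorating entirely, and the tests pin the aligned case to
exact per-sample counting.

## Synthetic data: what it does and does not show

The generators produce inputs whose correct analysis results are known
independently: uniform fluids (g = 1, G = 0), an NVT Metropolis Monte-Carlo
Lennard-Jones mixture (correct equilibrium *structure* by construction of
the acceptance rule; single-particle moves, Lorentz–Berthelot defaults with
per-pair overrides, sequential-insertion start, 20 % burn-in, logged
acceptance rate), Brownian walkers with per-step variance 2·D·dt per
dimension, exact donor–H–acceptor placements, and analytic g(r) curves whose
G∞ is a closed form or a quadrature constant computed at fixture-creation
time (never typed in).

The direction experiment fixes one mixture — 20 solute, 67 cosolvent and 67
water particles in an 8σ box at reduced temperature 1.35, solute–water and
solute–solute ε = 0.3, bath ε = 0.5, and solute–cosolvent ε ∈
{0.1, 1.0, 1.9} — sampled for 2400 sweeps with every 4th sweep recorded.
These sizes are chosen so the seed-mean KBI-difference ordering across the
three attraction levels is stable over replicate seed triples.

Passing on this data shows the estimators are correct and the pipeline's
plumbing is sound. It does not show anything about force-field accuracy,
real solvent structure, electrostatics, molecular flexibility, or dynamics
beyond free diffusion — no claim of reproducing any particular solvent
system's numbers is made or implied.

## Known limitations

Orthorhombic cells only (no triclinic); text formats only (GRO/XYZ/PDB plus
a topology sidecar table); no grand-canonical (particle-number fluctuation)
KBI route; no Luzar–Chandler autocorrelation lifetimes; MSD and SASA scale
as O(F²·M) and O(atoms · points · neighbours) respectively — fine at desk
scale, unoptimized for production trajectories.
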