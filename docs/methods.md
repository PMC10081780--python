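# Methods

## Dosimetry

Bead number concentration follows the manufacturer relation
`N/mL = 6·C·10¹² / (ρ·π·d³)` (C: weight/volume solids fraction; ρ: bead
material density, g/mL; d: diameter, μm). Defaults are a 2%-solids stock of
20 nm polystyrene beads (ρ = 1.05 g/mL), giving 4.55×10¹² beads/μL. The
"beads per fiber volume" normalisation multiplies the solution
concentration by the volume of a reference cylindrical fiber (20.0 μm ×
100 nm, 0.157 μm³). All arithmetic keeps full precision internally;
display rounding (3 significant figures for concentrations, 2 for
beads/fiber volume) is applied only in report formatting. The 1:300
dilution therefore reports 2.4 beads/fiber volume (round-half of 2.38),
not a truncated 2.3.

Light dose is `P·t` with t the shutter-open time: the full acquisition
duration in continuous mode, or `n_exposures × exposure_time` when gated.
The default power is 170 μW — the midpoint of the 160–180 μW measured
range, and the single value consistent with both reported doses (0.612 J
for a continuous hour; 0.0041 J for 120 × 200 ms exposures; ratio 150).
The default gated schedule is one 200 ms exposure per 30 s frame over one
hour.

## Lattice diffusion–binding simulation

Beads diffuse independently (no excluded volume) on a square lattice with
spacing Δx = 0.02 μm spanning a 2 μm × 2 μm box; node indices run
0..100 on both axes. The bottom row (j = 0) is absorbing — it represents a
fibrin fiber to which binding is irreversible — and the other three walls
reflect. 100 beads start uniformly at random on nodes in the top half
(j ≥ 50, inclusive; beads may share nodes) and walk for up to 60 s of
simulated time in steps of Δt = 1×10⁻⁵ s, derived from
Δt = Δx²/(4D) with D = 10 μm²/s (1×10⁻⁷ cm²/s, a ~24 nm bead).

Per time step a bead stays put or moves to one of its 4 nearest
neighbours, each outcome with probability 1/5 (**lazy5**, the default).
This stated rule has an effective per-axis diffusivity of Δx²/(5Δt) =
8 μm²/s rather than the nominal 10 μm²/s: the stay option slows the walk.
The **move4** variant (no stay, each neighbour 1/4) realises the nominal
relation D = Δx²/(4Δt) exactly. Both are exposed because the two
statements — the step rule and the D–Δt relation — are mutually
inconsistent at the 20% level; `msd_diagnostic` validates the per-rule
variance growth (2/5·Δx² vs 1/2·Δx² per axis per step) in free space.

"Reflecting" on a lattice is also underdetermined, so a wall rule is a
config option: `reject_stay` (default; an off-domain move is rejected and
the bead remains in place that step) or `mirror` (the move is folded back
about the wall). reject_stay keeps the transition matrix doubly
stochastic, so a uniform horizontal distribution is preserved exactly and
binding locations are uniform along the fiber; mirror perturbs edge
statistics. Depressed binding at the two fiber ends abutting the ridges
is therefore *reported* per wall rule, not asserted, since no symmetric
local rule reproduces an edge dip.

Binding occurs the instant a move lands on j = 0 (all bottom-row nodes,
corners included, absorb); the bind time is the post-move time, so bind
times are exact multiples of Δt and locations exact multiples of Δx.
Beads still unbound at 60 s are censored and excluded from mean binding
times (at the defaults this is ~none: the analytic mean first-passage
time is 11/48 ≈ 0.23 s ≪ 60 s). A simulation ends early once all beads
are bound.

Validation oracle: under lazy5 + reject_stay the vertical coordinate is a
1-D lazy walk with D_y = Δx²/(5Δt) = 8 μm²/s; the continuum mean
first-passage time from a uniform start on y ∈ [1, 2] with reflection at
y = 2 and absorption at y = 0 is (1/2D_y)·∫₁² y(4−y) dy = 11/(6·D_y)·…
= 11/48 s ≈ 0.2292 s. The exact lattice value, solving the tridiagonal
mean-first-passage system (closed form 5·[101j − j(j+1)/2] steps from
node j), is 0.23083 s; the ~0.7% gap is the Δx-discretisation bias, well
inside the sampling error at the ensemble sizes used.

Reproducibility: each simulation draws its seed from a child of
`numpy.random.SeedSequence(master_seed)` in spawn order (one uint32 state
word per child) and consumes its own stream inside the compiled kernel
(beads processed sequentially), so ensembles are bit-for-bit reproducible
and trivially parallelisable. The inner loop is numba-compiled; 500
simulations × 100 beads run in well under a minute on one CPU. Ensemble
summaries in the tests and the acceptance script use 50 simulations × 100
beads (5000 trajectories), which bounds the mean-bind-time standard error
at ~0.003 s — ample for every check performed; the full 500-simulation
scale is a CLI flag away.

Trace export writes positions every k-th step (default 100, i.e. every
10⁻³ s at the default Δt) for animation; bound beads are frozen at their
binding node.

## Outcome records and tabulation

The analysis granularity is one record per observed fiber: condition
(bead concentration, plasmin concentration, trial), `cleaved`, the
1-based `cleavage_frame` (frame 1 is captured at plasmin addition, so
cleaved fibers have frame ≥ 2 and time = frame·30 s − 30 s),
`cleavage_site` (`ridge` = at the fiber–ridge connection, `length` =
elsewhere), `further_digestion` for ridge-cleaved fibers
(`recoil_collapse` vs `none`), and for uncleaved fibers the `bundled`
and `elongated` flags. Elongation/bundling identification is manual in
the source assays, so the flags are inputs, not image-derived here.

Percentages carry explicit denominators because the conventions genuinely
differ by quantity: elongation and bundling rates are fractions of
*uncleaved* fibers; the bundled→elongated rate is a fraction of *bundled*
fibers; site and further-digestion rates are fractions of *cleaved* and
*ridge-cleaved* fibers respectively. Three disjoint uncleaved
sub-categories (bundled-only, bundled+elongated, elongated-only) are
always reported so either figure-panel convention is derivable. Pooled
(all fibers of a condition) and per-trial (mean ± SE over trials)
aggregations are computed separately and never interchanged — the two
disagree in real data and conflating them is the main reproduction
hazard. Conditions with an empty denominator report the percentage as
absent (NaN), never 0.

Box–whisker summaries use linear-interpolation quartiles (the common
spreadsheet convention; the choice is not otherwise determined) with
whiskers at the most extreme data values within [Q1 − 1.5·IQR,
Q3 + 1.5·IQR] and points beyond listed as outliers; mean ± SE (sd/√n)
accompany them. Two-condition comparisons use one-way ANOVA
(algebraically the two-sided pooled t-test for two groups; the identity is
asserted numerically in tests); a zero-total-variance input returns
F = 0, p = 1 with a `degenerate` flag rather than an error.
Dose-dependence is assessed by OLS of per-trial percentages on
log₁₀(bead concentration) — the default x-scale because the tested
dilutions span two decades; a linear scale is available by flag. The
slope p-value is the two-sided t-test.

## Synthetic record generator

The generator is a calibration stand-in with the statistical structure
the analysis assumes, not a mechanistic model of bead sheathing (for
which no equations exist). Per fiber at bead concentration c (beads/μL)
and plasmin p (U/mL):

- P(uncleaved) = logistic((log₁₀c − 9.8)/0.28 − 0.5·(p − 1)): a steep
  rise in survival with bead concentration (anchored so ~93% of fibers
  remain at 4.55×10¹⁰ beads/μL and essentially none at 4.55×10⁸) and a
  weak plasmin effect matching the observed ~15-point change between 0.7
  and 2 U/mL.
- Cleaved fibers: P(ridge site) = logistic(−(log₁₀c − 10.5)/0.4),
  falling from ~97% at the lowest tested concentration towards ~50% at
  the highest; ridge-cleaved fibers show no further digestion with
  probability 0.5. The cleavage frame is 1 + G with G geometric on the
  30 s frame grid — the memoryless per-frame hazard is the simplest model
  consistent with frame-censored observation — with mean time
  33.5·exp(1.33·(log₁₀c − 9.18)) s, reproducing the ~34 → ~240 s growth
  across two decades.
- Uncleaved fibers bundle with probability 0.27 and elongate with
  probability 0.75 if bundled vs 0.185 if not (the strong
  bundling→elongation coupling).

Defaults: the six serial dilutions of the 2% stock × plasmin
{0.7, 1.0, 2.0} U/mL, 5 trials × 20 fibers per condition (observed totals
range ~32–103 per concentration; 20/trial is a convenience within that
range). `cleave_prob_const` overrides the logistic with a flat cleavage
probability, giving the zero-slope null used for type-I-error calibration
of the regression stage.

What the generator does *not* emulate: within-trial correlation between
fibers (fibers in one field of view share a clot), any coupling between
cleavage time and site, drift over the acquisition hour, and
observer-dependent elongation calls. Passing recovery tests therefore
demonstrate that the tabulation/regression machinery is correct and
calibrated, not that real assays satisfy the independence assumptions.

## Numerical and design notes

- All counts are exact integers; every percentage recomputes exactly from
  its numerator/denominator pair.
- Recovery checks compare empirical frequencies to configured
  probabilities within 3 binomial standard errors at 10⁴ fibers per
  condition; with ~20 simultaneous checks an occasional 3σ excursion is
  expected at smaller sample sizes.
- Seeds: every stochastic entry point takes an explicit seed;
  `SeedSequence` children are used wherever multiple streams are needed.
- Degenerate inputs: empty samples, single-condition regressions and
  zero-variance group comparisons raise or flag as documented above
  rather than returning silent numbers.
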