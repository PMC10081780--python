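# beadlysis

Quantitative toolkit for *in vitro* fibrinolysis experiments in which fibrin
fibers are labeled with fluorescent nanobeads (20 nm carboxylate-modified
polystyrene microspheres). Labeling is not neutral: the concentration of
beads used changes whether, where and when single fibrin fibers are cleaved
by plasmin, and whether uncleaved fibers elongate or bundle. This package
provides the quantitative machinery such experiments need:

1. **Dosimetry** — bead number concentrations from stock properties
   (`N/mL = 6·C·10¹² / (ρ·π·d³)` with solids fraction *C*, material density
   *ρ* in g/mL, diameter *d* in μm), serial dilutions, the expected bead
   count per fiber volume (cylinder of length *L*, diameter *d_f*), and the
   optical energy `E = P·t` deposited during continuous or shutter-gated
   time-lapse imaging.
2. **Diffusion–binding simulation** — a 2-D lattice Monte Carlo of bead
   diffusion in a 2 μm × 2 μm box with reflecting top/left/right walls and
   an absorbing bottom row representing a fibrin fiber. Each step a bead
   stays or moves to one of 4 neighbours with probability 1/5 each
   (`lazy5`; a `move4` variant realises D = Δx²/(4Δt)). Ensembles report
   binding frequency and mean binding time per location along the fiber.
3. **Outcome statistics** — tabulation of per-fiber fate records (cleaved?
   at the ridge or along the length? further digestion? bundled?
   elongated?) into counts and percentages with explicit denominator
   conventions, cleavage times from frame indices
   (`t = frame·30 s − 30 s`), box–whisker summaries with 1.5×IQR whiskers,
   two-group one-way ANOVA, and OLS regression of per-trial percentages
   against (log) bead concentration.
4. **Synthetic records** — a seeded hierarchical generator of fiber-fate
   records (logistic dose–response in log₁₀ bead concentration, weak
   plasmin effect, bundling→elongation coupling, geometric frame-censored
   cleavage times) so the full pipeline is testable without microscopy
   data.

## Worked example

```sh
$ beadlysis dosimetry --dilution 100
```

reports (abridged) a stock of `4.55e12` beads/μL (`714` beads per
0.16 μm³ fiber volume), a 1:100 working concentration of `4.55e10` beads/μL
(`7.1` beads/fiber volume), and the full dilution series
`4.55e10, 1.52e10, 4.55e9, 2.27e9, 1.52e9, 4.55e8` beads/μL.

```sh
$ beadlysis simulate --n-sims 50 --seed 2023 --out summary.csv
bound 100.00% of 5000 trajectories; mean bind time 0.2298 s
```

Every bead found the fiber well within the 60 s simulated; the mean
first-passage time agrees with the analytic 1-D prediction 11/48 ≈ 0.229 s
for the lazy walk's vertical diffusivity (Δx²/5Δt = 8 μm²/s) from a uniform
start in the top half of the box. `summary.csv` holds the binding fraction
and mean binding time at each of the 101 lattice locations along the fiber.

```sh
$ beadlysis synth --seed 11 --out records.csv
wrote 1800 records to records.csv
$ beadlysis tabulate records.csv --out table.csv
$ beadlysis regress records.csv --out reg.json
slope 51.58 (p = 7.48e-43)
```

The generated study (6 bead × 3 plasmin concentrations × 5 trials × 20
fibers) shows the expected dose–response: the percentage of fibers
remaining uncleaved rises by ≈52 points per decade of bead concentration,
from ~1% at 4.55×10⁸ beads/μL to >90% at 4.55×10¹⁰ beads/μL.

Percentages in `table.csv` always name their denominator: e.g.
`pct_elongated_of_bundled` is the share of *bundled* fibers that elongated
(100% of 1 bundled fiber at the lowest concentration above — whence the
NaN where no fiber bundled).

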