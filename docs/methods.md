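# Methods

## qSIP equation chain

The estimator assumes that a marker gene's DNA forms a single Gaussian
band in the CsCl gradient and that the copy-weighted mean density
W = Σ ρᵢ yᵢ / Σ yᵢ of the qPCR-over-density profile estimates the band
centre. The chain W_light → G → M_light → (with W_lab) M_lab →
M_heavymax → EAF is linear in the density shift, so EAF inherits the
statistical properties of ΔW directly: it is invariant to any overall
scaling of copy numbers (qPCR efficiency differences between gradients
cancel), strictly increasing in W_lab, and bounded above by
1 − 0.01111233 (every carbon ¹³C).

Two GC–density calibrations coexist and are deliberately **not**
reconciled: the calibration used inside the EAF chain
(ρ = 1.646057 + 0.083506·G) and the classic Schildkraut-type relation
(ρ = 1.660 + 0.098·G). They differ by a few mg/mL over the GC range; each
is exactly self-inverse, and the pipeline's `calibration` switch (default
`hungate`-style) chooses which one interprets W_light. The Schildkraut
form is the one that reproduces the 1.69 g/mL prediction for a 31.5% GC
genome.

Decisions with no single established convention:

- Profiles need ≥ 3 fractions with detectable copies (configurable via
  `min_positive`); a single nonzero fraction is rejected rather than
  trusted as a band position.
- Fractions flagged below the qPCR detection limit (no-template-control
  Cq ≥ 35) contribute zero copies to W — the floor is treated as absence.
- Replicates are aggregated as per-pair EAF, then mean ± SD; an optional
  seeded bootstrap (default 1000 resamples when enabled) gives a
  percentile interval. Negative per-pair EAFs are retained (they diagnose
  noise) and clipped at zero only in the summary row of the output table.
- Pairing is either one-to-one by replicate id or each labeled gradient
  against the mean control density (`mean-control`), for designs without
  replicated controls.
- EAF is reported both as a fraction and as atom % (×100).

## Gradient simulator

The generator inverts the estimator's own forward model: the unlabeled
band centre comes from the taxon GC via the selected calibration; the
labeled centre from the true EAF through the molecular-weight chain;
copies per fraction are the Gaussian band mass integrated over each
fraction's density interval, scaled to a total copy number. Defaults are
the experimental geometry — 15 fractions spanning 1.66–1.78 g/mL (a
gradient started at 1.70 g/mL), band SD 0.006 g/mL, 20% CV multiplicative
lognormal qPCR noise (mean-one parameterization), optional detection
floor. Band centres falling outside the density span are a configuration
error; bands whose tails are clipped by the span edges introduce a small
truncation bias in W (the worst case over the tested GC/EAF grid is
≈0.002 EAF at GC 0.3, where the unlabeled band sits nearest the lower
edge), which is why the noise-free round-trip tolerance is 0.005 rather
than machine precision.

The stochastic round-trip tolerance (mean of 100 seeded estimates within
0.02 of truth at 20% CV) was set from the simulator's own Monte-Carlo
behaviour: the per-estimate SD is ≈0.014, so the standard error of the
mean is ≈0.0014, comfortably inside the band.

What the simulator does **not** emulate: multi-taxon mixtures within one
gradient, diffusion broadening differences between labeled and unlabeled
DNA, gradient-to-gradient density miscalibration, or partial labeling
heterogeneity within a population. Passing round trips therefore validate
the estimator's arithmetic and noise behaviour, not its robustness to
those real-data effects.

## Formula assignment

Neutral masses (m/z + 1.00727646 for [M−H]⁻) are decomposed over a
pre-computed skeleton grid of (C,O,N,S,P) counts; within a sub-ppm window
only the nearest integer hydrogen count can match, which makes the search
exact and fast. Filters beyond the element ranges: H ≤ 2C + 2 + N, and
DBE = 1 + C − H/2 + N/2 + P/2 must be a non-negative integer (this
encodes the nitrogen rule for even-electron neutrals; N and P are treated
as trivalent). Exact isotope masses: ¹²C = 12, ¹H = 1.00782503,
¹⁶O = 15.99491462, ¹⁴N = 14.00307401, ³²S = 31.97207069, ³¹P = 30.97376151.

- Default tolerance 0.5 ppm (15 T instrument class), config-exposed. At
  this tolerance the true formula of a zero-error mass ≤ 500 Da is the
  unique best candidate in 100% of sampled cases — a measured property of
  the constraint space (verified against an independent exhaustive
  enumerator in the test suite), not an assumption; above ~500 Da
  ambiguity grows and the `ambiguous` flag marks peaks with ≥ 2 in-window
  candidates.
- Only singly charged deprotonated ions are modelled; no adducts,
  multiply charged species, or isotopologue verification.
- The enumerator permits O = 0 when asked, but reported DOM formulas
  default to O ≥ 1 (`min_oxygen = 1`).
- Best candidate = smallest |ppm error|; ties broken lexicographically by
  formula string for determinism.
- Internal calibration fits a linear model of relative mass error vs m/z
  to ≥ 5 calibrant matches (3 ppm match window) and divides it out; least
  squares guarantees the calibrant RMS error never increases. Fewer than
  5 matches is an error (or a warned pass-through in non-strict mode, as
  used by the CLI).
- The relative detection limit removes peaks below a given fraction of
  the base-peak intensity; it is idempotent and order-preserving.
- If several peaks map to the same formula, the most intense is kept so
  each formula appears once per sample; relative intensities are then
  normalized to sum to one, and intensity-weighted molar ratios are
  weighted means of per-formula ratios (hence always convex combinations).

Compound classification order: AI_mod > 0.5 → aromatic (split at
O/C = 0.5); else H/C < 1.5 → highly unsaturated (split by O/C); else
H/C ≤ 2 with N > 0 → unsaturated with N (nitrogen takes precedence over
the O/C split, consistent with its reading as peptide-like material);
else H/C ≤ 2 → unsaturated (split by O/C); else saturated (split by O/C).
The boundary AI_mod = 0.5 routes to the non-aromatic branch. This order
makes the nine classes a total partition of the constraint space.

## Ordination

Bray–Curtis, BC(j,k) = Σ|xⱼ − xₖ| / Σ(xⱼ + xₖ), is computed on rows of
the sample × formula relative-intensity matrix; formulas absent from a
sample contribute zero (no imputation). PCoA double-centres the squared
dissimilarities (B = −½ J D² J) and eigendecomposes; coordinates use only
positive eigenvalues, negatives are reported unmodified (no square-root
or additive correction is applied by default), and explained proportions
are taken over the positive spectrum. Dissimilarities are reported on
[0, 1] with an optional ×100 percent-scale view. The implementation is
independent of scikit-bio, which serves as the cross-check oracle in the
tests (agreement to 1e−12 on Bray–Curtis, eigenvalue agreement and
sign-invariant coordinate agreement for PCoA).

Habitat grouping is rule-based: water-column samples by depth window
(surface 5–10 m, oxycline 50–95 m, OMZ 95–125 m, with the 95 m boundary
assigned to the OMZ), sediment samples by redox state (suboxic → core
top, sulfidic → subseafloor). Metadata outside every rule raises an
error rather than being silently binned.

## Grouped-DOM simulator

Groups share one formula library with lognormal baseline intensities;
each group multiplies the intensities of whole compound classes by an
effect factor (the level at which between-habitat differences are
reported, e.g. elevated N-containing unsaturated formulas in sediment
pore water), then per-sample lognormal noise is applied and rows are
renormalized. With zero effect, within- and between-group Bray–Curtis
dissimilarities are statistically indistinguishable (checked over 50
seeds); with strong effects, PCoA axis 1 separates the groups.

## Problem sizes and numerics

The test suite and acceptance script use deliberately compact problem
sizes chosen to exercise every code path with stable statistics:
15-fraction gradients over a 3×4 GC×EAF grid (noise-free) and 100 seeded
noisy replicates; 500 random formulas ≤ 500 Da for enumerator/oracle
equivalence plus 3000 random formulas (and explicit boundary cases) for
the classification partition sweep; 6–10-sample matrices for the
ordination properties. Numeric tolerances follow the quantity's
conditioning: 1e−12 where the computation is exact linear algebra or
arithmetic, 1e−8 for eigendecomposition-based reconstructions, and the
simulation-derived bands above for stochastic round trips.
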