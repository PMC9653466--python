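# Methods

This note documents the models behind each module, the defaults and why,
what the simulator does and does not emulate, and the numerical choices a
maintainer would want to know.

## Data model and snapshots

The flock is an event-sourced ledger: animal registrations plus dated
trait, reproduction, health and disposal records, stored as four CSV
tables with ISO-8601 dates.  Farm state on any date is reconstructed by
the `snapshot` primitive: an animal is present iff it entered on or
before the date and has no disposal dated on or before it — i.e. an
animal disposed on day *d* is present through *d−1* and absent from *d*.
The source gives no convention for the disposal day itself; this one is
fixed and documented in the CLI help.  Unknown parents are accepted as
empty or literal `"0"` cells (both occur in on-farm ledgers) and always
written back as empty.  `entry_date` defaults to `birth_date` because
on-farm births dominate.  A castration health event flips an animal's
effective sex to WETHER in all later snapshots; wethers are excluded from
breedable-ram counts at any age past lambhood.

## Pedigree algebra

`amatrix` is the standard tabular method on a topologically sorted
pedigree.  `inbreeding` computes F_i as the kinship of the parents by
memoised recursion, never materialising A (dense A is refused above 5,000
animals; A⁻¹ and F have no such limit).  `inbreeding_wright` enumerates
sire→common-ancestor→dam paths and sums (½)^(n+1)(1+F_A); enumeration is
exponential, so it is guarded at 25 ancestors per side and serves purely
as an independent oracle for the recursive route.  `ainverse` assembles
A⁻¹ directly from pedigree structure: for each animal the contribution
α_i = 1/d_i with Mendelian-sampling variance d_i = ½ − ¼(F_s + F_d)
(unknown-parent terms replaced by founder variance, giving d = ¾ or 1) is
scattered over the (animal, sire, dam) index triple with coefficients
(1, −½, −½).  Animals with any unknown parent are treated as non-inbred
founders for their own F — the standard convention; unknown-parent groups
are not modelled.

## Heritability

**Sib analysis.**  Full sibs nested within paternal half-sib groups.
Sums of squares follow the definitional three-way partition; the
unbalanced expected-mean-square coefficients are

    k1 = (N − Σ_ij n_ij²/n_i·)/(D − S)
    k2 = (Σ_ij n_ij²/n_i· − Σ_ij n_ij²/N)/(S − 1)
    k3 = (N − Σ_i n_i·²/N)/(S − 1)

which reduce to (n, n, dn) on balanced designs.  Components solve
σ²w = MS_w, σ²d = (MS_d − MS_w)/k1, σ²s = (MS_s − MS_w − k2σ²d)/k3;
negative solutions are truncated to zero and flagged, which is standard
practice.  h² is 4σ²s/σ²p, 4σ²d/σ²p or 2(σ²s+σ²d)/σ²p with
σ²p = σ²s + σ²d + σ²w; both the raw value and its [0, 1] clamp are
reported.  Phenotypes may optionally be pre-adjusted by fixed-effect
subclass means before grouping; default off.

**Animal model.**  y = Xb + Zu + e with u ~ N(0, Aσ²u).  Fixed factors
are sex and year of record (farm auto-included when records span more
than one farm; single-level factors dropped), encoded as a mean column
plus dummy contrasts dropping the alphabetically first level, which makes
X full rank and the MME nonsingular.  Variance components are estimated
by EM-REML on the mixed-model equations:

    σ²u ← (û'A⁻¹û + σ²e·tr(A⁻¹C_uu)) / q
    σ²e ← (y − Xb̂ − Zû)'y / (n − rank X)

with C_uu the u-block of the inverse coefficient matrix.  EM keeps both
components non-negative by construction and ascends the restricted
likelihood (verified in tests against an independent dense V-matrix
evaluation).  Defaults: tol 1e-6 on relative component change, maxit 200.
EM converges slowly when h² is near a boundary; the non-convergence flag
is returned rather than raised because the point estimate is still
usable.  One random unit is fitted at a time (animal or sire);
simultaneous animal+sire+dam random effects are not identifiable without
structure the data model does not carry.  A deterministic REML point
estimate was chosen over MCMC posterior sampling: downstream consumers
need only the h² value, and a sampler adds diagnostics without adding
information to that use.

## BLUP

λ = (1−h²)/h² for the animal model and (4−h²)/h² for the sire model.
Both models are exposed: the sire model treats u as sire transmitting
abilities; the animal model, the default for whole-flock EBV reports,
evaluates every pedigree member including unrecorded ancestors (their
equations enter only through λA⁻¹).  The system is solved by direct
sparse symmetric factorisation — at the target sizes (≤ ~10⁴ equations)
iterative solvers buy nothing — and reference-level dropping rather than
a generalised inverse makes solutions unique and bit-stable.  Repeated
records per animal are allowed; no permanent-environment effect is
fitted.  The mass-selection predictor EBV = P̄ + h²(P_i − P̄) is kept on
the trait scale as defined, while BLUP û is a deviation from the genetic
base; the two scales are reported as-is, never silently reconciled.

## Selection index and economics

The index is the exact linear combination I = Σ v_i·EBV_i over
BLUP EBVs (consumed from the evaluation, not typed by the user).  Full
index theory weights b = P⁻¹Gv are deliberately out of scope; economic
values serve directly as weights, overridable per flock.  The body-weight
economic value is ((book value / trait mean) / days to attain) ×
survivability — marginal currency per kg per day discounted by survival
to the age point; the fleece value is (book value / days) × mean fleece
weight.  Wool-quality values are the raw least-squares slope of price
per kg on fibre diameter or staple length from user-supplied market
observations, sign preserved and not normalised per genetic standard
deviation (no further scaling is defined for them).  Whether book value
is per animal or per kg is the caller's units contract.  A helper
computes survivability as survivors-at-age / born from flock counts.

## Neural predictor

Architecture: 4 hidden layers × 10 tanh units, linear output (451
parameters at 5 inputs) — "4 layers, 10 neurons each" is read as hidden
layers, since the per-layer unit count only applies to them.  Training:
mini-batch Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), 500 epochs, batch
10, validation split 0.2, Glorot-uniform init from a seeded generator.
Data preparation drops rows with missing values, then rows with any
feature or label beyond ±3 column SD, drops constant columns, splits
80/20 by seeded shuffle and z-scores features and labels on the training
portion only.  The outer 20 % test split exists so a held-out "testing
correlation" can be reported at all; the validation split only monitors
training.  Correlation is reported both as r and r×100 (a correlation
printed as "82.48" can only be the latter scale).  The network is plain
numpy forward/backward — at 451 parameters a framework would add a
dependency, not capability — which also makes runs bit-reproducible for
a fixed seed.  Divergence to NaN raises with advice to lower the
learning rate.

## Simulator

`simulate_flock` follows the additive infinitesimal model: founder
breeding values a ~ N(0, h²σ²p); offspring a = ½(a_s+a_d) + m with
m ~ N(0, ½σ²A(1 − ½(F_s+F_d))) — with that parental-inbreeding correction,
consistency between simulated BV covariance and the A matrix is a
testable theorem, not an assumption.  Phenotypes add a sex effect for
males, a per-generation year effect, and residual N(0, (1−h²)σ²p).
Defaults (10 founder sires, 50 dams, 3 generations, 2 lambs per ewe,
h² 0.3, σ²p 16 kg², mean 30 kg, sex effect +3 kg, 90 % survival to 12
months) are ordinary numbers for a meat-wool flock of this scale.
Generations are discrete birth-year cohorts; the 12-month weighing is
dated on the first birthday so year cohorts stay distinct in the fixed
year factor.  Mating is random with sires reused across dams and
parent–offspring pairs avoided unless `allow_close_mating` is set.
Animals that die before 12 months get a disposal record and no 12-month
weight.  Two traits are generated genetically (BWT as a scaled shadow of
W12M); wool traits and market prices come from `simulate_wool_market`
(price linear in fibre diameter and staple length plus noise, FD uniform
18–36 µm, SL 5–12 cm).

What the simulator does **not** emulate: maternal genetic and litter
effects, dominance, selection across generations, seasonality inside a
year, genotype×farm interaction, and measurement error beyond the single
residual.  Estimator recoveries on simulated data therefore show
correctness of the algebra and calibration under the stated model, not
robustness to real-data pathologies.

## Reports

Every report is a pure function of (dataset, request, config); run
timestamps live in metadata so outputs are byte-stable.  Conventions the
source leaves undefined are config defaults: lamb < 12 months, breedable
≥ 18 months, standard weigh ages 0/90/180/270/365 d with ±15 % windows
(minimum ±7 d so the birth column can fill), lambing rate = lambing
events in the calendar year / breedable ewes at the year start, mortality
= deaths in year / year-start snapshot size.  Empty denominators yield an
explicit NA marker, never an exception or an interpolated value.

## Problem sizes and tolerances

Oracle equivalences (tabular A vs kinship recursion, recursive vs path
inbreeding) are asserted at 1e-12 over 200 random pedigrees of ≤ 15
animals; A·A⁻¹ = I at 1e-8 up to ~240 animals; MME solutions against the
dense GLS/BLUP closed form at 1e-6 over 100 random systems of ≤ 50 units.
Monte-Carlo recoveries use 200 replicates of a 100×3×4 sib design (sire
h² within ±0.05 of 0.3) and 20 replicates of ~500-record flocks (EM-REML
h² within ±0.08 of 0.4).  The neural benchmark is 2500 rows × 5 features
with planted signal at R² ≈ 0.7, where the held-out correlation reaches
≈ 0.8.  These sizes keep the full suite and the acceptance script each
around two minutes on one CPU while leaving the Monte-Carlo standard
errors comfortably inside the asserted bands.

## Known limitations

No genomic relationships, unknown-parent groups, multi-trait or
repeatability models, EBV reliabilities (PEV), maternal effects, or
standard errors on h².  The sib analysis requires ≥ 2 sires and at least
one sire with ≥ 2 dams.  Wright path counting is an oracle, not a
production path.  The CLI holds whole tables in memory; it is a desk
tool, not a database server.
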