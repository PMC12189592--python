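# Methods

This note documents the models, conventions and numerical choices behind
`phesense`, in the order the pipeline runs them: process model →
synthetic data → PLSR → UKF → noise calibration. It also states what the
synthetic study can and cannot demonstrate about real fermentation data.

## Coarse-grained process model

State vector (fixed order everywhere):
`[V, S, X, P, A, Y, phi_T, phi_R, phi_Fp, m]` — volume [L], glycerol,
biomass, L-phe, acetate, L-tyr [g/L], then three proteome mass fractions
and a metabolite pool [–]. A fixed housekeeping fraction φ_Q completes
the proteome; the closure maintained by the dynamics is
φ_T + φ_R + φ_Fp ≤ 1 − φ_Q, with *m* accounted as a separate pool
alongside the proteome (metabolites, proteins and residual biomass are
distinct pools of the cell's mass budget).

Specific rates (per g biomass per hour):

    v_T = k_T φ_T S/(K_S + S)                       glycerol uptake
    μ   = v_R = k_R φ_R · m/(K_mR + m) · Y/(K_Y + Y)  growth (L-tyr limited)
    v_F = k_F φ_Fp · m/(K_mF + m)                   L-phe formation
    v_A = k_A · max(0, v_T − v_crit)                acetate overflow
    v_Y = c_Y μ                                     L-tyr demand

Allocation targets sum to one: α_Q = φ_Q,
α_Fp = α_Fp,max · I/(K_I + I) for inducer dose I [mM],
α_R = α_R,max · m/(K_mR + m) · (1 − α_Fp − α_Q), α_T the remainder.
Sector fractions relax toward their targets at the growth rate,
dφ_i/dt = μ(α_i − φ_i); the metabolite balance is
dm/dt = Y_MS v_T − μ/Y_XM − v_F/Y_PM − v_A/Y_AM − μ m. Liquid-phase
balances use the standard fed-batch form with dilution F/V and
phase-dependent feed concentrations.

**Feeding.** Three phases: batch (no feed) until glycerol depletion;
biomass production with a closed-loop exponential feed
F = μ_set/(Y_MS Y_XM) · X V / S_feed2 targeting μ_set = 0.1 1/h
(feed: 312.5 g/L glycerol plus 1.65 g/L L-phe and 3.75 g/L L-tyr for the
auxotrophies); induced production with constant specific feeding
F = q_feed3 · X V / S_feed3 at q_feed3 = 0.18 g_gly g_X⁻¹ h⁻¹
(800 g/L glycerol, no amino acids). The closed-loop form was preferred
over a precomputed exponential because it stays consistent when the
filter perturbs the state. The batch→feed switch is detected on the
simulated truth as the first crossing of S below 0.01 g/L (the stand-in
for the dissolved-oxygen spike an operator would watch); induction
follows after ≥ 21 h of biomass production. IPTG is a schedule input,
not a dynamic state.

**Parameter defaults.** The kinetic constants
(k_T = 2.5, k_R = 1.8, k_F = 0.9 1/h; K_S = 0.1 g/L; K_mR = K_mF = 0.05;
K_Y = 0.005 g/L; c_Y = 0.02; yields Y_MS = 0.7, Y_XM = 0.8, Y_PM = 0.6,
Y_AM = 0.5; v_crit = 0.6 g g⁻¹ h⁻¹; k_A = 0.3; φ_Q = 0.45;
α_R,max = 0.8; α_Fp,max = 0.25; K_I = 0.02 mM) are engineering choices
calibrated only to the qualitative phenotype of this process class —
batch ends after ≈ 15 h from a 4 g/L, 1 L start; the exponential-feed
phase realizes μ within 10% of its 0.1 1/h setpoint; tens of g/L L-phe
after induction; low acetate — and are **not** fitted to any experimental
dataset. All defaults live in `CGMParameters` and round-trip through a
unit-annotated YAML file so an alternative parameterization can be
swapped in without code changes.

**Integration.** Ground truth uses an adaptive stiff-capable solver
(LSODA, atol = rtol = 1e−9), integrated phase by phase so the feed-law
switches never land inside an adaptive step. Two bookkeeping states (the
cumulative glycerol mass fed and taken up) ride along, so the
liquid-phase glycerol balance S·V = S₀V₀ + ∫F S_feed − ∫v_T X V closes
to integrator accuracy (verified to < 1e−6 relative over a 70 h run).
Components more negative than tolerance abort; smaller excursions are
clipped to zero on output.

**Known limitation.** Growth stops when L-tyr depletes in the production
phase (no L-tyr in the final feed), freezing the proteome fractions; with
the production drain saturated, continued feeding then accumulates the
metabolite pool *m* without bound (≈ 1.9 by 70 h). The rate laws contain
no uptake regulation that would throttle v_T in that regime, so this is
inherent to the model structure, not the implementation. It does not
affect the measurable concentrations' plausibility but *m* should not be
interpreted quantitatively late in the production phase. Plasmid burden,
pH/temperature dynamics and gas-phase transfer are out of scope.

## Synthetic process data

The observation model mapping states to the eight online channels is
invented (real processes log real sensors), engineered so the correlation
structure a PLSR soft sensor exploits is present and realistic:

- **Off-gas CO₂** follows growth plus maintenance:
  CER ∝ (y_c μ + m_c) X V, CO₂% = baseline + gain·CER/aeration.
- **DO cascade**: oxygen demand is taken proportional to CER; the
  controller raises transfer capacity kLa ∝ (stirrer/300)^1.2 ·
  (aeration/0.5)^0.5 to hold pO₂ near its 40% setpoint (+8 points
  headroom), ramping the stirrer to 1200 rpm before touching aeration
  (max 5 L/min). pO₂ = 100 − k_our·OUR/kLa. The scaling k_our = 2400 puts
  cascade engagement in mid biomass production, so the stirrer sweeps its
  range during the exponential phase and the cascade channels sit nearly
  flat during constant-feed production — the signal geometry a soft
  sensor faces in practice.
- **Base addition** integrates the acid loads: a₁∫μXV dt (ammonia demand
  of growth) + a₂·P·V + a₃·A·V with a₃ = 4.0 ≫ a₂ = 0.4 mL/g (L-phe is a
  weak ampholyte; acetate a strong acid). Non-decreasing before noise.
  This is the channel that carries the product signal.
- **Feed mass flow** is F·ρ_feed; **pH and temperature** are controlled
  setpoints plus stationary AR(1) wander — deliberately uninformative.

Gaussian sensor noise per channel; everything deterministic under a
single seeded generator. Offline samples mimic an HPLC workflow: none in
the batch phase (nobody samples overnight), six in the growth phase,
eight in production, at jittered regular times, with mean-one lognormal
noise (CV 5%) plus a 0.01 g/L additive floor, clipped at zero.
`simulate_noisy` additionally generates truths with known additive
process noise (for calibration studies). Antifoam events, probe drift
and foam excursions are not emulated.

Three scenarios mirror the study design: a reference process at 0.3 mM
IPTG and two low-induction processes at 0.01 mM. Observed reality for
this strain is that *weaker* induction yields *higher* titers (plausibly
reduced metabolic burden) — an effect the allocation model cannot
produce, since α_Fp increases with dose. The low-induction scenarios
therefore generate their ground truth with a phenomenological override —
a stronger, more sensitive production response (α_Fp,max 0.30,
K_I 0.002 mM, k_F ×1.5) — while the filter always runs the nominal
parameterization. This is an emulation of the phenotype, not a mechanism,
and creates exactly the model-mismatch regime the hybrid filter exists
for. Consequently, what the passing tests show is that the filter
corrects a *misparameterized* model of the *correct structure* using
realistic signal correlations; they cannot certify performance under
structural errors real cells will produce (acetate dynamics, burden,
foam-driven signal artifacts).

## Phase-wise PLSR

Inputs of each phase are offset-centered against the phase-start row
(X̃ᵢ = Xᵢ − X₀; by default X₀ is literally the first row, configurable to
an average of the first few rows), which removes between-run offsets
inherited from the previous phase; a constant shift present at the phase
start provably cannot affect predictions. Training outputs are the
simulated concentrations linearly interpolated onto the online
timestamps (sparse offline samples alone cannot supervise per-row
training); outputs are additionally mean-centered inside the regression,
and both offsets are stored in the model object.

SIMPLS is implemented directly: at each step the dominant left singular
vector of the deflated cross-product S = XᵀY gives the X-weight, scores
are normalized, and S is deflated against an orthonormal basis of the
X-loadings, which keeps successive scores orthogonal. At full rank the
coefficients coincide with ordinary least squares (tested to 1e−8
against the normal equations). Inputs are not variance-scaled by default
(offset removal is the only input pretreatment); a standardize flag is
deliberately absent rather than half-supported.

Cross-validation uses contiguous time blocks (five of them) to limit
leakage between autocorrelated neighbours; random-row folds are
available behind a flag. The per-count criterion is the root of the mean
per-output MSE with outputs standardized by their training spread, so
biomass (tens of g/L) does not drown L-tyr (tenths). Selection follows
the one-standard-error rule: the smallest count within one SE (over
folds) of the minimum. Past the true latent dimension the RMSECV curve
is flat to within noise, where a strict argmin picks an arbitrary
over-parameterized model; the 1-SE rule treats near-ties as ties and
breaks them toward parsimony (strict argmin remains available as
`rule="min"`). Negative predicted concentrations are passed through
raw — the state constraint belongs to the filter, not the regression.

## Constrained unscented Kalman filter

Scaled unscented transform with α = 0.5, β = 2, κ = 0 by default
(λ = α²(n+κ) − n, n = 10): center weights W_m⁰ = λ/(n+λ),
W_c⁰ = λ/(n+λ) + (1 − α² + β), off-center weights 1/(2(n+λ)) — the form
that makes the mean weights sum to one and the transform exact for
linear maps (verified against a textbook Kalman filter to 1e−6 over 200
steps, and in practice to machine precision). Sigma points come from a
Cholesky factor of (n+λ)P with escalating diagonal jitter
(1e−10…1e−6 × trace/n) before declaring degeneracy.

Cadence: two 60 s prediction steps per 120 s measurement update,
matching the online logging interval; seconds convert to hours at the
configuration boundary. The initial estimate refers to one update
interval before the first online row, so every row receives exactly one
update preceded by two predictions. Sigma-point propagation integrates
the process model with classical RK4 at a fixed 15 s substep, vectorised
across all 21 points. An adaptive stiff solver per sigma point per step
would be two orders of magnitude slower and makes Q calibration
(hundreds of filter runs) impractical; the fastest mode in the relevant
regime — quasi-steady glycerol at high cell density, time constant
≳ 14 s·(35 g/L / X) — is resolved with margin at 15 s, and the
propagator agrees with a 1e−10-tolerance adaptive solve to < 1e−6 over a
prediction interval. Concentrations are clipped at zero *inside the rate
evaluations only*, so slightly negative sigma-point excursions stay well
defined without modifying the state.

Update: innovation covariance solved (never inverted), posterior
covariance symmetrized. Constraint handling: when any posterior
component falls below its bound (zeros; 1e−6 L for volume), sigma points
are regenerated from the posterior, every violating coordinate is
clipped to its bound, and the set is recombined with the standard
weights — once, with no iteration and no re-propagation through the
dynamics (re-propagation is available behind a flag, reading the
procedure's "another prediction step" as a full time update instead of a
recombination). Because the scaled transform's center covariance weight
can be negative, the recombined covariance of an asymmetric clipped set
can acquire a tiny negative eigenvalue; it is floored at PSD. Negative
PLSR measurements are passed to the filter unclipped — the constraint
acts on states, not measurements.

P₀ defaults to diag((10% of x₀)²) floored at 1e−6, with the glycerol
entry inflated ×10: starting substrate varies between runs more than
other initial conditions, so the filter should lean on measurements for
that state early.

## Noise calibration

R = diag(RMSE²) of the PLSR predictions against the calibration
process's offline samples, with RMSEs floored at 1e−3 g/L before
squaring: an output whose calibration samples all sit in a flat
near-zero stretch (glycerol, which is only ever high during the
unsampled batch phase) would otherwise get an absurdly trusted channel.

Q's diagonal is tuned by a generalized pattern search in log10 space
over [1e−8, 1e2]: opportunistic coordinate polling in fixed order, mesh
×2 on success, ×0.5 on a failed full poll, stop at mesh < 1e−3 or the
evaluation budget (500 by default; the shipped pipeline uses 40, each
evaluation being a full filter pass). The objective is the mean squared
error between the posterior (interpolated to the offline sampling times)
and the offline measurements, per-output standardized by the offline
spread. Fully deterministic. By default only the five measured-state
entries are polled (the intracellular entries keep their defaults) —
they are the only coordinates the offline data can inform. Q and R are
constant over the whole run; per-phase R is a known possible refinement
that is intentionally not implemented here.

## Problem sizes and determinism

The default study simulates ≈ 70 h processes at 120 s cadence
(≈ 2100 online rows; 6 + 8 offline samples). The test suite exercises
the same pipeline on a shortened variant (21 h biomass production, 8 h
production phase, ≈ 1300 rows) and caps the calibration budget at 8–14
filter evaluations, sizes chosen so the full suite stays comfortable on
a single CPU while leaving every stage's behaviour intact; the
acceptance script runs the full-size study with the default budget of
40. Every random draw flows from a single seed through named
sub-sequences, and the complete workflow writes byte-identical outputs
when rerun with the same seed and configuration.
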