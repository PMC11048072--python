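# Methods

`chometab` models the central carbon metabolism of CHO cells in
high-seeding-density (HSD) and standard fed-batch (STD FB) antibody
production processes. It combines a stoichiometric network analysed by
FBA/MFA with a reduced kinetic ODE model whose regulatory structure
reproduces the lactate shift — the transition from net lactate production
(overflow metabolism) to net lactate consumption — and the machinery to
calibrate, select and exercise an ensemble of such models.

## Stoichiometric network

The default network (46 reactions, 41 metabolites) covers glycolysis, the
oxidative pentose-phosphate entry, the TCA cycle, anaplerosis (pyruvate
carboxylase and malic enzyme), lactate exchange, catabolism of asparagine,
aspartate, glutamate, serine, isoleucine and leucine, ammonium release,
oxidative phosphorylation and ATP maintenance, plus biomass and mAb
pseudo-reactions. It is shipped as an editable reaction table
(`data/default_reactions.tsv`, equations in `A + 2 B -> C` syntax) so users
can substitute their own network; SBML L3 round-trip I/O is available via
cobrapy.

Conventions and choices:

* Redox and energy cofactors (NAD(H), NADP(H), FAD(H2), ATP/ADP) are
  carried as carbon-free conserved pairs, so carbon/nitrogen balancing acts
  on the substrate skeletons. Every internal reaction must balance exactly;
  exchanges, the biomass and product sinks and the ATP drain are exempt.
* Oxidative phosphorylation uses fixed P/O ratios: 3 ATP per mitochondrial
  NADH, 2 per FADH2. Cytosolic NADH enters the chain through a
  glycerol-3-phosphate-shuttle-equivalent at FADH2 yield. With these
  stoichiometries the network's LP-maximal ATP yield is exactly 2 per
  glucose for glycolytic fermentation to lactate and 36 per glucose for
  complete oxidation — the textbook figures the energy-efficiency
  discussion of the lactate shift rests on.
* Biomass and mAb synthesis are precursor drains with documented, editable
  coefficients; no measured composition is implied.
* Compartments are annotations; no membrane potential or proton accounting.

## FBA and MFA

Measured cell-specific exchange rates constrain their reactions to ±10% of
the measured value; unmeasured reactions keep lower bound 0 (irreversible)
or −1000, upper bound 1000 (µmol/g_DW/h). FBA maximizes biomass during the
growth phase and mAb production during the production phase (changeover day
configurable, default 7). Analysis windows per condition: STD FB days 4–13
(skipping the lag phase), HSD control days 0–11 (the process runs 11 days),
supplemented HSD runs days 2–13.

Among alternate LP optima the reported flux distribution is the one of
minimal Euclidean norm (a secondary QP), making results reproducible. MFA
refines the FBA point by weighted least squares on the measured fluxes
(weights 1/max(q², 1e−6)) subject to S·v = 0 and the structural
irreversibility bounds only; the quadratic program is solved in the
nullspace of S (the steady-state constraint is eliminated exactly, bounds
become linear inequalities). The reported R² pools all measured fluxes:
R² = 1 − SSR/SST with SST about the measured mean. On synthetic
steady-state-consistent flux sets with 5% multiplicative measurement noise
the median pooled R² over 20 replicates is ≈ 0.999, comfortably above the
0.98 validation threshold used for the stoichiometric model. When noisy
±10% measurement windows make the FBA infeasible, the window fraction is
widened by factors of 1.5 until a feasible start point exists (the MFA
result does not use these windows).

## Preprocessing

Concentration series are cleaned with a Hampel identifier (moving median,
window 5, window-local MAD scale, default threshold 4 robust SDs; flagged
points replaced by linear interpolation), then smoothed by LOWESS (tricube
local linear regression, fraction 0.5, one pass, no robustifying iteration
— the series have only 13 points). Cell-specific rates are interval mass
balances on the smoothed series:

    q = [Δ(C·V)/Δt − F·C_feed − Σ boluses/Δt] / (X_dw·V)

assigned to interval midpoints, with X_dw·V the interval-mean biomass
(dry weight per cell 250 pg, configurable — the conversion the per-g_DW
scale rests on). Consumption is negative. The recovered rates re-integrate
the fed-batch balance to the observed amounts to well under 2%. Growth rate
µ comes from Δln(X·V), specific productivity from Δ(titer·V). Sampling
losses are neglected.

## Kinetic model

Thirteen states: Glc, Pyr, Lac, NH4, Asn, Asp, Glu, Ser, Ile, Leu
[mmol/L], biomass X [g_DW/L], mAb [mg/L], volume V [L]. All lumped rates
are multiplicative Michaelis–Menten forms evaluated on non-negative-clipped
states; growth is multiplicative Monod on Glc/Asn/Ser/Ile/Leu with
first-order death; mAb synthesis is glucose-saturable. Dilution terms
(F/V)(C_feed − C) apply to all concentrations.

The lactate-shift core couples four regulatory terms:

* r_gly = vmax·Glc/(Km+Glc)·Asn/(Ka+Asn) — glycolysis activated by
  asparagine;
* r_ldh = vmax·Pyr/(Km+Pyr)·Ki^n/(Ki^n+Lac^n) — LDH feedback-inhibited by
  lactate with a parametric Hill exponent n ≥ 1;
* r_up = vmax·Lac/(Km+Lac)·α/(α+r_gly) — lactate uptake inversely coupled
  to the glycolytic rate. The saturating inverse term α/(α+r_gly) is a
  regularized stand-in for a literal 1/r_gly proportionality; it preserves
  the inverse monotone coupling while remaining finite at r_gly = 0;
* r_tca = vmax·Pyr/(Km+Pyr)·Ki/(Ki+Asn) — pyruvate entry into the TCA
  cycle inhibited by asparagine.

The causal chain: asparagine depletion switches glycolysis off, which both
releases lactate uptake (through the inverse coupling) and opens pyruvate's
route into the TCA cycle, so net lactate flux changes sign. Clamping Asn at
its initial value abolishes the shift in simulation; reducing vmax_gly
never delays it.

Three structure variants share this core. Variant 1 is the base model;
variant 2 makes the Asp→Glu transamination lump reversible; variant 3
routes the serine consumption lump into pyruvate. These secondary
differences are package choices standing in for structure variants that
differ only in peripheral reactions.

Fed-batch events: continuous feed (constant rate from a start time),
glucose-threshold control (integration-event-triggered bolus restoring
glucose from 11 to 33 mmol/L with a 2775 mmol/L stock), lactate boluses
checked at daily marks (days 3–13, trigger 2 g/L ≈ 22.2 mmol/L, the lower
end of the stated 2–3 g/L band), amino-acid bolus medium on days 1–6, and
volume-only boluses standing in for the cysteine additions on days 1–5
(cysteine is not a model state; only its dilution effect is represented).
Boluses are instantaneous well-mixed jumps, C⁺ = (C·V + C_b·V_b)/(V+V_b),
between LSODA integration segments.

### Reference parameters

The appendix-level parameter tables of the source study are not available,
so the package ships a documented reference set (`reference_parameters()`)
with magnitudes in the literature ranges for CHO kinetic models
(Km ~ 0.1–5 mmol/L, vmax ~ 0.01–1 mmol/g_DW/h, µmax 0.035 1/h, kd 0.004
1/h). The set was chosen once so that the simulated HSD control reproduces
the qualitative study features: asparagine drops steeply and nearly
depletes within ~3 days, lactate rises to a peak and then is consumed
(shift day 3 on the daily grid), the LAC+CYS condition shows
lactate/glucose uptake ratios above 1 after the shift, an asparagine feed
factor of 0.75 shifts no later than control while a factor of 2.0 abolishes
the shift, and biomass peaks near 8 g_DW/L (~32×10⁶ cells/mL at 250
pg/cell). Absolute concentration scales (initial Glc 40, Asn 10, Lac 1
mmol/L; feed Glc 150, Asn 40 mmol/L; BM Asn 100 mmol/L) are likewise
package defaults, not measured values.

## Synthetic data

`synthetic.generate_dataset` simulates the truth model under a condition's
schedule (HSD conditions seeded at 10×10⁶ cells/mL for 12 days, STD FB at
0.7×10⁶ for 14 days; 13 samples at 24 h), then adds multiplicative Gaussian
noise (CV 5% concentrations and titer, 8% VCD) and clips at zero. Viability
is a synthetic sigmoid (it is not a model state; supplemented conditions
decline later) — it carries no information used by the pipeline. The
returned measurement object records the feed actually delivered (including
controller-fired boluses) so preprocessing can correct for it; the sealed
truth record (noise-free samples, true parameters) supports recovery tests.
What the generator does not emulate: analytical recovery artifacts,
correlated errors between metabolites, sampling-volume losses, pH/pO₂
signals, and any product-quality attribute. Passing tests therefore
demonstrate internal consistency of the pipeline under the stated noise
model, not performance on real cultivation data.

`make_consistent_flux_set` samples steady-state flux distributions as
random Dirichlet-weighted convex combinations of LP polytope vertices
(random objectives, bounds clipped to a magnitude scale), guaranteeing
S·v = 0 exactly; the measured-exchange subset, optionally noise-perturbed,
feeds the MFA validation.

## Calibration, selection, ensembles

The fit cost is a max-scaled SSR: Σ_states Σ_t ((sim−obs)/scale)² with
scale the maximum observed magnitude of the state, so all 12 observed
states contribute comparably. Parameters are searched in log space within
box bounds (default ×/÷5 around the reference magnitudes). Model-based
fits run a seeded two-stage strategy: a differential-evolution global
stage over the log-box (Sobol initialization, deferred updating, ~2/3 of
the evaluation budget) followed by trust-region least-squares polishing of
the residual vector. Surrogate scalar costs use a Latin-hypercube +
recombination + Nelder–Mead path instead. Everything is deterministic
given the seed.

On the model's own synthetic data (13 daily samples, 12 observed states,
5% noise) the 8 lactate-shift core parameters are searched over ×/÷5
bounds. The cost landscape is multimodal and sloppy: vmax_ldh/Ki_lac and
α/vmax_tca form compensating pairs, so point recovery of every parameter
is not expected. Practical identifiability is quantified from the
Gauss–Newton covariance at the fit (`calibrate.identifiability`): a
parameter counts as identifiable when its 2σ linearized confidence
interval lies within the ±20% recovery band, i.e. fractional standard
error ≤ 10%. Those parameters (the asparagine-side constants vmax_asn,
vmax_gly, ka_asn_gly in the shipped setup) are recovered within ±20% of
truth, while the best-fit cost reaches the noise floor (the cost evaluated
at the true parameters). The compensating pairs are reported with large
standard errors and are not claimed as point estimates.

Model selection uses the Gaussian-residual AIC, n·ln(cost/n) + 2k, with
the small-sample correction available; structures within ΔAIC ≤ 10 of the
best are retained. Per structure the five lowest-cost parameter sets enter
the ensemble; the ensemble prediction is the pointwise member mean with a
min–max band, and failing members are excluded with a warning.

The viable parameter space (cost below a threshold) is characterized in
two stages: an adaptive random walk with flat acceptance (any in-bounds
point below threshold accepted; step size tuned toward ~30% acceptance)
followed by uniform resampling inside an ellipsoid fitted to the accepted
cloud, keeping viable points. This is a simplified, documented
re-implementation of the out-of-equilibrium-Metropolis + multiple-ellipsoid
idea; its contract is coverage of the viable set, verified against an
analytic spherical set and a curved valley.

Global sensitivity uses Morris elementary-effects screening (4 levels,
µ* and σ per parameter) implemented directly.

## Feed-composition studies

`feedscan.scan_feed_asparagine` scales asparagine in the continuous feed
and in every bolus composition by a factor (defaults 0.75 for "reduced" and
2.0 for "elevated"), simulates every ensemble member, and reports the
member-mean trajectory, the shift day, per-phase net volumetric lactate
rates and the final titer. The shift day is defined as the first day whose
feed-corrected net volumetric lactate rate is negative and stays negative
for at least 48 h; the source study prints no criterion, so this sustained
sign-change rule is a package definition. Phase windows default to growth
D0–D5 and production D5–D10. Rate tables are extracted at days 2 and 5,
marking the overflow and post-shift phases.

## Numerical choices and limitations

* LSODA with rtol 1e-7/atol 1e-9 for reported simulations (1e-6/1e-8 in
  the fitting hot path); states floored at 0 inside the RHS with a clip
  counter.
* LP via HiGHS; QPs via SLSQP on full-row-rank reductions (SVD) of the
  steady-state constraint.
* Problem sizes in the test suite are chosen for a laptop-scale run:
  recovery fits use a few thousand ODE evaluations, MFA validation 20
  replicates, sensitivity screenings a handful of trajectories.
* Known limitations: no pH/osmolality regulation of productivity (the
  model will overpredict titer gains from elevated asparagine), no
  product-quality attributes, viability only implicit via first-order
  death, cysteine only as dilution, and the kinetic lumps hand carbon to
  an unmodelled TCA pool that is accounted in tests but not tracked as a
  state.
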