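# Methods

## State space and energetics

A transcription elongation complex (TEC) transcribing a gene of length L is
described by states S(l, t): mRNA length l (nt, counted along the coding
strand, 1-based) and translocation register t (0 = pretranslocated, 1 =
posttranslocated). Backtracked (t < 0) and hypertranslocated (t > 1) states,
pausing and misincorporation are outside the model: the observable is the
pause-free velocity. Transcription runs from S(l0, 0) to S(L, 0) with
l0 = β1 + h + 2; the geometry is held at h = 9 hybrid basepairs and
β1 = 2 / β2 = 1 unpaired template bases upstream/downstream, giving a 12-nt
transcription bubble. The stored strand is the coding strand; the mRNA (U
for T) and template strand are derived views.

The basepairing energy of a state sums nearest-neighbour doublet energies:
SantaLucia-1998 unified DNA/DNA ΔG°37 for the closed duplex flanking the
bubble, Sugimoto-1995 DNA/RNA ΔG°37 (keyed by the RNA strand 5′→3′) for the
hybrid, shipped as TSV data files and used unchanged at T = 310 K
(k_BT = 4.28001×10⁻²¹ J; 1 kcal/mol = 1.6233 k_BT). Because only energy
*differences* at a fixed l enter the kinetics, each site evaluates its
states within a fixed local window of gene doublets; window constants cancel
identically.

Forward translocation melts the basepair at the downstream bubble edge and
the basepair at the upstream end of the hybrid (pre: h basepairs; post:
h − 1). The transition state T(l, 0) contains exactly the basepairs common
to S(l, 0) and S(l, 1).

**Dangling ends.** The published recipe this component follows is not
restated in its source, so the shipped treatment is a documented
reconstruction: a single 5′ dangling-end term (Bommarito-2000 DNA set,
ΔG°37 derived from the published ΔH/ΔS at 310.15 K) at the upstream hybrid
terminus, present only in the shortened hybrid register (post and transition
states) — physically, the mRNA base freed by melting the upstream hybrid
basepair remains stacked on the hybrid end. Two constraints guided the
choice among the enumerated alternatives (no dangling ends; terms at both
termini; terms only in the open register): the literature's description of
*the* dangling end of the DNA/RNA hybrid with a mean contribution of about
−1 k_BT (the 5′ dangling table averages −0.75 k_BT), and the reported
sequence-averaged equilibrium constants (below). The term is switchable off
via `EnergyModel(dangling_ends=False)`.

## Kinetics and the 12-model space

Transition-state theory gives force-dependent translocation rates (assisting
force positive, 1 pN·Å = 10⁻²² J):

    k_fwd(l) = A exp(−(ΔG_τ‡ + ΔG_TS(l) − ΔG_pre(l) − F δ1/k_BT))
    k_bck(l) = A exp(−(ΔG_τ‡ + ΔG_TS(l) − (ΔG_post(l) + ΔG_τ1) + F (δ−δ1)/k_BT))

with prefactor A fixed at 10⁶ s⁻¹ (ΔG_τ‡ is only interpretable jointly with
A), δ = 3.4 Å, and the detailed-balance identity k_fwd/k_bck =
e^{Fδ/k_BT}/K_τ(l) holding for every barrier height and δ1. NTP binding is
k_bind·[NTP] against release k_rel = K_D·k_bind, where [NTP] is the
concentration of the NTP complementary to template position l + 1; catalysis
k_cat returns the enzyme to S(l+1, 0).

Either step may instead be a partial equilibrium: translocation equilibrium
replaces (k_fwd, k_bck, ΔG_τ‡, δ1) by K_τ(l) with the posttranslocated
weight scaled by e^{Fδ/k_BT}; binding equilibrium replaces (k_bind, k_rel)
by the occupancy [NTP]/([NTP]+K_D). Crossing the two approximations with
whether ΔG_τ1 and δ1 are estimated or held at their neutral values (0 and
δ/2) yields 12 models, from model 1 (both equilibria, {k_cat, K_D}) to
model 12 (fully kinetic, all six parameters). Models 6, 7, 9, 10 carry the
canonical assignment 6 = {+δ1}, 7 = {+k_bind}, 9 = {+k_bind, ΔG_τ1},
10 = {+k_bind, δ1} over the three-parameter kinetic-translocation base
(model 3); the model network connects any two models whose active-parameter
sets differ by exactly one parameter.

## Simulation

Every variant reduces, per site, to a CTMC on ≤ 3 states (pre, post/
coalesced, bound), so per-site rates are precomputed per (model, parameters,
condition) and shared across replicates. The Gillespie kernel (numba)
consumes only uniform draws (inverse-transform exponentials), making
trajectories deterministic given a seed and independent of any library's
distribution implementations; per-replicate streams are derived from the
root seed with `SeedSequence`, so results do not depend on scheduling.
The mean velocity estimator averages per-replicate velocities
(nucleotides/elapsed time), matching how the observable is computed from
single-molecule records.

The exact oracle computes the mean first-passage time through each site in
closed form (e.g. (k_fwd + k_bck' + k_cat·f)/(k_fwd·k_cat·f) under binding
equilibrium) and sums sites. Equivalence tests compare mean *completion
times*, because the replicate-averaged velocity E[N/T] carries an O(1/N)
Jensen bias relative to N/E[T] (~1–3% on a 100-nt template) that is a
property of the estimator, not a simulator defect.

Pathological parameter draws can cycle millions of times without advancing;
the dataset simulator caps events per replicate (200 per site + 10⁴) and the
inference engine treats an over-cap simulation as a rejected proposal.

## Priors and inference

Priors (per enzyme profile): k_cat ~ LN(3.454, 0.587) for RNAP/pol II and
LN(4.585, 0.457) for T7; K_D ~ LN(1.844, 1.762); k_bind ~ LN(−1.498, 1.585);
ΔG_τ1 ~ N(0, 1.55) / N(−3.3, 1.55); ΔG_τ‡ ~ N(5.5, 0.97) / N(2.5, 1.36);
δ1 ~ U(0, 3.4). The model indicator carries mass 2/16 for each
translocation-equilibrium model (they do not use δ1) and 1/16 otherwise.

The sampler is Marjoram-style ABC-MCMC on the joint state (M, Θ) with all
six parameters always carried. Proposals: single-component Gaussian random
walks — log-space for k_cat, K_D, k_bind, linear for the energies,
reflecting at the δ1 bounds — with step sd equal to half the prior's own
scale; model moves (probability 0.25) pick a uniform neighbour in the model
network and draw newly activated parameters from their priors, so the MH
ratio reduces to the model-mass and neighbour-count ratios. A proposal is
accepted iff the MH draw accepts *and* X²(Θ) = Σ(v_sim−v_obs)²/v_obs ≤ ε
(inclusive); the MH draw is evaluated first so prior rejections skip the
simulation (the chain's law is unchanged). X² is recomputed from fresh
simulations at each proposal; the stored X² of the current state is not
refreshed (noisy ABC-MCMC). Chains are initialised by prior draws until the
distance ball is hit (capped at 2000 attempts). Burn-in is 10% and traces
are thinned to ≥ 10³ retained states per chain by default.

The historical thresholds ε = 2.39/0.705/4.63 per enzyme profile are shipped
as order-of-magnitude defaults only: they are tied to the original
analysis's distance definition and chain scale and should be recalibrated
via the noise-floor helper for new data.

## Diagnostics

ESS = n/(1 + 2Σρ_k) with the autocorrelation sum truncated at the first
non-positive pair; R̂ is the classic Gelman–Rubin potential scale reduction
(no rank normalisation, matching the era of the analyses this mirrors); HPD
intervals are the narrowest contiguous window holding ⌈0.95 n⌉ sorted
samples; the multivariate point estimate is the geometric median by
Weiszfeld iteration on per-dimension standardised samples (the parameters
mix s⁻¹, μM, k_BT and Å; whether to standardise is an open choice and is
documented here as ours). Summaries are conditional on each model of the
credible set. Convergence flags use ESS > 100 and R̂ < 1.1.

## Synthetic data and study designs

The generator emulates three published experimental layouts: a force sweep
(−10…30 pN) at saturating (1 mM) and limiting NTP ([ATP] = 5, [CTP] = 2.5,
[GTP] = 10, [UTP] = 10 μM) for bacterial RNAP; an NTP titration at ±6.5 pN
for pol II; and a force sweep at two NTP levels including strong hindering
loads for T7. Default noise is multiplicative Gaussian with cv = 5%, the
order of scatter in published single-molecule velocity data. The default
template is synthetic iid sequence — it reproduces average dinucleotide
composition but not the local sequence correlations, repeats or codon
structure of real genes, so passing tests demonstrate correctness of the
machinery on realistic *average* energetics, not prediction of any real
gene's site-specific behaviour.

Study sizes (chosen for minutes-scale runs on one core):

- **Sequence-averaged K̄_τ** uses a 4029-nt GC-0.52 iid stand-in for a ~4 kb
  bacterial coding sequence. On it, the shipped energetics give K̄_τ =
  0.71/0.052/0.096 at ΔG_τ1 = −2.0/−4.6/−4.0 k_BT; the ratios between the
  three values are exactly e^{ΔΔG_τ1} on any template. The absolute values
  carry the dangling-end-reconstruction and template-composition caveats
  above (K̄_τ moves by roughly ±15% across GC 0.48–0.54).
- **Oracle equivalence**: 300 replicates on random 100-nt templates, one
  model per equilibrium variant, compared on completion time (|z| < 3);
  closed-form recovery on a 200-site homogeneous landscape over a 4×4
  force/[NTP] grid, 60 replicates per cell.
- **Prior recovery**: 2 chains × 6×10⁴ iterations with the simulator
  bypassed; KS tests per parameter conditional on activity after
  subsampling at stride 2n/ESS (raw MCMC samples would make the KS test
  anti-conservative); χ² on model frequencies.
- **Parameter recovery**: 500-nt template, 12-cell design, 5% noise,
  generated from model 11 (truth k_cat = 30, K_D = 20, ΔG_τ1 = −2,
  δ1 = 2.5, ΔG_τ‡ = 5.5, 8 generator replicates); fitted with 2 chains ×
  2×10⁴ states restricted to models {4, 11}, 2 simulation replicates per
  condition, ε = 2.5 ≈ 5× the analytic noise floor E[X²] = cv²Σv_i of the
  dataset — loose enough to seed the chain from prior draws, tight enough
  that the translocation-equilibrium alternative (model 4) cannot absorb
  the force response of the kinetic-translocation truth.

## Numerical choices and degenerate inputs

Energies are kept in k_BT throughout; rates are plain `exp` evaluations, so
extreme prior draws can overflow to inf — such states stall or hit the
event cap and are rejected rather than propagated. A template with L = l0
yields zero nucleotides in zero time and NaN velocity. [NTP] = 0 gives zero
binding propensity and a stalled-simulation error on a full template. Ties
in the HPD window and the model credible-set ordering break toward the
lower index; the Weiszfeld iteration nudges exact data-point hits by 10⁻¹²
to avoid division by zero and stops at a relative tolerance of 10⁻⁸.

## Known limitations

- The master-equation oracle is per-site (valid because the state graph is
  a chain of independent site cycles); it does not generalise to models
  with backtracking.
- ABC posteriors depend on ε; the shipped ε values are not transferable
  across distance definitions, and at desk scale the posterior
  probabilities of closely competing models (e.g. 11 vs 12) are not
  expected to reproduce analyses run with 10⁷–10⁸-state chains on the
  original datasets.
- The dangling-end treatment is a reconstruction (see above); absolute
  K̄_τ values inherit ~±20% interpretation uncertainty.
- k_rel and k_bind are entangled through K_D (only their ratio and one rate
  enter); A and ΔG_τ‡ are entangled by construction.
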