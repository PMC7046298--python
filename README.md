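# ratchetabc

Bayesian comparison of stochastic Brownian-ratchet models of transcription
elongation, for single-molecule force–velocity data.

RNA polymerase adds one nucleotide per cycle of (1) forward translocation,
(2) NTP binding, (3) catalysis. Single-molecule optical-trapping experiments
measure the pause-free elongation velocity as a function of applied force
*F* and NTP concentration, and different published models disagree about
which of the first two steps may be treated as a fast partial equilibrium
and which energetic parameters are needed. This package implements a
hierarchical family of 12 nested sequence-dependent elongation models and
the machinery to compare them against data:

- **Energetics** — the standard Gibbs basepairing energy of a transcription
  elongation complex state *S(l, t)* (mRNA length *l*, translocation register
  *t* ∈ {0, 1}) is the sum of nearest-neighbour doublet energies of the
  closed dsDNA flanking the transcription bubble (SantaLucia DNA/DNA), of
  the 9-bp DNA/mRNA hybrid (Sugimoto DNA/RNA), and a dangling-end term at
  the hybrid terminus, all in units of k_BT at 310 K.
- **Kinetics** — transition-state theory gives the sequence-dependent
  translocation rates

  k_fwd(l) = A·exp(−(ΔG‡(l) − ΔG_pre(l) − F·δ₁/k_BT)),
  k_bck(l) = A·exp(−(ΔG‡(l) − (ΔG_post(l) + ΔG_τ1) + F·(δ−δ₁)/k_BT)),

  with A = 10⁶ s⁻¹, δ = 3.4 Å, barrier ΔG‡(l) = ΔG_τ‡ + ΔG_TS(l), and up to
  six estimated parameters {k_cat, K_D, k_bind, ΔG_τ1, δ₁, ΔG_τ‡}. Treating
  translocation and/or NTP binding as a partial equilibrium coalesces states
  and removes parameters; when both are equilibrated the per-site velocity
  reduces to the classic closed form
  v = k_cat / (1 + (K_D/[NTP])·(1 + K_τ·e^(−Fδ/k_BT))).
- **Simulation** — Gillespie simulation of full-template transcription
  (numba-accelerated), plus an exact per-site mean-first-passage oracle.
- **Inference** — MCMC-ABC over the joint space of (model indicator,
  parameters): a proposal is accepted only if the Pearson-type distance
  X² = Σ(v_sim − v_obs)²/v_obs between simulated and observed velocities is
  ≤ ε and a Metropolis–Hastings draw on the priors accepts. Model moves walk
  the single-parameter-difference network between the 12 models.
- **Diagnostics** — ESS, classic Gelman–Rubin R̂, highest-posterior-density
  intervals and geometric-median point estimates, reported per model of the
  95% credible set.
- **Synthetic data** — templates and force–velocity–[NTP] datasets with
  known ground truth, emulating three published experimental designs.

## Worked example

Simulate a synthetic dataset from model 11 and fit it:

```sh
ratchetabc synth --design abbondanzieri-like --model 11 \
    --params params.yaml --length 500 --seed 3 --out dataset.tsv
ratchetabc infer --data dataset.tsv --fasta template.fasta \
    --enzyme-profile rnap --epsilon 2.5 --chains 2 --length 20000 \
    --seed 1 --out-trace trace.tsv
ratchetabc diagnose --trace trace.tsv --out report.json
```

The same pipeline is driven as a scripted analysis under `analysis/`:

```sh
python analysis/01_energy_landscape.py   # per-site energetics, K̄_τ
python analysis/02_force_velocity.py     # stochastic vs exact velocities
python analysis/03_generate_datasets.py  # synthetic observed datasets
python analysis/04_abc_recovery.py       # scaled-down ABC recovery run
python analysis/05_posterior_summaries.py
```

`analysis/01_energy_landscape.py` prints, for a 4 kb GC-matched synthetic
coding sequence:

```
template synthetic-rpoB-like: 4016 sites
mean forward-translocation basepairing barrier: 3.95 kBT (sd 1.24)
basepairing alone favours the pretranslocated state by 1.65 kBT on average (mean ln Ktau at dG_t1=0)
rnap: dG_t1 = -2.0 kBT -> sequence-averaged Ktau = 0.706 (posttranslocated favoured)
polii: dG_t1 = -4.6 kBT -> sequence-averaged Ktau = 0.052 (posttranslocated favoured)
t7: dG_t1 = -4.0 kBT -> sequence-averaged Ktau = 0.096 (posttranslocated favoured)
```

i.e. basepairing alone favours the pretranslocated register (losing a hybrid
basepair costs energy), but the inferred protein bias ΔG_τ1 < 0 overrides
it, so all three polymerases preferentially occupy the posttranslocated
state (K̄_τ < 1). `analysis/04_abc_recovery.py` then shows that a 2-chain ×
2·10⁴-state ABC run on a 12-cell, 5%-noise dataset places the generating
model in the 95% credible set and recovers k_cat inside its 95% HPD
interval.

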