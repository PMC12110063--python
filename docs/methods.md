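# Methods

## Model overview

The package simulates focused-attention meditation as a three-level
discrete-time dynamical system (1 timestep ≡ 1 second):

1. **Thoughtseed level.** Five attentional agents carry activations
   α_i(t) ∈ [0, 1].  During training they relax toward state-conditioned
   targets with momentum γ; during simulation they follow a
   Wilson–Cowan-style competition driven by a signed interaction network,
   a state bias, and meta-awareness coupling, with per-run responsiveness
   r_i.
2. **State level.**  Four meditation states act as attractor regimes.
   Each state assigns primary/secondary attractor roles to thoughtseeds:
   breath_control → {breath_focus} + {equanimity}; mind_wandering →
   {pain_discomfort, pending_tasks}; meta_awareness → {self_reflection};
   redirect_breath → {equanimity, breath_focus}.
3. **Meta-cognitive level.**  A scalar μ(t) follows a five-branch
   state-dependent rule (floors/caps 0.55–0.9 plus noise) and feeds back
   into thoughtseed targets.

## Key parameters

| parameter | novice | expert | units / notes |
|---|---|---|---|
| activation noise σ | 0.08 | 0.04 | std of η(t), Gaussian (uniform ±σ available via `noise_law`) |
| meta-awareness noise | 0.03 | 0.03 | std of ε(t) |
| responsiveness r_i | U(0.6, 0.7) | U(0.7, 0.8) | drawn once per simulation run |
| momentum γ | 0.1 | 0.1 | the 90/10 blend |
| distraction spike prob | 0.10 | 0.03 | per distraction per step; amplitude U(0.2, 0.4) |
| mind-wandering dwell | N(25, 5²) | N(10, 2²) | per-episode requirement, clipped to [3, mean+2·sd] |
| other-state dwell | N(10, 3²) | N(10, 3²) | same clipping |
| transition threshold θ | 0.45 | 0.45 | per candidate state |
| suppression / enhancement | 0.05 / 1.2 | — | mind-wandering modulation when μ < 0.6 |
| ω_base | 1.0 | 1.0 | weight scale; 1.0 keeps weights directly interpretable |
| τ (network gain) | 1.0 | 1.0 | multiplies both the interaction sum and the state bias |
| β_i (μ coupling) | +0.1 bf, +0.3 eq/sr, −0.2 distractions | same | signs follow the monitoring role of μ |

## Transition mechanics

Each episode samples a dwell requirement D ~ round(N(mean, sd)) clipped to
[3, mean + 2·sd].  Below D the state is held.  From D onward the system
either transitions **naturally** — some other state's attractor evidence
φ_j (mean activation over its primary+secondary attractors) exceeds θ
*and strictly exceeds the current state's own attractor support* — or is
**forced**: the next state is sampled from the transition-matrix row
(reference matrix in training; learned matrix in simulation, falling back
to the reference for rows never exited during training), renormalized over
off-diagonal entries.  Ties in the natural argmax resolve to the earlier
state in canonical order.

Two points here were genuinely open design territory:

- *Basin-takeover condition.*  A plain "φ_j > θ" rule degenerates:
  breath_control and redirect_breath have identical attractor sets, so
  each would permanently trigger transitions into the other, and the
  simulator's meta-awareness coupling raises equanimity/self_reflection
  baselines above θ in most states.  Requiring the candidate's evidence to
  strictly exceed the current basin's support makes "natural" mean an
  actual takeover; since identical attractor sets give numerically equal
  φ, the strict inequality can never fire between breath_control and
  redirect_breath, which are instead linked through the transition
  matrices — matching the canonical meditation cycle.
- *Per-episode dwell sampling.*  Dwell limits act through a sampled
  requirement rather than a fixed cap, so episode durations concentrate
  around the profile means (novice mind-wandering 20–30 s, expert
  8–12 s) instead of piling at mean + 2·sd.  No episode can exceed
  mean + 2·sd (+1 step of bookkeeping).

## Reference transition matrices

The packaged novice/expert matrices carry per-entry provenance.
`printed` entries are the published empirical values; `filled` entries
complete each row: with exactly two unspecified targets the remaining
mass splits equally; with three, it goes to mind_wandering when
unspecified (the default lapse path), otherwise it splits equally among
the unspecified targets.  Tests and acceptance checks assert only
`printed` entries.

## Network extraction choices

- Eq-form ambiguity: the pairwise Granger statistic is computed from one
  pooled regression with L = 5 lags (restricted vs unrestricted), not L
  separate per-lag fits; G is the aggregate relative RSS reduction and the
  p-value comes from the likelihood-ratio statistic n·log(RSS_r/RSS_u)
  against χ²(L).  This matches the `lrtest` variant of standard Granger
  implementations (cross-checked against statsmodels in the tests).
- "Strength inversely proportional to p" is realized as the linear map
  0.7·(1 − p/0.05) for p < 0.05 (a −log10 alternative is available via
  the `calibration` config switch).  The consequence is that the weak-edge
  filter (< 0.1) removes pairs with p > 0.0429.
- Edge sign: sign of the summed unrestricted-model cross-lag
  coefficients.
- Final scaling into (−0.6, 0.6) is a global max-abs rescale, preserving
  weight ratios, not per-entry clipping.

## Synthetic-data considerations

The package generates all of its own data; the training runs *are* the
study conditions (200 timesteps, 20-seed ensembles for stochastic
contrasts — ensemble size chosen to bound Monte-Carlo error at desk
scale; type-I-error and edge-recovery checks use 200 and 50 replicates
respectively, n = 300–500 samples).  What passing tests show is that the
coded dynamics reproduce the intended qualitative physiology-inspired
contrasts (episode-length and meta-awareness orderings, activation bands,
transition-cycle structure) and that the statistical machinery is
calibrated on data satisfying its own assumptions (linear VAR with
Gaussian noise).  They say nothing about real meditators: activations are
not fit to EEG/fMRI or experience-sampling data, and the reference
matrices are aggregate literature values, not subject-level estimates.

## Numerical and bookkeeping details

- All stochastic paths flow through one `numpy.random.Generator` per run;
  identical seeds give bit-identical traces.  The CLI expands a global
  seed into per-stage child seeds via `SeedSequence.spawn`.
- Activations clip to [0, 1] after every update; learned weights clip to
  [0, 1.1·ω_base].
- Meta-awareness branch constants are stored pre-resolved (0.55, 1.0,
  0.85, 0.8, 0.9) so zero-noise evaluations are exact in floating point.
- Winner-takes-all ties resolve to the earliest thoughtseed in canonical
  order (breath_focus first).
- The trace records the post-update state at each step; t = 0 is the
  initial condition (breath_control, α = clipped weight row).
- Episode statistics count the final right-censored episode as complete
  by default (`drop_censored` toggles exclusion); zero-variance series in
  correlation estimates are zeroed with a warning; fully degenerate
  transition rows fall back to a uniform off-diagonal draw.

## Known limitations

- Expert 200-step simulations visit all four states in ≈90% of seeds;
  novice runs often miss meta_awareness or redirect_breath because long
  mind-wandering episodes leave only ~8 episodes per run — a direct
  consequence of the novice dwell distribution, not a bug.
- The novice/expert difference in breath_focus activation during
  breath_control manifests as a variability difference (novices fluctuate
  more) rather than a mean difference: without the (unavailable)
  inter-thoughtseed feedback during training, distraction intrusions do
  not directly depress breath_focus, so both levels sit in a similar high
  band.
- The mind-wandering/non-distraction meta-awareness branch evaluates to
  ≈1.0, above the nominal expert band (0.75–0.9); the formula is
  implemented as specified and reports show observed simulated ranges.
- Discrete time only; no continuous-time integration.  Two expertise
  levels only; no individual-meditator fitting.
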