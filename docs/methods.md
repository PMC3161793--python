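# Methods

`avpercept` models audiovisual spatial localization as a hybrid Bayesian
network over six variables: the task / primary sensory modality `S`
(0 acoustic, 1 visual), the mode of presentation `M` (0 unisensory,
1 bisensory), the primary and secondary stimulus positions `XP` and `XS`
(degrees; `XS` carries a sentinel category for unimodal trials), the
normalized localization response `X̂` and the decision time `T` (latency
from stimulus onset to movement onset — not a reaction time, as responses
are unspeeded). The package covers the full workflow: simulating the
behavioral study, extracting the behavioral variables, eliciting the
network structure from information measures, fitting the conditional
distributions by maximum likelihood, and evaluating MAP inference of both
outputs under leave-one-subject-out cross-validation.

## Synthetic study and its calibration

No public dataset exists for this protocol, so the package ships a
generator that emulates it: per subject and task, 450 trials — 75
unimodal (15 per primary position in {−10,−5,0,5,10} deg), 75 spatially
coincident bimodal, and 300 non-coincident bimodal (secondary offsets
±5, ±10 deg; secondary positions thus span [−20, 20] deg). Responses are
pointer angles from a 40-deg neutral stop, clipped to the ±40-deg
physical range. With the default 10 subjects this yields 9000 trials
(4500 per task).

Percept model (per trial): in the visual task and on unimodal trials the
localization is `XP + bias + noise` (segregation); on bimodal acoustic
trials it is `XP + w·(XS − XP) + bias + noise` (visual capture), with a
subject-specific fusion weight `w` and Gaussian noise whose SD depends on
task and mode. Decision times are log-normal: `log T ~ N(μ[S,M] + b_subj +
δ_ecc·1[S=0, |XS|=20], σ_logT)`.

Calibration of the defaults:

- Localization noise SDs are set to the observed per-condition
  dispersions of the emulated study: 7.5 deg (acoustic unisensory),
  2.8 deg (visual unisensory), 5.8 deg (acoustic bisensory), 3.1 deg
  (visual bisensory, splitting the reported 3.2 coincident / 3.0
  non-coincident values).
- The fusion weight solves `w²·62.5 + 5.8² = 9.5²` — 62.5 being the
  variance of the equiprobable non-coincident offsets — so that pooled
  non-coincident acoustic responses reproduce the 9.5-deg SD. This gives
  `w ≈ 0.952`; a Monte-Carlo check over simulated non-coincident trials
  confirms the pooled SD.
- Decision-time medians default to 0.95 / 0.80 s (acoustic uni/bi) and
  0.75 / 0.62 s (visual uni/bi), encoding the two robust orderings
  (acoustic slower than visual, unisensory slower than bisensory); the
  source study prints only F statistics, so the magnitudes are free
  parameters of the simulator.
- The eccentricity penalty `δ_ecc = 0.25` (log-units, ≈ 28% longer times
  at the ±20-deg secondary positions in the acoustic task) encodes the
  reported concentration of the secondary-position effect at maximal
  eccentricity. Its size is chosen so that the dependence is detectable
  by the elicitation procedure at the study's sample size: a much weaker
  effect would sit below the null thresholds and the true `T–XS` edge
  would be unrecoverable in principle.
- The dispersion pair (`σ_logT`, between-subject time offset SD) is
  fixed by the closed-form cross-validated-R² expectation oracle in
  `avpercept.evaluate` (see below): solving for expected cell-level and
  collapsed decision-time R² of 0.63 and 0.92 gives `σ_logT ≈ 0.417`
  and an essentially zero subject offset (default 0.01). The oracle
  treats observed cell summaries as truth plus sampling noise and
  includes a second-order (Jensen) correction for the finite number of
  cells entering each R²; a 20-seed simulation verifies it to ±0.03.
- The primary-position effect on decision time is zero by default (the
  source analysis localized it to a single maximally eccentric target
  and excluded a `T–XP` edge); per-subject sensorimotor bias (SD 3 deg)
  is shared across tasks, consistent with the observation that the bias
  is a subject property, not a task property.
- Pointer trajectories are minimum-jerk reaches with condition-
  independent movement duration (movement time showed no condition
  effects), sampled at 100 Hz; they exist so that onset/end detection
  can be exercised end-to-end and are not generated by default.

What the generator deliberately omits: attention and vigilance dynamics,
sequential (trial-order) effects, subject-by-condition interactions
beyond the global time offset, eye movements, and any EEG-level
structure. Passing tests therefore certify the pipeline's correctness
and its behavior under the stated statistical structure, not the full
richness of real pointing data.

## Preprocessing

Movement onset is the first sample whose pointer speed exceeds
1.5 deg/s; movement end the first time after the speed peak at which
speed stays below 1.5 deg/s for a 0.2-s window. Velocity is estimated by
centered differences after a 3-sample moving average (the cutoff is
prescribed; the differentiation scheme is ours). Decision time is onset
minus stimulus time; the endpoint is the median of the hold phase. Note
that for a smooth reach the threshold crossing lags the true movement
start by `√(v_th·T/(30·|d|))·T` (≈ 40 ms for typical amplitudes), so
detected decision times carry that small systematic offset.

Localizations are normalized per subject by subtracting the mean of that
subject's unisensory responses pooled over both tasks; since the design
positions average to zero this removes the sensorimotor bias estimate.
Condition summaries report per-cell means and SDs plus across-subject
averages of per-subject SDs (the dispersion statistic used for
calibration checks; both poolings are computed).

## Discretization and information measures

Histograms use fixed schemes: `XP` 5 width-5 bins on the design grid;
`XS` 9 width-5 bins on [−20, 20] plus a sentinel bin; `X̂` 13 width-5
bins centered on −30…30 plus two open-ended boundary bins beyond
±32.5 deg where data are sparse (±32.5 itself belongs to the inner
bins); `S`, `M` two bins; `T` width-0.2 bins centered on 0.1 + 0.2k up
to the empirical 99th percentile, plus one overflow bin (the grid origin
and extent are configuration defaults; the source leaves them open).
Bins are half-open `[a, b)` with the last regular bin closed. All pmfs
are maximum-likelihood plug-in estimates; entropies are in bits
(normalized quantities are base-invariant).

Dependence is measured by mutual information normalized by the joint
entropy, `I(X;Y)/H(X,Y) ∈ [0,1]`, comparable across variable pairs, and
by conditional MI normalized by `H(X,Y|Z)` (the conditional
normalization is our choice, making thresholds comparable across
conditioning sets).

## Structure elicitation

1. **Skeleton.** Every pair is tested against a null threshold built
   from artificial independent variables uniform on each variable's
   bins: 100 seeded replicates at the matched sample size, 0.95
   quantile. This absorbs the finite-sample bias of the plug-in
   estimator. An edge is kept iff the normalized MI exceeds its
   pair-specific threshold.
2. **CMI pruning.** Edges are processed in ascending order of marginal
   MI. Conditioners are single *input* variables (`S`, `M`, `XP`, `XS`)
   adjacent to an endpoint. Conditioning on the finely discretized
   outputs is not admissible: with 15 response bins the plug-in CMI's
   bias under the null exceeds realistic signals at n = 9000, so such
   tests are uninformative. CMI null thresholds use conditional
   permutations of the data (X shuffled within strata of Z; 100
   replicates, 0.99 quantile) rather than the uniform null: permutation
   preserves the occupied-cell structure, so the null carries exactly
   the estimator's bias on this data, whereas a uniform null's bias can
   differ several-fold from the real one and miscalibrates the test in
   both directions. A conditioner that is a deterministic function of an
   endpoint (here: the mode, which the secondary-position variable
   determines exactly) is skipped — such a test cannot distinguish a
   direct link from one mediated by the deterministic summary; the
   redundancy resolves the other way (the summary's own edge is removed
   given the richer variable, reproducing the retention of `T–XS` over
   `T–M`). For the single output–output pair (`X̂`, `T`) the joint input
   configuration is additionally tested as one compound conditioner:
   the scientific hypothesis is precisely that percept and decision time
   are independent given the whole stimulus context, and no single
   variable can certify it.
3. **Orientation.** Colliders `X → Z ← Y` are declared for non-adjacent
   pairs whose recorded separating sets never contain `Z`; all passing
   independence tests count as separating sets (conservative collider
   detection), and an extra screen tests non-adjacent pairs against
   their common neighbors so that a marginally-undetectable chain is
   not mistaken for a collider. Triples whose collider status is
   unidentifiable because of a deterministic relation are left
   unoriented. Orientations propagate by the standard Meek rules.
   Optionally (and by default in the full pipeline) the stimulus
   variables are declared exogenous: no arrow may point from a response
   variable into an experimenter-controlled stimulus. Conflicting
   orientation demands are recorded on the returned PDAG, never
   silently resolved.
4. **Context-specific independence.** For a binary context variable the
   elicitation re-runs on each context subset with the context column
   dropped, yielding a multinet of local networks. On default data the
   acoustic-context network links the percept to both stimulus
   positions (fusion) while the visual-context network drops the
   `X̂–XS` edge (segregation); in the unisensory context `XS` is
   constant and isolated while `T` remains task-dependent.

On the default calibration the elicited PDAG has directed edges
`XP→X̂`, `XS→X̂`, `S→X̂`, `S→T`, `XS→T` and undirected `M–XS`, `XP–XS`.
The `XP–XS` edge is real and by design: the protocol places the
secondary stimulus at an offset from the primary, so the two positions
are statistically dependent; it is an experimental-design edge, not a
perceptual one. The factorization resolves the undirected design edges
as `M→XS` and `XP→XS`, giving

    P(S) P(M) P(XP) P(XS|M,XP) P(X̂|S,XP,XS) P(T|S,XS).

## Model fit and MAP inference

Discrete factors are empirical multinomials; `X̂` given each
`(S, XP-bin, XS-bin)` is Gaussian (sample mean and SD of the normalized
response); `T` given `(S, XS-bin)` is log-normal (sample mean and SD of
log decision time — the location is definitionally the mean log). No
smoothing or priors are applied; a parent configuration with fewer than
two observations is flagged and inference on it refuses rather than
backing off. The full factorial design guarantees 15 observations per
cell per subject, so flagged cells do not occur in the standard
workflow.

MAP queries: the percept MAP is the Gaussian mode, i.e. the fitted cell
mean. For decision time two conventions are implemented: the mode of
the log-normal density in seconds, `exp(μ − σ²)`, and the mode on the
log scale, `exp(μ)` (equivalently the model median).

## Evaluation

`crossvalidate` performs exact leave-one-subject-out cross-validation
(with 10 subjects, the exhaustive deterministic version of picking 9
training subjects at random 10 times). Observations are the held-out
subject's per-condition summaries at `(task, XP, XS)` resolution — 60
cells per fold; predictions are the fold model's MAP values (the
decision-time prediction depends on `(task, XS)` only, as the model
prescribes). R² is computed per primary position, pooling both tasks
(12 cells each), and averaged over positions and folds; this
per-position averaging is the headline statistic, and the per-position
table is reported alongside (an all-cells pooled R² is also computed
for reference; it is systematically higher because the between-position
variance inflates the denominator).

Decision-time agreement is assessed on the scale where the time model
is Gaussian: predictions `exp(μ̂)` against held-out geometric cell means
(exp of the mean log). Pairing the seconds-scale log-normal mode with
arithmetic means instead introduces a systematic multiplicative bias of
`exp(1.5σ²)` between prediction and observation — with any dispersion
large enough to produce realistic cell-level scatter this bias alone
would push the collapsed-mode R² far below its observed value, so the
matched log-scale comparison is the only internally consistent choice;
the arithmetic-mean and seconds-mode columns are still computed and
reported. The collapsed-mode analysis regroups decision-time cells into
2 tasks × 3 modes of presentation (unisensory, bisensory coincident,
bisensory non-coincident), refits the time factor per group, and scores
the six group means per fold.

The closed-form expectation oracle for these R²s (used for calibration,
and exposed as `expected_r2_oracle`) models each observed summary as the
true condition value plus sampling noise and each prediction as a
training-set estimate, with a common per-fold offset; the expectation of
`1 − SS_res/SS_tot` is corrected to second order for the variance of
`SS_tot` across replicates. Defaults reproduce percept R² ≈ 0.90,
cell-level time R² ≈ 0.61 and collapsed time R² ≈ 0.91 in 20-seed
simulation.

## Numerical and interface choices

- All randomness flows through `numpy` Generators; a single dataset
  seed fans out to independent substreams for profiles, responses, and
  trial shuffling, and the threshold policy carries its own seed, so
  every stage is independently reproducible.
- Degenerate inputs: zero-entropy variables give normalized MI 0;
  empty context subsets and subjects without unisensory trials raise;
  R² of fewer than two cells raises; negative R² is reported as-is.
- Trial tables are plain CSV with the unimodal sentinel serialized as
  the token `NA_UNIMODAL`; graphs export as edge-list CSV and DOT;
  fitted models and evaluation reports as JSON text.
- The command-line interface (`avpercept simulate|preprocess|structure|
  fit|evaluate|all`) is a thin orchestration layer over the library and
  writes a run log (seed, config, version) beside every artifact.

## Known limitations

- Structure learning uses single conditioners (plus the one compound
  context test); independences requiring larger separating sets are
  found only through that compound test. The conservative collider
  rules leave deterministically-confounded triples unoriented rather
  than guessing.
- The uniform-null pairwise thresholds are slightly conservative for
  variables whose histograms occupy fewer cells than the uniform null
  assumes; weak true edges near threshold (normalized MI of order
  10⁻³) are detected with high but not certain probability, which is
  why recovery guarantees are stated as rates over seeded replicates.
- The decision-time R² depends on within-cell dispersion through the
  15-trials-per-cell observation noise; the oracle makes that
  dependence explicit, and conclusions about real data would require
  recalibrating the dispersion to that data.
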