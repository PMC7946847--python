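# Methods

## The task and its measurement procedure

A session is a stratified factorial design: every (meridian, separation)
cell of the 4 × 8 grid occurs exactly `reps_per_cell` (default 9) times —
288 trials. Randomisation affects only trial order, the per-trial
cue-validity draw, invalid-cue placement and stimulus contents; two
sessions with different seeds therefore have identical cell-count tables.
Each stimulus group has four elements; the number of light-gray triangles
(the target count) is drawn uniformly from {0,…,4} (20 % each) and the
remaining elements uniformly from the non-target alphabet (3 types under
`basic4`, 5 under `high6`). Breaks and practice trials have no
computational effect and are not modelled.

Cue validity is an independent Bernoulli(cue_valid_fraction) draw per
trial (long-run 80 % in the modified task), not a fixed per-session
quota: 0.8 × 288 is non-integral, so any exact split would be arbitrary;
the independent-draw choice is documented so a stratified allocator can
be swapped in. On invalid trials both cues are placed symmetrically on
one uniformly chosen non-target meridian at one uniformly chosen grid
separation, mirroring the valid-cue geometry.

`soa_ms` denotes the blank interval between cue offset and target onset
(the operational usage for the 200-ms basic task); the onset-to-onset
asynchrony is `soa_ms + 200 ms` of cue duration and is exposed as
`cue_onset_asynchrony_ms`.

Scoring: a trial is pair-correct iff both reported counts are right. Per
meridian *class* (the two diagonals pooled by trial union: 18 trials per
separation vs 9) accuracy is an exact rational n_correct/n_trials. The
threshold scan ascends the grid and stops at the first separation with
accuracy `< 0.75` (exactly 0.75 passes — with 9 trials the effective pass
mark is 7/9); the threshold is the previous separation. Later recoveries
above criterion are ignored (the procedure is sequential), and a missing
grid point is an error rather than a silent skip. If the smallest
separation fails the threshold is 0° (`floor` flag); if nothing fails it
is the largest tested separation (`ceiling` flag). Censored values enter
the ANOVA numerically (0/45) with flag counts reported; no censored-data
likelihood is attempted.

Window geometry: vertices at radius threshold/2 along the eight
half-meridians (0°, 45°, …, 315°, counterclockwise from the positive
horizontal axis); polygon area by the shoelace formula, which for
45°-spaced vertices equals ½·sin 45°·Σ rᵢrᵢ₊₁ (equal thresholds give a
regular octagon of area 2√2·R²). The secondary ellipse area uses the
endpoint radii as semi-axes, π·(H/2)·(V/2), and the aspect ratio is H/V.

## Observer models

`attention_field` (default): per-stimulus correct-report probability

  q(s) = γ + (1 − γ)·Λ(s),  Λ(s) = 1/(1 + exp((s − E\*)/τ)),

with the effective extent E\* = E_m · κ_inv^[invalid] · g(SOA) ·
ρ_c^[high6] and g(SOA) = min(1, f₀ + (1 − f₀)·SOA/T_full). The two
stimulus groups are identified independently (no capacity-sharing term —
a documented simplification), so the pair probability is q². q is the
*unconditional* correct-report probability: the simulator reports the
true count with identification probability (5q − 1)/4 (clamped at 0) and
guesses uniformly from the five responses otherwise, making the realised
correct rate exactly q, the floor q = γ = 1/5 pure uniform guessing, and
the pair floor γ² = 0.04. The 75 % point is then the closed form
s\* = E\* + τ·ln((1 − Λ\*)/Λ\*), Λ\* = (√0.75 − γ)/(1 − γ), i.e.
s\* = E\* − 1.604·τ for the defaults — below the midpoint E\*, as it must
be since the criterion (0.75) exceeds the midpoint pair accuracy (0.36).

`spotlight_shift`: a movable narrow beam processes the first group with
q(s); shifting costs a + b·s ms (defaults 50 ms + 10 ms/°), and when that
exceeds the 300-ms exposure the second group falls to the guessing floor.
This reproduces the qualitative short-SOA penalty mechanistically and has
no closed-form threshold; it is provided as an alternative generative
account, not as the default.

### Parameter defaults and where they come from

| parameter | default | role |
| --- | --- | --- |
| E_h, E_v, E_d | 42°, 32°, 34° | meridian extents (diagonals share one) |
| τ | 3° | logistic scale |
| γ | 0.2 | guessing floor = 1/response alphabet |
| κ_inv | 0.88 | invalid-cue extent multiplier |
| T_full, f₀ | 200 ms, 0.62 | SOA ramp (g(50 ms) ≈ 0.71) |
| ρ_c | 0.75 | high-complexity multiplier |
| population SD | 4° per extent, truncated to [15°, 55°] | between-subject spread |

The extents and population SD were chosen once so that the analytic
thresholds s\* = E − 1.604τ of an average valid-condition observer, snapped
to the 5° grid, give a simulated group mean/SD near 29 ± 4° across
meridian classes — the scale of reported human AW measurements — and the
modifiers so that the qualitative effect ordering holds (invalid < valid;
50 ms ≪ 200 ≈ 350 ms; high6 < basic4) with percent reductions in the tens.
These are simulator conditions, not fitted estimates; the package fits
nothing to human data.

## Statistical battery

Two-way fully-within-subject ANOVA by direct sum-of-squares partition
(subject, A, B, A×B, and the three subject-interaction error strata);
each effect is tested against its own error stratum, so a balanced
n-subject 2×3 design has df (1, n−1) and (2, 2(n−1)). Partial
η² = SS_effect/(SS_effect + SS_error). For any effect with ≥ 2 numerator
df, the data are projected onto orthonormal effect contrasts (Kronecker
products for the interaction); Mauchly's W = det(S)/(tr(S)/k)^k with the
standard χ² scaling, and ε̂ = tr(S)²/(k·tr(S²)) from the contrast
covariance S. Greenhouse–Geisser-corrected df/p are reported whenever
Mauchly rejects at 0.05 (the conventional reporting rule) and emitted
unconditionally alongside for comparison. Implementation is verified
against a deliberately naive loop-based SS oracle (1e-10 agreement) and
cross-checked against pingouin. Pairwise follow-ups are paired t-tests on
subject-level marginal means with adjusted α = 0.05/k (0.017 for three
levels). Percent reduction is 100·(mean_ref − mean_cmp)/mean_ref.

## Monte-Carlo studies and problem sizes

Large calibration studies (type-I error of the condition main effect over
1,000 null cohorts of 20 subjects; anisotropy-signature rates over 100
cohorts) use a distributionally exact shortcut: within a design cell all
trials are iid Bernoulli at the model's pair-correct probability, so the
per-cell correct count is drawn directly as a Binomial (with a Binomial
split of the cell into valid/invalid trials under cue mixtures). The
shortcut is equivalence-tested against the per-trial simulator. Parameter
recovery uses the full per-trial path over 200 sessions of the default
observer; design-fidelity checks use 10⁵ stimulus draws and 100 sessions.
These sizes keep every study's Monte-Carlo error well below the bands it
is compared against.

## Measurement properties worth knowing

- **Downward bias of the first-failure rule.** With 9 trials per point
  the pass mark is effectively 7/9 ≈ 0.778 > 0.75, and a single binomial
  dip below criterion at any point under s\* truncates the scan, so
  estimated thresholds sit mostly at or one grid step below the analytic
  75 % point. For the default observer the exact distribution puts ≈ 92 %
  of estimates within one 5° step of s\* (≈ 89 % for the 9-trial
  horizontal/vertical profiles, ≈ 99 % for the 18-trial pooled diagonal).
  Observers whose s\* falls just past a grid point fare worst; averaged
  over a population of extents the within-one-step rate drops to ≈ 85 %.
- **Sparse invalid-cue cells.** In the modified task only ~20 % of the 9
  trials per raw cell are invalid, so per-validity thresholds rest on 1–4
  trials per point; their effective pass mark is harsher (e.g. 2/2) and
  invalid-condition thresholds are biased low. This is a property of the
  design being simulated, not of the implementation.
- **Type-I calibration.** Under identical observers across two task
  versions the condition main effect rejects at ≈ 0.05 despite the
  discrete 5°-grid response scale.

## What the synthetic data do and do not show

The generator reproduces the structure the analysis assumes: logistic
accuracy decay with separation, horizontal > vertical anisotropy,
multiplicative condition effects, between-subject extent variability, and
uniform guessing. It does not model eye movements, visual short-term
memory limits, masking, lapses/attentional dropouts, learning or fatigue
across the session, or capacity sharing between the two stimulus groups
— so green tests certify the *pipeline* (design balance, scoring rule,
ANOVA correctness, recovery behaviour under the stated model), not the
behaviour of human observers.

## Numerical conventions

Logistic arguments are clipped at ±700 before exponentiation; thresholds
and grid separations are compared exactly (the grid is float-valued but
5°-spaced, so no tolerance is needed); a singular contrast covariance
(constant data) makes Mauchly's W = 0 and is reported as such rather than
extrapolated; seeds derive from one master `SeedSequence` with separate
child streams for trial order, validity draws, stimulus contents,
invalid-cue placement, population draws and response noise, so each
component is independently reproducible.
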