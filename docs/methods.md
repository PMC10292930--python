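# Methods

## The model

A reading scanpath over a short multi-line text is reduced to a categorical
time series: for each fixation `t` the outgoing saccade is coded by the
signed change in fixated word index into one of five **Read modes** —
`Bwd-` (regression of more than one word), `Bwd` (one word back), `Rfx`
(refixation), `Fwd` (one word forward), `Fwd+` (progression of more than
one word). This coding is invariant to screen layout: it depends on word
order only.

The sequence `X_1..X_T` is modelled by a **hidden semi-Markov chain**
(HSMC) with `K` states. A state `k` is entered, occupied for a number of
fixations drawn from a state-specific **sojourn law** `d_k`, emits one Read
mode per fixation from a categorical distribution `b_k`, and is left
through a transition matrix `A` with zero diagonal (a transition always
changes the state). Sojourn laws are *shifted* — support starting at one
fixation — and parametric:

- shifted binomial, `D = 1 + Bin(n, p)`, mean `1 + np`;
- shifted negative binomial, `D = 1 + NB(r, p)` (number-of-failures
  convention), mean `1 + r(1-p)/p`;
- absorbing: the state is never left (`P(D >= d) = 1` for all `d`).

The final sojourn of every sequence is **right-censored**: the trial ends
by the reader's decision, not by a state exit, so the *survival function*
of the sojourn law replaces its mass function for the last run. The
likelihood of a sequence sums, over all segmentations into state runs, the
products initial probability x sojourn masses x transitions x emissions,
with the last run contributing survival.

States linked by short, near-systematic alternation cycles (mutual
transition probabilities above a threshold, mean sojourns below a bound)
are merged into **phases** — the units interpreted as reading strategies:
normal reading (NR), information search (IS), fast reading (FR), slow
confirmation (SC).

## Exact inference by countdown augmentation

All smoothing and likelihood computations run on the *countdown*
augmentation: the augmented state is `(state, remaining occupancy)`, with
remaining occupancy capped at the sequence length `T` and the tail mass
`P(D >= T)` lumped into the cap. A path whose countdown is still positive
at `T` is exactly a right-censored final sojourn, so this augmentation
reproduces the censored likelihood **exactly** — there is no
duration-truncation error anywhere in the package. Forward/backward passes
are scaled per step and compiled (numba); the E-step yields smoothed state
marginals, expected initial/transition/emission counts, and expected
completed and censored sojourn counts per duration. Restoration uses an
explicit-duration Viterbi whose final run is scored with the survival
function; ties resolve to the lower state index of the final run, then the
shorter duration, then the lower preceding state working backwards.

Everything above is verified in the test suite against brute-force
enumeration over all segmentations for `T <= 8`, `K <= 3`, to 1e-10.

## Estimation

Parameters are estimated by EM (an ECM variant):

- **E step**: exact expected counts from the countdown forward/backward.
- **M step**: closed-form updates for initial, transition and emission
  probabilities; sojourn laws are re-fit per state by weighted maximum
  likelihood over completed-sojourn counts (log pmf terms) and censored
  counts (log survival terms), with moment-matched starts and
  Nelder-Mead/bounded-scalar polish. The family itself is re-selected each
  M step among shifted binomial, shifted negative binomial and absorbing;
  "absorbing" is admissible only for a state with essentially no expected
  exits, where it maximizes the expected complete-data likelihood by
  construction. During exploratory passes only the negative binomial
  family is refit (cheaper; a valid generalized EM step).
- **Restarts**: short categorical sequences produce a heavily multimodal
  likelihood. Restarts therefore cycle through three data-anchored
  proposal families: (i) *alternation seeds* — two states biased toward a
  pair of symbols (pairs ordered by frequency product) with strong mutual
  transitions and near-1 mean sojourns, precisely the cycle regime the
  phase model targets; (ii) the same with a third state started as an
  *exact* two-symbol mixture of the pair — emission zeros are invariant
  under EM, so boundary-supported states must be proposed, they are never
  reached from the interior; (iii) *crude segmentations* — a random
  surjective symbol-to-state assignment hard-labels every fixation and its
  smoothed statistics seed the parameters. The best restart by
  log-likelihood after a short run is polished to convergence.
- **Structure consolidation**: interior EM only approaches boundary
  structure asymptotically, leaving phantom parameters (a transitory
  state's never-re-entered column at 1e-5, an absorbing state's exits at
  1e-6). After polishing, transition entries below 1e-3 are pruned to
  exact zeros, a state with negligible expected exits becomes absorbing,
  and EM re-runs briefly; the consolidated model is kept only if its
  likelihood is not worse. BIC's free-parameter count then reflects the
  structure the data support.

The per-iteration log-likelihood is asserted non-decreasing (tolerance
1e-6 relative, covering the numerical sojourn refits).

BIC is `-2 log L + d log N` with `N` the total number of fixations and
`d` = (K-1) initial probabilities + free off-diagonal transition entries
minus one constraint per non-absorbing row + 2 parameters per parametric
sojourn law + 4 emission probabilities per state. `select_states` scans a
K range and returns the BIC minimizer with the full table.

Default fitting settings: 10 restarts, 40 exploratory iterations each,
polish up to 500 iterations at relative tolerance 1e-7. A full K=1..7 scan
on 2000 sequences of mean length ~17 runs in roughly 6-8 minutes on one
CPU.

### Known estimation limits

Two quantities are weakly identified at the default study scale (2000
sequences, mean length ~17): the sojourn mean of the rare
information-search state (initial probability 0.01, a few hundred
completed sojourns) and that of the long transitory fast-reading state
(mean ~13 against trials of ~17 fixations, so mostly censored).
Maximum-likelihood estimates of these means started *at the generating
values* scatter by 10-20% across simulation seeds, and the likelihood
surface contains several optima within a few nats of each other whose IS
mean differs by a similar margin. The fitter reports the best-likelihood
solution it finds; no preference for solutions resembling any particular
parameter table is applied.

## Preprocessing

Fixations shorter than 80 ms or longer than 1000 ms and fixations outside
every line's vertical text band are removed; the trial-final fixation is
removed after its word has served to code the preceding saccade (it has no
outgoing saccade of its own). Scanpaths with fewer than four retained
fixations are dropped. Word assignment uses an asymmetric
word-identification span of 4 characters left and 8 right of the fixated
character (35 px high) on the fixated line: a candidate word must have at
least 1/3 of its beginning or 2/3 of its end inside the span
(character-level, implemented as `3*prefix >= len` / `3*suffix >= 2*len`);
among candidates the nearest non-stop word to the fixation centre wins,
ties toward the earlier word. A fixation whose span crosses a line break
only considers candidates on the fixated line. The character-to-pixel
mapping assumes fixed-width rendering when deriving the fixated character
from pixel coordinates.

Reading speed (words per minute) is computed at three scales: per saccade
(`(|crossed words| + 1) / (fixation + saccade time)`), per segment (newly
covered words over the segment's summed fixation and saccade durations),
and per phase (the union of words covered by all same-phase segments of a
text — each word counted once — over their summed durations). "Covered"
includes words crossed between consecutive fixated words, inclusive of the
landing word.

## Phase statistics

The participant x phase contingency table counts restored fixations.
Independence is tested by Pearson chi-square (`(rows-1)(cols-1)` df, no
continuity correction). Correspondence analysis decomposes the
standardized residual matrix `D_r^{-1/2}(P - rc')D_c^{-1/2}` by SVD; both
row and column clouds are reported in principal coordinates (symmetric
map), the sum of eigenvalues equals chi-square over the grand total by
construction, and a perfectly independent table yields zero axes. Phase
distributions per extended text type are fixation-weighted and
row-normalized. Mixed-model regressions on these tables are deliberately
out of scope; the tidy TSV-ready tables are their input.

## Semantics of phase transitions

Texts come in related (HR), moderately related (MR) and unrelated (UR)
types; an HR text containing a literal target-topic word is reclassified
HR+ and those words are its target words. Trigger words are detected from
a word-embedding table (standard whitespace-separated text format) by
cosine similarity to the topic vector (mean of the topic words' vectors):
HR takes the two closest words, both required above 0.3, otherwise the
text is excluded; HR+ takes the target word(s) plus the second-closest
word if it reaches 0.3; UR takes the two furthest; MR the closest and the
furthest. Stop words and words without embeddings are ineligible.

For each phase transition (first fixation of every restored segment after
the first) the distance in fixations to the closest *fixed* trigger word
is computed; a trigger word fixed several times contributes its first
fixation index, and scanpaths whose triggers are never fixed are dropped
and counted. Transition frequencies per integer distance are normalized by
the number of fixation boundaries at that distance (the "opportunity"
structure); distances whose opportunity count falls below max(5, 1% of all
boundaries) cannot support a frequency estimate and are excluded. Ordinary
least squares per (incoming phase x extended type) group gives the
regression lines; groups with too few transitions are flagged, not fitted.

Two permutation schemes assess whether transitions cluster near triggers
beyond what short scanpaths force: *constrained* re-draws each scanpath's
transition positions uniformly without replacement (preserving the number
of transitions and their incoming-phase labels), *free* additionally
permutes incoming-phase labels across the cohort. The headline statistic
is the pooled frequency-vs-distance OLS slope — the quantity the
regression lines interpret — with one-sided p-values toward negative
association (add-one corrected); it is insensitive to the label shuffle,
so the schemes differ through the phase-weighted statistic that is also
returned. Under the uncoupled generator the constrained p-values pass a
Kolmogorov-Smirnov uniformity screen, though the scheme is mildly
anti-conservative by construction: real transitions avoid the absorbing
tail of a scanpath while uniform redraws do not, which mimics a weak
negative association on short trials — the very artifact the test is
designed to expose.

## The synthetic cohort generator

The generator is first-class, tested code and the ground-truth oracle for
every recovery study. Its default chain has five states: two short-sojourn
states in near-systematic alternation (refixation-dominated and
long-progression-dominated — the normal-reading cycle; shifted binomial
sojourns, means 1.29 and 1.22), an information-search state mixing
refixations and long progressions (shifted negative binomial, mean 3.38;
its emission row is renormalized to sum to one), a long-sojourn transitory
fast-reading state (mean 13.37, zero re-entry column) and an absorbing
slow-confirmation state rich in regressions. Initial probabilities are
(0.40, 0.35, 0.01, 0.24, 0). The transition values realize this structure
with alternation probabilities 0.96/0.94 — strong enough that the
five-state structure is statistically detectable by BIC at the default
cohort size, which a weaker alternation is not. Trial lengths follow a
shifted negative binomial with mean 16.6 and sd ~7, truncated below at 4.

Full cohorts add: ~30-word, ~5-line layouts with fixed-width character
geometry; word-index trajectories integrated from the emitted Read modes
(long progressions/regressions move 2-4 words, clipped at text bounds with
the realized category recorded, so re-encoding is exact); fixation
coordinates at assigned word centres (optional jitter); per-phase
log-normal fixation durations (defaults ordered so implied phase speeds
satisfy FR > NR > SC > IS) scaled by a log-normal participant effect
(sd 0.18 on the log scale) and clipped into the retention bounds; two
designated trigger words per text with an embedding table constructed so
the type-specific detection rules recover exactly those words; and
optional coupling that multiplies the per-step sojourn-ending hazard
(capped at 0.999) whenever a trigger word was fixed within a configurable
radius of fixations.

What the generator does *not* emulate: raw gaze samples and tracker noise,
typography beyond fixed-width layout, word-frequency/length effects on
fixation durations, stop-word fixations, and any semantic structure beyond
the two trigger words. Passing recovery tests therefore demonstrates
correctness of the inference machinery and the pipeline's internal
consistency under the model's own assumptions — not fidelity of the model
to real readers.

## Reproducibility

All randomness flows through explicit seeds (`numpy.random.default_rng`);
identical seeds give byte-identical cohorts. `scripts/acceptance.py`
derives its simulation and fitting seeds from a single `--seed`, simulates
2000 sequences from the default chain, scans K=1..7 with 10 restarts each,
matches estimated to generating states by optimal assignment on
total-variation distance between emission rows, and writes the selected K
together with the recovered parameters as JSON.
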