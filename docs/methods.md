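# Methods

## Tetramer-segregation model

A silenced chromatin domain with `N` nucleosomes carries `N` parental
H3-H4 tetramers into replication. Each tetramer is assumed to segregate
independently to the designated daughter strand with probability
`p_strand` (0.5 = unbiased random segregation). A daughter chromatid
loses the silenced state when it inherits fewer than
`min_parental_required` (`m`, default 1) parental tetramers, giving the
closed-form per-chromatid loss probability `P(X < m)` with
`X ~ Binomial(N, p_strand)`. No co-segregation or clustering term is
included: the prediction under test is the pure binomial.

Loss is reported **per daughter chromatid** — the arithmetic behind
"one in eight daughter cells" for N = 3 — with
`per_division_loss_probability` as a documented helper for the chance
that at least one of the two daughters falls short. Replisome mutants
that bias inheritance toward the lagging (`dpb3∆`) or leading
(`mcm2-3A`) strand are modelled by moving `p_strand` off 0.5; no numeric
bias has been measured for either mutant, so no mutant-specific value is
baked in, and the deprived chromatid is obtained with `focal="other"`
(per-tetramer probability `1 − p_strand`).

## Two-state switching kinetics

States silenced (GFP−) and expressed (GFP+) interconvert at per-hour
rates `k_on` (loss) and `k_off` (establishment). Assuming equal birth
and death rates in the two states, the expressed fraction obeys
`dx_on/dt = k_on − (k_on + k_off)·x_on`, with solutions

    x_on(t) = E (1 − e^{−(k_on+k_off) t})                  x_on(0) = 0
    x_on(t) = E (1 − e^{−(k_on+k_off) t}) + e^{−(k_on+k_off) t}   x_on(0) = 1

and equilibrium `E = k_on/(k_on + k_off)`. The degenerate case
`k_on = k_off = 0` returns the initial condition rather than erroring.
Per-hour rates convert to per-generation by multiplying by the
generation time (default 1.96 h, the measured doubling time in CSM at
30 °C; the same value is assumed for all genotypes).

### Estimation

`fit_rates` minimizes the unweighted squared error between observed
GFP+ fractions and the closed form, jointly over all points of all
subpopulations of a genotype (`pooled`, the default), using bounded
(non-negative) trust-region least squares so that zero rates remain
representable. Starting values are heuristic: `k_on + k_off` from the
time at which the trajectory first crosses half the gap to its apparent
equilibrium (log 2 / t_half), and the equilibrium fraction from the mean
of the late observations; on optimizer failure up to five log-normally
jittered restarts are tried before an explicit convergence error naming
the genotype. Fewer than three distinct time points, or a constant
observed trajectory, raise an unidentifiability error instead of
returning numbers.

95% confidence intervals come from the asymptotic linearization of the
least-squares Jacobian with a t-quantile at `n − 2` degrees of freedom,
clipped below at zero. A singular Jacobian direction (which occurs when
the sampling grid cannot resolve `k_on + k_off`, e.g. very fast
relaxation observed only after it has completed) yields an infinite
half-width rather than a silent small interval. The alternative
`per_replicate_averaged` method fits each subpopulation separately,
averages the rates, and reports their standard deviation alongside a
t-interval on the mean; on clean synthetic data the two methods agree.

Sorted-silenced experiments constrain `k_on` much better than `k_off`
(the early signal is pure loss), and vice versa; the analysis scripts
therefore take `k_on` from the silenced sort and `k_off` from the
expressed sort. The corresponding CI-width asymmetry holds in the
slow-relaxation regime (e.g. the wild-type rate pair, where the 48 h
window samples the approach to equilibrium); when relaxation completes
within the first sampling interval, both sorts constrain the rates
through the equilibrium plateau and the asymmetry can invert.

Unweighted least squares is the default deliberately; binomial
weighting (`n/(x(1−x)+ε)`) would be straightforward but changes the
estimator, and the unweighted fit is what the relaxation protocol
assumes. Staggered time points are kept exactly as recorded per
replicate; nothing is interpolated to a common grid. Time zero is the
sorting moment of each sample and sort purity is assumed perfect.

## Assay quantification

**CRASH.** Events are gated into RFP±/GFP± quadrants (booleans accepted
directly, or raw intensities against positive thresholds). The apparent
loss rate is `n(RFP+GFP+) / (n(RFP+GFP+) + n(RFP+GFP−))`; RFP−GFP+
cells (older loss events) are counted but excluded, so the statistic is
invariant to their number. Replicate rates are summarized as mean ± SD
and kept for downstream ANOVA/Tukey by standard routines.

**FLAME.** The GFP gate is placed at the log-scale midpoint between the
medians of fully silenced and fully expressed control populations; a
band spanning the central 20% of the log gap flags ambiguous events,
and a population with more than 20% of events in that band is marked as
poorly separated (warning, not error).

**Pedigrees.** Point estimate `events/divisions`; 95% CIs use the
Wilson score interval, chosen for its coverage at the few-events-in-
a-thousand-divisions regime typical of these data (no CI method is
canonical for the assay; Wilson's exact coverage at n = 1000,
rate 0.01 is 96.4%). Simultaneous mother–daughter switches should be
counted upstream as one event. Pairwise rate comparisons use the Yates
continuity-corrected chi-square on the 2×2 events × group table, with
the correction clipped at zero; empty margins raise an error advising an
exact test.

## MNase occupancy profiles

Mapped paired-end fragments (BED3, 0-based half-open) are filtered to
140–180 bp **inclusive** — the bounds retain the canonical 147 bp core
symmetrically — then each fragment adds one count at
`floor((start+end)/2)`, and the histogram is smoothed with a centered
25 bp rolling mean whose windows shrink at the edges (a window wider
than the profile degenerates to the global mean). Midpoints outside the
region of interest go to a logged overflow count, so the in-region
histogram total always equals the retained in-region fragment count.
Peak positions are the local maxima of the smoothed profile above half
its maximum, at least 100 bp apart; no peak-calling model beyond that.

Resolution vs coverage: with midpoint scatter of ~10 bp SD around a
dyad, the argmax of the 25 bp-smoothed histogram recovers the dyad with
a sampling error whose tail shrinks with coverage — at 50 fragments per
dyad the median error is within 5 bp but individual dyads miss by more
in roughly 6% of cases, while at 150× every dyad lands within 5 bp.
The tests assert exactly that pair of statements.

## Synthetic-data generators

The generators emulate the study conditions, not arbitrary data:

- **CRASH colonies** grow synchronously by doubling from silenced
  founders; each silenced cell loses silencing with probability
  `loss_rate` per division (default 0.001, the wild-type figure),
  irreversibly, and retains RFP for `rfp_persistence_gens` generations
  (default 2 — the reporter's decay is only qualitatively described, so
  a fixed two-generation window is used and is configurable). The
  expected apparent loss rate is `1 − (1 − q)^persistence`.
- **Relaxation experiments** default to the sorted-population design:
  3 technical replicates × 8 time points over 48 h (0, 4, 8, 12, 18,
  24, 36, 48 h), 500 cells sampled per point, with each successive
  replicate's post-sort time points offset by 20 min (sorting took
  ~20 min per sample, staggering the clocks; t = 0 is each sample's own
  sort). The latent expressed fraction follows the exact closed form by
  default; an agent-based per-cell Markov chain (discrete generations)
  is available as a stress test. Observations are binomial draws.
- **Pedigrees** draw Bernoulli events per observed division conditioned
  on the parent state; `simulate_state_lineages` runs the full per-cell
  chain and converges to the stationary distribution
  `k_off/(k_on+k_off)` silenced.
- **MNase fragments** have midpoints `N(dyad, 10 bp)` and lengths
  `N(147, 8) bp` truncated positive, `coverage` fragments per dyad.

All generators are bitwise-reproducible under a fixed seed, and file
outputs carry provenance comments (config hash, seed).

What the generators deliberately omit — sorter impurity, cell death,
fitness differences between states, cell-cycle age structure, sequence-
dependent nucleosome positioning, background (non-nucleosomal) MNase
fragments — bounds what green tests show: parameter recovery and
pipeline correctness under the stated statistical model, not robustness
to those real-data pathologies.

## Problem sizes

The recovery studies use 200 seeded experiments per condition (the
acceptance script) and 30–40 per condition in the ordering/recovery
tests; the CRASH simulation grows 16 founders for 13 generations
(131,072 cells); Wilson coverage uses 1000 simulated pedigrees of 1000
divisions. These sizes put Monte-Carlo error well below the tolerances
being checked while keeping the full suite fast.

## Known limitations

- The equilibrium consistency check (`E/S` vs `k_on/k_off`) is exact
  arithmetic on its inputs; for rate pairs fitted from finite data the
  two ratios differ by sampling error, and the discrepancy ratio is
  reported rather than tested.
- The per-hour ↔ per-generation conversion assumes one common
  generation time across genotypes.
- BAM ingestion is not built in; fragments arrive as BED3 (a
  `samtools`-based conversion to BED3 is a one-liner upstream).
- The fitted CIs are asymptotic; a bootstrap would be preferable for
  very short time courses.
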