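# Methods

`boutondyn` re-implements, as a tested pipeline, the analysis of corticostriatal
axonal-bouton activity and structure during motor learning: behaviour
segmentation of a cued lever-pushing task, calcium-trace processing, bouton
reward-selectivity classification, population trajectory analysis, and
structural bouton turnover with a spatial clustering test.  A synthetic-data
generator provides ground truth for every stage; all recovery claims in the
test suite are claims about this generator, not about real recordings.

## Behaviour

Lever displacement is sampled uniformly (default 15 Hz).  Movement bouts are
segments where the position exceeds a movement threshold; the onset is the
first sample at or above threshold and the offset the first sample back below
it.  Bouts separated by less than 500 ms are merged; a bout is excluded when
any other movement ends within the 3 s before its onset, so that every
analysed movement has a clean pre-movement baseline.

A rewarded movement (RM) is a push whose peak clears the push threshold
(default 1.5 mm) inside a trial's task window `[cue, cue + task_window)`;
pushes that stay below threshold in the window, and pushes during the
inter-trial interval (ITI: end of one trial to the next cue), are unrewarded
movements (UM).

The movement threshold, when not supplied, is the resting median plus 6×MAD of
the trace.  A 3×MAD cut sits at about two standard deviations of Gaussian
resting jitter and flags roughly 2% of resting frames as movement — tens of
spurious "bouts" per session, each of which also poisons the 3-s exclusion
rule for genuine movements that follow it.  Six MADs (≈4 s.d.) brings the
per-frame false-crossing probability below 1e-4 while remaining far below any
real push amplitude; the multiplier is a config key.

Movement trajectories for correlation analyses are the lever position over
`[onset − 0.5 s, onset + 2 s]` resampled to 64 points; pairs with a
zero-variance trajectory are flagged undefined and skipped.

## Fluorescence processing

The baseline F₀ of each ROI is the 30th percentile of the raw trace in a 30-s
sliding window, centered with windows truncated at the segment edges
(a trailing variant is available as `baseline.align`).  ΔF/F = (F − F₀)/F₀,
and the z-score of ΔF/F over the segment is the working trace; thresholds
quoted in "s.d." are z units of that trace.  The implementation maintains a
sorted rolling window and reproduces the percentile (including its linear
interpolation) bitwise against a direct per-frame computation; the test suite
asserts this equivalence on random traces.

Calcium events are strict local maxima of z above 1 s.d. (plateaus take their
first frame; endpoints are never peaks).  Events of two ROIs within 670 ms of
each other are matched one-to-one as the *same peak*, greedily by ascending
time difference, each event participating in at most one match; unmatched
events are *unique peaks*.  One-to-one matching keeps the bookkeeping
conservative (`matched + unique = total` per ROI, and the matched count is
symmetric between the two ROIs).  The same-peak fraction of a bouton in a
pair is its matched events over its total events; fractions average over a
bouton's pairings, then over boutons of an axon, then over axons of a mouse.
Events are movement-labelled when they fall within `[onset − 0.33 s,
onset + 0.67 s)` of an RM or UM onset (nearest onset wins on overlap; 0.33 s
and 0.67 s are 5 and 10 frames at 15 Hz).

### Accuracy limits of the same-peak estimate

Two opposing error sources bound what the same-peak fraction can recover, and
both are properties of any threshold detector plus tolerance matcher at high
event rates:

* *Chance coincidences.* Independent bouton-unique events on two boutons fall
  within ±0.67 s of each other with probability ≈ 1 − exp(−2·0.67·r_u), where
  r_u is the unique-event rate.  At 200 events per bouton in a 4-min segment
  (0.83 Hz) this inflates the estimate even with perfect detection.
* *Decay riders.* At snr 8 the 1-s.d. z threshold sits near half the typical
  transient amplitude, and noise maxima riding a transient's decay shoulder
  register as extra peaks (~18% of detections at that rate), deflating the
  estimate.

The net effect at 200 events/bouton and snr 8 is a downward-biased estimate,
and recovery sharpens as snr grows (riders shrink with the noise floor).  The
benchmark suite asserts the ±0.05 recovery property at these conditions and
reports the measured error where it fails; the stage-contrast benchmark shows
the estimate remains strictly monotone in the true fraction, which is what
the learning comparison relies on.

## Responsiveness classification

Activity is aligned to movement onsets over `[−1 s, +3 s)` (60 frames at
15 Hz; onsets without a full window are dropped) and averaged across trials
per condition.  A bouton is *responsive* in a condition when the peak of the
trial-averaged trace inside `[−0.2 s, 3 s)` minus the 5th percentile of that
trace exceeds 0.9 (z units).  Axons instead use a per-mouse threshold: the
peak values of all axons are histogrammed at 0.1-unit bins for RM and UM
separately, the threshold is the mean of the two modal bin centres (ties go
to the lowest bin), capped at 1.0; with fewer than 10 axons the histogram is
skipped and the cap used directly.  The two responsiveness flags combine into
RM_only / UM_only / both / unresponsive; RM-responsive = RM_only ∪ both.
Units with fewer than 5 trials of a label (configurable) count as
unresponsive for it and are flagged unclassified.

Early→late category transitions are tabulated as a 4×4 fate table with
row-normalized (fate) and column-normalized (origin) proportions; empty rows
are reported as missing rather than zeros.

A bouton is *delay-reward modulated* when the trial-averaged peak time in
reward-delay trials lags the RM peak time by more than 0.93 s; for such
boutons the mean z over `[1.67, 2.33) s` (delay trials) and `[0.67, 1.33) s`
(omission trials) quantifies reward-expectation activity.

## Population analyses

*Embedding.* Each bouton contributes its trial-averaged RM activity stacked on
its UM activity, giving a 2M×N matrix (M = 60 frames per condition, N
boutons).  PCA runs across the timepoints; a bouton's coordinates are its
loadings on the first three components, oriented so the largest-magnitude
loading is positive.  On rank-3 input the three components explain all
variance to 1e-8.

*Trajectory selectivity.* PCA is fit on the continuous segment (frames ×
boutons); the first three PC time courses are cut into per-trial trajectories
over `[−1, 3) s`.  For an RM trial with summed frame-wise Euclidean distances
d_RM, d_UM to the mean RM and UM trajectories, the selectivity index is
(d_UM − d_RM)/(d_RM + d_UM), and symmetrically for UM trials: +1 means the
trial sits on its own condition's mean trajectory, −1 on the opposite one.
Summing versus averaging the frame-wise distances does not change the index.

*Trial-pair curves.* The population vector of a trial concatenates the aligned
`[−1, 3) s` activity of all responsive boutons in a fixed order; pattern
correlation is the Pearson r between two trials' vectors.  The activated
ensemble difference for counts a, b of activated boutons ("activated" = a
responsive bouton with at least one event in `[0, 3) s` after onset) is
|a−b| / (0.5·(a+b)) ∈ [0, 2].  Both statistics are averaged within
movement-trajectory-correlation bins with edges −0.2, 0, 0.2, 0.4, 0.6, 0.8,
1; empty bins are reported missing.

*Axon heterogeneity* is the minority fraction of RM/UM labels among an axon's
responsive boutons (∈ [0, 0.5]; ties → 0.5 with a flag).  Boutons of the
'both' category count toward the dominant side by default
(`heterogeneity.both_policy = exclude` drops them); unresponsive boutons never
enter the denominator.  Axon-pair Pearson correlations above 0.7 mark pairs
likely originating from one neuron.

## Structural dynamics

Between adjacent sessions, boutons are matched by persistent id (synthetic
maps) or greedy nearest-position matching within 2 µm (real data).  Formation
and elimination rates are counts over the previous session's bouton count —
one denominator for both keeps the two rates comparable — and density is
count per µm of traced axon.  Survival of a formed cohort is the fraction
still present at each later session, tracked through the surviving subset so
the curve cannot increase.  The conservation identities
`persistent + eliminated = previous` and `persistent + formed = current` are
asserted on every record.

*NND clustering test.*  Within each axon, every bouton of interest (e.g.
newly formed ones) gets the distance to its nearest neighbour; values pool
across axons into an empirical CDF on a 1-µm grid.  The null repositions the
same number of boutons per axon uniformly along the axon (1,000 shuffles; a
variant permutes the pooled observed positions across axons).  Two summaries
are computed:

* the descriptive pointwise 2.5/97.5-percentile band of the shuffle CDFs, and
* the *decision*, via a global envelope: each curve is reduced to its maximum
  studentized deviation from the shuffle mean, and the observed curve is
  significant where its deviation exceeds the 95th percentile of the shuffle
  maxima.

Anywhere-exceedance of a pointwise band is not a valid test: its family-wise
false-positive rate compounds at roughly 2.5% per effectively independent
grid point, an order above nominal for a CDF whose correlation length is much
shorter than the axon.  The envelope controls the family-wise rate by
construction.  The benchmark asserts ≤10% false positives on unclustered maps
and ≥90% detection of σ = 10 µm clustered formation within 5–30 µm.

## Synthetic data generator

The generator emulates, per mouse: a behavioural session, bouton/shaft
fluorescence, and multi-session structural maps.  All randomness derives from
one seed through named substreams (behaviour / activity / structure), so each
part regenerates independently and byte-identically.

*Behaviour.*  Trials are cue-initiated; with probability `p_rm` the trial
contains a supra-threshold raised-cosine push (0.3–1.2 s latency, 0.4–0.8 s
duration, peak 1.3–1.8× threshold), otherwise a sub-threshold push
(0.4–0.9×).  Reward is delivered at the threshold crossing (delayed by 1 s or
omitted in the delay/omission variants); the next cue follows the later of
trial end and task-window end plus a 3–6 s ITI, so task windows never
overlap.  Resting jitter is a discretized Ornstein–Uhlenbeck process (τ =
0.1 s, σ = 0.03 mm).  Optional ITI pushes occur at a configurable rate
(default 0: every UM in the default datasets is a failed in-window push).
The default allocated task window is 2.5 s — pushes arrive ~1 s after cue, so
a shorter allocated window only compacts the session, and a 4-min segment
holds a realistic trial count.

*Activity.*  Each axon carries transients shared across its boutons and each
bouton additionally carries its own unique transients; with shared fraction
s and per-bouton event rate R, shared events occur at s·R and per-bouton
unique events at (1−s)·R, so each bouton's realized event mix is s shared /
(1−s) unique — the estimand of the same-peak analysis.  Background events are
Poisson; movement-locked events fire at each RM/UM onset with probability
0.9, 0.05–0.35 s after onset.  Bouton categories are organised around a
per-axon dominant category drawn from `category_mix`; each bouton deviates
(RM↔UM) with probability equal to the unique fraction 1−s (overridable via
`category_deviation_p`), which ties activity heterogeneity and category
heterogeneity to one learning-stage parameter.  A bouton expresses only
events whose movement label its category admits; the shaft expresses the
shared events admitted by the dominant category.  Traces are event impulses
convolved with a difference-of-exponentials kernel (rise 0.05 s, decay 0.6 s;
amplitude snr × noise s.d. with 0.2 log-normal jitter) on a baseline of 100
with a slow sinusoid-plus-linear drift (≤10% of baseline) and white Gaussian
noise per frame.

What this generator does *not* emulate: motion artifacts, neuropil
contamination, brightness-dependent (shot) noise, indicator saturation and
bleaching, correlated noise across ROIs, and axonal conduction failures.
Recovery results on it therefore demonstrate the correctness of the analysis
chain under its stated statistical assumptions, not performance on real
recordings.

*Structure.*  Session 1 places boutons uniformly along each axon (default 10
per 100 µm, mirroring reported per-axon bouton counts); later sessions
eliminate each bouton with `p_elim` and form `Binomial(previous, p_form)` new
ones, uniformly or around a per-axon Gaussian centre (σ =
`cluster_sigma_um`), with positions reflected into the axon.  Ids persist
across sessions, so id-based turnover is exact by construction.

## Benchmark problem sizes

The benchmark suite validates: the two analytic selectivity cases; shared-
fraction recovery at 50 axons × 5 boutons, 200 events/bouton, snr 8, 20
seeds; category recovery at ~30 RM + 30 UM trials, snr 8 (~240 boutons
pooled); NND calibration and power at 40 axons × 10 boutons, 100 seeds each,
1,000 shuffles; turnover exactness over 4 sessions; and the early/late stage
contrast (unique fraction 0.35 vs 0.20) over 20 seeds.  Multi-seed benchmarks
derive their dataset seeds from a single master `SeedSequence`.

## Known limitations

* The same-peak fraction is a biased estimator of the true shared fraction at
  high event rates (see above); comparisons across conditions remain valid
  because the bias is monotone in the truth.
* Axon-level classification needs ≥10 axons per mouse for the histogram
  threshold; below that it falls back to the 1-s.d. cap.
* Cue-only and punishment-only trial variants are generated but no
  modulation criterion is applied to them.
* Real-data bouton matching by position assumes ≤2 µm drift between sessions
  after registration; it does not model axon stretch.
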