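# Methods

This note documents the models and procedures implemented in `measeq`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Recording model and layout

The package operates on per-electrode spike-time lists (seconds, strictly
increasing) tied to an electrode layout: 60 electrodes in four spatial
clusters (quadrants), sampled at 10 kHz. The default layout
(`default_layout_4q`) places 15 electrodes per quadrant on a 200 µm-pitch
grid centred at ±1 mm from the array centre; coordinates are a documented
convention and any layout can be supplied as CSV
(`electrode_id, x_um, y_um, cluster_id`). Electrodes are treated as units —
no spike sorting is performed or supported.

Time is held in seconds as floats throughout; sample indices appear only at
I/O boundaries. Three on-disk formats are supported: long-form CSV, HDF5
(one variable-length dataset per electrode), and a read-only MAT dialect (a
single cell array with one cell per layout electrode holding spike times as
sample ticks). The MAT reader converts ticks to seconds at the layout
sampling rate and fails loudly on any structural mismatch rather than
guessing, because the exact deposited structure of archival peak-train files
varies.

## Spike detection (PTSD)

Noise SD is estimated per electrode with the MAD estimator
(`median(|x − median(x)|)/0.6745`) over the whole trace: it is consistent for
Gaussian noise and nearly unaffected by sparse spikes, where the plain sample
SD inflates. A windowed estimate adds nothing for stationary noise and is
therefore not the default (a `noise_window_s` config hook exists).

Detection scans the alternating local extrema of the trace. A spike is
declared when an extremum and an opposite-sign counterpart within the peak
lifetime window (default 2 ms) span a peak-to-peak excursion above
`threshold_factor × noise SD` (default 8). The timestamp is the
larger-magnitude extremum of the pair (earlier sample on ties), which pins
the spike to the dominant trough/peak of the waveform; the scan then resumes
after the pair, and detections closer than the refractory period (default
1 ms) collapse to the larger one. No band-pass pre-filtering is applied by
default.

## Bursts, network bursts, activity metrics

The string method partitions each train into maximal strings whose
consecutive ISIs never exceed `max_isi` (default 100 ms); strings with at
least `min_spikes` (default 5) are bursts. Burst start/end are the first/last
spike, so every spike belongs to at most one burst by construction.

Network bursts merge electrode bursts that overlap or sit within the merge
interval (default 100 ms), chained transitively; a merged candidate is kept
when it involves at least `nb_min_fraction` (default 20 %) of the reference
electrode pool. The reference pool defaults to **active** electrodes
(MFR strictly > 0.1 spikes/s) — this matches the activity definition used for
all other metrics and avoids dead-electrode bias — and can be switched to all
layout electrodes (`participation_base="all"`), since which base the original
analyses used is not derivable from the stated parameters. The cited
self-adaptive ISI-threshold variant of NB detection is deliberately not
implemented: both governing parameters are pinned (20 %, 100 ms), so the
fixed-parameter rule is the contract.

Metrics: MFR = spikes/duration (spikes/s); MBR = bursts/minute per electrode;
BD = burst end − start (s); IBI = next burst start − current burst end within
an electrode (s). NB-level inter-event intervals are available separately
from the NB list.

## IFR and activation sequences

The IFR convolves 1 ms binned spike counts with a unit-area Gaussian kernel
of SD 25 ms truncated at ±2 SD. The plain-language "100 ms smoothing window"
is read as the kernel's total support (±2 SD), not its SD — a window most
plausibly denotes support — and both the SD and the truncation are
configurable. Unit area makes the trace linear in its input and its integral
equal to the windowed spike count.

For each NB, the IFR of every participating cluster (≥ 1 spike inside the NB)
is evaluated over the NB span padded by 2 kernel SDs; clusters are ordered by
the time of their global IFR maximum, ties resolving to the earlier sample
and then to the lower cluster id. Silent clusters are excluded, so sequences
can be partial; partial sequences are distinct types from full ones (a
`full_sequences_only` filter exists, recorded in the output manifest).

Run lengths are the lengths of maximal series of identical consecutive
sequences (exact tuple equality); singleton runs are included internally and
"repeated" sequences are runs of length ≥ 2, which is also what the
cumulative-frequency output tabulates. Shannon diversity uses natural logs
over the **observed** sequence types, `J = H/ln N` with `N` the observed type
count (J ≡ 0 for a single type); using all 24 possible orderings as N instead
is not the default because unobserved types carry no frequency information.

The Monte Carlo null permutes the observed sequence list uniformly
(preserving the type multiset exactly), recomputes run lengths per iteration
(default 1000, minimum 100), and pools them; observed-vs-null run-length
distributions are compared with the two-sample KS test. Because run-length
samples are small and discrete, the asymptotic KS p is conservative under the
null rather than uniform; the calibration property asserted is therefore that
a true null is rejected at p ≤ 0.01 in at most 5 % of seeded replicates.

## Connectivity (TSPE) and CI₀

For an ordered pair i→j the cross-correlogram of `t_j − t_i` is computed in
1 ms bins centred on integer delays and normalised by the source spike count,
giving the probability of a target spike at each delay. For every candidate
delay d in 1–25 ms a peak score is computed with a family of filters — a
central running-average plateau of width `a` centred on d minus the mean of
two flanking background windows of width `b` offset by a crossing gap `c` —
summed over `a ∈ {3..8}`, `b ∈ {2,3}`, `c ∈ {0}` (the published defaults of
the filter family; the grid is configurable). The edge weight is the signed
extremum of the summed score over delays (positive ⇒ putative excitation,
negative ⇒ inhibition); the best delay is its location, with exact-magnitude
ties resolved toward the most extreme raw correlogram bin, then the earliest
delay. Pairs with fewer than 10 spikes in either train are skipped.

Edge pruning applies three deterministic, idempotent filters:
propagation speed (electrode distance / best delay) within
`[0.02, 2] m/s`; best delay within synaptic latency bounds `[1, 25] ms`; and
optionally `|weight|` above a surrogate threshold. Speed and latency bounds
are package defaults recorded in every manifest — only the existence of the
two filters, not their values, is fixed by the analysis definition. The
surrogate null jitters every train uniformly by ±10 ms, recomputes all
weights, pools |weight| across surrogates (default 100) and takes the 99th
percentile; jitter destroys millisecond timing while preserving rates, so
the threshold isolates fine-timing structure. The pooled (rather than
per-pair) null keeps the cost linear in the surrogate count; it is the
package's own choice since no numeric weight cutoff is prescribed.

CI₀ uses a ±100 ms correlogram at 0.5 ms bins with edges symmetric about
zero lag (making CI₀ symmetric under train exchange up to bin-edge
coincidences); it is the count mass in bins inside ±1 ms divided by the total
mass, 0 for an empty correlogram, and independent of correlogram
normalisation by construction. Edges between same-cluster electrodes are
labelled `intra`, otherwise `inter`; condition-versus-baseline variation
reports `100 × (cond − base)/base` for inter/intra edge counts, mean
|weight|, and mean CI₀, with zero-baseline entries flagged as undefined
(`None`), never silently zeroed.

## Dose–response

Responses are MFRs normalised to the drug-free baseline. The Hill model
`r(c) = bottom + (top − bottom)/(1 + (c/IC50)ⁿ)` is fitted by bounded least
squares in `log10 c`, with one start per decade across the sampled range ±1
decade to avoid local minima over 4 decades. Asymptotes default to fixed
top = 1 and bottom = 0 (baseline-normalised responses, full block at
saturation); both can be freed. Fits are flagged non-converged when the
response range is under 0.1 (flat, IC₅₀ unidentifiable) or the fitted IC₅₀
lands more than two decades outside the sampled range. Fitting on
log-concentration makes the estimate exactly scale-equivariant.

## Statistical tests

Wilcoxon signed-rank: zero differences dropped, midranks for ties, statistic
W = min(W⁺, W⁻). Exact mode enumerates all 2ⁿ sign patterns (n ≤ 15) and
reports `p = min(1, 2·P(W⁺ ≤ W))`; normal mode reports the tie-corrected z
for W⁺ and its two-sided p. Both modes are exposed because archival analyses
sometimes report a z whose tie/zero handling cannot be reconstructed; with
n = 9 untied pairs and W = 7 the standard approximation gives |z| ≈ 1.84, so
a reported z of 2.09 implies a different variance convention — the package
reproduces the p from a given z via `two_sided_p_from_z` without forcing
either mode to match. Paired condition comparisons use the culture as the
pairing unit. KS is the standard two-sample statistic with asymptotic p;
t-tests are two-sided Student's tests with the Bonferroni threshold
`alpha / n_comparisons`, reporting raw p alongside the adjusted decision.

## Synthetic generator: what it emulates and what it does not

NB onsets follow a shifted-exponential renewal process: gaps are the 1 s
minimum separation plus an exponential whose rate is set so the mean event
rate equals `nb_rate` exactly (plain thinning of a Poisson process would
bias the count); packing is rejected as infeasible when
`nb_rate × min_separation ≥ 1`. Sequence persistence is first-order Markov:
each NB repeats its predecessor's sequence with probability `p_rep`,
otherwise draws uniformly from the motif repertoire — the simplest mechanism
that generates heavy-tailed run-length distributions. Within an NB, the
cluster at rank r activates `r × inter_cluster_lag` (default 80 ms) after
onset; each member electrode fires `burst_spikes_per_electrode` (default 8)
spikes with 2–6 ms ISIs, centred with Gaussian per-electrode jitter of SD
`intra_cluster_lag` (default 10 ms); background activity is independent
Poisson at 0.2 spikes/s per electrode by default. Sequence recovery is
reliable when the inter-cluster lag is at least ~3 IFR-kernel SDs and the
background stays below ~0.5 spikes/s.

Planted connectivity inserts (excitatory) a target spike at
`source time + delay` with the stated transfer probability, or deletes
(inhibitory) target spikes within a 5 ms suppression window after source
spikes — a probabilistic deletion that gives the correlogram a trough
without a membrane model. Outputs are re-sorted and deduplicated at 0.1 ms.
Voltage synthesis plants a biphasic template (peak-to-peak scaled to
`amplitude_sd_ratio × noise_sd`, largest-magnitude sample at the spike time)
in white Gaussian noise, summing overlaps linearly with a warning.

The generator imposes ground truth rather than growing it: there are no
biophysical neurons, no plasticity, no pacemaker mechanism, and background
spikes are independent of NBs. Passing tests therefore demonstrate that each
analysis stage recovers a known structure of the stated kind under realistic
rates and noise — not that the stages are robust to every failure mode of
biological recordings (electrode drift, non-stationary noise, overlapping
units, rate co-modulation).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as the package's own
choice of benchmark conditions: 60-electrode recordings of 120–750 s for
burst/sequence checks, a 20-electrode 300 s network with 30 planted edges
(transfer probability 0.5, delays 3–10 ms) for the TSPE direction-recovery
AUC, 100 planted spikes at 10× noise SD over 60 s for detector
sensitivity/precision, 1000 Monte Carlo iterations (10 000 where a null is
compared against exhaustive enumeration), and 20 seeded replicates for noisy
IC₅₀ recovery. All stochastic stages take explicit integer seeds and are
bit-reproducible; degenerate inputs (empty trains, all-silent NBs, flat
dose-response data, zero baselines) raise or flag rather than returning
silent defaults.

## Known limitations

- The TSPE filter grid and the surrogate threshold are defaults, not fitted
  to any reference dataset; absolute weights are unitless scores meaningful
  for ranking and thresholding, not as synaptic strengths.
- The NB detector uses fixed parameters; recordings with strongly
  non-stationary ISI statistics may warrant the adaptive variant, which is
  out of scope.
- Exact Wilcoxon enumeration is limited to n ≤ 15 pairs (2ⁿ growth); larger
  samples use the normal approximation.
- The MAT dialect covers one cell-array convention; other vendor formats are
  out of scope.
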