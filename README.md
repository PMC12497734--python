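# measeq

Spike-train analysis for **clustered multi-electrode array (MEA) recordings**:
cortical cultures grown as four spatially separated neuronal assemblies
(quadrants) on a 60-electrode array, whose population events propagate across
the clusters in recurring activation sequences.

The package is aimed at electrophysiologists and network neuroscientists who
need to quantify, from per-electrode spike times, how a drug or manipulation
changes (i) overall excitability, (ii) the repertoire and persistence of
cluster activation motifs, and (iii) directed functional connectivity within
and between clusters.

## What it computes

- **Spike detection (PTSD)** — a spike is a peak-to-peak voltage excursion
  between two opposite-sign local extrema within a 2 ms *peak lifetime*
  exceeding 8× the noise SD (robust MAD estimate), with a 1 ms refractory
  period; the timestamp is the larger-magnitude extremum.
- **Bursts and network bursts** — the *string method* (≥ 5 spikes, inter-spike
  intervals ≤ 100 ms) per electrode; network bursts (NBs) merge electrode
  bursts closer than 100 ms and require ≥ 20 % of active electrodes
  (active ⇔ MFR > 0.1 spikes/s). Metrics: MFR (spikes/s), MBR (bursts/min),
  burst duration BD (s), inter-burst interval IBI (s).
- **Activation sequences** — per NB, each cluster's instantaneous firing rate
  (IFR; Gaussian kernel, 100 ms window = ±2 SD of 25 ms) peaks at its
  activation time; the order of peaks is the NB's activation sequence, its
  first element the *initiator*. Sequence lists are summarised by run lengths
  of identical consecutive sequences, Shannon diversity
  `H = −Σ pᵢ ln pᵢ`, equitability `J = H / ln N`, and a Monte Carlo
  permutation null that preserves the type multiset, compared by a
  two-sample Kolmogorov–Smirnov test.
- **Functional connectivity (TSPE)** — for each ordered electrode pair, the
  normalised cross-correlogram is scanned with a family of peak/edge filters;
  the signed extremum over delays 1–25 ms is the edge weight (positive =
  excitation). Edges are pruned by propagation-speed and synaptic-latency
  filters, and optionally by a jitter-surrogate weight threshold. Pairwise
  synchrony is the coincidence index CI₀ = correlogram mass within ±1 ms over
  the total mass in a ±100 ms window.
- **Dose–response** — mean firing rate normalised to baseline, fitted with the
  Hill equation `r(c) = bottom + (top − bottom)/(1 + (c/IC50)ⁿ)` on
  log-concentration with decade multi-start, to extract IC₅₀.
- **Statistics** — Wilcoxon signed-rank (exact enumeration for n ≤ 15, or
  tie-corrected normal approximation), two-sample KS, and Student's t-tests
  with Bonferroni correction.
- **Synthetic data** — a generator producing clustered spike trains with
  known ground truth (NB times, activation sequences with first-order Markov
  persistence `p_rep`, planted directed connections, optional voltage traces
  from a biphasic spike template in Gaussian noise), so every stage is
  testable end to end without recordings.

## Worked example

```python
import itertools
from measeq import (default_layout_4q, simulate_activity, detect_all_bursts,
                    detect_network_bursts, extract_sequences, sequence_stats)

layout = default_layout_4q()                  # 60 electrodes, 4 quadrants
motifs = list(itertools.permutations((1, 2, 3, 4)))[:6]
sts, truth = simulate_activity(layout, duration=600, nb_rate=0.2,
                               motif_repertoire=motifs, p_rep=0.5, seed=1)

nbs = detect_network_bursts(sts, detect_all_bursts(sts))
seqs = extract_sequences(nbs, sts)
stats = sequence_stats(seqs, n_iter=1000, seed=1)
print(len(truth.nb_onsets), len(nbs), len(seqs))
print(round(stats.equitability_j, 3), round(stats.ks_d_vs_null, 3))
```

prints

```
116 116 116
0.983 0.419
```

All 116 simulated network bursts are detected and each yields an activation
sequence. Equitability J = 0.983 means the six motifs occur nearly uniformly
(J = 1 is perfectly even, 0 a single dominant type); the KS statistic
D = 0.419 against the permutation null shows the observed run lengths are far
from chance ordering — at `p_rep = 0.5`, half of all network bursts repeat
their predecessor's sequence, producing longer runs than any permutation of
the same multiset.

The same chain is available from the shell:

```bash
mea simulate --out sim --seed 1 --duration 600
mea sequences --out seq --spikes sim/spikes.h5
mea connectivity --out conn --spikes sim/spikes.h5 --baseline sim/spikes.h5
```

Every subcommand writes a `manifest.json` with the full configuration, seed
and input digests; identical manifests reproduce identical output files.

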