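# Methods

`culturenet` analyzes the spontaneous activity of cultured hippocampal
neuron networks recorded on planar multielectrode arrays (MEAs) and by
calcium imaging, and ships a synthetic-data generator that emulates
both recording modalities so every analysis stage can be validated
against planted ground truth. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
world does and does not establish.

## Network bursts from the total spiking rate

The total spiking rate (TSR) is the spike count across all electrodes
in fixed, half-open 50-ms bins `[k*w, (k+1)*w)` anchored at t = 0; the
last partial bin is included and a spike exactly at the recording end
is assigned to it, so the spike count is always conserved. A bin
*qualifies* when it holds at least `min_spikes` spikes (default 4) from
at least `min_electrodes` distinct electrodes (default 4) — the
classical network-burst criterion for dissociated cultures. A burst is
a maximal run of contiguous qualifying bins; by default a single
sub-threshold bin splits bursts (`max_gap_bins` relaxes this).

Two counting scopes coexist deliberately:

* the **size class** uses the peak single-bin count, following the
  small/large split defined per 50 ms (small = 4–100 spikes in a bin,
  large = ≥ 101);
* **spikes per burst** sums the whole extent, because reported
  per-burst spike counts in this preparation (hundreds of spikes)
  cannot fit in one 50-ms small-burst bin.

Summaries are normalized to the conventional reporting windows:
small bursts per 5 min (`n_small * 300 / duration`), large bursts per
10 min, and the mean spikes per burst over all bursts (a flag restricts
the mean to small bursts).

## Delayed-synchrony connectivity (the C matrix)

For an ordered electrode pair (i presynaptic, j postsynaptic), the
connection weight is the proportion of transmitted spikes

    C_ij = n_synchr,ij / n_j ,

where `n_j` is the number of spikes received by electrode j and
`n_synchr,ij` counts the spikes of j that follow a spike of i at an
axonal delay τ inside a coincidence window of width δ. Because the
true axonal delay per pair is unknown, a grid of candidate delays is
scanned (default τ = 1–20 ms in 1-ms steps — a few milliseconds is the
expected conduction delay at a 200-µm electrode pitch) and the maximum
over the grid is kept together with the best delay. Numerical rules:

* the window is half-open, `[τ − δ/2, τ + δ/2)` (default δ = 2 ms), so
  a lag sitting exactly on a window edge belongs to exactly one
  candidate delay; grid ties resolve to the smallest τ;
* each postsynaptic spike is matched at most once per τ, so
  0 ≤ C_ij ≤ 1 always;
* a silent postsynaptic electrode (`n_j = 0`) yields C_ij = 0 (flagged
  by `n_post`) rather than an undefined value;
* C is directional and not symmetric; the diagonal is excluded.

**Edge selection** takes the largest 5% of coefficients over the
M = n(n−1) ordered off-diagonal pairs: `k = max(1, floor(0.05 · M))`
edges (171 for a 59-electrode array). Ties at the cutoff break
deterministically by higher `n_synchr`, then lexicographic pair label;
zero coefficients are never selected. **Hubs** are electrodes that
appear in at least 10 selected edges (in-degree + out-degree); the
summary statistic is the mean connection count over hubs, falling back
to the top-5 highest-degree connected nodes when no electrode meets the
hub rule. The functional graph keeps every electrode as a node
(isolated ones included) with edges weighted by C_ij and annotated with
the best delay; the rendered figure draws vertex size proportional to
degree with `Cell X [n]` labels.

Known limitation: the top-5% rule always selects k edges, so in sparse
recordings with little correlated structure most selected edges are
chance-level coincidences; where their quantized C values tie, the
deterministic tie-break concentrates them on lexicographically early
labels, which can inflate apparent hub counts. No chance-level
(surrogate) correction is applied by default because the procedure this
package mirrors applies none; the `spike_scope="burst"` option
restricts the computation to spikes inside detected network bursts.

## Calcium events and the three activity statistics

Raw fluorescence is converted to ΔF/F with a running-percentile
baseline, `F0(t)` = 8th percentile over a 60-s window (edges use
nearest-window values; F0 is floored at a small positive constant).
This absorbs slow drift while leaving transients intact.

The event detector is a re-specification (the original analysis used
unpublished in-house software, so only its three output statistics are
defined): per cell,

1. the noise SD is estimated as `1.4826 · MAD(diff(ΔF/F)) / √2`.
   Differencing removes the smooth transient component, so the estimate
   stays calibrated even when transients occupy ~25% of the trace —
   plain MAD of the trace inflates by tens of percent in that regime
   and systematically shortens measured durations;
2. frames with ΔF/F above `median + 2.5 σ` are marked; runs separated
   by sub-threshold gaps of at most 1 s are merged into one event.
   The merge is needed because an exponentially decaying transient
   dwells seconds inside the ±1 σ band around any threshold, where
   frame noise would otherwise fragment one transient into several
   events; `max_gap_s = 0` restores the strict one-frame-splits rule;
3. an event must span at least `min_duration_s` (default 1 s, i.e. two
   frames at 2 Hz) and reach `median + 4 σ` at its peak. The peak
   requirement keeps the false-positive rate on noise-only cells below
   1% (measured ≈ 0.3%) while real transients (amplitude ≈ 30 σ at the
   default settings) are unaffected.

Durations are threshold-crossing widths in whole frames; at the 2-Hz
imaging rate their resolution is capped at 0.5 s. The three summary
statistics are: percentage of active cells (≥ 1 event), events/min
averaged over active cells (a flag switches to all-cells averaging —
active-cell averaging is the default because reported nonzero event
frequencies coexist with large inactive fractions), and the mean event
duration over all events.

The detector is not globally monotone in `threshold_sd`: a higher
threshold can separate two transients that a lower threshold merged
into one extent. The monotone quantities are the supra-threshold frame
mass and, in the high-threshold regime, the event count (reaching zero
once the threshold exceeds the transient amplitude).

## Synthetic recordings

### MEA generator

The stated world is a planted hub network on 59 electrodes: every
electrode fires background spikes as an independent homogeneous Poisson
process (default 0.2 Hz); each hub initiates network bursts as a
Poisson process (`burst_rate_per_min` per hub) emitting a packet of 10
spikes at 5-ms intervals; every source spike at electrode i triggers a
spike at follower j with probability `w_ij`, arriving after the edge's
axonal delay (2–10 ms, evenly spaced across a hub's followers by
construction — the spec of a network contains no randomness) plus
Gaussian jitter (1 ms SD). Transmission is single-hop by default
(transmitted spikes do not re-propagate), which keeps the planted
adjacency directly interpretable for recovery tests; `max_hops`
enables limited cascades. Spikes transmitted past the recording end
are truncated. All randomness descends from one seed through
per-electrode, per-hub and per-edge substreams
(`numpy.random.SeedSequence.spawn`), so output is bit-identical for a
given (spec, seed) regardless of iteration order, and transmission
draws are made for every source spike regardless of `w`, giving a
monotone coupling of transmitted counts in `w`.

A consequence of per-spike transmission worth knowing: a hub's
*background* spikes also relay to its followers, and a single relayed
volley (~9 spikes on ~9 electrodes within 10 ms) already satisfies the
network-burst criterion. The sham presets therefore detect roughly
twice as many small bursts as planted initiations (~450/5 min vs the
217.5 initiation total they plant), with correspondingly smaller mean
spikes per burst. Large-burst rates and hub connection counts land
near the values the presets were calibrated toward (≈ 14/10 min and
≈ 15 mean connections per hub for sham at DIV 21).

### Calcium generator

Each cell is active with probability `active_fraction`. Active cells
receive transients whose times form a refractory renewal process: a
dead time of one transient duration plus two frames, then an
exponential wait with its mean corrected so the overall mean rate
equals the planted events/min. A plain Poisson process was rejected
deliberately: at the sham rate (2.49/min) with 6.2-s transients it
overlaps ~24% of adjacent events, which no detector can unmerge, so the
planted rate would be unrecoverable by construction; the recorded
statistics this generator emulates describe distinct, non-overlapping
oscillations. Rates high enough that the dead time exceeds the target
inter-event interval are rejected as infeasible.

Each transient has an instant rise and exponential decay. Only the
*duration above threshold* is a stated quantity, so the decay constant
is solved from it: `τ_decay = D / ln(amplitude / θ_off)` with
θ_off = 0.05 ΔF/F, equal to the detector's nominal threshold
(2.5 × the nominal ΔF/F noise SD of 0.02 — raw noise SD 2 a.u. on a
baseline of 100 a.u.). Amplitude defaults to 0.6 ΔF/F (≈ 30 σ, a
realistic high-affinity-dye transient); both amplitude and duration are
fixed per preset rather than jittered, so recovered dispersion reflects
only noise and frame quantization. Inactive cells are noise-only; an
optional linear drift checks baseline correction.

### Condition presets

`condition_preset(name)` returns a (NetworkSpec, CalciumSpec) pair per
condition token (sham / chronic Aβ / Aβ + BDNF / 5xFAD crossed with day
in vitro). Calcium presets plant the printed group statistics
(percent active cells, oscillations/min, duration); where a value was
not printed for a group/day, the preset uses the printed same-day
control value or the printed fold-change (e.g. 5xFAD durations are
1.55× / 1.75× the same-day control), documented in the registry source.
MEA presets plant hub counts, transmission probabilities and
initiation totals scaled from the printed small-burst rates
(initiations/5 min = printed bursts/5 min), with the ~2× detection
caveat above. The 5xFAD cohort has no MEA data; its MEA entries are
qualitative Aβ-like stand-ins. Group means are planted as exact
parameters — the generator makes no claim of matching the biological
variance structure, so a green recovery test establishes that the
pipeline measures what was planted, not that the generator reproduces
real recordings.

## Pipeline

`run_pipeline(RunConfig)` simulates (or loads) recordings per group,
runs all three analyses, and writes per-recording tables (TSV/JSON/
GraphML), group-level mean ± SEM tables, and a manifest with SHA-256
checksums; per-recording seeds derive deterministically from the master
seed, so a rerun is byte-identical (floats are serialized with `%.17g`
and re-parsed with round-trip precision). Inferential statistics
across groups (ANOVA, post hoc tests) are deliberately out of scope;
the tidy tables are the interface to external statistics tools.

## Known limitations

* The generator's conditions differ only through planted statistics —
  there is no pharmacology, no development over days in vitro, and no
  biophysical neuron model.
* Burst detection uses fixed bin phase (anchored at t = 0); a burst
  straddling a bin edge can split if its trough-free extent is shorter
  than one bin. No sliding-window or adaptive (ISI-based) detector is
  provided.
* Edge selection is a fixed quantile, not a significance test; see the
  sparse-recording caveat above.
* Calcium durations are threshold-crossing widths; full-width at
  half-maximum or other definitions would give systematically different
  values on the same events.
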