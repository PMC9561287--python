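# Methods

## Kinetic model

One trace is one ribosome in one ZMW well over a 360 s movie. The 30S
pre-initiation complex is present from `t = 0`; the delivery mixture
(quencher-labelled 50S, labelled and suppressor ternary complexes, EF-G)
arrives at `t = 10 s`. After a 50S-joining dwell the ribosome runs one
elongation cycle per codon of the reporter `[Phe, UAG(sup), Phe, Phe, Phe,
Phe]`: a non-rotated phase (ternary-complex arrival plus accommodation at
labelled codons; a single decoding dwell at the unlabelled suppression
codon), a rotated phase, then translocation back to non-rotated. Each
labelled tRNA raises the red-dye count on A-site arrival and lowers it two
cycles later when it leaves the P site.

The chain is semi-Markov with *branch-specific outcome probabilities*, not
competing rates: at the suppression codon the trace decodes with probability
`p_decode_sup` (otherwise it stalls dark-red-state-preserving until movie
end or a green bleach); conditional on decoding it disassembles from the
rotated state with probability `p_pre_dis`; conditional on translocation the
triple `p_post = {continue, disassemble, censor}` applies; codons ≥ 4
continue with `p_continue_late` per codon. Disassembly is 50S dissociation
(dequench to high) with probability `p_mode_50S`, else 70S dissociation
(signal loss). This parameterisation makes the published fractions direct
model parameters, so parameter recovery through the full pipeline is
well-posed; closed forms live in `expected_fractions` and are the oracle for
every Monte-Carlo check.

### Dwell distributions

Dwells are shifted exponentials: `floor + Exp(mean − floor)` with
`dwell_floor = 0.5 s`, preserving the stated mean. Conformational
transitions and substrate binding are not instantaneous, and any detector
with finite dead time (here ~0.3 s: a 5-frame running median plus a 3-frame
minimum dwell at 10 frames/s) would irretrievably censor the mass a pure
exponential puts below it — e.g. 14% of 2 s rotated-state dwells — making
the generator's own branch fractions unrecoverable *by construction* rather
than by noise. The floor keeps every mechanistic dwell at least 5 frames
long while leaving all sample means, and therefore all exponential MLEs,
equal to the preset means.

### Parameter defaults

| parameter | default | units | provenance |
|---|---|---|---|
| `p_decode_sup` | 0.83 (UTu1, UTu1A), 0.72 (supD), 0.95 (Ser) | – | measured / control choice |
| `p_pre_dis` | 0.09 (UTu1 @ 50 nM), else 0 | – | measured / unstated→0 |
| `p_post` UTu1@50 | {0.2308, 0.7033, 0.0659} | – | solves 0.91·x = {0.21, 0.64} |
| `p_post` UTu1@200 | {0.72, 0.256, 0.024} | – | printed 72% survival, 64%/2.5 disassembly |
| `p_post` supD | {0.84, 0.01, 0.15} | – | measured + residual |
| `p_post` UTu1A | {0.75, 0.19, 0.06} | – | printed 75% + split choice |
| `p_continue_late` | 0.95 per codon | – | survival-curve tail shape |
| `p_mode_50S` | 0.5 | – | mode split not published |
| `t_join_mean` | 5 | s | keeps 6 cycles well inside the movie |
| `t_arrival_mean` | 10 · (50 / [TC] in nM) | s | ∝ 1/concentration |
| `t_accom_mean` | 1.0 | s | makes arrival observably precede rotation |
| `t_decode_sup_mean` | 7 / [sup TC] in µM (Ser: 3.5) | s | measured at 1 µM |
| `t_rotated_mean` | 2 | s | EF-G-saturated translocation scale |
| `t_disassembly_mean` | 9 | s | measured |
| `dwell_floor` | 0.5 | s | see above |
| bleach rates | 1e-4 per channel | 1/s | see below |

Bleaching is a *minor censoring mode* by design: at 1e-4/s about 3.5% of
dyes bleach per movie. A much higher rate is untenable here because a green
bleach from the non-rotated state is observationally identical to 70S
dissociation (both are a one-step drop to baseline with no red dye on
board), so every percent of bleach-in-stall leaks directly into the
disassembly statistics; with ~15% of natural-suppressor decoders on the
censored branch, a 0.001/s rate would more than quadruple an expected 1%
post-translocation disassembly fraction.

## Rendering

Ideal signals are piecewise constant per mechanistic interval — green:
high (pre-initiation, 50S-dissociated) 1.0 / medium (rotated) 0.45 / low
(non-rotated, stalled) 0.15 / baseline (70S-dissociated, bleached) 0.0;
red: 0.5 per labelled tRNA, zeroed after the red-bleach time — sampled at 10
frames/s with additive zero-mean Gaussian noise (SD 0.05 per channel, per
frame). Adjacent levels are separated by 3–11 raw noise SDs, so default
detection is accurate but not trivial. No EMCCD gain, shot noise, spectral
crosstalk or drift is modelled. Per-trace randomness derives from a child
stream of `(master_seed, trace_index)`, making datasets byte-reproducible
and individual traces regenerable in isolation.

## Detection

1. **Quantization** — per channel: running median (5 frames); nearest-level
   assignment with a hysteresis deadband (a frame is assigned outright only
   beyond the midpoint toward a level by a quarter of the inter-level gap;
   deadband frames inherit the previous label only if that label bounds
   their deadband); merging of runs shorter than 3 frames into the flanking
   level with the closer center. Level centers default to the emission
   configuration; an optional per-trace 1-D k-means re-fit
   (`estimate_levels`) handles miscalibrated inputs.
2. **Absorbing-terminal cleanup** — disassembly and bleaching are
   irreversible, so a dark (or post-joining dequenched) green run that
   conflicts with later translation-level signal is resolved by relabelling
   the *shorter* of the two conflicting runs: a sub-second dark blink inside
   an active phase, or a noise flicker inside a long dark tail. Without
   this, one sustained ~4-sigma noise excursion per ~10^6 frames creates a
   false irreversible event, and a rare false "disassembly" at a 100–300 s
   dwell moves a mean-based dwell estimate by several tenths of a second.
3. **Grammar parsing** — deterministic mapping of level transitions to
   events (joining, rotation/translocation per codon, arrivals/departures,
   50S dequench, 70S loss, signal loss); inconsistent transitions truncate
   parsing at the last consistent event and flag the remainder anomalous
   (anomalies are data, not exceptions).
4. **Classification** — decoded codons = highest accepted rotation, where
   rotations at labelled codons additionally require a red arrival inside
   that codon's non-rotated window (the suppression codon is scored from
   green alone, its tRNA being dark); disassembly phase is read from the
   state the signature fired from (rotated = pre-translocation, non-rotated
   = post-translocation); the disassembly dwell is measured from the
   preceding translocation.

At zero noise and zero bleach, detected events equal the trajectory-implied
events exactly (boundaries within one frame), for every registered preset —
this oracle equivalence is asserted in the test suite.

## Statistics

- **Survival**: fraction of translating ribosomes (≥ 1 decoded codon)
  reaching each codon; censored traces count up to their last decoded codon;
  conditional survival is the ratio of adjacent fractions.
- **Decoding efficiency**: decoders of codon *k* among decoders of *k−1*,
  with Wilson 95% intervals.
- **Dwells**: exponential MLE (the sample mean) over observed dwells;
  dwells whose event never occurred (movie end first) are simply absent
  rather than survival-weighted — a simplicity/bias trade-off that is
  negligible here because all dwell scales are ≪ the movie length. The
  disassembly-dwell sample is restricted to post-translocation events at the
  suppression codon. Bootstrap 95% intervals use 1000 trace-level resamples
  (percentile method), seeded.
- **Pathway map**: conditional on decoding the suppression codon —
  pre-translocation disassembly, post-translocation disassembly, survival to
  the next codon, censored; fractions over all decoders sum to 1; the
  50S/70S mode split is reported separately.
- **Condition comparison**: per-field fold change with percentile bootstrap
  intervals from trace-level resampling within each cohort; zero
  denominators yield NaN, not errors. Conditions are compared pairwise
  with no multiplicity correction.

## Validation and problem sizes

The recovery suite (`ribotrace.recovery.recovery_suite`, also behind
`ribotrace targets` and `scripts/acceptance.py`) simulates 2000 traces per
condition — 4000 for the natural suppressor, whose disassembly branch is
~1% — and requires each recovered statistic to match its preset-implied
value within max(3 binomial SEs, 2 percentage points) for fractions (1 point
for the rare branch), ±1 s for dwell means and ±0.3 for the concentration
fold change. Property checks use 10^5 trajectories per preset for
Monte-Carlo-vs-closed-form branch fractions (4 SE), 20 000 trajectories
(≥ 10^4 dwells per class) for 5% dwell-MLE recovery, and 100 replicate
cohort pairs of 250 traces for ≥ 90/100 bootstrap-interval coverage of the
true fold change. These sizes make each statistic's sampling error several
times smaller than its tolerance while the full suite runs in a few minutes
on one CPU.

## What the generator does and does not emulate

It emulates the event structure and timing of the two-channel assay —
delivery delay, joining, per-codon rotation cycles, two-cycle labelled-tRNA
occupancy with double/single alternation after the suppression codon, both
disassembly signatures, stalls, photobleaching, movie-end censoring, and
additive camera noise. It does not emulate transient (sub-frame) sampling
of ternary complexes, E-site dwell of deacylated tRNA, dye blinking as a
kinetic process (blink-like artifacts arise only from noise), re-initiation
or multiple ribosomes per well, baseline drift, or spectral crosstalk.
Passing tests therefore demonstrate that the analysis is correct and
well-calibrated *for this class of signals*; real traces with drift,
blinking dyes or crosstalk would need the optional level re-estimation and
additional preprocessing, and detection accuracy there is not certified by
this suite.

## Known limitations

- A green bleach from a dark-compatible state is observationally identical
  to 70S dissociation. At the default bleach rate this adds roughly +0.5 s
  to the recovered disassembly dwell and ~+0.5 points to the rare
  post-translocation disassembly fraction of the natural suppressor; both
  offsets are inside the recovery tolerances and are reported, not
  corrected, because no per-trace discriminator exists.
- Branch probabilities are outcome parameters, not competing hazards; the
  2.5-fold concentration effect is therefore encoded in the 200 nM preset
  rather than emerging from an arrival/disassembly race.
- Dwell MLEs ignore right-censoring (excluded, not survival-weighted).
- The registered UTu1A condition assumes the same suppression efficiency as
  UTu1; published data support similarity but do not quantify it.
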