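# ribotrace

Simulation and analysis of two-color single-molecule ribosome translation
traces with stop-codon suppression.

## The problem

Engineered suppressor tRNAs (for example, allo-tRNAs used for site-specific
selenocysteine insertion at UAG codons) can decode a stop codon efficiently
and yet stall protein synthesis one step later: after the suppressor tRNA is
translocated from the A to the P site, the ribosome may disassemble instead
of decoding the next codon. Zero-mode-waveguide (ZMW) experiments resolve
this codon by codon in real time with two fluorescence channels:

- **green** — Cy3B on the 30S subunit, quenched by BHQ-2 on the 50S subunit.
  High intensity before 50S joining, low in the non-rotated state, medium in
  the rotated state; a return to high signals 50S dissociation (dequenching),
  a drop to baseline signals 70S dissociation or dye loss;
- **red** — Cy5 on tRNA(Phe), reporting labelled-tRNA occupancy at 0, 1 or 2
  units (each tRNA stays on the ribosome for two elongation cycles, A to P to
  E site).

No raw traces for such experiments are generally deposited, so this package
pairs a mechanistic simulator with the analysis pipeline that one would run
on real traces, and validates the pipeline by parameter recovery: the
statistics it reports must reproduce the branch probabilities and dwell-time
means the traces were generated from.

## The model

A ribosome translating the six-codon reporter
`[Phe, UAG(sup), Phe, Phe, Phe, Phe]` is a semi-Markov chain: at each
decision point a branch is drawn from condition-specific probabilities, then
a dwell from a shifted exponential with the branch-specific mean.
Conditional on decoding the suppression codon (probability
`p_decode_sup`), the ribosome disassembles from the rotated state before
translocation with probability `p_pre_dis`; otherwise the post-translocation
triple `{continue, disassemble, censor}` applies. Closed forms follow, e.g.

    P(survive codon 3 | decode codon 2) = (1 − p_pre_dis) · p_continue

which for the allo-tRNA condition at 50 nM labelled ternary complex gives
(1 − 0.09) × 0.2308 ≈ 0.21. Registered conditions: `UTu1` (the 9/3
allo-tRNA, at 50 or 200 nM labelled TC), `supD` (natural amber suppressor),
`UTu1A` (single-base variant of UTu1), `Ser` (sense-codon control).

The analysis front end segments noisy traces into discrete levels (running
median, hysteresis assignment, minimum-dwell merging, absorbing-terminal
blink rejection), parses the level sequence against the signal grammar
(joining, per-codon rotation/translocation, tRNA arrivals/departures,
disassembly signatures), classifies each trace, and computes cohort
statistics: codon survival curves, decoding-efficiency fractions with Wilson
intervals, exponential dwell-time MLEs with bootstrap intervals, pathway
maps, and bootstrap fold-change comparisons between conditions.

## Worked example

```python
import ribotrace as rt

preset = rt.make_preset("UTu1", tc_phe_nM=50, sup_tc_uM=1.0)
cohort = rt.run_condition(preset, n=500, seed=7)   # simulate -> detect -> classify

eff = rt.decoding_efficiency(cohort.outcomes, codon=2)
surv = rt.survival_curve(cohort.outcomes, condition=preset.preset_id)
pm = rt.pathway_map(cohort.outcomes, condition=preset.preset_id)
dis = rt.dwell_summary(cohort.outcomes, "disassembly", seed=0)
```

With the values above this prints:

```
decoding efficiency at the suppression codon: 83.2% (95% CI 79.7-86.2, n=500)
conditional survival at codon 3: 19.7%
of 416 suppression-codon decoders: 10.8% disassembled before translocation,
64.7% after, 19.7% kept translating
disassembly time: 9.8 s (95% CI 8.5-11.4, n=269)
```

i.e. the pipeline recovers, from rendered noisy traces, the preset's 83%
decoding efficiency, 21% codon-3 survival, the 9%/64% pre-/post-translocation
disassembly split and the 9 s disassembly time, within sampling error at
n = 500.

The same workflow is available from the shell:

```sh
ribotrace simulate --preset UTu1 --n 500 --seed 7 --out data/utu1
ribotrace analyze data/utu1 --out reports/utu1 --plot
ribotrace benchmark data/utu1 --out reports/utu1/benchmark.json
ribotrace targets --seed 1            # full parameter-recovery suite
ribotrace show-config                 # all defaults as YAML
```

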