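# fretbind

Single-molecule FRET analysis of polymerase–DNA binding kinetics, built
around the model system of the Y-family translesion polymerase Dpo4 binding
primer-template DNA carrying bulky aromatic-amine adducts (AF-dG and
AAF-dG). The package provides the complete chain used in such experiments —

1. **Trace simulation** — a Gillespie simulator of the binding /
   conformational-shuttling kinetic scheme, rendered into noisy Cy3/Cy5
   per-frame intensities with shot + read noise and one-step donor
   photobleaching, with full ground truth retained;
2. **Trace processing** — photobleach detection and truncation, background
   estimation, apparent FRET `E = I_A / (I_A + I_D)`, validity filtering,
   moving-average smoothing;
3. **Idealization** — a 2-state Gaussian-emission hidden Markov model
   (Baum–Welch + Viterbi, written here) separating unbound (0-FRET) from
   bound epochs;
4. **Histogram decomposition** — frame-weighted bound-state FRET histograms
   fit with one or two Gaussian components (the binding conformations), with
   BIC + separation + dip model selection and molecule-level bootstrap
   uncertainties;
5. **Dwell-time kinetics** — bound-dwell extraction with right-censoring at
   photobleach/trace end and the censored-exponential maximum-likelihood
   dissociation rate, `k_off = n_uncensored / Σ τ`, with bootstrap standard
   errors and survival-curve / KS cross-checks.

Because no raw traces are deposited for this system, every published
quantity is transcribed into a packaged *scenario* (state FRET means,
occupancies, `k_off`) and validated by closed-loop parameter recovery:
simulate → analyze blind → compare with ground truth.

## Worked example

```bash
python analysis/01_simulate_conditions.py   # 6 conditions x 100 molecules
python analysis/02_analyze_conditions.py    # full blind analysis chain
python analysis/03_compare_kinetics.py      # k_off comparison table
python analysis/04_figures.py               # traces + histograms
```

The analysis step prints, per condition, the recovered Gaussian peaks and
dissociation rate next to the simulator truth, e.g.:

```
unmodified_binary:  97/100 molecules, peaks [0.570 (A=0.55), 0.797 (A=0.45)]
                    (truth [0.57, 0.8]), k_off 0.4939 /s (truth 0.52)
unmodified_ternary: 86/100 molecules, peaks [0.601 (A=1.00)]
                    (truth [0.6]),      k_off 0.1279 /s (truth 0.13)
```

Reading: the binary complex (no nucleotide) samples two conformations — the
insertion complex near FRET 0.57 and the preinsertion complex near 0.80 —
recovered here to 0.003 FRET with roughly equal areas (A), while the ternary
complex (with dCTP) collapses to a single state near 0.60. The kinetics
step then reports

```
nucleotide-induced stabilization (unmodified): binary dissociates
3.9 +/- 0.3x faster than ternary
```

i.e. nucleotide binding stabilizes the complex about four-fold
(0.52 → 0.13 s⁻¹), the signature of a catalytically poised ternary complex.

The same works from the command line:

```bash
fretbind simulate unmodified_binary --n 100 --seed 1 --out traces.tsv
fretbind analyze traces.tsv --out results.json --label unmodified_binary
fretbind recover aaf_templating_binary --n 100 --seed 1
```

`fretbind recover` is the one-shot closed loop: it prints PASS/FAIL per
quantity against the scenario truth (±0.03 FRET on peak centers, 10%
relative on rates).

## Scenarios

22 packaged conditions (`fretbind.list_scenarios()`) cover the binary and
ternary complexes on unmodified, AF- and AAF-modified templates with the
adduct at the templating position, across from the primer terminus, and
with terminal A:G / G:G mismatches. Each scenario file records which values
are transcribed measurements (`anchored: true`) and which are documented
placeholders for unprinted quantities (sub-state exchange rates, some area
fractions and binary-complex rates).

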