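# alphasync

Source-space MEG resting-state functional connectivity in the alpha band:
phase-locking-value (PLV) networks compared across three diagnostic groups
— healthy controls (HC), subjective cognitive decline (SCD) and mild
cognitive impairment (MCI) — with a permutation ANCOVA and FDR control.
Because raw clinical MEG cannot be shared, the package ships a synthetic
cohort generator whose connectivity ground truth is known by construction,
so every stage of the analysis is testable end to end.

It is aimed at researchers who analyse resting-state MEG/EEG phase
synchronisation and want a compact, fully reproducible reference
implementation of the complete chain: epoching → individual-alpha-band
filtering → LCMV beamforming → PLV networks → group statistics.

## The analysis

**Band definition.** The individual alpha frequency (IAF) is the most
prominent spectral peak over posterior channels; the analysis band is
anchored to it as (IAF − 2.5 Hz, IAF + 2 Hz). With the sample-average
IAF of 9.4 Hz this gives the 6.9–11.4 Hz band. Epochs (4 s,
artifact-free; subjects need at least 15) are band-passed with an
order-1800 Hanning windowed-sinc FIR at 1 kHz, applied forward and
backward (zero phase) with 2000 samples of padding per side.

**Source reconstruction.** A linearly constrained minimum-variance (LCMV)
beamformer with the epoch-averaged covariance C and leadfield column
l_s per source:

    w_s = (l_sᵀ C⁻¹ l_s)⁻¹ l_sᵀ C⁻¹

(unit gain at the source, minimum variance elsewhere). The forward model
is the analytic single-sphere magnetometer solution.

**Connectivity.** For phases φ_k, φ_l over a T-sample segment,

    PLV_kl = | (1/T) Σ_t exp(−j(φ_k(t) − φ_l(t))) |

with phases from the Hilbert analytic signal (2000-sample padding).
Area-level connectivity averages PLV magnitudes over all cross-area
source pairs; a subject's value averages their segments.

**Statistics.** Per edge, the F statistic for the group factor in
`value ~ group + age` is referred to a permutation null (10,000 label
shuffles preserving group sizes; p = (1 + #{F* ≥ F}) / (1 + P)), with
Benjamini–Hochberg FDR at Q = 0.05 over the edge family, permutation-
corrected Tukey-style pairwise contrasts for surviving edges, Pearson
correlations between edges and neuropsychological scores (joint FDR), and
the same machinery applied to beamformer-weight correlations as a source-
leakage control.

**Synthetic cohorts.** Source phases come from a correlated circular
complex Gaussian field smoothed in time; the closed form
PLV(ρ) = (π/4)·ρ·₂F₁(½, ½; 2; ρ²) maps any feasible target PLV matrix to
a Gaussian correlation matrix exactly. Default cohorts mirror the target
population: 39/41/51 subjects, group ages 70.4/71.6/73.0 years, a 9.4 Hz
alpha carrier, anterior hyper- plus posterior hypo-synchronisation in
SCD/MCI, MMSE/BNT-like scores loaded on coupled edges, and lower
normalized hippocampal volumes in MCI.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # desk-scale cohort -> scratch/
python analysis/02_run_pipeline.py      # full sensor-level pipeline
python analysis/03_effect_recovery.py   # study-size statistical recovery
python analysis/04_leakage_null.py      # leakage diagnostic under the null
```

`analysis/03_effect_recovery.py` generates 40 subjects per group whose
ground truth hyper-couples 3 anterior edges and hypo-couples 14 posterior
edges in SCD/MCI, then runs the full permutation ANCOVA + FDR. It prints:

```
sensitivity: 17/17 true edges discovered
directions:  17/17 discovered true edges with correct sign
false positives: ['CU|FP-L', 'CU|SF-R']

score correlations on the generator's coupled edges:
  FP-L|FP-R  vs MMSE                 r=-0.695 (FDR sig)
  CU|PC      vs MMSE                 r=+0.682 (FDR sig)
  FP-L|FP-R  vs BNT                  r=-0.422 (FDR sig)
  CU|PC      vs BNT                  r=+0.417 (FDR sig)
  CU|PC      vs hippocampal_volume   r=+0.500 (FDR sig)
```

Every ground-truth edge is recovered with the right direction; anterior
synchronisation correlates negatively and posterior synchronisation
positively with cognition, as built into the generator. The command-line
interface (`alphasync generate|run|stats|report|validate`) exposes the
same stages for YAML-configured runs.

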