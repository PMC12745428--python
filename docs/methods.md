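# Methods

This note documents the models, numerical choices and defaults behind
`strokenet`, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Preprocessing

All operations are pure functions of their inputs.

* **Filtering.** Windowed-sinc (Hamming) FIR filters, order from the
  3.3/Δf transition-width heuristic with the transition band set to a
  quarter of the lower edge (clamped to [0.5, 2] Hz) and length capped
  at 10·fs taps. Application is centred FFT convolution of the
  odd-length linear-phase kernel, i.e. zero phase with built-in delay
  compensation, so cue-locked epochs are not shifted. Defaults: 0.1–45
  Hz bandpass and 49–51 Hz bandstop. A 0.1 Hz edge cannot null DC with
  a realizable FIR; DC is attenuated to ≈ 36% (a 1 Hz edge removes it
  essentially completely — both behaviours are pinned by tests).
* **Resampling** uses polyphase anti-aliased resampling
  (`scipy.signal.resample_poly`); event indices are rescaled and
  rounded to the nearest output sample. Default target 500 Hz from a
  1000 Hz acquisition rate.
* **Re-referencing** subtracts the mean of A1/A2 sample-wise and drops
  both reference channels, leaving the 19 network electrodes.
* **Epoching** cuts [−1 s, +4 s) around each cue; the cue sample
  belongs to the action period. Windows that would cross a recording
  boundary are dropped (never padded — padding would bias spectra) and
  counted in the log. Baseline correction subtracts each channel's mean
  over [−1, 0) s.
* **Lateral mirroring** swaps homologous left/right channel rows
  (Fp1↔Fp2, F3↔F4, F7↔F8, C3↔C4, T3↔T4, T5↔T6, P3↔P4, O1↔O2), leaving
  Fz/Cz/Pz untouched. It is applied to right-affected patients so the
  cohort shares one laterality frame; mirroring is an involution and
  commutes with the other preprocessing steps (tested).

Interactive artifact removal (ICA component classification, visual
epoch rejection) is deliberately out of scope: the synthetic data
contain no artifacts, and real-data users can pre-clean externally.

## 2. wPLI connectivity

* **Spectra.** 0.4 s Hann windows over the post-cue action period only
  (0–4 s; the baseline second is excluded — the movement-state network
  is the object of analysis). Default hop 0.2 s (50% overlap). Windows
  are zero-padded to round(fs) samples, which makes the native DFT bins
  land exactly on the 1–30 Hz, 1 Hz analysis grid: an unpadded 0.4 s
  window has 2.5 Hz spacing, so zero-padding is the minimal-assumption
  way to realize a 1 Hz grid.
* **Estimator.** wPLI = |E[Im S_xy]| / E[|Im S_xy|] with the
  expectation pooled over trials and windows (a per-window variant that
  averages window-wise wPLI is available as a switch; the two agree
  closely on coupled data, tested). If every imaginary part is zero the
  estimator returns 0 by convention: a purely instantaneous
  relationship carries no lag information.
* **Bands.** delta 2–4, theta 4–8, alpha 8–13, beta 13–30 Hz, realized
  half-open [lo, hi) on the grid so shared endpoints are not counted
  twice; the top frequency of the highest band (30 Hz) is included.
  Band values are arithmetic means of per-frequency wPLI.
* **Bias.** The wPLI null mean shrinks roughly as 1/√n with the number
  of pooled observations (tested); group designs should therefore hold
  trial counts equal across groups, as the generator does.

## 3. Graphs and metrics

* **Thresholding.** k = round(s·N(N−1)/2) strongest upper-triangle
  weights at sparsity s; ties at the cut broken by lexicographic
  (i, j) order, so thresholding is deterministic. All-zero matrices are
  rejected (no ranking exists). Disconnected results are legal but
  logged.
* **Metrics** follow the standard binary-graph formulas (README §"The
  method") with the conventions: CC_i = 0 and LE contribution 0 for
  nodes of degree < 2 (the formulas divide by k(k−1)); GE counts
  unreachable pairs as 1/∞ = 0; L averages over connected pairs only;
  network means run over all 19 nodes. Shortest paths via BFS
  (`scipy.sparse.csgraph`); degree, CC, GE, LE and L are verified
  exactly against an exhaustive path-enumeration oracle on all 143
  connected graphs with ≤ 6 nodes.
* **Random reference.** Degree-preserving double-edge-swap rewiring
  (networkx), 10·|E| attempted swaps per realization, default 100
  realizations (seeded). A graph that admits no swap (complete graph)
  is its own reference, with a warning, making SW = 1 there. GE is
  monotone non-decreasing across nested sparsity levels and is tested
  as such; mean CC is *not* monotone under edge addition in general
  (attaching a pendant edge to a triangle lowers the mean), so no such
  test is asserted.
* **Aggregation.** Each metric is computed at the seven levels
  0.17…0.47 and averaged (equivalent to area-under-curve for evenly
  spaced levels); per-level values are kept in the output so analyses
  can also be run per level.

## 4. Statistics

* Normality gating is per comparison: both groups must pass
  Shapiro–Wilk at the gate level (default 0.05) for the pooled-variance
  t-test; otherwise Mann–Whitney U (two-sided, U of the first sample).
  Samples on which Shapiro–Wilk is undefined (constant, n < 3) route to
  the rank test rather than erroring, so degenerate cohorts remain
  processable. Wilcoxon signed-rank is not implemented: it applies to
  paired designs, and this design has none.
* Cohen's d always uses the pooled SD over n₁+n₂−2 df and satisfies
  d = t·√(1/n₁+1/n₂) exactly on any two samples (tested to 1e-10).
* BH-FDR is applied across the full metric × task × band grid of one
  run by default (per-task families via a flag); adjusted p-values are
  monotone and capped at 1.
* Spearman correlation with MAS uses midrank ties and the t-based
  two-sided p; an exact permutation p is available for n ≤ 9. MAS
  coding 0/1/1+/2 → 0/1/1.5/2 (conventional midpoint coding for the
  1+ grade). Which MAS column is used (upper limb vs. hand) is
  configurable; upper limb is the default.

## 5. The synthetic world

The generator produces what the estimators must measure, under the
conditions that make the measurement hard:

* **Trial structure.** Default 20 trials per task and three tasks
  (fist, elbow, wrist), 5 s epochs (1 s pre + 4 s post cue) at 1000 Hz,
  matching the acquisition design the package targets. The inter-trial
  gap defaults to 2 s (the clinical protocol's 10 s rest exists to
  avoid fatigue, not for analysis; epoching discards it, and 2 s keeps
  synthetic recordings tractable).
* **Coupling.** Per band, a set of (source, target, lag, strength)
  pairs: the source carries a unit-amplitude carrier whose phase is
  re-drawn uniformly each trial block; the target receives the copy
  delayed by the fixed lag and scaled by the strength. The lag's
  constancy across trials is exactly what wPLI detects; the per-trial
  jitter cancels trial-averaged zero-lag terms. Lags avoid 0/π, where
  Im S and hence wPLI vanish.
* **Default topology.** A global hub (Cz) at the band's centre carrier
  (alpha 10 Hz, beta 20 Hz) drives all 18 other electrodes with
  near-quadrature, narrowly spread lags: its star is the strongest edge
  tier and keeps the intact network efficient (all pairs within two
  hops). Three regional cores — frontal (Fz, F3, F4), central
  (C3, C4, T3), posterior (Pz, P3, P4) — hold sources at distinct
  flanking carriers (alpha 8/11/12 Hz, beta 15/24/27 Hz) at strength
  0.5, coupling each region internally (core triangles and core-leaf
  fans), which carries the clustering of the intact network. Distinct
  carriers keep tiers spectrally orthogonal on the 1 Hz grid. Only
  alpha and beta carry coupling by default; delta and theta are noise.
* **Noise and volume conduction.** White Gaussian sensor noise, default
  SD 7 relative to the unit carrier: a deliberately low single-trial
  SNR (≈ −17 dB broadband), the regime in which trial-averaged phase
  estimators are actually used. Zero-lag mixing is symmetric
  nearest-neighbour smoothing over the 10–20 grid
  (I + m·A/deg_max, default m = 0.2), a cheap stand-in for
  instantaneous volume conduction; it must not (and, tested, does not)
  raise wPLI above its null envelope. Pink noise and realistic
  leadfields are intentionally absent — a green test establishes
  estimator behaviour under stationary noise and instantaneous mixing,
  not performance on real EEG.
* **Patient effect.** Every patient's coupling strengths are multiplied
  by a factor ≤ 1 centred on `patient_attenuation` (default 0.3), with
  ±10% relative spread (the clinical inclusion band MAS 1–2 is narrow,
  so between-patient heterogeneity is modest). At attenuation 1 the
  jitter vanishes identically, so null cohorts are exactly
  exchangeable with controls. MAS grades are assigned by ranking
  patients by attenuation and grading by quartile (0, 1, 1+, 2), making
  severity monotone in the true effect by construction; hand MAS is the
  upper-limb grade with a ±1-step seeded jitter. One eighth of patients
  (rounded) is right-affected; their coupling topography is mirrored,
  which the preprocessing mirroring folds back.
* **Why the effect has the direction it does.** At fixed sparsity, a
  noise-ranked (random) graph is near-maximally efficient, so a *lower*
  patient GE is only obtainable if the intact network is itself
  hub-dominated (paths ≤ 2 via the star, GE at the density ceiling
  0.5 + m/342) while the attenuated network degrades toward random.
  Clustering works the other way: random graphs have CC near the edge
  density, far below the intact network's clique-driven CC. The
  two-tier topology was designed around these two facts; with it, the
  scaled validation configuration recovers patient < control in GE and
  CC in ≥ 80% of replicate cohorts at attenuation 0.3 (computed by
  `tests/test_acceptance.py`), while null cohorts stay at the nominal
  FDR level.

## 6. Scaled validation configuration

End-to-end recovery and type-I checks
(`strokenet.validation.scaled_cohort_comparison`) run one task, alpha
band only, 14 trials per subject at 250 Hz, a 0.1 s STFT hop, and no
small-world metric, with 8 subjects per group. Rationale: 250 Hz and
one task cut compute ~12×; 14 trials sits near the power optimum —
with many more trials the estimator begins to resolve the patients'
weak-but-real residual coupling, restoring their network structure and
*shrinking* the group contrast, while with many fewer both groups drown
in ranking noise; the denser hop partially compensates the reduced
trial count with more (overlapping) windows per epoch. Small-worldness
is validated separately on Watts–Strogatz graphs because its random
references dominate runtime without adding information about recovery.

## 7. Reproducibility

One master seed per run; per-stage child seeds are drawn from a
`numpy` generator seeded with it, and every stochastic routine takes an
explicit seed. Identical config + seed reproduces every artifact byte
for byte (tested, including all per-subject connectivity CSVs). The
run manifest records the config hash, stage seeds and library versions.

## 8. Known limitations

* Sensor-level analysis only; no source localization, no leadfield.
* The generator's oscillators are strictly sinusoidal and stationary
  within a trial; real EEG rhythms are bursty and non-stationary.
* Binary graphs only (per the analysis design); no weighted-graph
  metric variants, no community detection.
* The Mann–Whitney branch reports no degrees of freedom; Cohen's d is
  still reported from pooled SDs, which is conventional but
  rank-test-inconsistent for heavy-tailed data.
* EDF input/output is not implemented (no EDF library is available in
  the supported environment); recordings travel as labelled CSV
  matrices with an events side-car.
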