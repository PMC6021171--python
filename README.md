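# plugdyn

Single-molecule FRET analysis of SecYEG translocon plug dynamics.

The SecY channel is sealed by a short "plug" helix. Labelling the plug
(SecY M63) and a cytoplasmic reference (K106) with a donor/acceptor pair
makes its position read out as a FRET efficiency: E ≈ 0.4 with the channel
closed, E ≈ 0.2 open. `plugdyn` implements the complete analysis chain used
to turn two kinds of raw single-molecule recordings into kinetic numbers:

* **µsALEX confocal photon streams** (freely diffusing proteoliposomes,
  40 µs alternating laser excitation) — time-dependent background
  estimation, dual-channel burst search (DCBS) in sliding-window mode,
  stoichiometry filtering (0.25 ≤ S ≤ 0.75), **recurrence analysis of
  single particles (RASP)** for millisecond two-state kinetics, and
  **burst variance analysis (BVA)** for within-burst dynamics.
* **msALEX TIRF intensity traces** (immobilised complexes, 100 ms cyan /
  100 ms orange excitation) — per-frame E/S, quality control
  (stoichiometry, donor/acceptor anticorrelation, single-step
  photobleaching), two-state hidden-Markov segmentation into open/closed
  dwells, photobleaching-corrected dwell statistics, and the
  dwell-vs-substrate-length regression whose inverse slope is the
  intrinsic translocation rate (aa/s).

A first-class synthetic-data module generates both data types with known
ground truth (Brownian diffusion through a 3D-Gaussian confocal volume,
continuous-time Markov state switching, ALEX slot structure, Poisson
background; gamma open dwells with mean `offset + L/rate`, exponential
closed dwells and photobleaching), so every stage of the pipeline is
verifiable end to end. A dye accessible-volume module predicts E
distributions from structural models (Monte Carlo AV with steric-clash and
linker-reach tests, Förster conversion at R₀ = 6 nm).

## The models in brief

**RASP.** At high dilution a burst detected shortly after a previous one is
the *same* molecule returning to the focus. With P_same(τ) = 1 − 1/g(τ)
from the burst-time autocorrelation g, the state-A fraction of second
bursts relaxes as

    pA(τ) = P_same·pA_recur + (1 − P_same)·pA_new,
    pA_recur = (1 + ε(1/ρA − 1))⁻¹,
    ρA(τ) = ρA_eq + (ρA(0) − ρA_eq)·e^(−λτ),

where λ = k_open + k_close. The fit yields λ and ρA_eq, hence
τ_open = 1/(λ·ρA_eq) and τ_close = 1/(λ·(1 − ρA_eq)).

**BVA.** Bursts are cut into n-photon sub-bursts; for a static molecule the
sub-burst proximity ratio has SD √(E_p(1−E_p)/n). Monte Carlo replicas of
each proximity-ratio bin's exact window structure give an upper-tail
threshold (α = 0.001); bins whose empirical SD exceed it are dynamic.

**Dwell kinetics.** Photobleaching right-censors dwells
(P_measured ∝ P_estimate·S_photobleach); `plugdyn` reconstructs the
uncensored law by censored-gamma reconvolution and, for the length
regression, weights each dwell by its inverse probability of surviving
photobleaching. Ordinary least squares of all corrected open dwells
against substrate length gives slope (s/aa), intercept (s) and
rate = 1/slope (aa/s).

## Worked example

```python
from plugdyn import run_tirf_pipeline

report = run_tirf_pipeline({
    "seed": 1,
    "tirf": {"offset_s": 4.7, "n_traces": [200, 250, 300, 450]},
})
print(f"rate      {report['rate_aa_per_s']:.1f} ± {report['rate_se']:.1f} aa/s")
print(f"intercept {report['intercept_s']:.2f} ± {report['intercept_se']:.2f} s")
```

prints (simulating ~1200 TIRF traces at substrate lengths 100/233/354/683
aa, then running QC, HMM segmentation and the corrected regression):

```
rate      40.4 ± 2.6 aa/s
intercept 4.17 ± 0.44 s
```

i.e. the pipeline recovers the generator's ground truth (39.6 aa/s
intrinsic translocation rate with a 4.7 s length-independent offset) within
its standard errors. The analogous confocal pipeline
(`run_confocal_pipeline`) reports λ, ρA_eq and the opening/closing time
constants with bootstrap confidence intervals.

A thin CLI wraps the same functions:

```bash
plugdyn simulate confocal --seed 1 --out stream.h5
plugdyn bursts --in stream.h5 --m 10 --F 6 --out bursts.tsv
plugdyn rasp --bursts bursts.tsv --e1 0.0:0.25 --out rasp.json
plugdyn tirf --traces traces.tsv --out dwells.tsv
plugdyn rate --dwells dwells.tsv --out rate.json
plugdyn av --structure model.pdb --site A:63:CB --site2 A:106:CB --out av.tsv
```

## Layout

| module | contents |
| --- | --- |
| `plugdyn.synthetic` | ground-truth generators (confocal streams, TIRF traces, ATP/temperature series) |
| `plugdyn.bursts` | photon-HDF5-style I/O, background, DCBS, E/S, S-filter |
| `plugdyn.rasp` | P_same, recurrence pairs/histograms, 2D transition densities, kinetic / ATP / Arrhenius fits |
| `plugdyn.bva` | sub-burst partitioning, shot-noise reference, MC thresholds |
| `plugdyn.tirf` | trace I/O, E/S, QC, HMM segmentation, orientation correction, mixture fits |
| `plugdyn.dwells` | photobleaching PDF, dwell deconvolution, gamma fits, length regression |
| `plugdyn.dye_av` | structure loading, accessible volumes, distance → E prediction |
| `plugdyn.workflow` | YAML-configured end-to-end pipelines |
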