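# nanoquant

Quantification pipelines for the imaging modalities used to characterize
protein-driven DNA compaction and oligomerization at the single-molecule
scale, with matched synthetic-data generators for end-to-end validation.

Who it is for: researchers quantifying single-molecule fluorescence movies,
AFM height maps, fluorescence-fluctuation (Number & Brightness) stacks,
frequency-domain FLIM images or EMSA gels, who want the bespoke analysis
steps of such studies as a tested, reusable Python library.

## What it computes

| module | measurement |
|---|---|
| `nanoquant.compaction` | DNA-compaction lag time and time constant τ from tethered-DNA movies, by cluster-intensity analysis (fit of `I(t) = baseline + A(1 − e^{−(t−onset)/τ})`) and by intensity-fluctuation analysis (Savitzky-Golay-smoothed adjacent-frame variance decay); cluster size in bp via normalization to the 48.5-kbp λ-DNA signal |
| `nanoquant.afm` | DNA contour length (skeletonization, quasi-Euclidean metric), grain volumes (Σ height × pixel area), monomer/dimer two-Gaussian mixture, cluster calling at `μ_dimer + 7σ_dimer` (>99.9% confidence), binding density per 100 nm DNA |
| `nanoquant.nb` | per-pixel apparent brightness B = variance/mean with `B = ε + 1` for a photon-counting detector; cursor classification at B = 1.15 / 1.30 / 1.60 (monomer / dimer / oligomer for ε_monomer = 0.15) |
| `nanoquant.flim` | phasor transform `g + is = Σc e^{iωt}/Σc`, fluorescein (4.04 ns) calibration, two-species linear unmixing, FRET-efficiency assignment along the quenched-donor trajectory `τ_D(1 − E)`, IF-guided mask ratios of FRET-positive (compact-chromatin) fractions |
| `nanoquant.gel` | EMSA percent bound = 100·bound/(bound+unbound) per lane box, competition-uptake curves |
| `nanoquant.simulate` | generators for all five input classes, each returning a `GroundTruthManifest` sufficient to predict the analysis output |

The scientific background and every numerical choice are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```bash
python examples/compaction_kinetics.py
```

```
movie: 160 frames, injection at t = 10 s
lag time        : 31.0 s   (truth 30 s)
compaction tau  : 19.69 s  (truth 20 s, R^2 = 0.9990)
final cluster   : 48.0 kbp of the 48.5-kbp genome
fluctuation tau : 20.48 s  (same kinetics, variance read-out)
```

A tethered λ-DNA molecule is simulated with a 30-s lag and a 20-s
compaction time under Poisson noise.  The cluster-intensity analysis
reverse-tracks the cluster ROI, detects the onset one frame after the true
lag, and fits τ within 2%; the cluster at the end holds essentially the
whole 48.5-kbp genome.  The independent fluctuation analysis — variance of
the DNA signal between adjacent frames, which decays as the molecule is
immobilized — recovers the same time constant.

One script per capability lives in `examples/`:
`compaction_kinetics.py`, `afm_morphometrics.py`, `nb_oligomers.py`,
`flim_phasor_fret.py`, `gel_densitometry.py`.  Each builds a small
synthetic input, runs the pipeline and prints the numbers with a line on
what they mean.

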