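# mirspot

Single-molecule fluorescence spot counting for displacement-probe miRNA
assays, with a physics-based synthetic-movie generator for validating the
whole analysis chain against exact ground truth.

## The assay

A Cy5-labelled capture probe (probe 1) is anchored on a passivated coverslip
and pre-hybridized with a shorter quencher-labelled strand (probe 2), which
switches the dye off. A target miRNA (miR-126 in the reference configuration)
binds probe 1 more tightly than probe 2 does, displaces it, and switches the
dye back on. Wide-field EMCCD imaging then shows one diffraction-limited spot
per captured target, and the target abundance is read out by counting spots:
10 regions per sample, 30 frames of 100 ms each per region. Every counted
spot is vetted by its photobleaching trace — a single fluorophore bleaches in
one downward step (a one-level trace), whereas co-located fluorophores
produce a multi-level staircase and are excluded.

The mean accepted count N per region is linear in the decadic log of the
target concentration,

    N = a · log10(C / pM) + b,

and analogously in log10(cell number) for cellular extracts. The limit of
detection is the concentration where the calibration line crosses the blank
mean + 3 SD; selectivity is the fold ratio of mean counts between the
perfect-match target and a mismatched species.

## What is in the package

| module | role |
| --- | --- |
| `mirspot.binding` | competitive displacement isotherm and pseudo-first-order kinetics → fluorescent emitter density |
| `mirspot.simulate` | Poisson emitter fields, pixel-integrated Gaussian PSF, stochastic photobleaching, EMCCD noise chain; exact ground truth |
| `mirspot.detect` | DoG band-pass + robust threshold + local-maxima spot detection with sub-pixel centroids; truth matching |
| `mirspot.traces` | aperture photometry, penalized binary-segmentation step fitting, one-level single-molecule filter |
| `mirspot.quantify` | region counts, log-linear calibration (OLS), LOD, selectivity folds |
| `mirspot.experiments` | end-to-end experiment templates (calibration / selectivity / cell series) incl. the counting-efficiency forward model |
| `mirspot.pipeline`, `mirspot.cli` | YAML run configs, TIFF/CSV/JSON I/O, scenario presets, `mirspot` command |

The numbered scripts under `analysis/` run the four study analyses (surface
controls, concentration calibration + LOD, selectivity, cell lines) and write
their tables under `results/`.

## Worked example

```sh
python analysis/02_concentration_calibration.py --seed 0
```

```
replicate 0: N = 110.47·log10(C/pM) + 120.84  (R² = 1.0000)
      0.1 pM:    10.8 ± 3.0 spots/region
        1 pM:   120.1 ± 11.4 spots/region
       10 pM:   231.5 ± 13.1 spots/region
      100 pM:   341.9 ± 12.7 spots/region

blank: 3.20 ± 1.99 spots/region
LOD (calibration line crosses blank mean + 3 SD (9.167 counts); extrapolated below the fitted range): 97.5 fM
```

The simulator was configured so that the *expected* accepted count at each
concentration sits on the response line N = 111.21·log10(C/pM) + 120.84; the
full pipeline (simulate → detect → trace-filter → count → fit) recovers a
slope of 110.5 counts/decade and the configured intercept from the noisy
movies, i.e. the counting chain is accurate to ~1% here. The LOD line shows
where the fitted line crosses this blank's +3 SD threshold — with this
synthetic blank, some tens of fM.

The scenario presets reproduce the surface-chemistry controls:

```sh
python analysis/01_control_scenarios.py --seed 0
```

```
fig1a_probe1_only            mean   275.8 ± 10.6 accepted spots/region
fig1b_quenched               mean     4.0 ± 2.6 accepted spots/region
fig1c_target                 mean   107.1 ± 10.0 accepted spots/region
fig1d_no_streptavidin        mean     4.0 ± 2.6 accepted spots/region
```

— quenching removes ~98.5% of probe-1 spots, 10 pM target restores a large
count, and without the streptavidin anchor almost nothing sticks.

The same stages are scriptable through the CLI (`mirspot scenario`,
`mirspot simulate`, `mirspot analyze`, `mirspot calibrate`,
`mirspot selectivity`), all driven by one YAML config with per-stage
sections.

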