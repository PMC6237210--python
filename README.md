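# osteodyn

Quantitative analysis of mature-osteoclast dynamics in intravital-style
two-photon time-lapse images, together with a synthetic movie generator
that makes every stage of the pipeline testable without microscope data.

Bisphosphonates (risedronate, alendronate, minodronate) act on
bone-resorbing osteoclasts within hours of injection: the cells stop
secreting protons onto the bone surface and start moving. Intravital
imaging captures this with two readouts, both implemented here:

- **Cell deformation index.** For one tracked cell, compare its binarized
  footprint at the start and end of a 5-minute window and split the pixels
  into three areas — *A* (initial frame only), *B* (overlap), *C* (final
  frame only). The index is **(A + C)/(A + B)**: 0 for a perfectly static
  cell, larger for stronger shape change or displacement.
- **Bone-resorbing index.** A pH-sensing probe fluoresces in the acidic
  resorption pits beneath active osteoclasts. The index is the ratio of
  mean probe intensity inside binarized osteoclast areas (signal) to the
  mean outside (noise); ≈ 1 means no detectable acidification.

The package covers the full chain: synthetic multi-channel movie
simulation with ground truth (`osteodyn.simulate`), removal of a known
autofluorescence component by per-pixel nonnegative least-squares spectral
unmixing (`osteodyn.unmix`), Otsu thresholding / component extraction and
overlap-based cell tracking (`osteodyn.segment`), the two indices
(`osteodyn.deformation`, `osteodyn.resorption`), mean ± SD summaries with
two-tailed t tests (`osteodyn.stats`), and an end-to-end driver with a
reproducibility manifest (`osteodyn.pipeline`, CLI `osteodyn`).

## Worked example

Run the seven-condition battery (untreated plus three drugs at 12 h and
24 h, three movies per group at a reduced 256×256 / 8-frame geometry):

```sh
python analysis/03_run_battery.py
```

which prints, among other rows (mean ± SD over 3 movies per group):

```
           metric     group  n     mean       sd
resorption_index  untreated  3  5.6406   0.1004
resorption_index    ris_12h  3  1.2809   0.0463
resorption_index    aln_12h  3  1.3083   0.0205
resorption_index   mino_12h  3  1.2935   0.0169
deformation_index untreated  3  0.1184   0.0118
deformation_index   ris_12h  3  0.7468   0.0198
deformation_index   aln_12h  3  0.5143   0.0883
deformation_index  mino_12h  3  0.2017   0.0066
```

Untreated movies show a bone-resorbing index far above 1 (active
acidification) and near-static cells; at 12 h after any of the three drugs
the resorbing index collapses toward 1 (all two-tailed Welch t tests vs
untreated p < 0.05), while the deformation index rises — most strongly for
risedronate, less for alendronate, and for minodronate not until the 24 h
condition (0.60 at 24 h vs 0.20 at 12 h). Other drivers:
`analysis/01_simulate_movies.py` (write the condition movies as OME-TIFF),
`analysis/02_unmixing_check.py` (spectral round trip), and
`analysis/04_figures.py` (bar charts).

The same steps are available as a CLI:

```sh
osteodyn simulate --condition ris_12h --seed 1 --out stack.ome.tif
osteodyn segment stack.ome.tif --out tracks.csv
osteodyn analyze stack.ome.tif --out-dir results/ris_12h
osteodyn run --seed 1 --out-dir results/run
```

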