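# haircelltox

Quantitative analysis of acute versus delayed aminoglycoside-induced
hair-cell death in the zebrafish lateral line.

Aminoglycoside antibiotics (neomycin, gentamicin, G418) kill the
mechanosensory hair cells of the fish lateral line — some within an hour
of exposure ("acute" death), some over the following day after the drug
is washed out ("delayed" death). Distinguishing the two regimes takes a
chain of quantitative steps, and this package implements that chain as a
tested library for researchers working with neuromast imaging and
ototoxicity count data:

* **3-D segmentation** of the neuromast body, individual hair cells
  (Sauvola local threshold + seeded watershed) and AG-carrying
  endolysosomal vesicles (multi-scale dot + filament detectors), with
  exact cytoplasm/vesicle mask algebra;
* **accumulation statistics** — per-vesicle property tables, vesicles /
  volume / fluorescence per hair cell, and the vesicle-to-cytoplasm AG
  enrichment ratio;
* **calcium-transient analysis** — F/F₀ against a pre-exposure baseline,
  the 2-standard-deviation responder rule, fragmentation-endpoint
  alignment, and responder/maxima condition statistics (Pearson
  chi-square, Kruskal–Wallis with Dunn's post-hoc);
* **dose–response analysis** — survival normalized to untreated controls,
  the Hill model S(d) = 100 / (1 + (d/HC50)^h) fitted on log dose with a
  principled "HC50 not determined" outcome for shallow kill curves, plus
  washout time-course and protection-experiment ANOVA;
* **a synthetic-data module** that generates image phantoms, calcium
  traces and per-fish count tables with known ground truth, so the whole
  pipeline is testable without any acquisition.

## Layout

```
src/haircelltox/     library: synthetic_data, io, imaging, segmentation,
                     quantification, calcium, dose_response, pipeline
analysis/            numbered drivers reproducing the study's analyses
results/             tables the drivers write
docs/methods.md      models, parameter choices, limitations
scripts/acceptance.py  headline-number reproduction (below)
```

## Worked example

Segment a synthetic neuromast and quantify AG accumulation:

```python
from haircelltox.pipeline import benchmark_params, run_segmentation
from haircelltox.synthetic_data import StackPhantomParams, gen_neuromast_stack

stack, truth = gen_neuromast_stack(StackPhantomParams(seed=1, snr=30.0,
                                                      diffuse_fraction=0.1))
res = run_segmentation(stack, truth.seeds, benchmark_params())
s = res.summary
print(f"{s.n_cells} cells, {s.n_vesicles} vesicles "
      f"({len(truth.vesicle_table)} in ground truth)")
print(f"vesicles per hair cell: {s.vesicles_per_cell_mean:.2f}")
print(f"vesicle/cytoplasm AG ratio: {s.ratio_vesicle_to_cytoplasm:.1f}")
```

prints

```
12 cells, 58 vesicles (58 in ground truth)
vesicles per hair cell: 4.83
vesicle/cytoplasm AG ratio: 737.4
```

— all 58 ground-truth vesicles recovered; the large enrichment ratio
reflects a punctate (G418-like) AG distribution, where nearly all drug
sits in the small endolysosomal volume. Running the same chain on a
diffuse (neomycin-like) phantom (`diffuse_fraction=0.6`) drops the ratio
by an order of magnitude — the signature separating the two uptake
regimes.

Fit an HC50 from per-fish counts:

```python
from haircelltox.dose_response import fit_hill, normalize_survival
from haircelltox.synthetic_data import CountPhantomParams, gen_doseresponse_counts

counts = gen_doseresponse_counts(CountPhantomParams(true_hc50_um=44.0, seed=0))
fit = fit_hill(normalize_survival(counts), n_boot=200, seed=1)
print(f"HC50 = {fit.hc50_um:.1f} ± {fit.se_hc50:.1f} uM, slope {fit.hill_slope:.2f}")
```

prints `HC50 = 45.2 ± 2.4 uM, slope 1.70`.

The numbered scripts under `analysis/` run the full study-shaped
analyses (phantom simulation, segmentation + GPN comparison, calcium
condition statistics, HC50 recovery across treatment paradigms,
time-course and protection ANOVA) and write their tables to `results/`.

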