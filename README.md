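# cllscreen

Analysis pipeline for ex vivo drug-sensitivity screens of chronic
lymphocytic leukemia (CLL) samples — the functional-precision-medicine
workflow in which a patient's tumor cells are exposed to a drug library on
384-well plates and each compound's concentration–response curve is
condensed into a single drug sensitivity score (DSS). The package covers:

- **Plate I/O and normalization** — plate maps, raw luminescence (long or
  16×24 matrix CSV), drug libraries with log10-spaced dose series; percent
  viability anchored on the vehicle (0.1% DMSO, 100%) and full-kill
  (benzethonium chloride, 0%) controls of each plate.
- **Quality control** — the Z′-factor
  `Z' = 1 − 3(σ_pos + σ_neg)/|μ_neg − μ_pos|` per plate, with the
  conventional ≥ 0.5 pass gate.
- **Dose–response fitting and scoring** — bounded least-squares fits of the
  four-parameter logistic
  `v(x) = bottom + (top − bottom)/(1 + 10^(slope·(x − log EC50)))` on the
  log10-dose axis, and the DSS family (DSS1/DSS2/DSS3 plus the modified
  DSS3, the default): normalized area of excess inhibition over the tested
  window, with an activity threshold at 10% inhibition, a cap at 10%
  residual viability, and a width factor from the activity onset. Higher
  score ⇒ higher sensitivity.
- **Serial-sample comparison** — aligned DSS matrices across time-points
  (T0, T1, …) with deltas against a baseline draw, for tracking acquired
  resistance and its reversal after therapy stop.
- **Phospho-flow statistics** — arcsinh ratios of marker medians relative
  to an isotype/unstimulated reference
  (`asinh(s/cofactor) − asinh(r/cofactor)`, cofactor 150 by default),
  integer percent-changes between time-points, and Ward/Manhattan
  hierarchical ordering for heatmaps.
- **Synthetic screens** — a seeded generator producing plate maps, raw
  plates, libraries and ground-truth tables with the standard design
  (94 single agents + 87 fixed-molar combinations, five ten-fold doses,
  1–10,000 nM), so every stage is testable end to end.

## Worked example

```python
from cllscreen import DEFAULT_SERIES, dss, fit_4pl, logistic4

viability = logistic4(DEFAULT_SERIES.log10_values, 100, 0, 2, 1)
fit = fit_4pl(DEFAULT_SERIES, viability)
res = dss(fit, DEFAULT_SERIES)
```

Running `python examples/fit_dose_response.py` (the same computation)
prints:

```
doses (nM):      ['1', '10', '100', '1000', '10000']
viability (%):   ['99.01', '90.91', '50.00', '9.09', '0.99']
recovered: top=100.00% bottom=-0.00% EC50=100.0 nM slope=1.00 rmse=4.1e-15
mDSS3 = 32.82  (activity onset x1 = 1.05, viability-10% crossing x2 = 2.95 in log10 nM)
```

A compound crossing 50% viability at 100 nM scores 32.8 of a possible
~88.9 at the default windows; the fit recovers the generating parameters
exactly on noiseless data. The other scripts in `examples/` walk through a
full 181-entry screen (`score_screen.py`, including per-plate Z′ and the
score-vs-true-potency Spearman of 0.988 at seed 42), serial screens with an
injected 10× potency loss (`serial_resistance.py`, a −27.8 point delta for
the drifted entry), and longitudinal marker shifts
(`phosphoflow_markers.py`, e.g. Bcl-2 (pS70) rising from arcsinh ratio 0.28
to 1.97 = 704%).

A thin CLI mirrors the library for shell use:

```sh
cllscreen simulate --seed 42 --out-dir screen/
cllscreen score --library screen/library.tsv \
    --platemap screen/plate_1.map.csv --plates screen/plate_1.csv ... \
    --metric mdss3 --out dss.tsv
cllscreen flow --medians medians.csv --reference ref.csv --out ratios.tsv
```

## Layout

- `src/cllscreen/plates.py` — plate/library/readout data model and I/O
- `src/cllscreen/qc.py` — control summaries, Z′, viability normalization
- `src/cllscreen/doseresponse.py` — 4PL fitting and the DSS family
- `src/cllscreen/phosphoflow.py` — arcsinh ratios, percent changes, clustering
- `src/cllscreen/simulate.py` — synthetic screens and serial samples
- `src/cllscreen/pipeline.py` — orchestration and screen comparison
- `src/cllscreen/cli.py` — `cllscreen` subcommands
- `docs/methods.md` — model, assumptions, parameter choices, limitations
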