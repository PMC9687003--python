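# psboundary

Quantitative analysis of **parasegmental compartment boundaries (PSBs)** in
the early *Drosophila* germband, built as a reusable Python library driven
end-to-end by a synthetic-embryo generator — no raw microscopy data is
required to run, test or extend any part of it.

During germband extension (GBE), the columns of cell–cell interfaces that
separate adjacent parasegments stay straight and aligned with the
dorsoventral (DV) axis, while neighbouring "control" interface columns do
not.  This package implements the analyses used to quantify that behaviour:

* **Synthetic embryo generator** — a tracked honeycomb epithelium with
  ground-truth parasegment identities, stripe parity and interface classes
  (PSB / −1 / +1 / other), plus transcription-dot movies, interface line
  traces with a planted enrichment factor, and screen fixture tables.
* **Dot tracking** — intensity-threshold detection of nuclear reporter dots,
  greedy nearest-neighbour tracking, point-in-polygon assignment to cells,
  expressing-cell classification, stripe-parity calls from dot brightness,
  and AP-position kymographs.
* **Boundary identification** — parasegment labelling from expressing-cell
  stripes (PSBs at the anterior border of each stripe), classification of
  PSB and −1/+1 control interface columns, and label propagation through
  tracked time.
* **Co-alignment statistics** — interface orientations θ ∈ [0°, 180°) are
  reflected about 90°; co-alignment is the proportion of interfaces with
  reflected angle in [60°, 90°].  Per-minute proportions over the −10 to
  50 min window are smoothed with LOESS (span 0.75, 95% band) and conditions
  are compared with two-sample Kolmogorov–Smirnov tests at t = 30 min.
* **Fixed-embryo quantification** — straightness index S = chord/arc of a
  traced boundary, and Myosin II enrichment
  R = log₁₀[(PSB − bg) / (control − bg)], with each trace's background
  taken as the mean of its dimmest 20% of pixels and division-flagged
  boundaries excluded.
* **In-silico screen** — gene-symbol standardisation through an alias table,
  exact three-way criterion intersection (striped ∩ surface ∩ pair-rule
  regulated), a strict <5% early-expression filter (0–6 h as a fraction of
  0–24 h embryonic expression; equality keeps), and a fully recorded
  exclusion ledger.

## Worked example

```sh
python examples/03_boundary_coalignment.py
```

```
beta = 0.9 (wild-type-like)
     psb: proportion > 60 deg at t=30 = 1.00 (LOESS fit 1.00)
  minus1: proportion > 60 deg at t=30 = 0.33 (LOESS fit 0.43)
   plus1: proportion > 60 deg at t=30 = 0.25 (LOESS fit 0.44)
  KS psb vs minus1 at 30 min: D = 0.85, p = 9.96e-50 [***]
  KS psb vs plus1 at 30 min: D = 0.80, p = 7.79e-42 [***]
  KS minus1 vs plus1 at 30 min: D = 0.12, p = 2.82e-01 [ns]

beta = 0.0 (tartan-like mutant)
     psb: proportion > 60 deg at t=30 = 0.38 (LOESS fit 0.43)
  minus1: proportion > 60 deg at t=30 = 0.33 (LOESS fit 0.43)
   plus1: proportion > 60 deg at t=30 = 0.25 (LOESS fit 0.44)
  KS psb vs minus1 at 30 min: D = 0.07, p = 9.36e-01 [ns]
  ...
```

With boundary tension present (β = 0.9) the PSB column stays fully
co-aligned at 30 min while both control columns have decayed to ~0.3–0.4,
and the KS tests are highly significant; with β = 0 ("tartan-like") the
three columns are statistically indistinguishable.  The other examples
(`examples/01` … `05`) demonstrate the generator, dot tracking and
kymographs, fixed-embryo quantification, and the screen.

A thin CLI wraps the same pipeline: `psb all --seed 1 --out run/` writes the
mesh, dot/track tables, interface classifications, co-alignment curves, KS
reports, trace quantification and screen report, plus the serialized config
that makes the run exactly reproducible.

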