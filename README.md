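# paintqc

Quantifying the **addressability** of DNA origami — staple incorporation and
docking-site accessibility — from DNA-PAINT super-resolution localization
data.

DNA origami is addressable because single staple strands can be extended
with docking sites for downstream attachment. Whether a given site actually
works depends on two factors: the staple must be **incorporated** during
folding, and its docking site must be **accessible** for hybridization.
`paintqc` implements the analysis that separates and quantifies both on the
single-staple level, together with a kinetic DNA-PAINT simulator that
provides ground truth for validating every step.

## What it does

* **`paintqc.simulate`** — in-silico DNA-PAINT: imager binding as an
  alternating renewal process (dark ~ Exp(τ_d = 12.5 s), bright ~
  Exp(τ_b = 0.5 s)), frame discretization at 200 ms, photon-dependent
  localization error σ = psf_σ/√N (≈ 1.28 nm at 10,500 photons), per-site
  presence ground truth.
* **`paintqc.designs`** — site geometries (20-nm grid, the 3 BS / 6 BS
  false-positive pair, an 18-variant library probing 168 staple positions
  of the 2D rectangle) and Gaussian template rendering.
* **`paintqc.locio`** — Picasso-compatible HDF5 / CSV localization tables,
  automated structure picking, per-structure extraction.
* **`paintqc.align`** — registration to a design template by stepwise
  rotational cross-correlation (default 1° steps), with template-library
  classification via the asymmetric arrowhead + line pattern.
* **`paintqc.site_detect`** — per-site localization counts in discs of
  20/18/6/5 nm, detection threshold from a Gaussian fit to the counts
  histogram, detection efficiencies with subset-bootstrap errors,
  false-positive rates from absent-by-design sites.
* **`paintqc.stats`** — two-color (3′/5′) coincidence analysis: under
  channel independence, chance_none = (f_only5+f_none)·(f_only3+f_none);
  incorporated = 1 − f_none; offset = incorporated − det3′ translates
  detection into absolute incorporation. Plus Michaelis–Menten fits of
  efficiency vs staple excess and rectangle heatmaps.

## Worked example

Simulate fifty 20-nm grids in which each docking site is present with
probability 0.8, then run the full detection pipeline:

```bash
paintqc simulate --design grid20 -n 50 --presence 0.8 --seed 7 -o run/
paintqc analyze --table run/locs.hdf5 --design grid20 --preset grid20 -o run/
```

which prints

```
wrote run/locs.hdf5 (381570 localizations)
analyzed 49 structures (threshold 397.9): average detection efficiency 79.1%
```

The measured 79.1% matches the presence ground truth of this draw
(474/600 sites simulated = 79.0%; one pick is rejected by the cluster
extent filter). The threshold (≈ 398 localizations) is half
the fitted peak of the counts histogram, which sits in the valley between
undetected (~0 counts) and detected (~800 counts) sites; diagnostics are
written to `run/threshold.png`. The two-color worked example:

```bash
paintqc twocolor --tally 0.785,0.050,0.072,0.093 -o tc/
```

```
chance both ends missed if incorporated: 2.4% | incorporated: 90.7% | detection-to-incorporation offset: +7.2%
```

i.e. with 78.5% of sites seen in both channels, 5% only at the 3′-end,
7.2% only at the 5′-end and 9.3% in neither, an incorporated staple has
only a ~2.4% chance of escaping both channels — so the 9.3% silent sites
are attributed to missing incorporation, and a +7% offset converts 3′-end
detection efficiencies into incorporation efficiencies (77% average → 84%,
41% minimum → 48%).

## Layout

```
src/paintqc/     designs, simulate, locio, align, site_detect, stats,
                 pipeline (glue), cli
tests/           pytest suite incl. full-scale acceptance tests
scripts/         acceptance.py
docs/methods.md  models, parameter choices, limitations
```
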