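# trabec

Trabecular-bone morphometry of cubic volumes of interest and
phylogenetically informed comparative statistics, built for studies that
ask how the spongy bone inside an epiphysis — here, the femoral head of
squirrels and their relatives — responds to body size and locomotor
lifestyle.

Trabecular bone remodels under habitual loading, so its architecture
carries a signal of both allometry and behaviour. The package covers the
full desk side of such a study:

- **Morphometry** of a binary 3D volume: bone volume fraction *BV/TV*,
  connectivity density *ConnD* = (1 − Δχ)/V from the Euler characteristic,
  mean trabecular thickness *TbTh* and separation *TbSp* (diameter of the
  greatest inscribed sphere in bone / marrow), bone surface density
  *BS/BV* from a triangulated isosurface, and the mean-intercept-length
  (MIL) fabric tensor giving the degree of anisotropy *DA* ∈ [0, 1] and
  the main trabecular direction *MDT*.
- **VOI selection and QC**: the largest cube centred on the plane that
  halves the femoral head, excluding cortical bone; specimens flagged
  when relative resolution (*TbTh*/voxel) < 5 or absolute connectivity
  < 50.
- **Comparative statistics**: for each trait *tp*, the scaling exponent
  *a* in log *tp* ∝ *a* · log *vl* (where *vl*, the VOI edge length, is
  the body-size proxy) is estimated by generalized least squares with a
  Brownian-motion species covariance rescaled by Pagel's λ (REML). The
  observed exponent is tested against the isometric expectation
  *a*_iso ∈ {0, 1, −1, −3} by shifting the response by *a*_iso · log *vl*
  and testing a zero slope; lifestyle pairs are compared with
  log *tp* ~ log *vl* + lifestyle and Benjamini–Hochberg correction at
  α = 0.05.
- **Synthetic data**: phantoms (balls, boxes, cylinders, plate stacks,
  rod lattices, thresholded Gaussian random fields) with closed-form
  ground truth, and simulated comparative datasets (pure-birth trees,
  traits with known slopes, lifestyle offsets and λ), so every stage is
  testable without CT data.

## Worked example

```sh
trabec simulate --out-dir demo --n-species 69 --seed 3 --bm-sigma 0.1
trabec analyze --traits demo/traits.csv --tree demo/tree.nwk --out-dir demo/results
```

The `analyze` log prints one line per trait (this run's output):

```
INFO trabec: allometry BVTV: a_obs=0.169 (a_iso=0) p=1.94e-20 +allo lambda=0.81
INFO trabec: allometry DA: a_obs=-0.187 (a_iso=0) p=4.04e-22 -allo lambda=0.83
INFO trabec: allometry TbTh: a_obs=0.821 (a_iso=1) p=7.8e-24 -allo lambda=0.80
INFO trabec: allometry TbSp: a_obs=0.602 (a_iso=1) p=2.79e-46 -allo lambda=0.85
INFO trabec: allometry BSBV: a_obs=-0.822 (a_iso=-1) p=8.57e-27 +allo lambda=0.90
INFO trabec: allometry ConnD: a_obs=-2.126 (a_iso=-3) p=3.28e-67 +allo lambda=0.78
```

Each line is one trait's allometry: `a_obs` is the fitted scaling
exponent of the trait against the size proxy, `a_iso` the exponent
expected if trabecular geometry were simply scaled up with size, `p`
tests their difference, and the label classifies the scaling (here the
generating slopes were deliberately non-isometric, and every trait is
correctly flagged as positively or negatively allometric).
`demo/results/` then holds `allometry.csv`, `lifestyle_pairwise.csv`
(size-adjusted lifestyle contrasts with raw and BH-adjusted p-values)
and `dataset_summary.json`.

Morphometry of image stacks works the same way:

```sh
trabec measure --stacks voi_stacks/ --out-dir results --voxel-size-um 10 --side left
```

writing one CSV row per specimen with all seven parameters, the relative
resolution and the QC verdict.

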