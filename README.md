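# afpq — quantifying exhaled-aerosol fingerprints

When a person inhales a bolus of micrometre tracer aerosol and exhales it
again, the particles collected on the mouth-exit plane form a spatial
pattern — an *aerosol fingerprint* — shaped by the airway tree the flow
passed through. Obstructions (tumors, constricted bronchi) perturb the
expiratory flow and leave characteristic marks in that pattern: shifted
accumulation hot spots, particle-free voids, changed texture. `afpq` is a
toolkit for researchers developing such aerosol breath tests: it turns a
fingerprint (a set of 2-D particle positions, or a raster image of them)
into a compact, comparable feature vector.

## What it computes

For a binary occupancy image of the pattern:

* **Box-counting fractal dimension** `D_B = -slope of log N(eps) vs log eps`,
  where `N(eps)` is the number of boxes of side `eps` containing particles —
  whole image, rectangular ROI, and a tiled local-FD grid with the ratio map
  `beta(i) = FD_case(i)/FD_baseline(i)`.
* **Sliding-box lacunarity** `lambda(eps) = (sigma/mu)^2` of gliding-window
  particle counts, aggregated as `Lambda = mean_eps lambda(eps)` —
  heterogeneity, complementary to `D_B`.

For the grayscale relative-concentration map (local/overall concentration
ratio):

* **Multifractal spectrum** by the direct method: normalized measures
  `mu_i(q, eps) = P_i^q / sum_j P_j^q`, singularity strength `alpha(q)`,
  spectrum `f(alpha)`, generalized dimensions `D_q`, and shape summaries
  (`alpha` width, `f` width, asymmetry, `D0/D1/D2`).

For the particle positions directly:

* **Directional probability profiles** (horizontal, vertical, radial,
  circumferential "rose") in %/mm² with analytic bin areas, plus hot-spot
  (spike) detection and cross-direction triangulation.
* **Concentration-disparity maps** (signed difference against a healthy
  baseline) and replicate statistics: mean ± SD over repeated breath tests
  and Kruskal–Wallis comparison across airway models, with an exact
  permutation p-value for small samples.

A seeded synthetic-fingerprint generator (vortex pair, central stripe,
asymmetric background, crescent void, hot spots, graded severity series
D0–D3) stands in for flow-simulation output so that the entire chain is
reproducible and testable, and analytic fixtures with known dimensions
(Sierpinski carpet, multiplicative cascades) validate the estimators.

## Worked example

```python
import afpq

# healthy (A) vs asthma-like (D) fingerprints, one replicate each
a = afpq.generate_fingerprint(afpq.model_params("A", n_particles=100_000, seed=0))
d = afpq.generate_fingerprint(afpq.model_params("D", n_particles=100_000, seed=0))

config = afpq.AnalysisConfig(seed=0)
for cloud in (a, d):
    m = afpq.analyze_cloud(cloud, config)
    print(f"model {cloud.model_label}: FD_entire={m['fd_entire']:.4f} "
          f"FD_roi={m['fd_roi']:.4f} Lambda={m['lambda_entire']:.4f} "
          f"dAlpha={m['alpha_width']:.4f}")

# triangulate model D's planted hot spot against the healthy baseline
import numpy as np
for direction in ("horizontal", "vertical"):
    pd_ = afpq.directional_profile(d, direction, 50)
    pa = afpq.directional_profile(a, direction, 50)
    k = int(np.argmax(pd_.density - pa.density))
    print(direction, "max D-A excess at", round(pd_.bin_centers()[k], 3))
```

prints

```
model A: FD_entire=1.8726 FD_roi=1.6374 Lambda=0.3563 dAlpha=0.1949
model D: FD_entire=1.8722 FD_roi=1.8178 Lambda=0.3013 dAlpha=0.4722
horizontal max D-A excess at 0.19
vertical max D-A excess at 0.65
```

Reading: the two patterns are nearly indistinguishable by whole-image
fractal dimension (1.8726 vs 1.8722) but differ clearly in the upper-left
region of interest and in the multifractal width — and the two directional
scans locate the disease-shifted accumulation spot at normalized
(0.19, 0.65), within one bin of where the generator planted it (0.2, 0.65).

The same chain is available from the shell:

```bash
afpq simulate --model D -n 100000 --seed 0 -o d.csv
afpq scan d.csv -o d_scan.csv
afpq fractal d.csv -o d_fd.json
afpq pipeline -o out/            # 4 models x 5 replicates + comparison
afpq pipeline --mode severity -o out_sev/
```

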