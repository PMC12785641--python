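# xtalgen

Seedable generation of artificial triclinic (P-1 / P1) crystal structures
and their diffraction amplitudes with ground-truth phases — training data
for crystallographic phase-problem solvers — plus the statistical
machinery used to validate the design (analytic volume p.d.f.,
distribution checks).

## What it does

Per structure, the pipeline:

1. samples a unit-cell **volume** from a log-normal (default
   LN(6.04, 0.394), fitted to database statistics) or uniform
   distribution, truncated to the feasible range of the cell bounds;
2. derives **cell lengths** `a1 <= a2 <= a3` with exact product, lengths
   within `[lmin, lmax]` (default 4–10 Å) and adjacent ratios at most
   `r` (default 3), then permutes them randomly;
3. optionally applies a **monoclinic or triclinic skew** — a
   volume-preserving unimodular shear with `beta = 90° + arctan(t)`,
   `t` drawn uniformly, uniform-adjusted, or (default) truncated-
   exponentially; a length-preserving variant is available;
4. occupies the four inversion-center **special positions** independently
   with probability p = 0.05 (≈ 81.4% of structures end up with none);
5. fills the asymmetric unit under a content budget (volume per non-H
   atom ~ U(7, 22) Å³, hydrogen mole fraction ~ U(0.3, 0.6)) by either
   **uniform rejection sampling** (minimum contact 1.2 Å) or
   **artificial-molecule growth** (bond window 0.9–1.1 × summed covalent
   radii, non-bonded floor 1.5 ×, sphere-uniform directions), with
   periodic images and symmetry mates in every distance check;
6. assigns isotropic **ADPs** (structure-level U ~ U(0.01, 0.1) Å² plus
   per-atom deviation ~ U(−0.005, 0.005) Å²);
7. computes **structure factors** over the expanded cell with
   International-Tables 4-Gaussian scattering factors and Debye–Waller
   attenuation at fixed resolution 1.0 Å and 100% completeness by default
   (both samplable per structure); P-1 phases are exactly binary
   ({0, π}).

Everything is driven by one root seed; structure `k` is reproducible
independently of batch size.

## CLI

```sh
xtalgen generate --n 100 --seed 1 --out batch/     # CIF + HKL per structure
xtalgen validate batch/                            # self-consistency checks
xtalgen fit-volumes volumes.txt                    # log-normal MLE fit
xtalgen inspect --seed 1 --index 0                 # one-structure summary
```

`generate` writes the effective `config.yaml` and a `manifest.json` next
to the outputs. Configs are YAML; every CLI flag overrides the file.

## Library

```python
from xtalgen import GeneratorConfig, generate_batch

cfg = GeneratorConfig(seed=7, placement_mode="molecules")
for structure, reflections in generate_batch(cfg, 1000):
    ...  # reflections.hkl, .amplitude, .phase (0 or pi)
```

Grids for neural-network input: `xtalgen.diffraction.to_grid` maps the
Friedel hemisphere to dense `(cap+1, 2cap+1, 2cap+1)` arrays
(`grid[h, k+cap, l+cap]`); `xtalgen.gridio` serializes them to HDF5.

## Notes & conventions

- Default special-position set is the four centers (0,0,0), (½,0,0),
  (0,½,0), (0,0,½); the full eight-center P-1 set is available via
  `p1bar_group(8)`.
- Element frequency tables (general vs special positions) and Cordero
  covalent radii ship as plain-text package data and can be replaced via
  config paths; the frequency tables are documented approximations
  constrained so C+N+O accounts for 89% (general) / 49% (special) of
  non-hydrogen atoms.
- Dispersion corrections are omitted so centrosymmetric phases are
  exactly binary.
- No chemical valence/energy rules anywhere — by design.
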