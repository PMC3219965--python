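# helixchrom

Polymer modeling of chromatin contact-frequency decay: statistical-helix
fits, detection of the ~90–100 kb modulation of random collision
frequencies, and the companion genomic enrichment analyses.

## The problem

Chromosome Conformation Capture (3C-qPCR, 5C, Hi-C) measures how often two
genomic sites separated by `s` kb collide. In the absence of locus-specific
looping, this *random collision frequency* is set by polymer physics. At
gene-rich mammalian loci the decay of collision frequency with distance is
not monotonic: it is modulated with a ~90–100 kb period, rising again around
90–100 kb (supranucleosomal domain III) and around 180 kb (domain V). This
package implements, as a tested reusable library, the quantitative analysis
behind that observation: model fitting, modulation statistics, derived helix
geometry, and two genome-scale corollaries.

## The model

The chromatin fiber is a freely jointed chain of Kuhn segments of length `S`
kb (`S·L` nm, `L` = 9.6 nm/kb for mammals, 11.1 for yeast). Crosslinking
frequency follows the worm-like-chain interpolation

    X(s) = 0.53 · k · β^(−3/2) · exp(−1.8/β),      β = (⟨R⟩ / (S·L))²

where ⟨R⟩ is the mean spatial distance between the sites. Three geometries
set ⟨R⟩(s):

| family   | ⟨R⟩(s)                                               | β(s) |
|----------|------------------------------------------------------|------|
| linear   | `L·√(s·S)`                                           | `s/S` |
| circular | `L·√(S·s·(c−s)/c)` (ring of apparent size `c` kb)    | `s(c−s)/(S·c)` |
| helix    | `√(D²·sin²(θ/2) + (P·θ/2π)²)`, `θ = 2π·s·L/√(π²D²+P²)` | `⟨R⟩²/(S·L)²` |

The *statistical helix* (population-averaged helical tendency, mean diameter
`D`, mean step `P`) reproduces the modulation: collisions peak whenever the
chain completes a turn. Derived quantities: the DNA content of one turn `Sh`
(first maximum of `X(s)` past the initial decay), and the volumetric mass
density `Vs = π(D/2)²·⟨R⟩/s`, compared against a 30-nm fiber reference.

## Worked example

```python
from helixchrom import (PolymerModel, SimulationDesign, simulate_contact_profile,
                        fit_polymer_model, FitOptions, helix_turn_length, volume_report)

truth = PolymerModel(family="helix", S=2.709, D=292.03, P=162.13, L=9.6, k=1.0)
profile = simulate_contact_profile(SimulationDesign(
    model=truth, anchors=5, sites_per_anchor=50,
    s_range=(5.0, 340.0), noise_cv=0.2, seed=101))
fit = fit_polymer_model(profile, "helix", FitOptions(weighted=True))
print(f"D = {fit.model.D:.1f} nm, P = {fit.model.P:.1f} nm")
print(f"Sh = {helix_turn_length(fit.model):.1f} kb per turn")
rep = volume_report(truth)
print(f"Vs = {rep.Vs:.3g} nm^3/kb, {rep.fold:.1f}x a 30-nm fiber,"
      f" diploid genome = {rep.genome_volume:.0f} um^3")
```

prints

```
D = 287.3 nm, P = 168.0 nm
Sh = 92.4 kb per turn
Vs = 1.02e+05 nm^3/kb, 15.0x a 30-nm fiber, diploid genome = 610 um^3
```

i.e. the fit recovers the generative helix (287 vs 292 nm diameter; 168 vs
162 nm step, both within two standard errors at this noise level), one
helix turn holds ~92–94 kb of DNA, and a diploid genome
folded this way would occupy ~610 μm³ — more than a 10-μm nucleus (~520
μm³), so denser folding must coexist above this scale.

The numbered scripts under `analysis/` run the full study on synthetic
data: `01_simulate_profiles.py` → `02_fit_polymer_models.py` →
`03_modulation_scan.py` → `04_helix_geometry.py` →
`05_conserved_enrichment.py` → `06_hic_domains.py`, writing tables under
`results/`. The same stages are exposed as a CLI
(`helixchrom simulate|fit|scan|enrich|hic-domains|predict`).

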