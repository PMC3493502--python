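# mapcrystal

Coupled Swift-Hohenberg dynamics of visual cortical maps, with a complete
pinwheel detection, tracking, and crystallization-statistics toolkit.

## The problem

In primates and carnivores, visual cortical neurons are organized into
overlapping columnar maps — orientation preference (OP), ocular dominance
(OD), spatial frequency. A long-standing hypothesis holds that these maps
develop by jointly descending an energy functional, so that the geometric
relationships between maps (intersection angles, pinwheel placement) arise
from inter-map coupling terms. `mapcrystal` implements a dynamical-systems
version of that hypothesis and the analysis machinery needed to test it:
it integrates the coupled gradient flow

    ∂t z      = L̂_z z − |z|² z − δU/δz̄
    c_i ∂t o_i = L̂_i o_i − o_i³ + γ_i − δU/δo_i,   L̂ = r − (k_c² + Δ)²/k_c⁴

for a complex OP field z (θ = ½ arg z is the preferred orientation, |z| the
selectivity) and real columnar fields o_i (for OD, sign = eye dominance and
γ > 0 a contralateral bias), with inter-map coupling energies from a
symmetry-classified family: α o²|z|², τ o⁴|z|⁴, β|∇z·∇o|², ε|∇z·∇o|⁴.
Pinwheels — the topological defects of charge ±½ where all orientations
meet — are detected as crossings of the zero contours of Re z and Im z,
tracked across exponentially spaced snapshots, and summarized by densities
(per hypercolumn Λ²), charge-resolved nearest-neighbor distributions,
density-variability exponents, creation/annihilation rates, and survival
fractions.

The package answers questions like: does the coupling stabilize pinwheels
that the uncoupled dynamics would annihilate? Which crystalline attractors
(hexagonal pinwheel crystals at ≈ 5.2 defects per Λ², rhombic at ≈ 3.5)
emerge at which coupling strengths? How much of the final pattern is
inherited from the initial map?

Audience: computational neuroscientists and pattern-formation researchers
who want a reproducible, single-CPU implementation of these experiments.

## Numerics

The stiff dynamics is integrated fully implicitly: Crank-Nicolson steps
solved by matrix-free Newton-Krylov (finite-difference Jacobian action,
restarted GMRES with a Fourier-diagonal preconditioner, backtracking line
search) and step-doubling adaptive step control, which lets dt grow by
orders of magnitude as an attractor is approached. See `docs/methods.md`.

## Worked example

```python
import numpy as np
import mapcrystal as mc
from mapcrystal import experiments as ex

# strong high-order gradient coupling, biased OD -> hexagonal pinwheel crystal
fs = ex.crystallization_run(seed=1, eps=ex.EPS_STRONG,
                            grid=mc.GridSpec(64, 64, 8, 8),
                            t_end_tau=500, frame_count=60)
final = fs[-1]
pws = mc.find_pinwheels(final.z, fs.model.grid)
print("final OP power", round(float(np.mean(np.abs(final.z)**2)), 4))
print("pinwheels", len(pws), "density", mc.pinwheel_density(pws),
      "net charge", pws.total_charge)
```

prints

```
final OP power 0.005
pinwheels 336 density 5.25 net charge 0.0
```

i.e. the 8×8 Λ² domain ends in a hexagonal pinwheel crystal with 336
defects (5.25 per hypercolumn, close to the ideal hPWC value ≈ 5.2 and far
above the ≈ π of a random Gaussian map), perfectly charge-balanced on the
torus. With the coupling switched off (`eps=0`) the same initial condition
decays to pinwheel-free stripes (density → 0, OP power → r_z).

The same protocols are scriptable from the shell:

```sh
mapcrystal simulate --config run.yaml --seed 1 --out frames.h5
mapcrystal analyze --frames frames.h5 --out stats/
mapcrystal render --frames frames.h5 --out map.png
```

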