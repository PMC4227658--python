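# fibernet

Elastic bead-and-spring simulation of 3D collagen fiber network
mechanics.

Collagen gels dominate the mechanical environment of cells in soft
tissue, and their stiffness and fiber alignment are linked to cancer
progression and cell migration. Between the well-studied single-fiber
scale and the bulk-rheology scale lies the cell scale, where a network
of ~100 µm fibers responds to shear, tension, and the local tugging of
a pseudopod. `fibernet` simulates that scale: it builds random or
prealigned fiber networks at prescribed collagen concentrations,
connects them with elastic crosslinkers, and probes them with
quasi-static loading experiments driven by energy minimization. It is
aimed at researchers in ECM mechanics and cell–matrix interaction who
need a transparent, calibrated, reproducible network model.

## Model

Each fiber is a chain of 5 beads joined by Hookean springs; explicit
crosslinker springs connect beads on different fibers. The energy is

    U = Σ ½ k (ΔL)²,     k = E·A / L₀,

with E the Young's modulus (32 MPa for fibers; the crosslinker modulus
is a free parameter), A = πd²/4 the fiber cross-section (d = 0.3 µm),
and L₀ the spring rest length. The crosslinker model has two free
parameters — strength (Pa) and density (crosslinkers per fiber count,
"×N") — calibrated against bulk shear rheology to 634.38 kPa and
11.18N, the package defaults. After every imposed boundary
displacement the free beads are relaxed until the maximum per-bead
force falls to 10⁻⁵ of its strained-state value (quasi-equilibrium).
Shear modulus G is the regression slope of the stress–strain curve over
0.01–0.10 strain; Poisson's ratio is measured from a rectangular
lateral box fitted to boundary beads at nine heights. See
`docs/methods.md` for the full account.

## Worked example

Shear a calibrated 2 mg/ml random network (1347 fibers in a
200×200×300 µm box, top and bottom 50 µm gripped) through ten 0.01
strain steps and read off the modulus:

```python
from fibernet import CrosslinkerParams
from fibernet.workflows import shear_modulus_run

curve = shear_modulus_run(2.0, CrosslinkerParams(), seed=7)
print("strain   stress (Pa)")
for eps, sigma in zip(curve.strains, curve.stresses):
    print(f"{eps:5.2f}    {sigma:8.4f}")
print(f"shear modulus: {curve.modulus:.2f} Pa")
```

```
strain   stress (Pa)
 0.01      0.3211
 0.02      0.6486
 0.03      0.9823
 0.04      1.3238
 0.05      1.6747
 0.06      2.0383
 0.07      2.4103
 0.08      2.7966
 0.09      3.1807
 0.10      3.6011
shear modulus: 36.33 Pa
```

The stress rises mildly faster than linearly — the beginning of strain
stiffening as fibers rotate into the loading direction — and the
regression slope, 36.3 Pa for this seed (replicate means run ≈40 Pa),
sits near the 44.5 Pa measured for 2 mg/ml collagen in shear rheology.
A single run takes ~15 s on one CPU.

The same machinery is available from the shell:

```sh
fibernet generate --config run.yaml   # build + export networks
fibernet shear    --config run.yaml   # stress-strain curves + moduli
fibernet tensile  --config run.yaml   # trajectories + Poisson's ratio
fibernet poke     --config run.yaml   # local-deformation force fields
fibernet fit      --config run.yaml   # full crosslinker calibration
```

Configs are YAML; every omitted field falls back to the calibrated
collagen defaults (an empty file is a valid config). Each run writes
an effective-config echo, per-step convergence manifests, and
HDF5/XYZ/CSV/JSON outputs sufficient to reproduce it.

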