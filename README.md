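# tubetransit

Brownian-dynamics simulation of nanoparticle transit between middle
ears through the Eustachian-tube route.

Intratympanically injected drugs are usually assumed to stay on the
injected side, and the contralateral ear is often used as the control
in inner-ear delivery studies.  In rats, however, the two middle ears
are connected through the Eustachian tubes and the nasopharynx, and
imaging shows injected nanoparticles appearing in the *opposite* ear
within hours.  `tubetransit` provides a tested, reusable model of that
route: overdamped Langevin particles diffusing through a two-tube-plus-
cavity domain (Eustachian tube, 1.5 mm x 0.05 mm radius; nasopharynx,
1 mm cube; contralateral tube with an absorbing end), with optional
constant axial force and pairwise electrostatic repulsion.  Its output
is the **arrival fraction**: the cumulative share of the injected bolus
absorbed at the contralateral end within 180 minutes.

The model, in the field's standard notation:

* per-particle dynamics `dx = mu F dt + sqrt(2 D dt) xi`,
  `xi ~ N(0, I3)` (inertia neglected);
* `D = kB T Cc / (6 pi eta r)` (Stokes–Einstein with Cunningham slip
  `Cc(Kn)`), `mu = D / kB T` (Einstein relation);
* external force: none, or a constant `+x`/`-x` axial force with
  gravity-derived magnitude `(4/3) pi r^3 rho g` times one scale factor;
* inter-particle repulsion: softened Coulomb
  `k q_i q_j d / (|d|^2 + s^2)^{3/2}` with a 0.2 mm cutoff;
* walls reflect specularly; the plane at `x = 4 mm` absorbs;
* an independent 1-D drift–diffusion Crank–Nicolson solver (plus the
  pure-diffusion eigenfunction series) validates the stochastic engine
  in a straight-channel geometry, where the x-marginal is exactly 1-D.

Because the reference campaign left the medium, the force magnitude and
the charge unit unstated, each sweep family carries exactly one
calibratable scalar (global diffusion scale, force scale, interaction
strength); the remaining scenario of each family is a genuine
prediction.  See `docs/methods.md` for the full model account.

## Worked example

Simulate the no-force baseline at a diffusion scale of 20 (close to the
calibrated value) with 1000 particles of 200 nm:

```python
from tubetransit import SimulationConfig, ParticleSpec, run_simulation

config = SimulationConfig(particles=ParticleSpec(diameter=200, count=1000),
                          d_scale=20.0, seed=13)
curve, state = run_simulation(config)
print(f"arrival fraction at 180 min: {curve.fractions[-1]:.3f} "
      f"({state.n_absorbed}/{state.n_total})")
print(curve.to_frame().iloc[[30, 90, 180]])
```

prints

```
arrival fraction at 180 min: 0.227 (227/1000)
     time_min  fraction  n_absorbed  n_total
30       30.0     0.040          40     1000
90       90.0     0.126         126     1000
180     180.0     0.227         227     1000
```

i.e. 4.0% of the bolus has reached the contralateral plane after 30
minutes, 12.6% after 90, and 22.7% after the full 180-minute horizon —
the slow climb reflects the entropic trapping of the nasopharynx
cavity, which is drained only through the 0.05 mm tube mouths.

The same run from the shell, with outputs and a provenance manifest:

```sh
tubetransit simulate --config tests/data/oracle_equivalence.yaml --out run1
tubetransit oracle --D 4.7e-9 --v 0 --L 4e-3 --t-end 600   # reference F(t)
tubetransit scenarios run --family size --seeds 2 --d-scale 20 --out table.csv
```

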