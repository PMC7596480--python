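"""Initial particle ensembles and miniature test configurations.

The study's only "data" are the injected particle boluses themselves:
particles are loaded at the ipsilateral end of the tube.  Rather than a
point source (singular for the PDE comparison and implausible for an
injected bolus) the default source is a cylindrical slab of depth
0.05 mm at the tube entrance, sampled uniformly.
"""

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import MM, Geometry
from .physics import ParticleSpec
from .state import ACTIVE, EnsembleState


@dataclass(frozen=True)
class SourceSpec:
    """Uniform cylindrical slab source at the tube entrance (mm)."""

    region: str = "source_slab"
    slab_depth: float = 0.05

    def __post_init__(self):
        if self.region != "source_slab":
            raise ValidationError(
                f"region must be 'source_slab', got {self.region!r}")
        if not self.slab_depth > 0:
            raise ValidationError(
                f"slab_depth must be > 0 mm, got {self.slab_depth!r}")


def sample_initial_ensemble(geometry: Geometry, spec: ParticleSpec,
                            source: SourceSpec, seed) -> EnsembleState:
    """Draw N i.i.d. uniform positions in the source slab at t = 0.

    Cross-sections are drawn by rejection sampling in the tube disk;
    deterministic for a given seed (or Generator).
    """
    if source.slab_depth >= geometry.tube_length:
        raise ValidationError(
            f"slab_depth ({source.slab_depth} mm) must be smaller than "
            f"tube_length ({geometry.tube_length} mm)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(spec.count)
    R = geometry.tube_radius * MM
    depth = source.slab_depth * MM

    x = rng.uniform(0.0, depth, size=n)
    y = np.empty(n)
    z = np.empty(n)
    need = np.arange(n)
    while need.size:
        yy = rng.uniform(-R, R, size=need.size)
        zz = rng.uniform(-R, R, size=need.size)
        ok = yy * yy + zz * zz <= R * R
        y[need[ok]] = yy[ok]
        z[need[ok]] = zz[ok]
        need = need[~ok]

    positions = np.column_stack([x, y, z])
    return EnsembleState(
        time=0.0,
        positions=positions,
        status=np.full(n, ACTIVE, dtype=np.uint8),
        absorption_time=np.full(n, np.nan),
    )


def make_fixture_configs():
    """Miniature configurations that each run in a few seconds.

    Covers the three behaviours the fast tests need: oracle equivalence
    in a straight channel, force-direction ordering, and the zero-charge
    equivalence of the interacting code path.
    """
    from .engine import SimulationConfig  # local import avoids a cycle

    oracle = SimulationConfig(
        geometry=Geometry(mode="straight_channel", tube_radius=0.2),
        particles=ParticleSpec(count=200),
        d_scale=20.0,
        t_end=600.0,
        record_every=60.0,
        seed=0,
    )

    from .physics import ForceSpec, InteractionSpec

    force = SimulationConfig(
        particles=ParticleSpec(count=150),
        force=ForceSpec(mode="constant", direction="+x",
                        magnitude_model="gravity", scale=0.2),
        d_scale=8.0,
        t_end=900.0,
        record_every=60.0,
        seed=0,
    )

    zero_charge = SimulationConfig(
        particles=ParticleSpec(count=64, charge=0.0),
        interaction=InteractionSpec(enabled=True, strength=1e-24),
        d_scale=8.0,
        t_end=300.0,
        record_every=60.0,
        seed=0,
    )

    return {"oracle_equivalence": oracle,
            "force_ordering": force,
            "zero_charge": zero_charge}
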