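"""Single-particle and pairwise physics.

Drag on a sphere of radius r follows Stokes' law, optionally corrected
for gas slip with the Cunningham factor Cc(Kn); the diffusion coefficient
is the Stokes-Einstein value D = kB*T*Cc / (6*pi*eta*r) and the mobility
mu = Cc / (6*pi*eta*r) obeys the Einstein relation mu = D / (kB*T) by
construction.

The default medium is body-temperature air: the middle ear and the
Eustachian tube are air-filled, and at these particle sizes air gives
transit times on the scale of the 180-minute observation window.  A
``water`` preset (viscosity of water at 310 K, no slip) is provided for
liquid-filled variants.

Charge is a dimensionless multiplier of an unspecified reference charge;
the inter-particle repulsion is a softened Coulomb kernel with one free
coefficient (``InteractionSpec.strength``), a finite range cutoff, and a
softening length that removes the contact singularity.
"""

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

KB = 1.380649e-23  # Boltzmann constant, J/K
NM = 1e-9          # metres per nanometre
MM = 1e-3          # metres per millimetre
G_STANDARD = 9.81  # m/s^2


@dataclass(frozen=True)
class Medium:
    """Carrier medium for the suspended particles."""

    name: str = "air"
    temperature: float = 310.0          # K
    dynamic_viscosity: float = 1.86e-5  # Pa s (air at ~310 K)
    mean_free_path: float = 6.8e-8      # m (air; only used with slip on)

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValidationError(
                f"temperature must be > 0 K, got {self.temperature!r}")
        if not self.dynamic_viscosity > 0:
            raise ValidationError("dynamic_viscosity must be > 0 Pa s, got "
                                  f"{self.dynamic_viscosity!r}")
        if self.mean_free_path < 0:
            raise ValidationError("mean_free_path must be >= 0 m, got "
                                  f"{self.mean_free_path!r}")


AIR = Medium()
WATER = Medium(name="water", dynamic_viscosity=6.9e-4, mean_free_path=0.0)

_PRESETS = {"air": AIR, "water": WATER, "mucus": WATER}


def medium_preset(name: str) -> Medium:
    """Look up a named medium preset (``air``, ``water``/``mucus``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown medium preset {name!r}; choices: {sorted(_PRESETS)}")


@dataclass(frozen=True)
class ParticleSpec:
    """A monodisperse particle population.

    diameter is in nm, density in kg/m^3; charge is the dimensionless
    surface-charge multiplier (0.1 and 1 in the study sweeps).
    """

    diameter: float = 200.0
    density: float = 2000.0
    charge: float = 0.0
    count: int = 1000

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValidationError(
                f"diameter must be > 0 nm, got {self.diameter!r}")
        if self.density < 0:
            raise ValidationError(
                f"density must be >= 0 kg/m^3, got {self.density!r}")
        if self.charge < 0:
            raise ValidationError(
                f"charge must be >= 0, got {self.charge!r}")
        if int(self.count) < 1:
            raise ValidationError(
                f"count must be a positive integer, got {self.count!r}")

    @property
    def radius_m(self) -> float:
        return 0.5 * self.diameter * NM


@dataclass(frozen=True)
class ForceSpec:
    """Constant axial external force.

    ``magnitude_model='gravity'`` derives the magnitude from the particle
    weight (4/3*pi*r^3*density*g, buoyancy neglected); ``'explicit'``
    uses ``magnitude`` (N) directly.  ``scale`` is the single calibratable
    multiplier of the force family.
    """

    mode: str = "none"             # none | constant
    direction: str = "+x"          # +x | -x
    magnitude_model: str = "gravity"  # gravity | explicit
    magnitude: float = 0.0         # N, used when explicit
    scale: float = 1.0

    def __post_init__(self):
        if self.mode not in ("none", "constant"):
            raise ValidationError(
                f"force mode must be 'none' or 'constant', got {self.mode!r}")
        if self.direction not in ("+x", "-x"):
            raise ValidationError(
                f"direction must be '+x' or '-x', got {self.direction!r}")
        if self.magnitude_model not in ("gravity", "explicit"):
            raise ValidationError("magnitude_model must be 'gravity' or "
                                  f"'explicit', got {self.magnitude_model!r}")
        if self.magnitude < 0:
            raise ValidationError(
                f"magnitude must be >= 0 N, got {self.magnitude!r}")
        if self.scale < 0:
            raise ValidationError(
                f"scale must be >= 0, got {self.scale!r}")


@dataclass(frozen=True)
class InteractionSpec:
    """Pairwise softened Coulomb repulsion (lengths in mm)."""

    enabled: bool = False
    strength: float = 1e-24  # reference coefficient k_int, N m^2 per q^2
    cutoff: float = 0.2
    softening: float = 0.005

    def __post_init__(self):
        if self.strength < 0:
            raise ValidationError(
                f"strength must be >= 0, got {self.strength!r}")
        if self.softening < 0:
            raise ValidationError(
                f"softening must be >= 0 mm, got {self.softening!r}")
        if not self.cutoff > self.softening:
            raise ValidationError(
                f"cutoff ({self.cutoff!r} mm) must exceed softening "
                f"({self.softening!r} mm)")


def slip_correction(radius: float, mean_free_path: float) -> float:
    """Cunningham slip factor Cc = 1 + Kn*(1.257 + 0.4*exp(-1.1/Kn)).

    Kn = mean_free_path / radius.  Cc >= 1, and Cc -> 1 in the continuum
    limit (mean_free_path -> 0).
    """
    if not radius > 0:
        raise ValidationError(f"radius must be > 0 m, got {radius!r}")
    if mean_free_path < 0:
        raise ValidationError(
            f"mean_free_path must be >= 0 m, got {mean_free_path!r}")
    if mean_free_path == 0.0:
        return 1.0
    kn = mean_free_path / radius
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def _cc(spec: ParticleSpec, medium: Medium, slip: bool) -> float:
    return slip_correction(spec.radius_m, medium.mean_free_path) if slip else 1.0


def diffusion_coefficient(spec: ParticleSpec, medium: Medium,
                          slip: bool = True) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s)."""
    cc = _cc(spec, medium, slip)
    return KB * medium.temperature * cc / (
        6.0 * np.pi * medium.dynamic_viscosity * spec.radius_m)


def mobility(spec: ParticleSpec, medium: Medium, slip: bool = True) -> float:
    """Stokes mobility mu = Cc / (6*pi*eta*r), in m/(s N)."""
    cc = _cc(spec, medium, slip)
    return cc / (6.0 * np.pi * medium.dynamic_viscosity * spec.radius_m)


def gravity_force(spec: ParticleSpec, g: float = G_STANDARD) -> float:
    """Particle weight (N), buoyancy neglected: (4/3)*pi*r^3*density*g."""
    return (4.0 / 3.0) * np.pi * spec.radius_m ** 3 * spec.density * g


def external_force_vector(force: ForceSpec, spec: ParticleSpec) -> np.ndarray:
    """Resolve a ForceSpec into a constant 3-vector force (N)."""
    if force.mode == "none":
        return np.zeros(3)
    if force.magnitude_model == "gravity":
        mag = gravity_force(spec)
    else:
        mag = force.magnitude
    sign = 1.0 if force.direction == "+x" else -1.0
    return np.array([sign * mag * force.scale, 0.0, 0.0])


def pair_force(delta, q_i: float, q_j: float,
               interaction: InteractionSpec) -> np.ndarray:
    """Softened Coulomb force (N) on particle i from particle j.

    delta = position_i - position_j in metres.  Zero beyond the cutoff;
    antisymmetric under exchange of i and j.
    """
    delta = np.asarray(delta, dtype=float)
    r2 = float(delta @ delta)
    cutoff = interaction.cutoff * MM
    if r2 > cutoff * cutoff:
        return np.zeros(3)
    s = interaction.softening * MM
    w = interaction.strength * q_i * q_j / (r2 + s * s) ** 1.5
    return w * delta
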