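"""Flapping-wing structural surrogate.

Generates the spatio-temporal field of spanwise surface strain for a damped
rectangular plate wing, clamped at its base, driven by a prescribed flapping
motion and an optional constant-rate body rotation (roll, pitch or yaw).

The wing is a hawkmoth-scale plate: 50 mm span x 25 mm chord x 127 um thick,
density 1180 kg m^-3, Poisson ratio 0.35, mean Young's modulus around 3 GPa.
Stiffness is either uniform or declines log-linearly from the leading-edge
base corner (x = 0, y = 0) to the trailing-edge tip corner, normalised so the
mean modulus over the plate equals the nominal value:

    E(x, y) = E_mean * 10**(-m_x x - m_y y) / mean(10**(-m_x x - m_y y))

With the default decline rates m_x = m_y = 26.67 m^-1 the modulus spans two
orders of magnitude across the plate, the gradient measured in hawkmoth
forewings.

Flapping follows a two-harmonic pattern phi(t) = A1 sin(2 pi f1 t) +
A2 sin(2 pi f2 t) about the chordwise axis at the base.  In the co-rotating
wing frame the prescribed rigid motion enters as a transverse inertial load
per unit area

    p(x, y, t) = -rho h * [g_x(t) x + g_y(t) (y - y_c)],
    g_x = -omega_dot_y + omega_z omega_x,   g_y = omega_dot_x + omega_z omega_y,

where omega is the total angular velocity of the wing frame (flapping plus
body rotation, expressed in wing coordinates) and y_c is the chordwise
station through which the body-rotation axes pass (root mid-chord by
default, a centred gimbal mount).  Coriolis coupling of the
transverse plate velocity has no transverse component and drops out of the
linear model; stress stiffening is not modelled.

Viscous damping is applied as a volumetric force F = -c V with
c = 2 zeta m omega_n, where omega_n is the first structural eigenfrequency
recomputed for each stiffness configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._plate import PlateModel, PlateAssemblyError, SimulationDivergedError

__all__ = [
    "WingSpec", "StiffnessField", "Kinematics", "DampingSpec", "StrainField",
    "build_stiffness_field", "flap_angle", "flap_velocity", "flap_acceleration",
    "eigenfrequency", "damping_coefficient", "simulate_strain",
    "PlateAssemblyError", "SimulationDivergedError",
]

ROTATION_AXES = ("none", "roll", "pitch", "yaw")


@dataclass(frozen=True)
class WingSpec:
    """Geometry, material and damping parameters of the plate wing."""

    span: float = 0.05
    chord: float = 0.025
    thickness: float = 127e-6
    density: float = 1180.0
    poisson: float = 0.35
    E_mean: float = 3e9
    gradient: str = "uniform"          # "uniform" | "gradient"
    decline_x: float = 26.67           # log10 decline rate along span (1/m)
    decline_y: float = 26.67           # log10 decline rate along chord (1/m)
    zeta: float = 2.0

    def __post_init__(self):
        for name in ("span", "chord", "thickness", "density", "E_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.poisson < 0.5:
            raise ValueError("poisson must lie in (0, 0.5)")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")
        if self.gradient not in ("uniform", "gradient"):
            raise ValueError("gradient must be 'uniform' or 'gradient'")

    @property
    def mass(self) -> float:
        return self.span * self.chord * self.thickness * self.density

    @property
    def mx(self) -> float:
        """Effective spanwise decline rate (zero for uniform wings)."""
        return self.decline_x if self.gradient == "gradient" else 0.0

    @property
    def my(self) -> float:
        return self.decline_y if self.gradient == "gradient" else 0.0


@dataclass(frozen=True)
class StiffnessField:
    """Young's modulus sampled on the node grid (chord x span layout)."""

    E: np.ndarray          # (n_chord_nodes, n_span_nodes), Pa
    x: np.ndarray          # spanwise node coordinates (m)
    y: np.ndarray          # chordwise node coordinates (m)

    @property
    def log10_range(self) -> float:
        return float(np.log10(self.E.max() / self.E.min()))


@dataclass(frozen=True)
class Kinematics:
    """Prescribed flapping and body-rotation parameters."""

    A1: float = np.pi / 12
    A2: float = np.pi / 60
    f1: float = 25.0
    f2: float = 50.0
    rotation_axis: str = "none"
    rotation_rate: float = 1.0
    ramp_cycles: int = 1
    #: chordwise station (m) through which the body-rotation axes pass;
    #: ``None`` means the root mid-chord (a centred gimbal mount).
    axis_chord_position: float | None = None

    def __post_init__(self):
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("flapping frequencies must be positive")
        if self.rotation_axis not in ROTATION_AXES:
            raise ValueError(f"rotation_axis must be one of {ROTATION_AXES}")
        if self.rotation_rate < 0:
            raise ValueError("rotation_rate must be non-negative")
        if self.ramp_cycles < 1:
            raise ValueError("ramp_cycles must be at least 1")

    @property
    def period(self) -> float:
        """Wingbeat period (s), set by the fundamental harmonic."""
        return 1.0 / self.f1


@dataclass(frozen=True)
class DampingSpec:
    """Total viscous damping coefficient c = 2 zeta m omega_n."""

    c: float
    zeta: float
    mass: float
    omega_n: float


@dataclass
class StrainField:
    """Spanwise surface strain on the node grid, over time.

    ``epsilon_xx`` has one row per node (x fastest, chord-major layout) and
    one column per solver sample.  ``wingbeat_window`` is the half-open index
    range [start, stop) of the final analysed wingbeat.
    """

    epsilon_xx: np.ndarray
    times: np.ndarray
    X: np.ndarray                  # spanwise coordinate per node (m)
    Y: np.ndarray                  # chordwise coordinate per node (m)
    grid_shape: tuple              # (n_chord_nodes, n_span_nodes)
    condition: str                 # "flap" or "flap+rotation(<axis>)"
    wingbeat_window: tuple         # (start, stop) indices into times
    dt: float
    periodicity_error: float = np.nan
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def window(self) -> np.ndarray:
        i0, i1 = self.wingbeat_window
        return self.epsilon_xx[:, i0:i1]

    @property
    def window_times(self) -> np.ndarray:
        i0, i1 = self.wingbeat_window
        return self.times[i0:i1]


# ---------------------------------------------------------------------------
# stiffness field
# ---------------------------------------------------------------------------

def build_stiffness_field(spec: WingSpec, nx: int = 50, ny: int = 25) -> StiffnessField:
    """Sample the (possibly gradient) Young's modulus on the node grid.

    The gradient field is normalised by its *discrete* mean over the grid, so
    the sampled moduli average exactly to ``spec.E_mean``.  A uniform spec
    returns a constant field.
    """
    if not spec.E_mean > 0:
        raise ValueError("E_mean must be strictly positive")
    x = np.linspace(0.0, spec.span, nx + 1)
    y = np.linspace(0.0, spec.chord, ny + 1)
    XX, YY = np.meshgrid(x, y)
    shape_fn = 10.0 ** (-spec.mx * XX - spec.my * YY)
    E = spec.E_mean * shape_fn / shape_fn.mean()
    return StiffnessField(E=E, x=x, y=y)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def flap_angle(t, kin: Kinematics):
    """Flapping angle phi(t) = A1 sin(2 pi f1 t) + A2 sin(2 pi f2 t)."""
    t = np.asarray(t, dtype=float)
    w1, w2 = 2 * np.pi * kin.f1, 2 * np.pi * kin.f2
    return kin.A1 * np.sin(w1 * t) + kin.A2 * np.sin(w2 * t)


def flap_velocity(t, kin: Kinematics):
    """Analytic first time derivative of the flapping angle (rad/s)."""
    t = np.asarray(t, dtype=float)
    w1, w2 = 2 * np.pi * kin.f1, 2 * np.pi * kin.f2
    return kin.A1 * w1 * np.cos(w1 * t) + kin.A2 * w2 * np.cos(w2 * t)


def flap_acceleration(t, kin: Kinematics):
    """Analytic second time derivative of the flapping angle (rad/s^2)."""
    t = np.asarray(t, dtype=float)
    w1, w2 = 2 * np.pi * kin.f1, 2 * np.pi * kin.f2
    return -kin.A1 * w1**2 * np.sin(w1 * t) - kin.A2 * w2**2 * np.sin(w2 * t)


def _ramp(t, t_ramp):
    """Half-cosine ramp from 0 to 1 over [0, t_ramp] (C1, no accel jumps)."""
    if t >= t_ramp:
        return 1.0, 0.0
    r = 0.5 * (1.0 - np.cos(np.pi * t / t_ramp))
    rdot = 0.5 * np.pi / t_ramp * np.sin(np.pi * t / t_ramp)
    return r, rdot


def _load_coefficients(kin: Kinematics) -> tuple[Callable, Callable]:
    """Transverse inertial-load coefficients g_x(t), g_y(t).

    All rotation axes (flapping plus body roll/pitch/yaw) pass through one
    point on the clamped edge, so the rigid acceleration of a wing-frame
    point at r = (x, y - y_c, 0) relative to that point is exactly
    a_z = omega_dot_x (y - y_c) - omega_dot_y x
          + omega_z (omega_x x + omega_y (y - y_c)),
    i.e. a_z = g_x * x + g_y * (y - y_c) with the coefficients below.  The
    body-rotation axis is expressed in wing coordinates through the flap
    angle phi: roll is parallel to the flapping axis, pitch starts along the
    span and yaw along the plate normal.
    """
    axis = kin.rotation_axis
    rate = kin.rotation_rate
    t_ramp = kin.ramp_cycles * kin.period

    def coeffs(t: float) -> tuple[float, float]:
        phidd = float(flap_acceleration(t, kin))
        if axis == "none" or rate == 0.0:
            return -phidd, 0.0
        r, rdot = _ramp(t, t_ramp)
        Om = rate * r
        Omd = rate * rdot
        phi = float(flap_angle(t, kin))
        phid = float(flap_velocity(t, kin))
        s, c = np.sin(phi), np.cos(phi)
        if axis == "roll":
            # omega = (0, phid + Om, 0)
            return -(phidd + Omd), 0.0
        if axis == "yaw":
            # omega = (Om s, phid, Om c)
            gx = -phidd + Om * Om * s * c
            gy = Omd * s + 2.0 * Om * phid * c
            return gx, gy
        # pitch: omega = (Om c, phid, -Om s)
        gx = -phidd - Om * Om * s * c
        gy = Omd * c - 2.0 * Om * phid * s
        return gx, gy

    return (lambda t: coeffs(t)[0]), (lambda t: coeffs(t)[1])


# ---------------------------------------------------------------------------
# eigenfrequency and damping
# ---------------------------------------------------------------------------

def eigenfrequency(spec: WingSpec, stiffness: StiffnessField | None = None,
                   nx: int = 50, ny: int = 25, n_modes: int = 1):
    """First structural eigenfrequency (rad/s) of the clamped-free plate.

    Returns ``(omega_n, modes)`` where ``modes`` holds the full DOF vectors
    of the requested mode shapes.  ``stiffness`` defaults to the field built
    from ``spec`` on the same mesh.
    """
    if stiffness is None:
        stiffness = build_stiffness_field(spec, nx=nx, ny=ny)
    plate = PlateModel(spec.span, spec.chord, spec.thickness, spec.density,
                       spec.poisson, stiffness.E, nx=nx, ny=ny)
    omega, modes = plate.eigenfrequencies(n_modes=n_modes)
    if n_modes == 1:
        return float(omega[0]), modes[:, 0]
    return omega, modes


def damping_coefficient(zeta: float, mass: float, omega_n: float) -> DampingSpec:
    """Total damping coefficient c = 2 zeta m omega_n (N s / m)."""
    if zeta < 0 or mass < 0 or omega_n < 0:
        raise ValueError("zeta, mass and omega_n must be non-negative")
    return DampingSpec(c=2.0 * zeta * mass * omega_n, zeta=zeta,
                       mass=mass, omega_n=omega_n)


# ---------------------------------------------------------------------------
# strain simulation
# ---------------------------------------------------------------------------

def simulate_strain(spec: WingSpec, kin: Kinematics, dt: float = 2e-4,
                    n_cycles: int | None = None, nx: int = 50, ny: int = 25,
                    max_cycles: int = 10, periodicity_tol: float = 0.01,
                    record_energy: bool = False) -> StrainField:
    """Integrate the damped plate through flapping (+ rotation) wingbeats.

    The wing starts at rest; the body rotation, if any, ramps up over the
    first ``kin.ramp_cycles`` wingbeats.  Simulation proceeds wingbeat by
    wingbeat until the strain pattern of the last two cycles agrees to
    ``periodicity_tol`` of the overall amplitude (capped at ``max_cycles``),
    or for exactly ``n_cycles`` wingbeats when given (must be >= 3).  The
    final full wingbeat is marked as the analysis window.
    """
    if n_cycles is not None and n_cycles < 3:
        raise ValueError("n_cycles must be at least 3 (ramp + transient + analysis)")

    stiffness = build_stiffness_field(spec, nx=nx, ny=ny)
    plate = PlateModel(spec.span, spec.chord, spec.thickness, spec.density,
                       spec.poisson, stiffness.E, nx=nx, ny=ny)
    omega_n, _ = plate.eigenfrequencies(n_modes=1)
    omega_n = float(omega_n[0])
    damping = damping_coefficient(spec.zeta, plate.mass, omega_n)

    g_x, g_y = _load_coefficients(kin)
    y_axis = (spec.chord / 2.0 if kin.axis_chord_position is None
              else float(kin.axis_chord_position))
    Ly_vec = (plate.LY - y_axis * plate.L0)[plate.free]
    T = kin.period
    spc = int(round(T / dt))
    if not np.isclose(spc * dt, T, rtol=1e-9):
        warnings.warn("time step does not divide the wingbeat period evenly")

    target = n_cycles if n_cycles is not None else max_cycles
    min_cycles = n_cycles if n_cycles is not None else max(3, kin.ramp_cycles + 2)

    notes: list[str] = []
    q = v = None
    strain_chunks = []
    time_chunks = []
    rec = None
    per_err = np.inf
    cycles_run = 0
    while cycles_run < target:
        rec = plate.integrate(g_x, g_y, dt, spc, damping.c, q0=q, v0=v,
                              record_energy=record_energy,
                              t0=cycles_run * spc * dt, Ly=Ly_vec)
        q, v = rec.q, rec.v
        # drop the duplicated first sample on continuation chunks
        s0 = 1 if cycles_run > 0 else 0
        strain_chunks.append(rec.strain[:, s0:])
        time_chunks.append(rec.times[s0:])
        cycles_run += 1
        if cycles_run >= 2:
            eps = np.concatenate(strain_chunks, axis=1)
            last = eps[:, -spc:]
            prev = eps[:, -2 * spc:-spc]
            amp = np.abs(last).max()
            per_err = np.abs(last - prev).max() / amp if amp > 0 else 0.0
            if (n_cycles is None and cycles_run >= min_cycles
                    and per_err < periodicity_tol):
                break

    epsilon = np.concatenate(strain_chunks, axis=1)
    times = np.concatenate(time_chunks)
    n_samples = epsilon.shape[1]

    if per_err >= periodicity_tol and np.isfinite(per_err):
        msg = (f"steady periodicity not reached: last-cycle change "
               f"{per_err:.3g} exceeds tolerance {periodicity_tol:g}")
        notes.append(msg)
        warnings.warn(msg)

    condition = ("flap" if kin.rotation_axis == "none" or kin.rotation_rate == 0
                 else f"flap+rotation({kin.rotation_axis})")
    window = (n_samples - spc, n_samples)

    provenance = {
        "spec": spec.__dict__.copy() if hasattr(spec, "__dict__") else {},
        "kinematics": {k: getattr(kin, k) for k in
                       ("A1", "A2", "f1", "f2", "rotation_axis",
                        "rotation_rate", "ramp_cycles")},
        "dt": dt, "nx": nx, "ny": ny, "cycles_run": cycles_run,
        "omega_n": omega_n, "damping_c": damping.c,
    }
    provenance["spec"] = {k: getattr(spec, k) for k in
                          ("span", "chord", "thickness", "density", "poisson",
                           "E_mean", "gradient", "decline_x", "decline_y", "zeta")}

    return StrainField(
        epsilon_xx=epsilon, times=times, X=plate.X, Y=plate.Y,
        grid_shape=(ny + 1, nx + 1), condition=condition,
        wingbeat_window=window, dt=dt, periodicity_error=float(per_err),
        provenance=provenance, warnings=notes,
    )
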