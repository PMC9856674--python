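"""Particle dynamics in a clinorotated fluid-filled vessel.

A small sphere suspended in a vessel rotating at angular velocity omega about
a horizontal axis obeys, in complex rotating-frame coordinates
q = x_rot + i*y_rot = z * exp(-i*omega*t) (z the lab frame),

    m q'' + (2*i*omega*m + lam) q' - omega^2 (m - m_w) q
        = -i g (m - m_w) exp(-i*omega*t),

with m the particle mass, m_w the mass of displaced fluid, lam the viscous
drag coefficient (Stokes: 6*pi*eta*a), and g gravity.  The motion separates
into a circular orbit — the particular solution q_p = A exp(-i*omega*t) with

    A = -i g (m - m_w) / (omega * (omega * m_w - i * lam)),

whose radius |A| reduces to v_T/omega in the overdamped limit (v_T the
terminal sedimentation velocity g(m - m_w)/lam) — and a slow centrifugal
drift, the small root of the characteristic polynomial
m s^2 + (2*i*omega*m + lam) s - omega^2 (m - m_w) = 0, with overdamped
growth rate omega^2 v_T / g.  The orbit-radius-versus-1/omega line with
slope v_T is the quantity used to validate a clinostat design.

For micron-scale particles lam/m reaches ~1e6–1e7 1/s, so the full ODE is
stiff; integration uses an implicit scheme (Radau) with an analytic
Jacobian, and a first-order overdamped reduction (m q'' dropped) is provided
as a fast cross-check mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ClinostatSystem",
    "Trajectory",
    "integrate_trajectory",
    "steady_state_radius",
    "radial_drift_rate",
    "radius_curve",
]

RPM_PER_RAD_S = 60.0 / (2.0 * np.pi)  # 1 rad/s ~ 9.549 RPM


@dataclass
class ClinostatSystem:
    """Rotation, particle, fluid, and drag parameters (SI units throughout).

    Drag can be supplied directly (``drag``, kg/s), through a fluid
    viscosity (Stokes law), or implied by a measured terminal velocity
    ``terminal_velocity`` (signed: positive = sinking).  Supplying both drag
    and terminal velocity requires them to agree to 1e-6 relative.
    """

    omega: float  # rad/s
    particle_radius: float  # m
    particle_density: float  # kg/m^3
    fluid_density: float = 1000.0  # kg/m^3
    viscosity: float | None = None  # Pa*s, for Stokes drag
    drag: float | None = None  # kg/s
    terminal_velocity: float | None = None  # m/s, signed
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        for name in ("omega", "particle_radius", "particle_density", "fluid_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gravity < 0:
            raise ValueError("gravity must be non-negative")
        if self.drag is None and self.viscosity is not None:
            self.drag = 6.0 * np.pi * self.viscosity * self.particle_radius
        if self.drag is None and self.terminal_velocity is not None:
            dm = self.buoyant_mass
            if dm == 0:
                raise ValueError(
                    "terminal velocity cannot determine drag for a neutrally "
                    "buoyant particle"
                )
            self.drag = self.gravity * dm / self.terminal_velocity
        if self.drag is None:
            raise ValueError("supply drag, viscosity, or terminal_velocity")
        if self.drag <= 0:
            raise ValueError("drag must be positive")
        if self.terminal_velocity is not None:
            implied = self.gravity * self.buoyant_mass / self.drag
            scale = max(abs(self.terminal_velocity), abs(implied))
            if scale > 0 and abs(implied - self.terminal_velocity) > 1e-6 * scale:
                raise ValueError(
                    f"terminal_velocity={self.terminal_velocity} inconsistent with "
                    f"drag-implied value {implied} (tolerance 1e-6 relative)"
                )

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.particle_radius**3

    @property
    def mass(self) -> float:
        return self.particle_density * self.volume

    @property
    def displaced_mass(self) -> float:
        return self.fluid_density * self.volume

    @property
    def buoyant_mass(self) -> float:
        """m - m_w; any sign (zero = neutral buoyancy)."""
        return self.mass - self.displaced_mass

    @property
    def v_terminal(self) -> float:
        """Signed terminal sedimentation velocity g(m - m_w)/lam."""
        if self.terminal_velocity is not None:
            return self.terminal_velocity
        return self.gravity * self.buoyant_mass / self.drag

    def particular_amplitude(self) -> complex:
        """Complex amplitude A of the circular-orbit particular solution."""
        dm = self.buoyant_mass
        return -1j * self.gravity * dm / (
            self.omega * (self.omega * self.displaced_mass - 1j * self.drag)
        )

    def characteristic_roots(self) -> tuple[complex, complex]:
        """(slow, fast) roots of m s^2 + (2 i omega m + lam) s - omega^2 (m - m_w)."""
        m = self.mass
        roots = np.roots(
            [m, 2j * self.omega * m + self.drag, -self.omega**2 * self.buoyant_mass]
        )
        slow, fast = sorted(roots, key=abs)
        return complex(slow), complex(fast)


@dataclass
class Trajectory:
    """Integrated particle path in both frames, plus steady-state summaries."""

    times: np.ndarray
    q: np.ndarray  # rotating frame, complex
    omega: float
    steady_orbit_radius: float
    radial_growth_rate: float
    n_per_period: int = field(default=64, repr=False)

    @property
    def z(self) -> np.ndarray:
        """Lab frame: z = q * exp(i*omega*t); |z| = |q| by construction."""
        return self.q * np.exp(1j * self.omega * self.times)


def _measure_orbit_and_drift(
    t: np.ndarray, q: np.ndarray, omega: float, n_per_period: int
) -> tuple[float, float]:
    """Orbit radius and drift rate from the late-time solution.

    The e^{-i omega t} Fourier coefficient over the last full period gives
    the orbit amplitude (the slow mode averages out over a period); the
    per-period means trace the slowly drifting orbit center, and the slope
    of log|center| over the second half of the run gives the radial growth
    rate.
    """
    n_periods = (len(t) - 1) // n_per_period
    last = slice(len(t) - n_per_period - 1, len(t) - 1)
    radius = abs(np.mean(q[last] * np.exp(1j * omega * t[last])))

    centers, mids = [], []
    for p in range(n_periods):
        seg = slice(p * n_per_period, (p + 1) * n_per_period)
        centers.append(np.mean(q[seg]))
        mids.append(np.mean(t[seg]))
    centers = np.abs(np.array(centers))
    mids = np.array(mids)
    half = len(centers) // 2
    usable = centers[half:] > 0
    if usable.sum() >= 2:
        slope = np.polyfit(mids[half:][usable], np.log(centers[half:][usable]), 1)[0]
    else:
        slope = 0.0
    return float(radius), float(slope)


def integrate_trajectory(
    system: ClinostatSystem,
    q0: complex = 0.0,
    v0: complex = 0.0,
    n_periods: int = 20,
    n_per_period: int = 64,
    mode: str = "full",
    rtol: float = 1e-10,
    atol: float = 1e-18,
) -> Trajectory:
    """Integrate the rotating-frame equation of motion.

    ``mode='full'`` solves the second-order ODE with the implicit Radau
    scheme (stable in the stiff overdamped regime); ``mode='overdamped'``
    solves the first-order reduction with inertia dropped.  The duration is
    ``n_periods`` rotation periods sampled ``n_per_period`` times per period.
    """
    if n_periods < 2:
        raise ValueError("need at least two rotation periods")
    m, lam, w = system.mass, system.drag, system.omega
    dm = system.buoyant_mass
    g = system.gravity
    period = 2.0 * np.pi / w
    t_end = n_periods * period
    t_eval = np.linspace(0.0, t_end, n_periods * n_per_period + 1)

    if mode == "full":
        # state [Re q, Im q, Re q', Im q']
        def rhs(t, y):
            u, v, du, dv = y
            fr = -g * dm * np.sin(w * t)
            fi = -g * dm * np.cos(w * t)
            ddu = (-lam * du + 2 * w * m * dv + w**2 * dm * u + fr) / m
            ddv = (-lam * dv - 2 * w * m * du + w**2 * dm * v + fi) / m
            return [du, dv, ddu, ddv]

        jac = np.array(
            [
                [0, 0, 1, 0],
                [0, 0, 0, 1],
                [w**2 * dm / m, 0, -lam / m, 2 * w],
                [0, w**2 * dm / m, -2 * w, -lam / m],
            ]
        )
        y0 = [q0.real, q0.imag, v0.real, v0.imag]
        sol = solve_ivp(
            rhs, (0.0, t_end), y0, method="Radau", t_eval=t_eval,
            jac=lambda t, y: jac, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed ({sol.message}); try a smaller step or the "
                "overdamped mode"
            )
        q = sol.y[0] + 1j * sol.y[1]
    elif mode == "overdamped":
        # (2 i omega m + lam) q' = omega^2 (m - m_w) q - i g (m - m_w) e^{-i w t}
        coeff = 2j * w * m + lam

        def rhs_od(t, y):
            q = y[0] + 1j * y[1]
            dq = (w**2 * dm * q - 1j * g * dm * np.exp(-1j * w * t)) / coeff
            return [dq.real, dq.imag]

        sol = solve_ivp(
            rhs_od, (0.0, t_end), [q0.real, q0.imag], method="RK45",
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed ({sol.message})")
        q = sol.y[0] + 1j * sol.y[1]
    else:
        raise ValueError("mode must be 'full' or 'overdamped'")

    # blow-up guard: the solution cannot exceed the analytic envelope
    A = system.particular_amplitude()
    slow, _ = system.characteristic_roots()
    envelope = (abs(A) + abs(q0) + abs(v0) / max(w, 1e-300)) * np.exp(
        max(slow.real, 0.0) * t_end
    )
    if np.max(np.abs(q)) > 100.0 * max(envelope, 1e-300):
        raise RuntimeError(
            "integration unstable (solution exceeds the analytic envelope); "
            "reduce the step size or use an implicit scheme"
        )

    radius, drift = _measure_orbit_and_drift(t_eval, q, w, n_per_period)
    return Trajectory(
        times=t_eval,
        q=q,
        omega=w,
        steady_orbit_radius=radius,
        radial_growth_rate=drift,
        n_per_period=n_per_period,
    )


def steady_state_radius(system: ClinostatSystem, mode: str = "exact") -> float:
    """Radius of the steady circular orbit.

    ``exact`` is the modulus of the particular-solution amplitude;
    ``overdamped`` is the closed form |v_T|/omega valid for lam >> omega*m_w.
    """
    if mode == "exact":
        return abs(system.particular_amplitude())
    if mode == "overdamped":
        return abs(system.v_terminal) / system.omega
    raise ValueError("mode must be 'exact' or 'overdamped'")


def radial_drift_rate(system: ClinostatSystem, mode: str = "exact") -> float:
    """Growth rate (1/s) of the slow centrifugal drift of the orbit center.

    ``exact`` is the real part of the slow characteristic root;
    ``overdamped`` is the closed form omega^2 * v_T / g.
    """
    if mode == "exact":
        slow, _ = system.characteristic_roots()
        return slow.real
    if mode == "overdamped":
        return system.omega**2 * system.v_terminal / system.gravity
    raise ValueError("mode must be 'exact' or 'overdamped'")


def radius_curve(
    system: ClinostatSystem,
    omegas: Sequence[float],
    vt_sd: float | None = None,
    mode: str = "exact",
) -> pd.DataFrame:
    """Steady orbit radius as a function of inverse angular velocity.

    Returns columns omega, inv_omega, radius and, when ``vt_sd`` is given,
    radius_low / radius_high for terminal velocities one SD either side of
    the measured mean (overdamped band r = |v_T +- sd| / omega).
    """
    omegas = np.asarray(list(omegas), dtype=float)
    if np.any(omegas <= 0):
        raise ValueError("all omegas must be positive")
    rows = []
    vt = system.v_terminal
    for w in omegas:
        sys_w = _replace(system, omega=float(w))
        row = {
            "omega": float(w),
            "inv_omega": 1.0 / float(w),
            "radius": steady_state_radius(sys_w, mode=mode),
        }
        if vt_sd is not None:
            lo, hi = sorted((abs(vt) - vt_sd, abs(vt) + vt_sd))
            row["radius_low"] = max(lo, 0.0) / float(w)
            row["radius_high"] = hi / float(w)
        rows.append(row)
    return pd.DataFrame(rows)
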