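"""Forward simulation of the key-finger-exoskeleton system.

The finger is a planar serial chain of rigid phalanges (three links for the
long fingers, two for the thumb) moving in the sagittal plane.  The piano
key is a linear spring-damper acting at the fingertip while in contact.  The
exoskeleton contributes passive dynamics (inertia, damping, structural
stiffness about an equilibrium pose) plus an active PD drive toward a
desired trajectory, and per-joint muscle torques follow a Hill-type model:
maximum isometric force scaled by force-length and force-velocity curves,
activation, and the (virtual-work) moment arm.

Coupled dynamics integrated with fixed-step RK4:

    [Mf(th) + Me] th'' + Cf(th, th') th' + Ce th' + Ks (th - th_eq)
        = tau_muscle + tau_pd + J^T F_key

All quantities SI; angles in radians.  The chain inertia matrix comes from
uniform-rod link approximations; Coriolis/centrifugal terms use Christoffel
symbols evaluated by central finite differences of the mass matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import warnings

import numpy as np

from .errors import DataError, SimulationDivergedError

__all__ = [
    "KeyModel",
    "FingerChain",
    "ExoModel",
    "MuscleModel",
    "SimTrace",
    "key_force",
    "fingertip_jacobian",
    "force_length",
    "force_velocity",
    "hill_torque",
    "moment_arm",
    "joint_torque_and_assist",
    "exo_torque",
    "mass_matrix",
    "coriolis_vector",
    "simulate",
]


@dataclass
class KeyModel:
    """Piano key as a linear spring-damper: F = ks*xk + bs*xk_dot."""

    ks: float = 150.0  # N/m
    bs: float = 1.0  # N*s/m
    travel: float = 0.01  # m

    def __post_init__(self) -> None:
        if self.ks <= 0:
            raise ValueError("key stiffness must be positive")
        if self.bs < 0:
            raise ValueError("key damping must be non-negative")


@dataclass
class FingerChain:
    """Planar rigid-link finger: lengths/masses per phalanx, joint labels.

    ``d_joint`` holds the distances from the exoskeleton force-application
    points to the joint centers of rotation (defaults to half link length).
    """

    lengths: np.ndarray  # m, per link
    masses: np.ndarray  # kg, per link
    joint_names: list[str] = field(default_factory=list)
    d_joint: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.lengths.size != self.masses.size:
            raise ValueError("lengths and masses must align")
        if self.lengths.size not in (2, 3):
            raise ValueError("finger chains have 2 (thumb) or 3 links")
        if np.any(self.lengths <= 0) or np.any(self.masses <= 0):
            raise ValueError("lengths and masses must be positive")
        if not self.joint_names:
            self.joint_names = (
                ["MCP", "PIP", "DIP"] if self.n_links == 3 else ["MC", "IP"]
            )
        if self.d_joint is None:
            self.d_joint = self.lengths / 2.0
        self.d_joint = np.asarray(self.d_joint, dtype=float)
        if np.any(self.d_joint <= 0):
            raise ValueError("d_joint distances must be positive")

    @property
    def n_links(self) -> int:
        return self.lengths.size

    @classmethod
    def index_finger(cls) -> "FingerChain":
        """Anthropometric default: adult index finger phalanges."""
        return cls(lengths=[0.045, 0.025, 0.018], masses=[0.012, 0.006, 0.004])


@dataclass
class ExoModel:
    """Exoskeleton passive dynamics plus PD assistance.

    Passive side: added inertia ``me``, damping ``ce`` and structural
    stiffness ``ks_struct`` about the gravity-compensated equilibrium
    ``theta_eq``.  Active side: PD gains ``kp``/``kd`` tracking the desired
    trajectory ``theta_d(t)`` (constant vector or callable of time).
    """

    me: np.ndarray
    ce: np.ndarray
    ks_struct: np.ndarray
    theta_eq: np.ndarray
    kp: np.ndarray
    kd: np.ndarray
    theta_d: np.ndarray | Callable[[float], np.ndarray] | None = None
    theta_d_dot: np.ndarray | Callable[[float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.theta_eq, dtype=float).size
        self.theta_eq = np.asarray(self.theta_eq, dtype=float)
        for name in ("me", "ce", "ks_struct", "kp", "kd"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim <= 1:
                m = np.diag(np.broadcast_to(m, (n,)).astype(float))
            if m.shape != (n, n):
                raise ValueError(f"{name} must be scalar, length-{n} or {n}x{n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(m) < -1e-9):
                raise ValueError(f"{name} must be positive semidefinite")
            setattr(self, name, m)

    def desired(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        n = self.theta_eq.size
        if self.theta_d is None:
            thd = self.theta_eq
        elif callable(self.theta_d):
            thd = np.asarray(self.theta_d(t), dtype=float)
        else:
            thd = np.asarray(self.theta_d, dtype=float)
        if self.theta_d_dot is None:
            thd_dot = np.zeros(n)
        elif callable(self.theta_d_dot):
            thd_dot = np.asarray(self.theta_d_dot(t), dtype=float)
        else:
            thd_dot = np.asarray(self.theta_d_dot, dtype=float)
        return thd, thd_dot

    @classmethod
    def passive_only(cls, n: int, stiffness: float = 0.05, damping: float = 0.02,
                     inertia: float = 1e-3,
                     theta_eq: Sequence[float] | None = None) -> "ExoModel":
        """Exoskeleton with no PD drive.

        ``inertia`` defaults to 1e-3 kg m^2 per joint — the reflected inertia
        of a linear push-rod actuator through its linkage, which dominates
        the tiny phalanx inertias and sets the system's time scale.
        """
        eq = np.zeros(n) if theta_eq is None else np.asarray(theta_eq, float)
        return cls(me=inertia * np.ones(n), ce=damping * np.ones(n),
                   ks_struct=stiffness * np.ones(n), theta_eq=eq,
                   kp=np.zeros(n), kd=np.zeros(n))

    @classmethod
    def pd_default(cls, n: int, theta_d: Sequence[float] | None = None,
                   kp: float = 0.5, kd: float = 0.05) -> "ExoModel":
        """PD-driven exoskeleton with default passive terms."""
        thd = np.zeros(n) if theta_d is None else np.asarray(theta_d, float)
        return cls(me=1e-3 * np.ones(n), ce=0.01 * np.ones(n),
                   ks_struct=0.05 * np.ones(n), theta_eq=thd,
                   kp=kp * np.ones(n), kd=kd * np.ones(n), theta_d=thd)


@dataclass
class MuscleModel:
    """Hill-type muscle acting about one joint.

    ``lmt`` maps joint angle to musculotendon length (m); its derivative is
    the moment arm.  ``l_opt`` and ``v_max`` normalize fiber length and
    shortening velocity for the force-length / force-velocity curves.
    """

    fmax: float
    lmt: Callable[[float], float]
    l_opt: float = 1.0
    v_max: float = 1.0
    fl_width: float = 0.45
    fv_shape: float = 0.25
    activation: Callable[[float], float] | float = 0.0

    def __post_init__(self) -> None:
        if self.fmax <= 0:
            raise ValueError("fmax must be positive")

    def alpha(self, t: float) -> float:
        a = self.activation(t) if callable(self.activation) else self.activation
        return float(a)


@dataclass
class SimTrace:
    """Simulated trajectories of the coupled system (uniform time grid)."""

    t: np.ndarray
    theta: np.ndarray  # (steps, n_joints)
    theta_dot: np.ndarray
    tau_m: np.ndarray
    tau_e: np.ndarray
    f_key: np.ndarray  # scalar key force per step
    f_assist: np.ndarray  # (steps, n_joints)


# ------------------------------------------------------------- primitives


def key_force(xk: float, vk: float, key: KeyModel) -> float:
    """Elastic key feedback force F = ks*xk + bs*vk (N)."""
    return key.ks * xk + key.bs * vk


def _abs_angles(theta: np.ndarray) -> np.ndarray:
    return np.cumsum(theta)


def fingertip_position(chain: FingerChain, theta: np.ndarray) -> np.ndarray:
    phi = _abs_angles(theta)
    return np.array([np.sum(chain.lengths * np.cos(phi)),
                     np.sum(chain.lengths * np.sin(phi))])


def fingertip_jacobian(chain: FingerChain, theta: np.ndarray) -> np.ndarray:
    """Planar position Jacobian (2 x n) of the fingertip."""
    theta = np.asarray(theta, dtype=float)
    n = chain.n_links
    phi = _abs_angles(theta)
    J = np.zeros((2, n))
    for j in range(n):
        J[0, j] = -np.sum(chain.lengths[j:] * np.sin(phi[j:]))
        J[1, j] = np.sum(chain.lengths[j:] * np.cos(phi[j:]))
    return J


def force_length(l_norm: float, width: float = 0.45) -> float:
    """Gaussian force-length curve, f(1) = 1."""
    return float(np.exp(-(((l_norm - 1.0) / width) ** 2)))


def force_velocity(v_norm: float, shape: float = 0.25) -> float:
    """Hill hyperbolic force-velocity curve, f(0) = 1.

    ``v_norm`` > 0 is shortening (force drops to 0 at v_norm = 1); negative
    values (lengthening) follow the standard eccentric branch saturating at
    1.5 x isometric.
    """
    if v_norm >= 1.0:
        return 0.0
    if v_norm >= 0.0:
        return float((1.0 - v_norm) / (1.0 + v_norm / shape))
    return float(1.5 - 0.5 * (1.0 + v_norm) / (1.0 - 7.56 * v_norm / shape))


def hill_torque(
    m: MuscleModel, l_norm: float, v_norm: float, alpha: float, theta: float
) -> float:
    """Joint torque of a Hill-type muscle: Fmax * f_l * f_v * alpha * r_m(theta)."""
    if not 0.0 <= alpha <= 1.0:
        warnings.warn(f"activation {alpha} clamped to [0, 1]", stacklevel=2)
        alpha = float(np.clip(alpha, 0.0, 1.0))
    r = moment_arm(m.lmt, theta)
    return (m.fmax * force_length(l_norm, m.fl_width)
            * force_velocity(v_norm, m.fv_shape) * alpha * r)


def moment_arm(lmt: Callable[[float], float], theta: float, h: float = 1e-5) -> float:
    """Moment arm as the central finite difference of musculotendon length."""
    lo, hi = lmt(theta - h), lmt(theta + h)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise DataError("musculotendon length is non-finite near theta")
    return float((hi - lo) / (2.0 * h))


def joint_torque_and_assist(Ft: float, r_m: float, d_joint: float) -> tuple[float, float]:
    """Joint torque tau = Ft * r_m and assistive force Fa = tau / d_joint."""
    if d_joint <= 0:
        raise ValueError("d_joint must be positive")
    tau = Ft * r_m
    return tau, tau / d_joint


def exo_torque(exo: ExoModel, theta: np.ndarray, theta_dot: np.ndarray, t: float = 0.0) -> np.ndarray:
    """PD assistance torque Kp (th_d - th) + Kd (th_d' - th')."""
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    n = exo.theta_eq.size
    if theta.size != n or theta_dot.size != n:
        raise ValueError("state dimension does not match exoskeleton model")
    thd, thd_dot = exo.desired(t)
    return exo.kp @ (thd - theta) + exo.kd @ (thd_dot - theta_dot)


# ---------------------------------------------------------------- dynamics


def _com_jacobians(chain: FingerChain, theta: np.ndarray) -> list[np.ndarray]:
    n = chain.n_links
    phi = _abs_angles(theta)
    jacs = []
    for i in range(n):
        J = np.zeros((2, n))
        for j in range(i + 1):
            # distal half-link for the i-th COM
            lengths = chain.lengths[j : i + 1].copy()
            lengths[-1] *= 0.5
            J[0, j] = -np.sum(lengths * np.sin(phi[j : i + 1]))
            J[1, j] = np.sum(lengths * np.cos(phi[j : i + 1]))
        jacs.append(J)
    return jacs


def mass_matrix(chain: FingerChain, theta: np.ndarray) -> np.ndarray:
    """Configuration-dependent inertia matrix (uniform-rod links)."""
    theta = np.asarray(theta, dtype=float)
    n = chain.n_links
    M = np.zeros((n, n))
    for i, Jc in enumerate(_com_jacobians(chain, theta)):
        m_i = chain.masses[i]
        I_i = m_i * chain.lengths[i] ** 2 / 12.0
        Jw = np.zeros(n)
        Jw[: i + 1] = 1.0
        M += m_i * Jc.T @ Jc + I_i * np.outer(Jw, Jw)
    return M


def coriolis_vector(
    chain: FingerChain, theta: np.ndarray, theta_dot: np.ndarray, h: float = 1e-6
) -> np.ndarray:
    """Coriolis/centrifugal torques via Christoffel symbols (numeric dM/dth)."""
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    n = chain.n_links
    dM = np.empty((n, n, n))  # dM[k] = dM/dtheta_k
    for k in range(n):
        e = np.zeros(n)
        e[k] = h
        dM[k] = (mass_matrix(chain, theta + e) - mass_matrix(chain, theta - e)) / (2 * h)
    c = np.zeros(n)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                gamma = 0.5 * (dM[j][k, i] + dM[i][k, j] - dM[k][i, j])
                c[k] += gamma * theta_dot[i] * theta_dot[j]
    return c


def gravity_torque(chain: FingerChain, theta: np.ndarray, g: float) -> np.ndarray:
    if g == 0.0:
        return np.zeros(chain.n_links)
    tau = np.zeros(chain.n_links)
    for i, Jc in enumerate(_com_jacobians(chain, theta)):
        tau -= chain.masses[i] * g * Jc[1]  # d(y_com)/dtheta
    return tau


def default_contact(key: KeyModel, key_height: float = 0.0):
    """Contact rule: compression = downward fingertip excursion past the key top."""

    def rule(tip: np.ndarray, tip_vel: np.ndarray) -> tuple[float, float]:
        xk = key_height - tip[1]
        if xk <= 0:
            return 0.0, 0.0
        return min(xk, key.travel), -tip_vel[1]

    return rule


def simulate(
    chain: FingerChain,
    key: KeyModel | None,
    exo: ExoModel,
    muscles: Sequence[MuscleModel | None] | None = None,
    duration: float = 1.0,
    dt: float = 1e-3,
    contact: Callable[[np.ndarray, np.ndarray], tuple[float, float]] | None = None,
    theta0: np.ndarray | None = None,
    theta_dot0: np.ndarray | None = None,
    gravity: float = 0.0,
) -> SimTrace:
    """Fixed-step RK4 integration of the coupled key-finger-exoskeleton dynamics.

    ``contact`` maps (tip position, tip velocity) to (key compression,
    compression rate); key force acts only while compression > 0 and is
    transmitted to the joints through the fingertip Jacobian transpose.
    ``muscles`` supplies at most one Hill-type muscle per joint (None for an
    inactive joint).  Raises :class:`SimulationDivergedError` on a
    non-finite state, reporting the last valid time.
    """
    if dt > 2e-3 or dt <= 0:
        raise ValueError("dt must lie in (0, 2 ms]")
    n = chain.n_links
    muscles = list(muscles) if muscles is not None else [None] * n
    if len(muscles) != n:
        raise ValueError("one muscle slot per joint required")
    theta = np.zeros(n) if theta0 is None else np.asarray(theta0, float).copy()
    theta_dot = np.zeros(n) if theta_dot0 is None else np.asarray(theta_dot0, float).copy()
    if exo.theta_eq.size != n:
        raise ValueError("exoskeleton dimension does not match chain")

    def muscle_torques(th: np.ndarray, thd: np.ndarray, t: float) -> np.ndarray:
        tau = np.zeros(n)
        for j, mus in enumerate(muscles):
            if mus is None:
                continue
            r = moment_arm(mus.lmt, th[j])
            l_norm = mus.lmt(th[j]) / mus.l_opt
            v_norm = r * thd[j] / mus.v_max
            a = float(np.clip(mus.alpha(t), 0.0, 1.0))
            tau[j] = (mus.fmax * force_length(l_norm, mus.fl_width)
                      * force_velocity(v_norm, mus.fv_shape) * a * r)
        return tau

    def key_state(th: np.ndarray, thd: np.ndarray) -> tuple[float, np.ndarray]:
        if key is None or contact is None:
            return 0.0, np.zeros(n)
        J = fingertip_jacobian(chain, th)
        tip = fingertip_position(chain, th)
        tip_vel = J @ thd
        xk, vk = contact(tip, tip_vel)
        if xk <= 0:
            return 0.0, np.zeros(n)
        F = max(key_force(xk, vk, key), 0.0)  # key pushes, never pulls
        return F, J.T @ np.array([0.0, F])  # upward reaction on the fingertip

    def accel(t: float, th: np.ndarray, thd: np.ndarray) -> np.ndarray:
        M = mass_matrix(chain, th) + exo.me
        c = coriolis_vector(chain, th, thd) + exo.ce @ thd
        spring = exo.ks_struct @ (th - exo.theta_eq)
        tau_m = muscle_torques(th, thd, t)
        tau_pd = exo_torque(exo, th, thd, t)
        _, tau_key = key_state(th, thd)
        rhs = tau_m + tau_pd + tau_key + gravity_torque(chain, th, gravity) - c - spring
        return np.linalg.solve(M, rhs)

    steps = int(round(duration / dt)) + 1
    t_grid = np.arange(steps) * dt
    out_theta = np.empty((steps, n))
    out_thd = np.empty((steps, n))
    out_tau_m = np.empty((steps, n))
    out_tau_e = np.empty((steps, n))
    out_fkey = np.empty(steps)
    out_fa = np.empty((steps, n))

    for s, t in enumerate(t_grid):
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(theta_dot))):
            raise SimulationDivergedError(
                f"state became non-finite at t={t:.4f}s",
                last_valid_time=float(t_grid[max(s - 1, 0)]),
            )
        tau_m = muscle_torques(theta, theta_dot, t)
        out_theta[s] = theta
        out_thd[s] = theta_dot
        out_tau_m[s] = tau_m
        out_tau_e[s] = exo_torque(exo, theta, theta_dot, t)
        out_fkey[s], _ = key_state(theta, theta_dot)
        out_fa[s] = tau_m / chain.d_joint
        if s == steps - 1:
            break
        # RK4 step
        k1v = accel(t, theta, theta_dot)
        k1x = theta_dot
        k2v = accel(t + dt / 2, theta + dt / 2 * k1x, theta_dot + dt / 2 * k1v)
        k2x = theta_dot + dt / 2 * k1v
        k3v = accel(t + dt / 2, theta + dt / 2 * k2x, theta_dot + dt / 2 * k2v)
        k3x = theta_dot + dt / 2 * k2v
        k4v = accel(t + dt, theta + dt * k3x, theta_dot + dt * k3v)
        k4x = theta_dot + dt * k3v
        theta = theta + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        theta_dot = theta_dot + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)

    return SimTrace(t=t_grid, theta=out_theta, theta_dot=out_thd,
                    tau_m=out_tau_m, tau_e=out_tau_e, f_key=out_fkey,
                    f_assist=out_fa)
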