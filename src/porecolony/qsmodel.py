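"""Coupled glucose consumption–diffusion and AI-2 dynamics along a dead-end pore.

Inside a dead-end pore, glucose arrives only by diffusion from the
transmitting pore at the entrance while the resident biomass consumes it at
a fixed per-mass uptake rate; deeper than a limitation length ζ consumption
outpaces resupply and glucose is depleted.  Depletion lifts catabolite
repression of autoinducer-2 (AI-2) uptake, so quorum-sensing induction —
read out through the lsrR promoter — is expected deeper than ζ.

The model is one-dimensional along the pore axis x ∈ [0, L] (x = 0 at the
DEP–TP juncture):

    ∂c_G/∂t = D_G ∂²c_G/∂x² − U_1c · c_B            (glucose)
    ∂c_A/∂t = D_A ∂²c_A/∂x² + k_A+ c_B − k_A− f c_B  (AI-2)
    lsrR    = (1 − c_A)(1 − c_G)   on normalized fields

with f = 1 where glucose is below a threshold (catabolite repression
released) and 0 otherwise; the consumption term acts only where glucose is
still present.  Boundary conditions: glucose fixed at c_0 at the entrance
and no-flux at the dead end; AI-2 washed out at the entrance (advection in
the TP) and no-flux at the dead end.  Both equations are stepped with a
conservative backward-Euler scheme.

Two estimates of the limitation length are compared: the scaling
ζ = √(D τ_U) with τ_U = c_0/(U_1c·c̄_B), and the simulated front ζ_sim —
the shallowest x where the lsrR signal reaches 80% of its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "ModelParams",
    "ModelSolution",
    "DepletionLength",
    "stokes_einstein_diffusivity",
    "solve_coupled_model",
    "predict_zeta_scaling",
    "extract_zeta_sim",
    "lsr_signal",
]


def stokes_einstein_diffusivity(D_G: float, M_G: float, M_A: float) -> float:
    """AI-2 diffusivity from the glucose one via Stokes–Einstein.

    The hydrodynamic radius scales as the cube root of the molecular mass,
    so D_A = D_G · (M_G / M_A)^(1/3).
    """
    if D_G <= 0 or M_G <= 0 or M_A <= 0:
        raise ValueError("diffusivity and molecular masses must be positive")
    return D_G * (M_G / M_A) ** (1.0 / 3.0)


@dataclass
class ModelParams:
    """Physical and numerical parameters of the 1D DEP model.

    Units: lengths mm, times s, concentrations mM, biomass g/L.  ``U_1c`` is
    the glucose uptake rate per dry mass (mMol s⁻¹ g⁻¹); with c_B in g/L the
    product U_1c·c_B is a volumetric rate in mM/s.  ``k_Aplus``/``k_Aminus``
    are AI-2 production/uptake rates per biomass (mM s⁻¹ per g/L); their
    absolute scale cancels from the normalized lsrR signal.  ``theta_G`` is
    the glucose threshold of the catabolite switch f.  ``D_A`` defaults to
    the Stokes–Einstein value from the molecular masses (glucose 180.16,
    AI-2 as DPD 132.12 g/mol).
    """

    L: float = 0.2
    D_G: float = 6e-4
    U_1c: float = 10.0
    c_0: float = 5.0
    m_cell: float = 3e-13  # dry mass per cell, g
    k_Aplus: float = 1e-6
    k_Aminus: float = 2e-6
    theta_G: float = 0.05
    M_G: float = 180.16
    M_A: float = 132.12
    D_A: float | None = None
    dx: float | None = None  # default L/200
    dt: float = 0.1
    ai2_normalization: str = "production"  # or "instantaneous"

    def __post_init__(self) -> None:
        if self.dx is None:
            self.dx = self.L / 200.0
        if self.D_A is None:
            self.D_A = stokes_einstein_diffusivity(self.D_G, self.M_G, self.M_A)
        if min(self.L, self.D_G, self.U_1c, self.c_0, self.dt, self.dx) <= 0:
            raise ValueError("all physical parameters must be positive")
        if self.dx > self.L / 50.0:
            raise ValueError("grid step dx must be at most L/50")
        if not self.theta_G < self.c_0:
            raise ValueError("theta_G must lie below the entrance concentration")
        if self.ai2_normalization not in ("production", "instantaneous"):
            raise ValueError("ai2_normalization must be 'production' or 'instantaneous'")

    @property
    def x(self) -> np.ndarray:
        n = int(round(self.L / self.dx))
        return np.linspace(0.0, self.L, n + 1)


@dataclass
class ModelSolution:
    """Saved fields of one model run: glucose, AI-2, switch and lsrR signal."""

    x: np.ndarray
    times: np.ndarray
    c_G: np.ndarray  # (T, N) in mM
    c_AI2: np.ndarray  # (T, N), model units
    f: np.ndarray  # (T, N) binary switch
    lsrR: np.ndarray  # (T, N), in [0, 1]
    params: ModelParams
    U_T: float  # DEP-average uptake rate U_1c·mean(c_B), mM/s

    @property
    def c_G_norm(self) -> np.ndarray:
        return self.c_G / self.params.c_0


@dataclass
class DepletionLength:
    """Scaling estimate of the glucose limitation length and its time scales."""

    zeta_scaling: float  # √(D·τ_U), mm (clipped to [0, L])
    tau_U: float  # consumption time c_0/U_T, s
    tau_D: float  # diffusion time ζ²/D at the returned ζ, s
    U_T: float
    clipped: bool = False
    no_depletion: bool = False


def _banded_factor(n: int, alpha: float, dirichlet0: bool):
    """Banded (I − α·Lap) with Dirichlet at node 0, mirror no-flux at node n−1."""
    ab = np.zeros((3, n))
    ab[0, 1:] = -alpha  # upper
    ab[1, :] = 1.0 + 2.0 * alpha  # diag
    ab[2, :-1] = -alpha  # lower
    # no-flux at the far end: ghost mirror doubles the inner coupling
    ab[2, n - 2] = -2.0 * alpha
    if dirichlet0:
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
    else:
        # no-flux at node 0 as well (sealed)
        ab[1, 0] = 1.0 + 2.0 * alpha
        ab[0, 1] = -2.0 * alpha
    return ab


def _conservative_laplacian_step(c, ab):
    return solve_banded((1, 1), ab, c)


def solve_coupled_model(
    params: ModelParams,
    biomass: float | np.ndarray,
    t_end: float = 600.0,
    save_times: np.ndarray | None = None,
    glucose_boundary: str = "dirichlet",
) -> ModelSolution:
    """Backward-Euler integration of the coupled glucose/AI-2 system.

    ``biomass`` is c_B(x) in g/L (scalar = uniform), held constant in time
    unless an array of shape (T_frames, N) is given, in which case it is
    piecewise-constant between frames spanning [0, t_end].
    ``glucose_boundary='sealed'`` closes both ends (used to verify strict
    mass conservation of the transport scheme).
    """
    x = params.x
    n = len(x)
    dx, dt = params.dx, params.dt
    if save_times is None:
        save_times = np.array([t_end])
    save_times = np.asarray(save_times, dtype=float)

    cb = np.asarray(biomass, dtype=float)
    time_varying = cb.ndim == 2
    if cb.ndim == 0:
        cb = np.full(n, float(cb))
    if not time_varying and len(cb) != n:
        raise ValueError("biomass profile must match the model grid")
    if np.any(cb < 0):
        raise ValueError("biomass must be non-negative")

    dirichlet = glucose_boundary == "dirichlet"
    alpha_G = dt * params.D_G / dx**2
    alpha_A = dt * params.D_A / dx**2
    ab_G = _banded_factor(n, alpha_G, dirichlet0=dirichlet)
    ab_A = _banded_factor(n, alpha_A, dirichlet0=True)  # AI-2 washed out at x=0

    cG = np.full(n, params.c_0)
    cA = np.zeros(n)
    mean_cb = float(cb.mean())
    U_T = params.U_1c * mean_cb

    n_steps = int(np.ceil(t_end / dt))
    out_G, out_A, out_f, out_lsr, out_t = [], [], [], [], []
    si = 0
    t = 0.0

    def cb_at(t_now: float) -> np.ndarray:
        if not time_varying:
            return cb
        frames = cb.shape[0]
        k = min(int(t_now / t_end * frames), frames - 1)
        return cb[k]

    def record(t_now: float) -> None:
        f_now = (cG < params.theta_G).astype(float)
        gn = np.clip(cG / params.c_0, 0.0, 1.0)
        if params.ai2_normalization == "production":
            scale = params.k_Aplus * mean_cb * params.L**2 / params.D_A
        else:
            scale = cA.max()
        an = np.clip(cA / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(cA)
        out_G.append(cG.copy())
        out_A.append(cA.copy())
        out_f.append(f_now)
        out_lsr.append(lsr_signal(gn, an))
        out_t.append(t_now)

    for _ in range(n_steps):
        cb_now = cb_at(t)
        # glucose: implicit diffusion, explicit uptake active where c_G > 0
        uptake = params.U_1c * cb_now * (cG > 0)
        rhs = cG - dt * uptake
        if dirichlet:
            rhs[0] = params.c_0
        cG = _conservative_laplacian_step(rhs, ab_G)
        np.clip(cG, 0.0, params.c_0, out=cG)
        # AI-2: production everywhere, uptake where glucose is depleted
        f_now = (cG < params.theta_G).astype(float)
        src = (params.k_Aplus - params.k_Aminus * f_now) * cb_now
        rhs_A = cA + dt * src
        rhs_A[0] = 0.0
        cA = _conservative_laplacian_step(rhs_A, ab_A)
        np.clip(cA, 0.0, None, out=cA)
        t += dt
        while si < len(save_times) and t >= save_times[si] - dt / 2:
            record(save_times[si])
            si += 1
    while si < len(save_times):
        record(save_times[si])
        si += 1

    return ModelSolution(
        x=x,
        times=np.asarray(out_t),
        c_G=np.asarray(out_G),
        c_AI2=np.asarray(out_A),
        f=np.asarray(out_f),
        lsrR=np.asarray(out_lsr),
        params=params,
        U_T=U_T,
    )


def lsr_signal(c_G_norm: np.ndarray, c_AI2_norm: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """lsrR promoter signal (1 − c_AI2)(1 − c_G) on normalized fields."""
    g = np.asarray(c_G_norm, dtype=float)
    a = np.asarray(c_AI2_norm, dtype=float)
    for name, arr in (("glucose", g), ("AI-2", a)):
        if arr.min() < -tol or arr.max() > 1.0 + tol:
            raise ValueError(f"normalized {name} field outside [0, 1]")
    return (1.0 - a) * (1.0 - g)


def predict_zeta_scaling(
    params: ModelParams,
    biomass: float | np.ndarray,
) -> DepletionLength:
    """Scaling prediction ζ = √(D·τ_U) with τ_U = c_0/(U_1c·c̄_B).

    The diffusivity entering the scaling is the glucose one.  ζ is clipped
    to the DEP length (flagged); zero biomass means no depletion anywhere
    and returns ζ = L flagged accordingly.
    """
    cb = np.asarray(biomass, dtype=float)
    mean_cb = float(cb.mean())
    if mean_cb < 0:
        raise ValueError("biomass must be non-negative")
    if mean_cb == 0:
        return DepletionLength(
            zeta_scaling=params.L,
            tau_U=np.inf,
            tau_D=params.L**2 / params.D_G,
            U_T=0.0,
            clipped=True,
            no_depletion=True,
        )
    U_T = params.U_1c * mean_cb
    tau_U = params.c_0 / U_T
    zeta = np.sqrt(params.D_G * tau_U)
    clipped = zeta > params.L
    zeta = min(zeta, params.L)
    return DepletionLength(
        zeta_scaling=float(zeta),
        tau_U=float(tau_U),
        tau_D=float(zeta**2 / params.D_G),
        U_T=float(U_T),
        clipped=bool(clipped),
    )


def extract_zeta_sim(solution: ModelSolution, t: float | None = None, fraction: float = 0.8) -> float:
    """Simulated limitation length: shallowest x with lsrR ≥ 80% of its max.

    ``t`` selects the nearest saved time (default: the last).  Linear
    interpolation between grid nodes; NaN if the signal is identically zero.
    """
    if t is None:
        ti = len(solution.times) - 1
    else:
        ti = int(np.argmin(np.abs(solution.times - t)))
    prof = solution.lsrR[ti]
    amax = prof.max()
    if amax <= 0:
        return np.nan
    thr = fraction * amax
    above = prof >= thr
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    x0, x1 = solution.x[i - 1], solution.x[i]
    a0, a1 = prof[i - 1], prof[i]
    if a1 == a0:
        return float(x1)
    return float(x0 + (thr - a0) / (a1 - a0) * (x1 - x0))
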