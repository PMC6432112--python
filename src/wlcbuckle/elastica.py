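"""Zero-temperature Euler elastica: the fluctuation-free reference.

A hinged-hinged elastic rod of bending modulus kappa and length L under
a compressive end load f stays straight below the Euler force
fE = pi^2 kappa / L^2 and buckles above it.  The buckled shape follows
the pendulum equation; with elliptic modulus m (sin(theta_end/2) =
sqrt(m)) the standard parametric solution is

    sqrt(f/kappa) L = 2 K(m),      R/L = 2 E(m)/K(m) - 1,

with K, E the complete elliptic integrals, and the bending energy of the
buckled shape is EB = 2 f L (E/K - 1 + m).  All public functions work in
the chain's natural units (lengths 2 lp, energies kBT, forces
kBT/(2 lp)); a discrete-segment energy minimizer provides an
elliptic-function-free cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import ellipe, ellipj, ellipk

from .chain import ChainSpec

__all__ = [
    "ElasticaSolution",
    "euler_force",
    "euler_force_dimensionless",
    "elastica_extension",
    "min_bend_energy_at_R",
    "discrete_elastica_fixed_f",
    "discrete_elastica_fixed_R",
]


def euler_force(chain: ChainSpec) -> float:
    """Euler critical force fE = kBT lp pi^2 / L^2 (dimensional units)."""
    return chain.kBT * chain.lp * math.pi ** 2 / chain.L ** 2


def euler_force_dimensionless(N: float) -> float:
    """fE in kBT/(2 lp) units: pi^2 / (2 N^2)."""
    if N <= 0:
        raise ValueError("N must be > 0")
    return math.pi ** 2 / (2.0 * N * N)


def _modulus_from_force(load_ratio: float) -> float:
    """Solve 2 K(m) = pi sqrt(load_ratio) for m, load_ratio = f/fE > 1."""
    target = 0.5 * math.pi * math.sqrt(load_ratio)

    def g(m):
        return ellipk(m) - target

    # K(m) runs from pi/2 at m=0 to infinity at m=1
    hi = 1.0 - 1e-15
    if g(hi) < 0:
        raise ValueError(f"f/fE={load_ratio} beyond the elliptic solver's range")
    return brentq(g, 0.0, hi, xtol=1e-15, rtol=8.9e-16)


@dataclass
class ElasticaSolution:
    """A buckled (or straight) minimum-energy shape at fixed end distance."""

    chain: ChainSpec
    f: float              # compressive load, kBT/(2 lp)
    extension: float      # R/L
    s_grid: np.ndarray    # arclength, units of L
    theta: np.ndarray     # tangent angle along the rod
    bend_energy: float    # kBT

    def verify_extension(self) -> float:
        """Quadrature check: (1/L) int cos(theta) ds."""
        return float(np.trapezoid(np.cos(self.theta), self.s_grid))


def elastica_extension(chain: ChainSpec, f: float) -> float:
    """End extension R/L of the elastica under compressive load f.

    f in kBT/(2 lp) units; negative f (tension) and f <= fE return 1
    (the straight rod; tension does not stretch an inextensible rod at
    zero temperature).  The transition at fE is second order: R/L is
    continuous with a slope break.
    """
    fE = euler_force_dimensionless(chain.N)
    if f <= fE:
        return 1.0
    m = _modulus_from_force(f / fE)
    ext = 2.0 * ellipe(m) / ellipk(m) - 1.0
    if ext < -1.0 + 1e-9:
        raise ValueError(f"f/fE={f / fE:.3g} drives the rod into self-contact")
    return float(ext)


def _shape_from_modulus(chain: ChainSpec, m: float, n_s: int) -> tuple[np.ndarray, np.ndarray]:
    """theta(s) of the buckled hinged rod: sin(theta/2) = sqrt(m) sn(K - 2Ks/L)."""
    s = np.linspace(0.0, 1.0, n_s)
    Km = ellipk(m)
    sn, _, _, _ = ellipj(Km * (1.0 - 2.0 * s), m)
    theta = 2.0 * np.arcsin(np.sqrt(m) * sn)
    return s, theta


def min_bend_energy_at_R(chain: ChainSpec, R: float, n_s: int = 201) -> ElasticaSolution:
    """Minimal bending energy of a hinged rod constrained to end distance R.

    R in 2 lp units, 0 < R <= L.  The energy is zero for the straight rod
    (R = L) and grows as the end retraction L - R increases; near full
    extension it approaches fE (L - R), the second-order-transition
    energetics.
    """
    N = chain.N
    if R <= 0:
        raise ValueError("end distance R must be > 0")
    if R > N * (1.0 + 1e-12):
        raise ValueError(f"R={R} exceeds the contour length N={N} (inextensible)")
    fE = euler_force_dimensionless(N)
    ext = min(R / N, 1.0)
    if ext >= 1.0 - 1e-14:
        s = np.linspace(0.0, 1.0, n_s)
        return ElasticaSolution(chain=chain, f=fE, extension=1.0,
                                s_grid=s, theta=np.zeros(n_s), bend_energy=0.0)

    def g(m):
        return 2.0 * ellipe(m) / ellipk(m) - 1.0 - ext

    m = brentq(g, 1e-16, 1.0 - 1e-15, xtol=1e-15, rtol=8.9e-16)
    Km = ellipk(m)
    f = fE * (2.0 * Km / math.pi) ** 2
    eb = 2.0 * f * N * (ellipe(m) / Km - 1.0 + m)
    s, theta = _shape_from_modulus(chain, m, n_s)
    return ElasticaSolution(chain=chain, f=float(f), extension=float(ext),
                            s_grid=s, theta=theta, bend_energy=float(eb))


# ---------------------------------------------------------------------------
# brute-force discrete-segment oracle
# ---------------------------------------------------------------------------


def _discrete_energy_terms(theta: np.ndarray, N: float):
    n = len(theta)
    ds = N / n
    kappa = 0.5  # lp in 2 lp units
    bend = (kappa / (2.0 * ds)) * np.sum(np.diff(theta) ** 2)
    R = ds * math.hypot(float(np.sum(np.cos(theta))), float(np.sum(np.sin(theta))))
    return bend, R, ds, kappa


def discrete_elastica_fixed_f(N: float, f: float, n_seg: int = 201,
                              amp: float = 0.1) -> dict:
    """Minimize bend energy + f |R| over a planar n_seg-segment chain.

    Independent cross-check of the elliptic solution.  |R| is the true
    end-to-end distance (not a projection), so the soft rigid-rotation
    mode cannot cheat the load term.  The straight rod is a saddle above
    the Euler force; descent starts from a shallow sinusoid and the load
    is ramped to f in steps, warm-starting each minimization, to stay on
    the buckled branch.  Returns extension R/L and bending energy (kBT).
    """
    ds = N / n_seg
    s_mid = (np.arange(n_seg) + 0.5) * ds
    kappa = 0.5
    fE = euler_force_dimensionless(N)

    # classical column: both hinges ride on the load axis (transverse end
    # displacement zero) and the load works through the signed axial
    # projection, which goes negative when the ends cross (f >~ 2.18 fE)
    def objective(theta, fcur):
        dth = np.diff(theta)
        e = (kappa / (2.0 * ds)) * np.sum(dth ** 2) + fcur * ds * np.sum(np.cos(theta))
        grad = np.zeros_like(theta)
        grad[:-1] -= (kappa / ds) * dth
        grad[1:] += (kappa / ds) * dth
        grad -= fcur * ds * np.sin(theta)
        return e, grad

    # transverse end displacement enforced by a stiff quadratic penalty;
    # smooth unconstrained descent cannot hop the bending barrier to the
    # reversed-rod branch the way an SQP step can
    def penalized(theta, fcur, w):
        e, grad = objective(theta, fcur)
        y = ds * float(np.sum(np.sin(theta)))
        e += w * y * y
        grad += 2.0 * w * y * ds * np.cos(theta)
        return e, grad

    w = 2e3 * fE / N
    # hinged buckling mode: theta max at the moment-free ends
    theta = amp * np.cos(math.pi * s_mid / N)
    n_ramp = max(8, int(4.0 * f / fE)) if f > fE else 1
    f_steps = np.linspace(min(1.02 * fE, f), f, n_ramp) if f > fE else [f]
    ok = True
    for fcur in f_steps:
        out = minimize(penalized, theta, args=(fcur, w), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-11,
                                "maxcor": 30})
        theta = out.x
        ok = ok and bool(out.success)
    dth = np.diff(theta)
    bend = (kappa / (2.0 * ds)) * float(np.sum(dth ** 2))
    ext = float(np.sum(np.cos(theta))) * ds / N
    return {"theta": theta, "extension": ext, "bend_energy": bend,
            "converged": ok}


def discrete_elastica_fixed_R(N: float, R: float, n_seg: int = 201,
                              amp: float = 0.1) -> dict:
    """Minimize bend energy at fixed end distance R; brute-force oracle
    for ``min_bend_energy_at_R``.

    The end-to-end vector is gauge-fixed along x (sum of sines zero), so
    the constraint pair (projection = R, transverse = 0) pins the true
    end distance without leaving a soft rotation mode."""
    ds = N / n_seg
    s_mid = (np.arange(n_seg) + 0.5) * ds
    kappa = 0.5

    def energy(theta):
        dth = np.diff(theta)
        grad = np.zeros_like(theta)
        grad[:-1] -= (kappa / ds) * dth
        grad[1:] += (kappa / ds) * dth
        return (kappa / (2.0 * ds)) * np.sum(dth ** 2), grad

    cons = [
        {"type": "eq",
         "fun": lambda th: ds * np.sum(np.cos(th)) - R,
         "jac": lambda th: -ds * np.sin(th)},
        {"type": "eq",
         "fun": lambda th: ds * np.sum(np.sin(th)),
         "jac": lambda th: ds * np.cos(th)},
    ]
    # amplitude chosen so the start roughly satisfies the constraint
    amp0 = max(amp, math.sqrt(max(0.0, 4.0 * (1.0 - R / (ds * n_seg)))))
    theta0 = amp0 * np.cos(math.pi * s_mid / N)
    out = minimize(energy, theta0, jac=True, method="SLSQP",
                   constraints=cons,
                   options={"maxiter": 3000, "ftol": 1e-14})
    bend, Rout, _, _ = _discrete_energy_terms(out.x, N)
    return {"theta": out.x, "extension": Rout / N, "bend_energy": bend,
            "converged": bool(out.success)}
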