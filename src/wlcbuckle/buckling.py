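"""Finite-temperature buckling: free-energy landscapes and critical forces.

The Helmholtz free energy of a worm-like chain held at end separation r
under a compressive load f (natural units: r in 2 lp, f in kBT/(2 lp),
F in kBT) is

    F(r; f) = -log(r^2 G(r;N)) + f r,

with G the exact end-to-end distribution.  The force-extension relation
of the fluctuating chain is the minimizer Rmin(f); buckling at finite
temperature is not a sharp transition but a compliance maximum: the
response function alphaF = -dRmin/df peaks at the critical force fc
(the inflection point of Rmin versus f).  Sweeping chain lengths yields
the fc(N) curve, which exceeds the zero-temperature Euler force
fE = pi^2/(2N^2) everywhere - thermal fluctuations stabilize the chain.

Below the module's stiffness threshold the radial density comes from the
weakly-bending expansion, whose free energy is only controlled near full
extension; beyond a matched retraction the elastica bending energy
continues the landscape (the two agree to leading order at the splice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .chain import ChainSpec
from .elastica import euler_force_dimensionless, min_bend_energy_at_R
from .greens import STIFF_N_THRESHOLD, RadialGreen, radial_green

__all__ = [
    "BucklingError",
    "FreeEnergyProfile",
    "ProfileMinimum",
    "ForceExtensionCurve",
    "free_energy_profile",
    "minimize_profile",
    "force_extension",
    "critical_force_surface",
]


class BucklingError(RuntimeError):
    pass


@dataclass
class FreeEnergyProfile:
    """F(r) = -log(r^2 G) + f r on an interior r grid (kBT units).

    ``credible`` marks where the underlying density is above the
    quadrature noise floor; outside it F is +inf.
    """

    N: float
    f: float
    r_grid: np.ndarray
    F_values: np.ndarray
    Ef_values: np.ndarray
    credible: np.ndarray
    meta: dict = field(default_factory=dict)


def free_energy_profile(N: float, f: float, rg: RadialGreen | None = None,
                        **greens_kw) -> FreeEnergyProfile:
    """Assemble the compressive free-energy landscape at one force.

    The additive constant is fixed by the normalized G (no shifting);
    profiles at two forces differ exactly by (f2 - f1) r.
    """
    if rg is None:
        rg = radial_green(N, **greens_kw)
    F0 = rg.F0()
    Ef = f * rg.r_grid
    return FreeEnergyProfile(
        N=N, f=f, r_grid=rg.r_grid, F_values=F0 + Ef, Ef_values=Ef,
        credible=rg.credible.copy(), meta={"greens": rg.meta, "method": rg.method},
    )


@dataclass
class ProfileMinimum:
    Rmin: float            # 2 lp units
    F_min: float           # kBT
    curvature: float       # d2F/dr2 at the minimum (kBT/(2lp)^2)
    boundary: bool         # minimum sits at the edge of the credible window
    tie_broken: bool       # degenerate grid minimum resolved toward larger r


def minimize_profile(profile: FreeEnergyProfile) -> ProfileMinimum:
    """Global minimum of a tabulated profile, refined by local quadratics.

    Ties are broken toward larger r (the extended state); a minimum at
    the credible-window edge is flagged rather than trusted.
    """
    ok = profile.credible & np.isfinite(profile.F_values)
    if not np.any(ok):
        raise BucklingError(f"no credible grid points at N={profile.N}, f={profile.f}")
    r = profile.r_grid[ok]
    F = profile.F_values[ok]
    Fm = F.min()
    idx_candidates = np.nonzero(F <= Fm)[0]
    i = int(idx_candidates[-1])
    tie = len(idx_candidates) > 1
    boundary = i == 0 or i == len(F) - 1
    if boundary:
        return ProfileMinimum(Rmin=float(r[i]), F_min=float(F[i]),
                              curvature=math.nan, boundary=True, tie_broken=tie)
    # quadratic through the bracketing triple
    r3 = r[i - 1:i + 2]
    F3 = F[i - 1:i + 2]
    a, b, c = np.polyfit(r3 - r3[1], F3, 2)
    if a <= 0:
        rstar, Fstar = float(r3[1]), float(F3[1])
    else:
        dr = float(np.clip(-b / (2 * a), r3[0] - r3[1], r3[2] - r3[1]))
        rstar = float(r3[1] + dr)
        Fstar = float(a * dr * dr + b * dr + c)
    return ProfileMinimum(Rmin=rstar, F_min=Fstar, curvature=float(2 * a),
                          boundary=False, tie_broken=tie)


# ---------------------------------------------------------------------------
# continuous minimization via a spline of the force-free landscape
# ---------------------------------------------------------------------------


def _credible_window(rg: RadialGreen) -> tuple[np.ndarray, np.ndarray]:
    """Largest contiguous credible run containing the density peak."""
    ok = rg.credible & (rg.density > 0)
    ipk = int(np.argmax(rg.density))
    lo = ipk
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return rg.r_grid[lo:hi + 1], -np.log(rg.r_grid[lo:hi + 1] ** 2 * rg.G_values[lo:hi + 1])


def _f0_spline(rg: RadialGreen) -> CubicSpline:
    """Cubic spline of F0(r) = -log(r^2 G) over the credible window.

    For the weakly-bending (stiff) branch the expansion is only
    controlled near full extension; beyond a retraction eta_c = 2/alpha
    the landscape is continued by the constrained elastica bending
    energy, matched continuously at the splice (both equal
    alpha eta + O(eta^2) there).
    """
    r, F0 = _credible_window(rg)
    if rg.method == "stiff":
        alpha = math.pi ** 2 / (2.0 * rg.N ** 2)
        eta_c = 2.0 / alpha
        r_c = rg.N - eta_c
        chain = ChainSpec.from_dimensionless(rg.N)
        inner = r < r_c
        if np.any(inner) and np.any(~inner):
            i_c = int(np.argmin(np.abs(r - r_c)))
            e_match = min_bend_energy_at_R(chain, float(r[i_c])).bend_energy
            C = F0[i_c] - e_match
            F0 = F0.copy()
            for j in np.nonzero(inner)[0]:
                F0[j] = min_bend_energy_at_R(chain, float(r[j])).bend_energy + C
    if len(r) < 8:
        raise BucklingError(f"credible window too narrow at N={rg.N}")
    return CubicSpline(r, F0)


@dataclass
class ForceExtensionCurve:
    """Rmin(f), the response alphaF = -dRmin/df, and the critical force."""

    N: float
    f_grid: np.ndarray         # kBT/(2 lp)
    Rmin: np.ndarray           # 2 lp units (nan where flagged)
    Rmin_over_L: np.ndarray
    alphaF: np.ndarray         # (2 lp)^2/kBT units
    fE: float
    fc: float
    fc_over_fE: float
    boundary_flags: np.ndarray
    curvature: np.ndarray      # profile curvature at each minimum
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "f": self.f_grid, "f_over_fE": self.f_grid / self.fE,
            "Rmin": self.Rmin, "Rmin_over_L": self.Rmin_over_L,
            "alphaF": self.alphaF, "boundary": self.boundary_flags,
        })


def _minimize_spline(sp: CubicSpline, f: float, n_dense: int = 3000):
    """Minimum of sp(r) + f r over the spline domain.

    Dense scan, then the stationarity condition sp'(r) + f = 0 solved by
    bracketed root finding around the discrete minimum.
    """
    rlo, rhi = sp.x[0], sp.x[-1]
    rr = np.linspace(rlo, rhi, n_dense)
    tt = sp(rr) + f * rr
    i = int(np.argmin(tt))
    if i == 0 or i == n_dense - 1:
        return float(rr[i]), float(tt[i]), math.nan, True
    d = sp.derivative()
    lo, hi = rr[i - 1], rr[i + 1]
    glo, ghi = d(lo) + f, d(hi) + f
    if glo < 0 < ghi:
        rstar = brentq(lambda x: d(x) + f, lo, hi, xtol=1e-14)
    else:
        rstar = rr[i]
    curv = float(sp.derivative(2)(rstar))
    return float(rstar), float(sp(rstar) + f * rstar), curv, False


def default_force_grid(N: float, f_points: int = 121,
                       lo: float = -1.0, hi: float = 4.0) -> np.ndarray:
    fE = euler_force_dimensionless(N)
    return np.linspace(lo * fE, hi * fE, f_points)


def force_extension(N: float, f_grid: np.ndarray | None = None,
                    f_points: int = 121, rg: RadialGreen | None = None,
                    r_points: int | None = None,
                    **greens_kw) -> ForceExtensionCurve:
    """Map out Rmin(f) and extract the critical force fc = argmax alphaF.

    f_grid defaults to 121 points spanning [-1, 4] x fE(N) (the tension
    branch is included for continuity).  Rmin(f) is minimized
    continuously on a spline of F0; alphaF is the derivative of a cubic
    spline through Rmin(f); fc is the quadratically refined argmax and
    must lie strictly inside the usable force range.
    """
    fE = euler_force_dimensionless(N)
    if f_grid is None:
        f_grid = default_force_grid(N, f_points)
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(np.diff(f_grid) <= 0):
        raise ValueError("f_grid must be strictly increasing")
    if rg is None:
        if r_points is None:
            r_points = 1200 if N < STIFF_N_THRESHOLD else 400
        rg = radial_green(N, r_points=r_points, **greens_kw)
    sp = _f0_spline(rg)

    n = len(f_grid)
    Rmin = np.full(n, math.nan)
    curv = np.full(n, math.nan)
    flags = np.zeros(n, dtype=bool)
    Fm = np.full(n, math.nan)
    for i, f in enumerate(f_grid):
        r_star, F_star, c, bd = _minimize_spline(sp, f)
        Rmin[i] = r_star
        Fm[i] = F_star
        curv[i] = c
        flags[i] = bd
    good = ~flags
    if good.sum() < 10:
        raise BucklingError(
            f"too few usable forces at N={N} ({good.sum()}); widen the "
            "credible window or the force grid")
    fg, Rg = f_grid[good], Rmin[good]
    rs = CubicSpline(fg, Rg)
    f_dense = np.linspace(fg[0], fg[-1], 4000)
    aF_dense = -rs.derivative()(f_dense)
    j = int(np.argmax(aF_dense))
    if j <= 1 or j >= len(f_dense) - 2:
        raise BucklingError(
            f"response maximum at the force-grid edge at N={N}; widen f_grid")
    # quadratic refinement of the argmax
    x3 = f_dense[j - 1:j + 2]
    y3 = aF_dense[j - 1:j + 2]
    a, b, _ = np.polyfit(x3 - x3[1], y3, 2)
    fc = float(x3[1] - b / (2 * a)) if a < 0 else float(x3[1])
    alphaF = np.full(n, math.nan)
    alphaF[good] = -rs.derivative()(fg)
    return ForceExtensionCurve(
        N=N, f_grid=f_grid, Rmin=Rmin, Rmin_over_L=Rmin / N,
        alphaF=alphaF, fE=fE, fc=fc, fc_over_fE=fc / fE,
        boundary_flags=flags, curvature=curv,
        meta={"greens_method": rg.method, "F_min": Fm,
              "n_good": int(good.sum())},
    )


def critical_force_surface(N_grid: np.ndarray, f_points: int = 121,
                           rg_cache: dict | None = None,
                           **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """fc(N) table and the Rmin(f, N) surface over a chain-length grid.

    Returns (table, surface): table has one row per N with fE, fc,
    fc/fE; surface is long-format (N, f_over_fE, Rmin_over_L).  Per-N
    failures are recorded (fc = nan) without aborting the sweep.
    rg_cache maps N to a precomputed RadialGreen (exact-match reuse).
    """
    rows = []
    surf = []
    for N in np.asarray(N_grid, dtype=float):
        try:
            rg = (rg_cache or {}).get(float(N))
            fx = force_extension(N, f_points=f_points, rg=rg, **kwargs)
            rows.append({"N": N, "fE": fx.fE, "fc": fx.fc,
                         "fc_over_fE": fx.fc_over_fE, "error": ""})
            surf.append(pd.DataFrame({
                "N": N, "f_over_fE": fx.f_grid / fx.fE,
                "Rmin_over_L": fx.Rmin_over_L,
            }))
        except Exception as exc:  # noqa: BLE001 - per-N failures reported
            rows.append({"N": N, "fE": euler_force_dimensionless(N),
                         "fc": math.nan, "fc_over_fE": math.nan,
                         "error": str(exc)})
    table = pd.DataFrame(rows)
    surface = pd.concat(surf, ignore_index=True) if surf else pd.DataFrame()
    return table, surface
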