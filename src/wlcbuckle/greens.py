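"""Exact end-to-end distribution of the worm-like chain.

The Fourier-Laplace transform of the end-to-end vector distribution of a
worm-like chain has an exact continued-fraction representation

    G(K;p) = 1 / (P0 + (a1 K)^2 / (P1 + (a2 K)^2 / (P2 + ...))),

with P_l = p + l(l+1) and a_l = l/sqrt((2l+1)(2l-1)), where K is the
dimensionless wavevector (units 1/(2 lp)) conjugate to the end separation
and p is the Laplace variable conjugate to the dimensionless contour
length N = L/(2 lp).  The convention is the isotropic characteristic
function G(K;N) = <sin(Kr)/(Kr)>, so G(0;N) = 1.

This module performs both inversions:

* Laplace p -> N by a pole/residue expansion.  The truncated continued
  fraction is the (0,0) resolvent element of a tridiagonal operator; its
  poles and residues come from an eigendecomposition, polished by Newton
  iteration on the continued fraction itself.  Where pole pairs collide
  (merging into complex-conjugate pairs) a fixed-precision Fourier-series
  Bromwich inversion takes over; a high-precision de Hoog contour
  (mpmath) serves as the independent cross-check oracle.
* Fourier K -> r by Filon-type quadrature: G(K;N) is tabulated on a fine
  adaptive K grid by pole marching, interpolated by a cubic spline, and
  each spline piece is integrated against K sin(Kr) in closed form.

For very stiff chains the radial density collapses onto a shell of width
O(N^2) near full extension and the required Fourier content grows like
1/N^2; below a stiffness threshold the exact weakly-bending limit of the
same Green function (an alternating theta-type series) is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import eig as _dense_eig

__all__ = [
    "GreensError",
    "FractionParams",
    "PoleExpansion",
    "RadialGreen",
    "continued_fraction",
    "find_poles",
    "greens_K_N",
    "greens_r_N",
    "radial_green",
    "mean_square_r",
    "stiff_eta_density",
    "default_r_grid",
]

#: stiffness threshold below which the weakly-bending expansion is used
STIFF_N_THRESHOLD = 0.15

#: contributions e^{Re(p) N} smaller than e^{-LOG_CUT} x leading are dropped
LOG_CUT = 42.0


class GreensError(RuntimeError):
    """Raised when an inversion cannot meet its accuracy contract."""


def _al(l: int) -> float:
    """Coupling coefficient a_l = l / sqrt((2l+1)(2l-1))."""
    return l / math.sqrt(4.0 * l * l - 1.0)


@dataclass(frozen=True)
class FractionParams:
    """Arguments of the continued fraction G(K;p)."""

    K: float
    p: complex
    l_max: int = 60

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("wavevector K must be >= 0")
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")

    def Pl(self, l: int) -> complex:
        return self.p + l * (l + 1)

    def al(self, l: int) -> float:
        return _al(l)


def _cf_reciprocal(K, p, l_max: int):
    """Backward recurrence for T(p) = 1/G(K;p) and dT/dp.

    Generic arithmetic: works for python/numpy complex and for mpmath
    numbers (used by the high-precision contour inversion).
    """
    Ksq = K * K
    t = p + l_max * (l_max + 1)
    dt = 1.0
    for l in range(l_max, 0, -1):
        c = (l * l / (4.0 * l * l - 1.0)) * Ksq
        if t == 0:
            raise ZeroDivisionError(
                f"continued-fraction recurrence hit a zero at level {l} "
                f"(p={p} is at or near a pole; perturb p or use pole machinery)"
            )
        dt = 1.0 - c * dt / (t * t)
        t = (p + (l - 1) * l) + c / t
    return t, dt


def continued_fraction(params: FractionParams) -> complex:
    """Evaluate G(K;p) by backward recurrence from level ``l_max``."""
    t, _ = _cf_reciprocal(params.K, params.p, params.l_max)
    if t == 0:
        raise ZeroDivisionError("continued fraction evaluated exactly at a pole")
    return 1.0 / t


def _cf_adaptive(K: float, p: complex, rel_tol: float = 1e-12) -> complex:
    """G(K;p) with l_max doubled until the relative change is < rel_tol."""
    l_max = max(30, math.ceil(2.0 * K) + 20)
    val, _ = _cf_reciprocal(K, p, l_max)
    for _ in range(8):
        l_max *= 2
        new, _ = _cf_reciprocal(K, p, l_max)
        if abs(new - val) <= rel_tol * abs(new):
            return 1.0 / new
        val = new
    raise GreensError(f"continued fraction failed to converge at K={K}, p={p}")


# ---------------------------------------------------------------------------
# pole/residue machinery (inverse Laplace transform)
# ---------------------------------------------------------------------------


@dataclass
class PoleExpansion:
    """Poles and residues of G(K;p) in the Laplace variable.

    Poles are sorted by descending real part (slowest-decaying first).
    ``collision`` is set when two retained poles approach within ``tol``;
    residues are then unreliable and callers should fall back to the
    numerical contour inversion.
    """

    K: float
    poles: np.ndarray
    residues: np.ndarray
    n_poles: int
    collision: bool = False
    tol: float = 1e-9

    def greens_at(self, N: float) -> complex:
        """Sum of residue_l * exp(p_l N) over the retained poles."""
        return np.sum(self.residues * np.exp(self.poles * N))


def _operator_dim(K: float, min_dim: int = 40) -> int:
    """Truncation level: the fraction converges once l(l+1) dominates (K/2)^2."""
    return max(min_dim, int(0.55 * K) + 25)


def _eig_poles(K: float, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """All poles/residues of the dim-truncated G(K;p) via eigendecomposition.

    The tridiagonal Fourier-space operator (diagonal l(l+1), off-diagonal
    i K a_l) is similarity-transformed by diag(i^l) into a real matrix S with
    +K a_l above and -K a_l below the diagonal, whose resolvent (0,0)
    element equals the continued fraction.  Since S^T = E S E^{-1} with
    E = diag((-1)^l), left eigenvectors are parity-flipped right ones and
    the residues follow from right eigenvectors alone:
    res_j = v_j[0]^2 / sum_l (-1)^l v_j[l]^2.
    """
    l = np.arange(dim)
    S = np.diag(l * (l + 1.0))
    a = np.array([_al(k) for k in range(1, dim)])
    S[l[:-1], l[:-1] + 1] = K * a
    S[l[:-1] + 1, l[:-1]] = -K * a
    w, V = _dense_eig(S, check_finite=False)
    sign = np.where(l % 2 == 0, 1.0, -1.0)
    res = V[0, :] ** 2 / np.sum(sign[:, None] * V ** 2, axis=0)
    poles = -w
    order = np.argsort(-poles.real)
    return poles[order], res[order]


def _polish_poles(
    K: float, poles: np.ndarray, residues: np.ndarray, l_max: int,
    max_iter: int = 40, skip_below: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-polish poles on the continued fraction; residue = 1/T'(p).

    Vectorized over poles (the backward recurrence runs on the whole pole
    vector at once).  Poles with negligible residue are not zeros of the
    truncated reciprocal fraction (e.g. at K=0 only p=0 carries weight) and
    are left untouched.  A polish that moves a pole by more than a quarter
    of the local pole spacing is rejected as having jumped basins.
    """
    act = np.abs(residues) > skip_below
    if not np.any(act):
        return poles, residues
    p = poles[act].astype(complex)
    p0 = p.copy()
    spacing = np.full(p.shape, np.inf)
    if len(poles) > 1:
        allp = poles.astype(complex)
        for i, idx in enumerate(np.nonzero(act)[0]):
            d = np.abs(allp - allp[idx])
            spacing[i] = np.min(d[d > 0]) if np.any(d > 0) else np.inf
    Ksq = K * K
    ls = np.arange(l_max, 0, -1)
    cs = (ls * ls / (4.0 * ls * ls - 1.0)) * Ksq
    lower = (ls - 1) * ls
    converged = np.zeros(p.shape, dtype=bool)
    for _ in range(max_iter):
        t = p + l_max * (l_max + 1)
        dt = np.ones_like(p)
        for c, lo in zip(cs, lower):
            dt = 1.0 - c * dt / (t * t)
            t = (p + lo) + c / t
        with np.errstate(divide="ignore", invalid="ignore"):
            step = t / dt
        step = np.where(np.isfinite(step), step, 0.0)
        p = p - np.where(converged, 0.0, step)
        newly = np.abs(step) <= 1e-14 * (1.0 + np.abs(p))
        converged |= newly
        if np.all(converged):
            break
    ok = converged & (np.abs(p - p0) < 0.25 * np.where(np.isfinite(spacing), spacing, np.inf) + 1e-9)
    # final residues from the derivative at the polished locations
    t = p + l_max * (l_max + 1)
    dt = np.ones_like(p)
    for c, lo in zip(cs, lower):
        dt = 1.0 - c * dt / (t * t)
        t = (p + lo) + c / t
    with np.errstate(divide="ignore", invalid="ignore"):
        res_new = 1.0 / dt
    out_p = poles.astype(complex).copy()
    out_r = residues.astype(complex).copy()
    idx = np.nonzero(act)[0]
    good = ok & np.isfinite(res_new)
    out_p[idx[good]] = p[good]
    out_r[idx[good]] = res_new[good]
    return out_p, out_r


def find_poles(K: float, n_poles: int = 25, tol: float = 1e-9, polish: bool = True) -> PoleExpansion:
    """Locate the leading poles of G(K;p) and their residues.

    At K=0 the poles are exactly p_l = -l(l+1) with all weight on p=0.
    At K>0 they move (and can merge pairwise into complex-conjugate pairs
    at exceptional wavevectors).  If two retained poles approach within
    ``tol`` the expansion is flagged (``collision=True``) rather than
    returning unreliable residues.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if n_poles < 1:
        raise ValueError("n_poles must be >= 1")
    dim = _operator_dim(K, min_dim=n_poles + 15)
    poles, residues = _eig_poles(K, dim)
    if polish and K > 0:
        poles, residues = _polish_poles(K, poles, residues, l_max=dim + 60)
        order = np.argsort(-poles.real)
        poles, residues = poles[order], residues[order]
    poles = poles[:n_poles]
    residues = residues[:n_poles]
    collision = False
    if n_poles > 1:
        d = np.abs(poles[:, None] - poles[None, :])
        np.fill_diagonal(d, np.inf)
        collision = bool(np.min(d) < tol)
    return PoleExpansion(K=K, poles=poles, residues=residues,
                         n_poles=len(poles), collision=collision, tol=tol)


def _n_poles_for(K: float, N: float) -> int:
    """Retain poles down to e^{Re(p) N} ~ e^{-LOG_CUT} x leading."""
    lam_cut = LOG_CUT / N  # |Re p| cutoff; K=0 poles sit at -l(l+1)
    l_cut = int(math.sqrt(lam_cut)) + 3
    return max(6, l_cut)


def _greens_K_N_contour(K: float, N: float, rel_tol: float = 1e-10) -> float:
    """Numerical Bromwich inversion at elevated precision.

    Uses the de Hoog vertical-line method (mpmath): unlike a Talbot
    contour, the Bromwich line lies to the right of *all* singularities,
    which matters here because at large K the leading poles acquire
    imaginary parts comparable to K.  Precision and quadrature degree are
    raised together until two successive levels agree.
    """
    import mpmath as mp

    l_max = max(30, math.ceil(2.0 * K) + 30)

    def run(dps: int, degree: int | None) -> float:
        with mp.workdps(dps):
            def fp(p):
                t, _ = _cf_reciprocal(mp.mpf(K), p, l_max)
                return 1.0 / t

            kw = {} if degree is None else {"degree": degree}
            return float(mp.invertlaplace(fp, mp.mpf(N), method="dehoog", **kw))

    prev = run(30, None)
    for dps, degree in ((50, 50), (80, 80), (120, 120)):
        cur = run(dps, degree)
        if abs(cur - prev) <= rel_tol * max(abs(cur), 1e-300):
            return cur
        prev = cur
    raise GreensError(f"contour inversion did not stabilize at K={K}, N={N}")


def greens_K_N(K: float, N: float, method: str = "auto",
               cross_check_tol: float = 1e-8) -> float:
    """Inverse Laplace transform: G(K;N) at dimensionless length N.

    method:
        "residue"  pole/residue sum (exact structure; errors if a pole
                   collision makes residues unreliable),
        "contour"  high-precision Talbot contour,
        "auto"     residue with automatic contour fallback.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    if K < 1e-12:
        return 1.0
    if method not in ("residue", "contour", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if method == "contour":
        return _greens_K_N_contour(K, N)
    pe = find_poles(K, n_poles=_n_poles_for(K, N))
    if pe.collision:
        if method == "residue":
            raise GreensError(
                f"pole collision at K={K} (spacing < {pe.tol}); "
                "residues unreliable - use method='contour'"
            )
        return _greens_K_N_contour(K, N)
    val = pe.greens_at(N)
    if abs(val.imag) > 1e-8 * max(1.0, abs(val.real)):
        if method == "auto":
            return _greens_K_N_contour(K, N)
        raise GreensError(f"non-real inversion at K={K}, N={N}: {val}")
    return float(val.real)


def mean_square_r(N: float) -> float:
    """Closed-form WLC mean-square end-to-end distance, (2 lp)^2 units.

    <r^2> = N - (1 - e^{-2N})/2; the module's primary validation oracle.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    return N - 0.5 * (1.0 - math.exp(-2.0 * N))


# ---------------------------------------------------------------------------
# weakly-bending (stiff) limit
# ---------------------------------------------------------------------------


def _theta_series(x: np.ndarray) -> np.ndarray:
    """S(x) = sum_{k>=1} (-1)^{k+1} k^2 e^{-k^2 x}, x > 0.

    Direct sum for x >= 0.6; Jacobi-transformed (theta-function) series
    for small x, where the direct sum loses accuracy to cancellation:
    S(x) = sum_{m>=0} sqrt(pi) e^{-c_m/x} (c_m x^{-5/2} - x^{-3/2}/2),
    c_m = pi^2 (m + 1/2)^2.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    big = x >= 0.6
    if np.any(big):
        xb = x[big]
        s = np.zeros_like(xb)
        for k in range(1, 40):
            term = ((-1) ** (k + 1)) * k * k * np.exp(-k * k * xb)
            s += term
            if k * k * np.min(xb) > 45.0:
                break
        out[big] = s
    if np.any(~big):
        xs = x[~big]
        s = np.zeros_like(xs)
        for m in range(0, 40):
            c = math.pi ** 2 * (m + 0.5) ** 2
            e = np.exp(-c / xs)
            s += math.sqrt(math.pi) * e * (c * xs ** -2.5 - 0.5 * xs ** -1.5)
            if c / np.max(xs) > 45.0:
                break
        out[~big] = s
    return out


def stiff_eta_density(N: float, eta: np.ndarray) -> np.ndarray:
    """Density of the end retraction eta = N - r in the weakly-bending limit.

    P(eta) = 2 a S(a eta) with a = pi^2/(2 N^2) -- the exact N->0 limit of
    the worm-like chain end-to-end distribution with free (hinged) ends,
    obtained from the Laplace transform <e^{-mu eta}> = z/sinh z,
    z = sqrt(2 mu) N.  Note a equals the dimensionless Euler force.
    """
    alpha = math.pi ** 2 / (2.0 * N * N)
    eta = np.asarray(eta, dtype=float)
    out = np.zeros_like(eta)
    pos = eta > 0
    out[pos] = 2.0 * alpha * _theta_series(alpha * eta[pos])
    return out


# ---------------------------------------------------------------------------
# radial distribution (inverse Fourier transform)
# ---------------------------------------------------------------------------


@dataclass
class RadialGreen:
    """Exact end-to-end radial distribution G(r;N) on an interior r grid.

    ``density`` is the radial probability density 4 pi r^2 G(r;N);
    ``credible`` marks grid points where the density exceeds the
    quadrature noise floor (free energies -log(r^2 G) are only
    meaningful there).
    """

    N: float
    r_grid: np.ndarray
    G_values: np.ndarray
    density: np.ndarray
    norm_check: float
    second_moment: float
    credible: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def F0(self) -> np.ndarray:
        """Force-free free energy -log(r^2 G); +inf outside the credible range."""
        out = np.full_like(self.r_grid, np.inf)
        ok = self.credible & (self.density > 0)
        out[ok] = -np.log(self.r_grid[ok] ** 2 * self.G_values[ok])
        return out


def default_r_grid(N: float, n: int = 400) -> np.ndarray:
    """Interior r grid on (0, N), denser near r = N by a square-root stretch."""
    v = (np.arange(n) + 0.5) / n
    return N * (1.0 - (1.0 - v) ** 2)


def _phi_moments(w: np.ndarray) -> list[np.ndarray]:
    """phi_m(w) = int_0^1 v^m e^{i w v} dv for m = 0..3, stable for all w."""
    w = np.asarray(w, dtype=float)
    iw = 1j * w
    phis = [np.empty(w.shape, dtype=complex) for _ in range(4)]
    small = np.abs(w) < 0.9
    if np.any(small):
        ws = iw[small]
        sums = [np.zeros(ws.shape, dtype=complex) for _ in range(4)]
        term = np.ones(ws.shape, dtype=complex)
        for k in range(0, 22):
            if k > 0:
                term = term * ws / k
            for m in range(4):
                sums[m] += term / (m + k + 1)
        for m in range(4):
            phis[m][small] = sums[m]
    if np.any(~small):
        wl = iw[~small]
        e = np.exp(wl)
        prev = (e - 1.0) / wl
        phis[0][~small] = prev
        for m in range(1, 4):
            prev = (e - m * prev) / wl
            phis[m][~small] = prev
    return phis


def _filon_sine_transform(K_nodes: np.ndarray, f: np.ndarray, r: np.ndarray,
                          chunk: int = 16) -> np.ndarray:
    """I(r) = int f(K) sin(K r) dK with f given on nodes, via spline + Filon.

    Each cubic-spline piece is integrated against e^{iKr} exactly, so the
    oscillation in r is handled in closed form and accuracy is set purely
    by the spline fit of the smooth factor f(K).
    """
    sp = CubicSpline(K_nodes, f)
    c = sp.c  # (4, nseg), highest power first, in (K - K_a)
    Ka = K_nodes[:-1]
    h = np.diff(K_nodes)
    out = np.empty(r.shape, dtype=float)
    for i0 in range(0, len(r), chunk):
        rr = r[i0:i0 + chunk][:, None]
        w = rr * h[None, :]
        phis = _phi_moments(w)
        acc = np.zeros(w.shape, dtype=complex)
        for m in range(4):
            acc += c[3 - m][None, :] * (h[None, :] ** (m + 1)) * phis[m]
        acc *= np.exp(1j * rr * Ka[None, :])
        out[i0:i0 + chunk] = np.sum(acc.imag, axis=1)
    return out


def _fourier_series_G(K_arr: np.ndarray, N: float, A: float = 23.0,
                      M_euler: int = 32, pad: int = 40) -> np.ndarray:
    """G(K;N) for an array of K by Fourier-series Bromwich inversion.

    Abate-Whitt "Euler" algorithm on the vertical line Re p = A/(2N):
    discretization error ~ e^{-A} x |G| (aliasing picks up G at 3N, 5N,
    ...), Euler-accelerated truncation.  Robust where poles collide or
    sit anywhere left of the line, at fixed (double) precision -- used in
    the wavevector zone where G is not yet exponentially small and the
    pole expansion is unreliable (merging real pairs).  Vectorized over
    K with the backward recurrence for the continued fraction.
    """
    out = np.empty(len(K_arr))
    chunk = 256
    for c0 in range(0, len(K_arr), chunk):
        Kc = K_arr[c0:c0 + chunk]
        Kmax = float(np.max(Kc))
        l_max = 90 + int(0.55 * Kmax)
        n_base = int(Kmax * N / math.pi) + pad
        nk = n_base + M_euler + 1
        k = np.arange(nk)
        p = (A + 2j * math.pi * k) / (2.0 * N)
        # T(K;p) on the (nK, nk) grid by backward recurrence
        Ksq = (Kc ** 2)[:, None]
        t = np.broadcast_to(p + l_max * (l_max + 1), (len(Kc), nk)).copy()
        for l in range(l_max, 0, -1):
            ccoef = (l * l / (4.0 * l * l - 1.0))
            t = (p + (l - 1) * l) + (ccoef * Ksq) / t
        F = (1.0 / t).real * np.where(k % 2 == 0, 1.0, -1.0)
        F[:, 0] *= 0.5
        s = np.cumsum(F, axis=1)
        w = np.array([math.comb(M_euler, m) for m in range(M_euler + 1)],
                     dtype=float) * 2.0 ** -M_euler
        acc = s[:, n_base:n_base + M_euler + 1] @ w
        out[c0:c0 + chunk] = (math.exp(A / 2.0) / N) * acc
    return out


def _march_pole_grid(N: float, dK: float, tail_eps: float,
                     K_cap: float, cut_log: float = 33.0,
                     max_reseeds: int = 200, anchor_dK: float = 6.0):
    """Tabulate f(K) = K G(K;N) on a fine uniform K grid by pole marching.

    The poles of G(K;p) move smoothly with K (their real parts descend
    monotonically), so the few poles inside the decay window
    Re(p) N > -cut_log are continued in K with Newton polishing on the
    continued fraction; the fine grid then resolves the oscillation of
    G(K;N) itself for the downstream Filon quadrature.  While real poles
    remain in the window the set is resynced against a dense
    eigendecomposition every anchor_dK (real pairs merge into conjugate
    pairs there, and dormant poles re-activate); once every windowed pole
    is a well-separated conjugate pair the march runs free.  The march
    stops when the envelope of f falls below tail_eps x its maximum.

    Returns (K_fine, f_fine, g_lead) where g_lead is the leading
    complex-pair branch contribution K res e^{pN}, used for the analytic
    tail correction.
    """
    from ._march import march_block, MAXP

    cut_re = (cut_log + 6.0) / N
    period_nodes = max(8, int(2.0 * math.pi / (0.9 * N) / dK))
    block = max(2000, 2 * period_nodes)
    anchor_every = max(4, int(round(anchor_dK / dK)))

    def seed_state(K: float):
        dim = _operator_dim(K, min_dim=int(math.sqrt(cut_re)) + 12)
        poles, res = _eig_poles(K, dim)
        keep = (poles.real > -cut_re) & (poles.imag > -1e-9)
        p = poles[keep]
        r = res[keep]
        # conjugate-pair members count once (represented by Im >= 0)
        p_act = np.zeros(MAXP, dtype=complex)
        r_act = np.zeros(MAXP, dtype=complex)
        n = min(len(p), MAXP)
        p_act[:n] = p[:n]
        r_act[:n] = r[:n]
        all_pairs = bool(np.all(p[:n].imag > 0.5)) if n else True
        return p_act, r_act, n, all_pairs

    K_list = [np.array([0.0])]
    f_list = [np.array([0.0])]  # f(0) = 0 exactly
    g_list = [np.array([0.0 + 0.0j])]
    i0 = 1
    f_max = 0.0
    K_at_max = 0.0
    finished = False

    def record(K_vals, f_out, g_out):
        nonlocal f_max, K_at_max
        K_list.append(K_vals)
        f_list.append(f_out)
        g_list.append(g_out)
        blk_max = float(np.max(np.abs(f_out)))
        if blk_max > f_max:
            f_max = blk_max
            K_at_max = float(K_vals[np.argmax(np.abs(f_out))])

    def tail_done(f_out, K_now):
        ntail = min(len(f_out), period_nodes)
        env = float(np.max(np.abs(f_out[-ntail:])))
        return (K_now > 3.0 * K_at_max + 20.0 / N
                and env <= tail_eps * f_max), env

    # --- phase 1: collision-rich zone, Fourier-series inversion ---------
    # (real poles still inside the decay window merge pairwise into
    # conjugate pairs here; the fixed-precision Bromwich series is immune
    # to that and G is not yet exponentially small)
    p_act = r_act = None
    n_arr = np.array([0], dtype=np.int64)
    while True:
        K_vals = (i0 + np.arange(anchor_every)) * dK
        f_out = K_vals * _fourier_series_G(K_vals, N)
        record(K_vals, f_out, np.zeros(anchor_every, dtype=complex))
        i0 += anchor_every
        K_now = float(K_vals[-1])
        # anchor: dense eigendecomposition validates the series inversion
        # and decides whether the clean pole march can take over
        p_act, r_act, n_act, all_pairs = seed_state(K_now)
        term = r_act[:n_act] * np.exp(p_act[:n_act] * N)
        pair = p_act[:n_act].imag > 1e-7 * (1.0 + np.abs(p_act[:n_act]))
        G_eig = float(np.sum(np.where(pair, 2.0, 1.0) * term.real))
        if abs(G_eig - f_out[-1] / K_now) > 1e-7 * max(1.0, abs(G_eig)):
            raise GreensError(
                f"series/eigendecomposition mismatch at N={N}, K={K_now:.1f}: "
                f"{f_out[-1] / K_now:.3e} vs {G_eig:.3e}")
        done, env = tail_done(f_out, K_now)
        if done:
            finished = True
            break
        if all_pairs:
            break
        if K_now >= K_cap:
            raise GreensError(
                f"Fourier content not decayed at N={N}: K_max cap {K_cap} "
                f"reached in series zone, envelope {env:.3e} vs max {f_max:.3e}")

    # --- phase 2: clean zone, Newton pole march -------------------------
    if not finished:
        n_arr[0] = n_act
        slope = np.zeros(MAXP, dtype=complex)
        reseeds = 0
        while True:
            K_vals = (i0 + np.arange(block)) * dK
            f_out = np.empty(block)
            g_out = np.empty(block, dtype=complex)
            fail = march_block(K_vals, p_act, r_act, slope,
                               n_arr, N, cut_re, f_out, g_out)
            last_fail = -2
            while fail >= 0:
                # dense reseed at the failed node, then resume; a node that
                # fails twice (truly defective point) is filled directly
                # from the eigendecomposition sum and stepped over
                reseeds += 1
                if reseeds > max_reseeds:
                    raise GreensError(
                        f"pole march kept failing at N={N}, "
                        f"K~{K_vals[fail]:.1f}")
                if fail == last_fail:
                    Kf = float(K_vals[fail])
                    pd, rd, nd, _ = seed_state(Kf)
                    term = rd[:nd] * np.exp(pd[:nd] * N)
                    pair = pd[:nd].imag > 1e-7 * (1.0 + np.abs(pd[:nd]))
                    f_out[fail] = Kf * float(
                        np.sum(np.where(pair, 2.0, 1.0) * term.real))
                    g_out[fail] = 0.0
                    fail += 1
                    if fail >= block:
                        fail = -1
                        break
                last_fail = fail
                p_act2, r_act2, n_act2, _ = seed_state(float(K_vals[fail]))
                p_act[:] = p_act2
                r_act[:] = r_act2
                n_arr[0] = n_act2
                slope[:] = 0.0
                sub = K_vals[fail:]
                f_sub = np.empty(len(sub))
                g_sub = np.empty(len(sub), dtype=complex)
                f2 = march_block(sub, p_act, r_act, slope,
                                 n_arr, N, cut_re, f_sub, g_sub)
                f_out[fail:] = f_sub
                g_out[fail:] = g_sub
                fail = -1 if f2 < 0 else fail + f2
            record(K_vals, f_out, g_out)
            i0 += block
            K_now = float(K_vals[-1])
            done, env = tail_done(f_out, K_now)
            if done:
                break
            if K_now >= K_cap:
                raise GreensError(
                    f"Fourier content not decayed at N={N}: K_max cap "
                    f"{K_cap} reached, envelope {env:.3e} vs max {f_max:.3e}")

    return (np.concatenate(K_list), np.concatenate(f_list),
            np.concatenate(g_list))


def _tail_correction(K_m: float, g_nodes: np.ndarray, dK: float,
                     r: np.ndarray) -> np.ndarray:
    """Analytic continuation of the spectral tail beyond the last node.

    The tail of f(K) is dominated by the leading complex-pair branch
    g(K) = K res0 e^{p0 N} (f = 2 Re g).  Over the truncated region g is
    modelled as (g0 + g1 u) e^{beta u}, u = K - K_m, with beta fitted from
    the last nodes; the remaining integral against sin(Kr) then has a
    closed form.
    """
    g_end = g_nodes[-1]
    if abs(g_end) == 0.0:
        return np.zeros_like(r)
    m = min(16, len(g_nodes) - 1)
    if m < 4:
        return np.zeros_like(r)
    lg = np.log(g_nodes[-m:])
    # unwrap the imaginary part before fitting a line
    im = np.unwrap(lg.imag)
    u = np.arange(-m + 1, 1) * dK
    beta = complex(np.polyfit(u, lg.real, 1)[0], np.polyfit(u, im, 1)[0])
    if beta.real >= -1e-12:
        return np.zeros_like(r)
    g1 = (g_nodes[-1] - g_nodes[-2]) / dK - beta * g_end
    e_fwd = np.exp(1j * K_m * r)
    s1 = -(beta + 1j * r)
    s2 = -(np.conj(beta) + 1j * r)
    integral = e_fwd * (g_end / s1 + g1 / s1 ** 2) \
        + e_fwd * (np.conj(g_end) / s2 + np.conj(g1) / s2 ** 2)
    return integral.imag


def _integrate_padded(r: np.ndarray, y: np.ndarray, N: float) -> float:
    """Trapezoid over (0, N) with the vanishing endpoints appended."""
    rr = np.concatenate(([0.0], r, [N]))
    yy = np.concatenate(([0.0], y, [0.0]))
    return float(np.trapezoid(yy, rr))


def greens_r_N(N: float, r_grid: np.ndarray | None = None, r_points: int = 400,
               norm_tol: float = 1e-3, moment_tol: float = 1e-3,
               tail_eps: float = 1e-8, neg_tol: float = 1e-6,
               credible_floor: float = 1e-12, K_cap: float = 14000.0) -> RadialGreen:
    """Exact radial distribution G(r;N) by oscillatory Fourier inversion.

    G(r;N) = (1/(2 pi^2 r)) int_0^inf K sin(Kr) G(K;N) dK.  G(K;N) comes
    from the pole/residue expansion marched along a fine K grid; the grid
    extends until the spectral envelope falls below tail_eps of its peak
    (plus an analytic tail correction), and the result must pass the 3D
    normalization (to 1) and second-moment (closed form ``mean_square_r``)
    contracts.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    if r_grid is None:
        r_grid = default_r_grid(N, r_points)
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(r_grid >= N):
        raise ValueError("r_grid must lie strictly inside (0, N)")

    dK = min(0.033 / N, 0.45)
    K_fine, f, g_lead = _march_pole_grid(N, dK, tail_eps, K_cap)
    I = _filon_sine_transform(K_fine, f, r_grid)
    I += _tail_correction(float(K_fine[-1]), g_lead[-20:], dK, r_grid)
    dens = (2.0 / math.pi) * r_grid * I
    norm = _integrate_padded(r_grid, dens, N)
    m2 = _integrate_padded(r_grid, dens * r_grid ** 2, N)
    m2_exact = mean_square_r(N)
    if abs(norm - 1.0) > norm_tol or abs(m2 - m2_exact) > moment_tol * m2_exact:
        raise GreensError(
            f"inversion contracts failed at N={N}: norm={norm:.6g}, "
            f"m2={m2:.6g} vs {m2_exact:.6g}, K_max={K_fine[-1]:.1f}, "
            f"{len(K_fine)} nodes")
    K_max = float(K_fine[-1])

    peak = float(np.max(dens))
    if np.min(dens) < -neg_tol * peak:
        raise GreensError(
            f"radial density significantly negative at N={N} "
            f"(min {np.min(dens):.3e} vs peak {peak:.3e}; K_max={K_max:.1f})"
        )
    clipped = dens < 0
    dens = np.where(clipped, 0.0, dens)
    credible = dens > credible_floor * peak
    with np.errstate(divide="ignore", invalid="ignore"):
        G_vals = dens / (4.0 * math.pi * r_grid ** 2)
    return RadialGreen(
        N=N, r_grid=r_grid, G_values=G_vals, density=dens,
        norm_check=norm, second_moment=m2, credible=credible, method="exact",
        meta={"K_max": float(K_max), "dK": float(dK), "n_K_nodes": len(K_fine),
              "n_clipped": int(np.sum(clipped)), "norm_tol": norm_tol,
              "moment_tol": moment_tol, "credible_floor": credible_floor},
    )


def _stiff_radial_green(N: float, r_grid: np.ndarray | None, r_points: int,
                        credible_floor: float) -> RadialGreen:
    if r_grid is None:
        r_grid = default_r_grid(N, r_points)
    r_grid = np.asarray(r_grid, dtype=float)
    dens = stiff_eta_density(N, N - r_grid)
    norm = _integrate_padded(r_grid, dens, N)
    m2 = _integrate_padded(r_grid, dens * r_grid ** 2, N)
    peak = float(np.max(dens))
    credible = dens > credible_floor * peak
    with np.errstate(divide="ignore", invalid="ignore"):
        G_vals = dens / (4.0 * math.pi * r_grid ** 2)
    return RadialGreen(
        N=N, r_grid=r_grid, G_values=G_vals, density=dens, norm_check=norm,
        second_moment=m2, credible=credible, method="stiff",
        meta={"alpha": math.pi ** 2 / (2 * N * N), "credible_floor": credible_floor},
    )


def radial_green(N: float, r_grid: np.ndarray | None = None, r_points: int = 400,
                 method: str = "auto", **kwargs) -> RadialGreen:
    """Radial distribution with automatic stiff-limit dispatch.

    method "auto" uses the exact continued-fraction inversion for
    N >= STIFF_N_THRESHOLD and the weakly-bending expansion below it,
    where the exact route's Fourier content (K_max ~ 1/N^2) is out of
    reach of double-precision quadrature.
    """
    if method == "auto":
        method = "exact" if N >= STIFF_N_THRESHOLD else "stiff"
    if method == "exact":
        return greens_r_N(N, r_grid=r_grid, r_points=r_points, **kwargs)
    if method == "stiff":
        floor = kwargs.get("credible_floor", 1e-300)
        return _stiff_radial_green(N, r_grid, r_points, credible_floor=floor)
    raise ValueError(f"unknown method {method!r}")
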