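"""Theoretical scattering and primary SAXS analysis.

Implements the Debye equation for coarse-grained bead models, Guinier
fitting, indirect Fourier transform to the pair distance distribution
P(r), dimensionless Kratky analysis, the volume-of-correlation molecular
weight estimate, and the error-weighted χ goodness of fit.

Conventions
-----------
q = (4π/λ) sinθ, in Å⁻¹.  χ is the reduced, error-weighted form
sqrt(mean(((s·I_model − I_exp)/σ)²)) with the scalar s fitted by weighted
least squares, so all intensities are defined up to a positive scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "SaxsProfile", "GuinierResult", "PofR", "KratkyCurve",
    "GuinierFitError", "debye_profile", "guinier_fit", "pr_transform",
    "pr_from_coordinates", "kratky_dimensionless", "vc_mw", "chi_goodness",
    "sphere_pr", "sphere_profile",
]


class GuinierFitError(RuntimeError):
    """Guinier fit failed (non-physical slope or window too small)."""


@dataclass
class SaxsProfile:
    """A scattering curve: q grid (Å⁻¹), intensities, optional errors."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    wavelength: float | None = None   # Å

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)

    def validate(self) -> None:
        if self.q.ndim != 1 or len(self.q) != len(self.I):
            raise ValueError("q and I must be 1-d arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("non-finite intensities")
        if self.sigma is not None:
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "SaxsProfile":
        """Read a 3-column (q, I, σ) or 2-column (q, I) text file;
        '#' starts a comment."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: need at least 2 columns (q, I)")
        sigma = data[:, 2] if data.shape[1] >= 3 else None
        return cls(q=data[:, 0], I=data[:, 1], sigma=sigma,
                   label=label or Path(path).stem)

    def to_file(self, path: str | Path) -> None:
        cols = [self.q, self.I]
        header = "q[1/A]  I  " + ("sigma" if self.sigma is not None else "")
        if self.sigma is not None:
            cols.append(self.sigma)
        np.savetxt(path, np.column_stack(cols), header=header)


@dataclass
class GuinierResult:
    Rg: float                       # Å
    I0: float
    q_range_used: tuple[float, float]
    residual: float                 # RMS residual of the linear fit (ln I)
    n_points: int = 0


@dataclass
class PofR:
    """Pair distance distribution on r ∈ [0, Dmax], normalized to unit area."""

    r: np.ndarray
    p: np.ndarray
    dmax: float
    chi: float | None = None      # forward-fit quality (pr_transform only)
    alpha: float | None = None    # regularization weight used

    def validate(self) -> None:
        if np.any(self.p < 0):
            raise ValueError("p(r) must be non-negative")
        if abs(self.p[0]) > 1e-9 * max(self.p.max(), 1e-300):
            raise ValueError("p(0) must vanish")
        if abs(self.p[-1]) > 1e-9 * max(self.p.max(), 1e-300):
            raise ValueError("p(Dmax) must vanish")
        area = np.trapezoid(self.p, self.r)
        if not np.isclose(area, 1.0, rtol=1e-6):
            raise ValueError(f"p(r) area {area} != 1")

    def rg(self) -> float:
        """Real-space radius of gyration: Rg² = ∫r²p(r)dr / 2."""
        return float(np.sqrt(np.trapezoid(self.r ** 2 * self.p, self.r) / 2.0))


# ---------------------------------------------------------------------------
# Debye scattering


def debye_profile(conf, q, form_factor=None, method: str = "auto",
                  bin_width: float = 0.5, label: str | None = None) -> SaxsProfile:
    """Theoretical I(q) of a bead model by the Debye double sum
    I(q) = ΣᵢΣⱼ fᵢ(q)fⱼ(q) sinc(q·dᵢⱼ).

    form_factor: None for a constant per-bead scattering length of 1, or a
    callable f(q) -> array.  method 'exact' evaluates the full double sum;
    'histogram' bins pair distances (bin_width ≤ 0.5 Å) — the standard
    O(n²) → O(n_bins) reduction; 'auto' switches to the histogram when the
    exact sum would be large.
    """
    q = np.asarray(q, dtype=float)
    coords = conf.coords
    n = len(coords)
    if n == 0:
        raise ValueError("empty conformer")
    if n == 1:
        f2 = np.ones_like(q) if form_factor is None else form_factor(q) ** 2
        return SaxsProfile(q, f2, label=label or conf.model_id)
    d = pdist(coords)
    if method == "auto":
        method = "exact" if d.size * len(q) <= 2.0e7 else "histogram"
    if method == "exact":
        s = np.empty_like(q)
        block = max(1, int(2e7 // max(d.size, 1)))
        for i in range(0, len(q), block):
            qb = q[i:i + block, None]
            s[i:i + block] = np.sinc(qb * d[None, :] / np.pi).sum(axis=1)
    elif method == "histogram":
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        nbin = int(np.ceil(d.max() / bin_width)) + 1
        counts, edges = np.histogram(d, bins=nbin, range=(0, nbin * bin_width))
        sums, _ = np.histogram(d, bins=edges, weights=d)
        occ = counts > 0
        # represent each bin by its mean pair distance (second-order accurate)
        centers = sums[occ] / counts[occ]
        s = np.sinc(q[:, None] * centers[None, :] / np.pi) @ counts[occ]
    else:
        raise ValueError(f"unknown method {method!r}")
    f2 = np.ones_like(q) if form_factor is None else form_factor(q) ** 2
    I = f2 * (n + 2.0 * s)
    return SaxsProfile(q, I, label=label or conf.model_id)


# ---------------------------------------------------------------------------
# Guinier analysis


def guinier_fit(profile: SaxsProfile, qrg_limit: float = 1.3,
                min_points: int = 5, max_iter: int = 50) -> GuinierResult:
    """Iterative weighted Guinier fit of ln I vs q² on the low-q window.

    The window starts at the lowest q and is shrunk/expanded until
    q_max·Rg ≤ qrg_limit; Rg = sqrt(−3·slope), I0 = exp(intercept).
    """
    q, I = profile.q, profile.I
    sigma = profile.sigma if profile.sigma is not None else np.ones_like(I)
    pos = I > 0
    q, I, sigma = q[pos], I[pos], sigma[pos]
    if len(q) < min_points:
        raise GuinierFitError("fewer than min_points positive intensities")

    def fit(n):
        x = q[:n] ** 2
        y = np.log(I[:n])
        w = (I[:n] / sigma[:n]) ** 2      # error propagation ln I
        W = np.sum(w)
        xm, ym = np.sum(w * x) / W, np.sum(w * y) / W
        sxx = np.sum(w * (x - xm) ** 2)
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx
        icpt = ym - slope * xm
        resid = np.sqrt(np.mean((y - (icpt + slope * x)) ** 2))
        return slope, icpt, resid

    n = min_points
    for _ in range(max_iter):
        slope, icpt, resid = fit(n)
        if slope >= 0:
            raise GuinierFitError("non-physical Guinier slope (>= 0)")
        rg = np.sqrt(-3.0 * slope)
        n_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        n_new = max(min_points, min(n_new, len(q)))
        if n_new == n:
            break
        n = n_new
    if n < min_points:
        raise GuinierFitError("Guinier window smaller than min_points")
    return GuinierResult(Rg=float(rg), I0=float(np.exp(icpt)),
                         q_range_used=(float(q[0]), float(q[n - 1])),
                         residual=float(resid), n_points=n)


# ---------------------------------------------------------------------------
# P(r): indirect Fourier transform and coordinate-space histogram


def pr_transform(profile: SaxsProfile, dmax: float, alpha: float | None = None,
                 n_points: int = 101,
                 alpha_grid=None) -> PofR:
    """Regularized indirect Fourier transform of I(q) to P(r) on [0, Dmax].

    Solves the least-squares problem I(q) ≈ 4π ∫ p(r) sinc(qr) dr on an
    r-grid with a second-difference smoothness penalty (weight α) and
    boundary conditions p(0) = p(Dmax) = 0.  With alpha=None, α is chosen
    by an L-curve scan (maximum curvature) over a log grid.  Negative
    values are clipped and the result renormalized; the forward-computed
    fit χ is stored on the result.
    """
    if dmax <= 0:
        raise ValueError("Dmax must be positive")
    profile.validate()
    sigma = profile.sigma if profile.sigma is not None else np.ones_like(profile.I)
    r = np.linspace(0.0, dmax, n_points)
    dr = r[1] - r[0]
    w = np.full(n_points, dr)
    w[0] = w[-1] = dr / 2.0
    # design matrix on interior nodes (boundaries pinned to zero)
    A_full = 4.0 * np.pi * np.sinc(profile.q[:, None] * r[None, :] / np.pi) * w
    A = A_full[:, 1:-1] / sigma[:, None]
    b = profile.I / sigma
    # second difference operator over the full (zero-padded) vector
    m = n_points - 2
    D = np.zeros((n_points, m))
    for k in range(n_points):
        for j, c in ((k - 2, 1.0), (k - 1, -2.0), (k, 1.0)):
            if 0 <= j < m:
                D[k, j] += c
    scale = np.linalg.norm(A) / max(np.linalg.norm(D), 1e-300)

    def solve(a):
        M = np.vstack([A, np.sqrt(a) * scale * D])
        rhs = np.concatenate([b, np.zeros(n_points)])
        x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        return x

    if alpha is None:
        if alpha_grid is None:
            alpha_grid = np.logspace(-4, 2, 25)
        rho, eta, xs = [], [], []
        for a in alpha_grid:
            x = solve(a)
            rho.append(np.log(np.linalg.norm(A @ x - b) + 1e-300))
            eta.append(np.log(np.linalg.norm(D @ x) + 1e-300))
            xs.append(x)
        rho, eta = np.array(rho), np.array(eta)
        # discrete curvature of the L-curve; corner = max curvature
        k1r, k1e = np.gradient(rho), np.gradient(eta)
        k2r, k2e = np.gradient(k1r), np.gradient(k1e)
        curv = (k1r * k2e - k2r * k1e) / np.power(k1r ** 2 + k1e ** 2, 1.5)
        best = int(np.nanargmax(curv))
        x, alpha = xs[best], float(alpha_grid[best])
    else:
        x = solve(alpha)
    if not np.all(np.isfinite(x)):
        raise np.linalg.LinAlgError(
            "ill-conditioned P(r) system; retry with a larger alpha")
    p = np.concatenate([[0.0], np.clip(x, 0.0, None), [0.0]])
    area = np.trapezoid(p, r)
    if area <= 0:
        raise np.linalg.LinAlgError(
            "P(r) solution vanished; retry with a larger alpha")
    p /= area
    # forward fit quality (free scale, as in chi_goodness)
    I_fwd = A_full @ np.concatenate([[0.0], np.clip(x, 0.0, None), [0.0]])
    chi = chi_goodness(SaxsProfile(profile.q, I_fwd), profile)
    return PofR(r=r, p=p, dmax=float(dmax), chi=float(chi), alpha=alpha)


def pr_from_coordinates(conf, bin_width: float = 0.5) -> PofR:
    """Normalized histogram of all pairwise bead distances; the
    coordinate-space oracle for pr_transform.  Dmax = max pair distance."""
    if conf.n_atoms < 2:
        raise ValueError("need at least 2 beads")
    d = pdist(conf.coords)
    dmax = float(d.max())
    nbin = int(np.floor(dmax / bin_width)) + 2
    centers = bin_width * np.arange(nbin)
    edges = np.concatenate([[0.0], centers[:-1] + bin_width / 2.0,
                            [centers[-1] + bin_width / 2.0]])
    counts, _ = np.histogram(d, bins=edges)
    p = counts / (len(d) * bin_width)
    if p[0] != 0:
        warnings.warn("pairs closer than half a bin; p(0) > 0", stacklevel=2)
    area = np.trapezoid(p, centers)
    return PofR(r=centers, p=p / area, dmax=dmax)


# ---------------------------------------------------------------------------
# Kratky, Vc/MW, chi


@dataclass
class KratkyCurve:
    """Dimensionless Kratky transform: x = qRg, y = (qRg)²·I/I0."""

    x: np.ndarray
    y: np.ndarray

    def peak(self) -> tuple[float, float] | None:
        """(x, y) of the interior maximum, refined by quadratic
        interpolation around the grid maximum; None if the curve has no
        interior peak."""
        i = int(np.argmax(self.y))
        if i == 0 or i == len(self.y) - 1:
            return None
        if self.y[i] - max(self.y[0], self.y[-1]) <= 1e-9 * abs(self.y[i]):
            return None   # flat or boundary-dominated: no interior peak
        x0, x1, x2 = self.x[i - 1:i + 2]
        y0, y1, y2 = self.y[i - 1:i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        bq = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
        if a >= 0:
            return float(x1), float(y1)
        xp = -bq / (2 * a)
        cq = y1 - a * x1 ** 2 - bq * x1
        return float(xp), float(a * xp ** 2 + bq * xp + cq)


def kratky_dimensionless(profile: SaxsProfile, rg: float, i0: float) -> KratkyCurve:
    """Dimensionless (Rg-based) Kratky transform of a profile.

    For globular particles the curve is bell-shaped with its maximum at
    (√3 ≈ 1.73, 3/e ≈ 1.10); flexible chains rise monotonically.
    """
    if rg <= 0 or i0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    x = profile.q * rg
    y = x ** 2 * profile.I / i0
    return KratkyCurve(x=x, y=y)


def vc_mw(profile: SaxsProfile, guinier: GuinierResult,
          q_limit: float = 0.3) -> tuple[float, float]:
    """Volume of correlation and molecular weight estimate.

    Vc = I(0) / ∫ q·I(q) dq (trapezoid, q ≤ q_limit).  MW via the protein
    power-law calibration of the volume-of-correlation method:
    Qr = Vc²/Rg, MW = Qr/0.1231 Da.  Returns (Vc [Å²], MW [kDa]).
    """
    sel = profile.q <= q_limit
    q, I = profile.q[sel], profile.I[sel]
    if len(q) < 2:
        raise ValueError("profile does not cover the integration range")
    integrand = q * I
    tail = integrand[-max(3, len(q) // 10):]
    if tail.mean() > 0.05 * integrand.max():
        warnings.warn("q·I(q) has not converged at the integration limit; "
                      "Vc may be biased", stacklevel=2)
    denom = np.trapezoid(integrand, q)
    if denom <= 0:
        raise ValueError("non-positive ∫ q·I dq")
    vc = guinier.I0 / denom
    qr = vc ** 2 / guinier.Rg
    mw_kda = qr / 0.1231 / 1000.0
    return float(vc), float(mw_kda)


def chi_goodness(model: SaxsProfile, exp: SaxsProfile,
                 q_min: float | None = None, q_max: float | None = None) -> float:
    """Reduced error-weighted goodness of fit between a model curve and
    data, with the model scale fitted by weighted least squares:
    χ = sqrt((1/N) Σ ((s·I_m − I_e)/σ)²)."""
    sel = np.ones(len(exp.q), dtype=bool)
    if q_min is not None:
        sel &= exp.q >= q_min
    if q_max is not None:
        sel &= exp.q <= q_max
    sel &= (exp.q >= model.q[0] - 1e-12) & (exp.q <= model.q[-1] + 1e-12)
    if not sel.any():
        raise ValueError("model and experimental q grids do not overlap")
    qe, Ie = exp.q[sel], exp.I[sel]
    sig = exp.sigma[sel] if exp.sigma is not None else np.ones_like(Ie)
    Im = np.interp(qe, model.q, model.I)
    s = np.sum(Im * Ie / sig ** 2) / np.sum(Im ** 2 / sig ** 2)
    return float(np.sqrt(np.mean(((s * Im - Ie) / sig) ** 2)))


# ---------------------------------------------------------------------------
# closed forms for a uniform sphere (oracles and synthetic references)


def sphere_pr(r, radius: float):
    """Closed-form normalized pair distance distribution of a uniform
    sphere: p(s) = 3s² − (9/4)s³ + (3/16)s⁵ with s = r/R, support [0, 2R]."""
    s = np.asarray(r, dtype=float) / radius
    p = (3.0 * s ** 2 - 2.25 * s ** 3 + 0.1875 * s ** 5) / radius
    return np.where((s >= 0) & (s <= 2.0), p, 0.0)


def sphere_profile(q, radius: float, i0: float = 1.0) -> SaxsProfile:
    """Exact form-factor intensity of a uniform sphere."""
    q = np.asarray(q, dtype=float)
    x = q * radius
    f = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    return SaxsProfile(q, i0 * f ** 2, label=f"sphere_R{radius:g}")
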