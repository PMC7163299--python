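"""Half-bleach FRAP model for diffusion in a disk with a partially permeable rim.

Half-compartment FRAP bleaches one half of a roughly circular nuclear body
(chromocenter, nucleolus) and follows the fluorescence in the bleached and the
non-bleached half.  If the body is bounded by a barrier that slows exchange
with the nucleoplasm, bleached molecules preferentially redistribute *within*
the body, so the non-bleached half transiently darkens; without a barrier the
bleached molecules are diluted into the nucleoplasmic pool and the dip is
shallow.  The model is effective free diffusion inside a disk of radius ``R``
with a Robin ("radiation") boundary condition

    dc/dr + h*c = 0    at r = R,

where ``h`` is the barrier height (1/length).  Its inverse ``l = 1/h`` is the
effective thickness of the boundary, and the dimensionless permeability

    p = R*h = R/l

summarizes the rim: ``p = 0`` is an impermeable boundary, ``p -> inf`` no
boundary at all.  Working in units of ``R`` (radii in [0, 1]) and of the
diffusion time ``tauD`` the eigenvalues are ``alpha**2`` with ``alpha`` the
positive roots of

    alpha*J_n'(alpha) + p*J_n(alpha) = 0,

``J_n`` the Bessel function of the first kind.  The concentration of bleached
molecules after bleaching one half of the disk is expanded in these modes; the
semicircle-integrated contents ``c_B(t)`` (bleached half) and ``c_NB(t)``
(non-bleached half) start at (1, 0) and relax to 0.5/0.5 for a closed disk or
to 0/0 for a leaky one.  Only the angular orders ``n = 0`` (exchange across
the rim) and odd ``n`` (exchange between the halves) contribute; even orders
are killed by the half-disk symmetry.

Effective diffusion implicitly absorbs transient binding inside the body, so
``tauD`` is an apparent, not a molecular, diffusion time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, special

__all__ = [
    "BoundaryGeometry",
    "HalfBleachModel",
    "RecoveryPair",
    "HalfBleachFitResult",
    "boundary_roots",
    "n0_closed_form_weights",
    "halfbleach_modes",
    "halfbleach_profile",
    "halfbleach_curves",
    "normalize_recovery_pair",
    "fit_halfbleach",
]

ROOT_TOL = 1e-10


@dataclass(frozen=True)
class BoundaryGeometry:
    """Disk radius and rim permeability.

    ``p = R*h`` is the dimensionless permeability reported to users; the
    barrier height ``h`` (1/um) is kept internal.
    """

    R: float = 1.0
    p: float = 0.0

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError("disk radius R must be > 0")
        if not (self.p >= 0 and np.isfinite(self.p)):
            raise ValueError("permeability p must be finite and >= 0")

    @property
    def h(self) -> float:
        """Barrier height h = p/R (1/um)."""
        return self.p / self.R

    @property
    def l(self) -> float:
        """Effective boundary thickness l = 1/h (um); inf for p = 0."""
        return np.inf if self.p == 0 else self.R / self.p


@dataclass(frozen=True)
class HalfBleachModel:
    """Parameters of the confined-diffusion half-bleach model."""

    geometry: BoundaryGeometry
    tauD: float = 1.0
    f_immobile: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tauD > 0 and np.isfinite(self.tauD)):
            raise ValueError("tauD must be finite and > 0")
        if not (0.0 <= self.f_immobile <= 1.0):
            raise ValueError("f_immobile must lie in [0, 1]")
        if not (self.amplitude > 0):
            raise ValueError("amplitude must be > 0")

    @property
    def p(self) -> float:
        return self.geometry.p


def _robin_f(alpha: np.ndarray, n: int, p: float) -> np.ndarray:
    """Robin characteristic function alpha*J_n'(alpha) + p*J_n(alpha)."""
    return alpha * special.jvp(n, alpha) + p * special.jv(n, alpha)


def boundary_roots(n: int, p: float, k_max: int, *, scan_step: float = 0.05) -> np.ndarray:
    """First ``k_max`` positive roots of ``alpha*J_n'(alpha) + p*J_n(alpha) = 0``.

    The roots are bracketed on a fine grid and refined with Brent's method;
    alpha = 0 is excluded (it is a root only for n = 0, p = 0, where it
    carries the conserved uniform mode, handled separately by the series).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not np.isfinite(p) or p < 0:
        raise ValueError("p must be finite and >= 0")
    n = int(n)
    if n < 0:
        raise ValueError("angular order n must be >= 0")

    roots: list[float] = []
    # Roots are asymptotically pi-spaced; scan well past the expected range.
    # All roots exceed the first extremum of J_n, which lies above n, so the
    # scan starts there (this also avoids spurious "zeros" from J_n underflow
    # at small arguments for large n).
    lo = max(1e-6, float(n))
    span = (k_max + 3) * np.pi + 10.0
    for _attempt in range(4):
        upper = lo + span
        grid = np.arange(lo, upper, scan_step)
        fvals = _robin_f(grid, n, p)
        sign = np.sign(fvals)
        # treat exact zeros on the grid as sign changes
        idx = np.nonzero((sign[:-1] * sign[1:] < 0) | (fvals[:-1] == 0))[0]
        roots = []
        for i in idx:
            a, b = grid[i], grid[i + 1]
            if fvals[i] == 0.0:
                root = a
            else:
                root = optimize.brentq(_robin_f, a, b, args=(n, p), xtol=1e-14, rtol=1e-15)
            if root <= 1e-9:
                continue
            scale = max(1.0, p, abs(fvals[i]), abs(fvals[i + 1]))
            if abs(_robin_f(np.asarray(root), n, p)) > ROOT_TOL * scale:
                continue
            roots.append(float(root))
            if len(roots) == k_max:
                return np.asarray(roots)
        span *= 2.0
    raise RuntimeError(
        f"failed to bracket {k_max} boundary roots for n={n}, p={p} "
        f"(found {len(roots)} scanning up to alpha={upper:.1f})"
    )


def n0_closed_form_weights(p: float, alphas: np.ndarray) -> np.ndarray:
    """Closed-form n=0 mode weights 2*p**2 / (alpha**2*(alpha**2 + p**2)).

    This is the rim-exchange term of the semicircle series (identical for the
    bleached and the non-bleached half); used as an analytic cross-check of
    the quadrature-projected weights.
    """
    alphas = np.asarray(alphas, dtype=float)
    return 2.0 * p**2 / (alphas**2 * (alphas**2 + p**2))


# -- eigenmode table ---------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(200)
_GL_R = 0.5 * (_GL_NODES + 1.0)  # map [-1,1] -> [0,1]
_GL_W = 0.5 * _GL_WEIGHTS


def _radial_overlap(n: int, alphas: np.ndarray) -> np.ndarray:
    """R_n(alpha) = int_0^1 J_n(alpha*r) r dr by Gauss-Legendre quadrature."""
    a = np.asarray(alphas, dtype=float)[:, None]
    vals = special.jv(n, a * _GL_R[None, :]) * _GL_R[None, :]
    return vals @ _GL_W


def _radial_norm(n: int, p: float, alphas: np.ndarray) -> np.ndarray:
    """int_0^1 J_n(alpha*r)**2 r dr = (alpha**2+p**2-n**2) J_n(alpha)**2 / (2 alpha**2)."""
    a = np.asarray(alphas, dtype=float)
    return (a**2 + p**2 - n**2) * special.jv(n, a) ** 2 / (2.0 * a**2)


@dataclass(frozen=True)
class _Mode:
    n: int
    alpha: float
    # coefficient of J_n(alpha r)*sin(n phi) (or J_0(alpha r) for n=0) in the
    # normalized profile (pi/2 * concentration of bleached particles)
    profile_coeff: float
    # contribution weights to c_B(t), c_NB(t)
    w_B: float
    w_NB: float


@dataclass(frozen=True)
class SeriesSolution:
    """Truncated eigenmode table for a given permeability ``p``.

    ``constant`` is the conserved-mass term present only for p = 0 (0.5 in
    each semicircle); every other mode decays as exp(-alpha**2 * t/tauD).
    """

    p: float
    modes: tuple[_Mode, ...]
    constant: float
    truncation_tol: float = 1e-6

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted({m.n for m in self.modes}))

    def roots_per_order(self) -> dict[int, np.ndarray]:
        out: dict[int, list[float]] = {}
        for m in self.modes:
            out.setdefault(m.n, []).append(m.alpha)
        return {n: np.asarray(sorted(v)) for n, v in out.items()}


def _build_modes(p: float, alpha_max: float) -> tuple[list[_Mode], float]:
    modes: list[_Mode] = []
    constant = 0.5 if p == 0 else 0.0

    # n = 0: rim exchange (vanishes for p = 0 because J_0'(alpha) = 0 there
    # forces R_0 = 0)
    if p > 0:
        k_guess = max(2, int(alpha_max / np.pi) + 2)
        alphas = boundary_roots(0, p, k_guess)
        alphas = alphas[alphas <= alpha_max]
        if alphas.size:
            R0 = _radial_overlap(0, alphas)
            N0 = _radial_norm(0, p, alphas)
            # projection of the half-disk initial condition: B = 2*R0,
            # |psi|^2 = 2*pi*N0, semicircle overlap P = pi*R0
            w = R0**2 / N0
            coeff = (np.pi / 2.0) * (R0 / (np.pi * N0))
            for a, wi, ci in zip(alphas, w, coeff):
                modes.append(_Mode(0, float(a), float(ci), float(wi), float(wi)))

    # odd n: exchange between the two halves
    n = 1
    while n <= alpha_max:
        k_guess = max(2, int((alpha_max - n) / np.pi) + 3)
        alphas = boundary_roots(n, p, k_guess)
        alphas = alphas[alphas <= alpha_max]
        if alphas.size == 0 and n > 3:
            break
        if alphas.size:
            Rn = _radial_overlap(n, alphas)
            Nn = _radial_norm(n, p, alphas)
            with np.errstate(invalid="ignore", divide="ignore"):
                w = 8.0 * Rn**2 / (n**2 * np.pi**2 * Nn)
                coeff = (np.pi / 2.0) * (-4.0 * Rn / (n * np.pi**2 * Nn))
            for a, wi, ci in zip(alphas, w, coeff):
                if np.isfinite(wi) and np.isfinite(ci):
                    modes.append(_Mode(n, float(a), float(ci), float(wi), float(-wi)))
        n += 2
    return modes, constant


def halfbleach_modes(p: float, t_min: float, *, tol: float = 1e-6) -> SeriesSolution:
    """Build the eigenmode table, truncated adaptively for times >= ``t_min``.

    The cutoff ``alpha_max`` is raised until the semicircle content at the
    earliest requested time changes by less than ``tol``.  Times below
    2e-3*tauD are clamped for the truncation estimate: the highest modes they
    would demand are numerically negligible everywhere except in the first
    instants after an (idealized) instantaneous bleach.  Tables are memoized
    on (p, clamped t_min, tol); t_min is quantized to powers of two of the
    clamp so nearby requests share a table.
    """
    t_min = max(float(t_min), 2e-3)
    # quantize down to the next power-of-two multiple of the clamp: a smaller
    # t_min only adds modes, so the cached table is always sufficient
    t_min = 2e-3 * 2.0 ** np.floor(np.log2(t_min / 2e-3))
    return _halfbleach_modes_cached(float(p), float(t_min), float(tol))


@lru_cache(maxsize=128)
def _halfbleach_modes_cached(p: float, t_min: float, tol: float) -> SeriesSolution:
    alpha_max = np.sqrt(max(25.0, -np.log(1e-10) / t_min))
    prev = None
    for _ in range(6):
        modes, constant = _build_modes(p, alpha_max)
        w = np.array([m.w_B for m in modes])
        a2 = np.array([m.alpha**2 for m in modes])
        cB = constant + float(w @ np.exp(-a2 * t_min)) if modes else constant
        if prev is not None and abs(cB - prev) <= tol * max(abs(cB), 1e-3):
            return SeriesSolution(p, tuple(modes), constant, tol)
        prev = cB
        alpha_max *= 1.3
    raise RuntimeError(
        f"half-bleach series did not converge at t/tauD={t_min} "
        f"(last change {abs(cB - prev):.2e} vs tolerance {tol:.1e})"
    )


# -- forward evaluation ------------------------------------------------------

def halfbleach_profile(
    model: HalfBleachModel,
    t_over_tauD: float,
    phi: np.ndarray | float,
    r_grid: np.ndarray,
    *,
    series: SeriesSolution | None = None,
) -> np.ndarray:
    """Normalized bleached-particle concentration c(r, phi, t/tauD).

    The bleached half is phi in (pi, 2*pi); the profile is normalized so the
    initial concentration on the bleached half is 1.  Returns an array with
    shape broadcast(phi, r) evaluated on the grid (phi x r) if both are
    vectors.
    """
    if t_over_tauD < 0:
        raise ValueError("t must be >= 0")
    r = np.atleast_1d(np.asarray(r_grid, dtype=float))
    ph = np.atleast_1d(np.asarray(phi, dtype=float))
    if series is None:
        series = halfbleach_modes(model.p, max(t_over_tauD, 1e-3))
    out = np.full((ph.size, r.size), series.constant, dtype=float)
    for m in series.modes:
        decay = np.exp(-m.alpha**2 * t_over_tauD)
        radial = special.jv(m.n, m.alpha * r)
        ang = np.ones_like(ph) if m.n == 0 else np.sin(m.n * ph)
        out += m.profile_coeff * decay * ang[:, None] * radial[None, :]
    return out.squeeze()


def halfbleach_curves(
    model_or_p: HalfBleachModel | float,
    times_over_tauD: np.ndarray,
    *,
    tol: float = 1e-6,
    series: SeriesSolution | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Semicircle-integrated bleached contents (c_B(t), c_NB(t)).

    ``c_B(0) = 1`` and ``c_NB(0) = 0`` exactly; both curves live in [0, 1].
    Times are in units of tauD.
    """
    p = model_or_p.p if isinstance(model_or_p, HalfBleachModel) else float(model_or_p)
    t = np.atleast_1d(np.asarray(times_over_tauD, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    pos = t[t > 0]
    if series is None:
        t_min = pos.min() if pos.size else 1.0
        series = halfbleach_modes(p, t_min, tol=tol)
    a2 = np.array([m.alpha**2 for m in series.modes])
    wB = np.array([m.w_B for m in series.modes])
    wNB = np.array([m.w_NB for m in series.modes])
    decay = np.exp(-np.outer(t, a2)) if a2.size else np.zeros((t.size, 0))
    cB = series.constant + decay @ wB
    cNB = series.constant + decay @ wNB
    # the truncated series carries Gibbs error exactly at t=0; the value there
    # is fixed by the initial condition
    cB[t == 0] = 1.0
    cNB[t == 0] = 0.0
    return cB, cNB


# -- experimental normalization chain ---------------------------------------

@dataclass
class RecoveryPair:
    """Paired bleached / non-bleached ROI time series.

    ``raw_means`` columns are the frame-averaged intensities
    (I_B, I_NB, I_Nucleus, I_BG); ``signal_B``/``signal_NB`` hold the curves in
    the current normalization ``state``.
    """

    times: np.ndarray
    signal_B: np.ndarray
    signal_NB: np.ndarray
    N_B: int
    N_NB: int
    t_bleach: int
    raw_means: dict[str, np.ndarray] = field(default_factory=dict)
    state: str = "raw"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal_B = np.asarray(self.signal_B, dtype=float)
        self.signal_NB = np.asarray(self.signal_NB, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.N_B <= 0 or self.N_NB <= 0:
            raise ValueError("ROI pixel counts must be > 0")
        if not (0 <= self.t_bleach < self.times.size):
            raise ValueError("bleach frame index out of range")


def normalize_recovery_pair(pair: RecoveryPair) -> RecoveryPair:
    """Apply the full half-bleach normalization chain.

    1. background-correct against the nucleoplasm:
       FRAP = (I - I_BG) / (I_Nucleus - I_BG)
    2. weight by relative ROI size so the curves are proportional to particle
       numbers: FRAP' = N/(N_B + N_NB) * FRAP
    3. double-normalize *both* curves with the bleached-ROI constants so their
       relative magnitude is preserved: pre-bleach mean of the bleached curve
       maps to 1 and its bleach-frame value to 0
    4. shift the non-bleached curve additively to unity before the bleach
    """
    if pair.state != "raw":
        raise ValueError("pair is already normalized")
    if pair.t_bleach < 1:
        raise ValueError("need at least one pre-bleach frame")
    rm = pair.raw_means
    for key in ("I_B", "I_NB", "I_Nucleus", "I_BG"):
        if key not in rm:
            raise ValueError(f"raw_means missing {key!r}")
    I_BG = np.asarray(rm["I_BG"], dtype=float)
    I_nuc = np.asarray(rm["I_Nucleus"], dtype=float)
    denom = I_nuc - I_BG
    if np.any(denom <= 0):
        raise ValueError("I_Nucleus - I_BG must be > 0 at every frame")

    frap_B = (np.asarray(rm["I_B"], float) - I_BG) / denom
    frap_NB = (np.asarray(rm["I_NB"], float) - I_BG) / denom
    n_tot = pair.N_B + pair.N_NB
    frap_B *= pair.N_B / n_tot
    frap_NB *= pair.N_NB / n_tot

    pre = slice(0, pair.t_bleach)
    b_pre = frap_B[pre].mean()
    b_bleach = frap_B[pair.t_bleach]
    depth = b_pre - b_bleach
    if depth <= 1e-9 * max(abs(b_pre), 1e-30):
        raise ValueError("zero bleach depth: bleached ROI did not lose signal")
    norm_B = (frap_B - b_bleach) / depth
    norm_NB = (frap_NB - b_bleach) / depth
    norm_NB = norm_NB - norm_NB[pre].mean() + 1.0

    return RecoveryPair(
        times=pair.times,
        signal_B=norm_B,
        signal_NB=norm_NB,
        N_B=pair.N_B,
        N_NB=pair.N_NB,
        t_bleach=pair.t_bleach,
        raw_means=dict(rm),
        state="normalized",
    )


# -- fitting -----------------------------------------------------------------

def model_pair_curves(
    model: HalfBleachModel,
    t_post: np.ndarray,
    *,
    series: SeriesSolution | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized model curves at post-bleach times (seconds since bleach).

    bleached:     F_B(t)  = 1 - amplitude*(f_imm + (1 - f_imm)*c_B(t/tauD))
    non-bleached: F_NB(t) = 1 - amplitude*(1 - f_imm)*c_NB(t/tauD)
    """
    cB, cNB = halfbleach_curves(model, np.asarray(t_post, float) / model.tauD, series=series)
    f = model.f_immobile
    s = model.amplitude
    return 1.0 - s * (f + (1.0 - f) * cB), 1.0 - s * (1.0 - f) * cNB


@dataclass(frozen=True)
class HalfBleachFitResult:
    model: HalfBleachModel
    stderr: dict[str, float]
    residuals_B: np.ndarray
    residuals_NB: np.ndarray
    rss: float
    at_bounds: tuple[str, ...]
    n_starts: int

    @property
    def p(self) -> float:
        return self.model.p


_P_BOUNDS = (0.0, 100.0)
_TAUD_BOUNDS = (1e-3, 1e4)


def fit_halfbleach(
    pair: RecoveryPair,
    *,
    fit_immobile: bool = True,
    p_starts: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> HalfBleachFitResult:
    """Jointly fit the bleached and non-bleached curves of a normalized pair.

    Bounded least squares over (p, tauD, f_immobile, amplitude) with
    multi-start over ``p_starts`` — the sum of squares is weakly curved in p
    for large p (a nearly open boundary looks the same at any larger
    permeability), so a single start can stall in that valley.
    """
    if pair.state != "normalized":
        raise ValueError("pair must be normalized first (normalize_recovery_pair)")
    t_post = pair.times[pair.t_bleach :] - pair.times[pair.t_bleach]
    y_B = pair.signal_B[pair.t_bleach :]
    y_NB = pair.signal_NB[pair.t_bleach :]
    data = np.concatenate([y_B, y_NB])

    # rough tauD scale from the observation window
    t_span = max(t_post[-1], 1.0)

    def residual(theta: np.ndarray) -> np.ndarray:
        p, tauD, f_imm, amp = theta
        m = HalfBleachModel(BoundaryGeometry(1.0, p), tauD, f_imm, amp)
        fB, fNB = model_pair_curves(m, t_post)
        return np.concatenate([fB, fNB]) - data

    lo = [_P_BOUNDS[0], _TAUD_BOUNDS[0], 0.0, 0.5]
    hi = [_P_BOUNDS[1], _TAUD_BOUNDS[1], 1.0 if fit_immobile else 1e-9, 1.5]
    best = None
    # a start that already fits to well below measurement noise makes the
    # remaining starts redundant
    good_enough = 0.5 * (1e-4) ** 2 * data.size
    for p0 in p_starts:
        x0 = [p0, min(max(t_span / 3.0, 2 * _TAUD_BOUNDS[0]), _TAUD_BOUNDS[1] / 2),
              1e-3 if fit_immobile else 0.0, 1.0]
        try:
            sol = optimize.least_squares(residual, x0, bounds=(lo, hi), xtol=1e-9, ftol=1e-9)
        except Exception as exc:  # noqa: BLE001 — a failed start is retried from the others
            last_exc = exc
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < good_enough:
            break
    if best is None or not best.success:
        detail = f"; last iterate {best.x}" if best is not None else f"; last error: {last_exc}"
        raise RuntimeError("half-bleach fit did not converge" + detail)

    p, tauD, f_imm, amp = best.x
    model = HalfBleachModel(BoundaryGeometry(1.0, p), tauD, f_imm, amp)
    names = ("p", "tauD", "f_immobile", "amplitude")
    stderr = _stderr_from_jac(best, len(data))
    at_bounds = tuple(
        nm
        for nm, v, a, b in zip(names, best.x, lo, hi)
        if np.isclose(v, a, atol=1e-9) or np.isclose(v, b, rtol=1e-6)
    )
    nb = y_B.size
    return HalfBleachFitResult(
        model=model,
        stderr=dict(zip(names, stderr)),
        residuals_B=best.fun[:nb],
        residuals_NB=best.fun[nb:],
        rss=float(2 * best.cost),
        at_bounds=at_bounds,
        n_starts=len(p_starts),
    )


def _stderr_from_jac(sol, n_obs: int) -> np.ndarray:
    """Standard errors from the least-squares Jacobian (Gauss-Newton covariance)."""
    _, s, VT = np.linalg.svd(sol.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    cov = (VT.T / s**2) @ VT
    dof = max(n_obs - sol.x.size, 1)
    sigma2 = 2 * sol.cost / dof
    return np.sqrt(np.diag(cov) * sigma2)


def simulate_pair(
    model: HalfBleachModel,
    n_frames: int,
    dt: float,
    *,
    n_pre: int = 5,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RecoveryPair:
    """Forward-construct a raw RecoveryPair from the model (see synthetic_data)."""
    from .synthetic_data import gen_halfbleach_pair

    return gen_halfbleach_pair(model, n_frames, dt, n_pre=n_pre, noise=noise, rng=rng)
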