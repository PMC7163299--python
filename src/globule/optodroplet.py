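"""Optodroplet abundance and dissociation kinetics.

Light-induced condensates ("optodroplets", cryptochrome-2 PHR fusions) make
the nucleoplasmic intensity distribution heterogeneous; the coefficient of
variation (CV = standard deviation / mean) of nucleoplasmic pixels therefore
reports droplet abundance without segmenting individual droplets.  After the
inducing light is switched off, droplets dissolve with a short lag phase that
a single exponential cannot produce; the decay is modelled as a two-step
dissociation

    A(t) = A0 * (1 + k*t) * exp(-k*t)          (+ plateau for long-lived droplets)

whose half-decay time defines the reported lifetime tau = 1.68/k (1.68... is
the positive root of (1 + x)*exp(-x) = 1/2).

Conventions fixed here: the CV uses the population standard deviation, and in
the double normalization the final-frame value is subtracted *after* dividing
by the first-frame CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "CVSeries",
    "DecayFit",
    "HALF_DECAY_CONSTANT",
    "half_decay_root",
    "nucleoplasm_cv",
    "relative_abundance",
    "double_normalize_series",
    "two_step_decay",
    "fit_two_step_decay",
    "saturation_curve",
]


def half_decay_root(tol: float = 1e-10) -> float:
    """Positive root of (1 + x) * exp(-x) = 1/2, found by bisection.

    This is the time (in units of 1/k) at which A(t) = A0*(1+kt)*exp(-kt) has
    dropped to half its initial value; it evaluates to 1.68 at the reported
    precision.
    """
    f = lambda x: (1.0 + x) * np.exp(-x) - 0.5
    lo, hi = 1.0, 3.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


HALF_DECAY_CONSTANT = 1.68  # half_decay_root() to the reported precision


@dataclass
class CVSeries:
    """Per-frame coefficient of variation of nucleoplasmic pixel intensities."""

    times: np.ndarray
    cv: np.ndarray
    cv_pre: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        if self.times.shape != self.cv.shape:
            raise ValueError("times and cv must have the same length")

    @property
    def cv_last(self) -> float:
        return float(self.cv[-1])


@dataclass(frozen=True)
class DecayFit:
    A0: float
    k: float  # 1/s
    plateau: float
    errors: dict

    @property
    def tau(self) -> float:
        """Optodroplet lifetime tau = 1.68/k (s), the half-decay time."""
        return HALF_DECAY_CONSTANT / self.k


def nucleoplasm_cv(
    image: np.ndarray,
    mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    smooth_sigma: float | None = None,
) -> float:
    """CV (population SD over mean) of the included nucleoplasmic pixels.

    ``exclusion_mask`` removes e.g. intensely labeled nucleoli or pre-existing
    aggregates; ``smooth_sigma`` applies a Gaussian blur first (useful when
    shot noise would otherwise dominate the CV of dim cells).
    """
    img = np.asarray(image, dtype=float)
    if smooth_sigma:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    keep = np.asarray(mask, dtype=bool)
    if exclusion_mask is not None:
        keep = keep & ~np.asarray(exclusion_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no pixels left after applying exclusions")
    vals = img[keep]
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean intensity must be > 0")
    return float(vals.std() / mean)  # population SD


def relative_abundance(cv_pre: float, cv_post: float) -> float:
    """Relative droplet abundance: CV after minus CV before illumination."""
    if not (np.isfinite(cv_pre) and np.isfinite(cv_post)):
        raise ValueError("CV values must be finite")
    return cv_post - cv_pre


def double_normalize_series(series: CVSeries) -> CVSeries:
    """Divide by the first-frame CV, then subtract the final normalized value.

    If the pre-illumination CV (when supplied) is lower than the last-frame
    CV — residual droplets never fully dissociated — the pre-illumination
    value is subtracted instead, so the curve still reports the decaying
    population.  The subtracted reference maps exactly to 0.
    """
    if series.normalized:
        raise ValueError("series is already normalized")
    if series.cv.size < 3:
        raise ValueError("need at least 3 frames")
    first = series.cv[0]
    if first <= 0:
        raise ValueError("first-frame CV must be > 0")
    scaled = series.cv / first
    if series.cv_pre is not None and series.cv_pre < series.cv_last:
        ref = series.cv_pre / first
    else:
        ref = scaled[-1]
    return CVSeries(
        times=series.times,
        cv=scaled - ref,
        cv_pre=series.cv_pre,
        normalized=True,
    )


def two_step_decay(t: np.ndarray, A0: float, k: float, plateau: float = 0.0) -> np.ndarray:
    """A(t) = A0*(1 + k*t)*exp(-k*t) + plateau; flat (dA/dt = 0) at t = 0."""
    t = np.asarray(t, dtype=float)
    return A0 * (1.0 + k * t) * np.exp(-k * t) + plateau


def fit_two_step_decay(series: CVSeries, with_plateau: bool = False) -> DecayFit:
    """Least-squares fit of the two-step dissociation model to a normalized series.

    The plateau term is reserved for proteins forming long-lived droplets; by
    default it is pinned at zero.
    """
    if not series.normalized:
        raise ValueError("normalize the series first (double_normalize_series)")
    t = series.times - series.times[0]
    y = series.cv
    if t.size < 6:
        raise ValueError("need at least 6 frames to fit")
    amp0 = float(y[0])
    if amp0 <= 0 or y.max() <= 1e-12:
        raise ValueError("no decay amplitude: series has no initial abundance")

    # initial rate from the half-crossing
    below = np.nonzero(y < 0.5 * y.max())[0]
    t_half = t[below[0]] if below.size and below[0] > 0 else t[-1] / 2
    k0 = HALF_DECAY_CONSTANT / max(t_half, t[1])

    def model(theta):
        if with_plateau:
            A0, k, pl = theta
        else:
            (A0, k), pl = theta, 0.0
        return two_step_decay(t, A0, k, pl)

    x0 = [amp0, k0, min(max(y[-1], 0.0), amp0)] if with_plateau else [amp0, k0]
    lo = [0.0, 1e-8] + ([0.0] if with_plateau else [])
    hi = [np.inf, 1e3] + ([np.inf] if with_plateau else [])
    sol = optimize.least_squares(lambda th: model(th) - y, x0, bounds=(lo, hi))
    if not sol.success:
        raise RuntimeError(f"two-step decay fit did not converge: {sol.message}")
    A0, k = sol.x[0], sol.x[1]
    plateau = sol.x[2] if with_plateau else 0.0
    if np.isclose(k, hi[1]) or np.isclose(k, lo[1]):
        raise RuntimeError(f"decay rate pinned at bound (k = {k:.3g}/s)")
    errs = _lsq_stderr(sol, y.size)
    names = ("A0", "k", "plateau") if with_plateau else ("A0", "k")
    return DecayFit(A0=A0, k=k, plateau=plateau, errors=dict(zip(names, errs)))


def _lsq_stderr(sol, n_obs: int) -> np.ndarray:
    _, s, VT = np.linalg.svd(sol.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    cov = (VT.T / s**2) @ VT
    sigma2 = 2 * sol.cost / max(n_obs - sol.x.size, 1)
    return np.sqrt(np.diag(cov) * sigma2)


@dataclass(frozen=True)
class SaturationCurve:
    bin_centers: np.ndarray  # uM
    mean_abundance: np.ndarray
    sem_abundance: np.ndarray
    n_per_bin: np.ndarray
    saturation_concentration: float | None  # None if never crossed


def saturation_curve(
    cells: list[tuple[float, float]] | np.ndarray,
    n_bins: int = 8,
) -> SaturationCurve:
    """Concentration-abundance relationship on log-spaced concentration bins.

    The relative saturation concentration is taken as the center of the first
    bin whose mean abundance exceeds the baseline (lowest bin) by more than
    two of its SDs; cells that never cross return ``None``.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 10:
        raise ValueError("need >= 10 (concentration, abundance) cells")
    conc, ab = arr[:, 0], arr[:, 1]
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if conc.max() / conc.min() < 10:
        raise ValueError("need at least one decade of concentrations")
    edges = np.geomspace(conc.min(), conc.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(conc, edges) - 1, 0, n_bins - 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = ab[idx == b]
        n[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sd[b] = sel.std(ddof=1) if sel.size > 1 else 0.0
            sem[b] = sd[b] / np.sqrt(sel.size)
    filled = np.nonzero(n > 0)[0]
    base = filled[0]
    thr = mean[base] + 2.0 * sd[base]
    crossing = None
    for b in filled[1:]:
        if mean[b] > thr:
            crossing = float(centers[b])
            break
    return SaturationCurve(
        bin_centers=centers[filled],
        mean_abundance=mean[filled],
        sem_abundance=sem[filled],
        n_per_bin=n[filled],
        saturation_concentration=crossing,
    )
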