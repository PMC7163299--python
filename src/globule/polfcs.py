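"""Polarization-resolved fluorescence correlation spectroscopy.

Pol-FCS records fluorescence through polarizers parallel and perpendicular to
the excitation beam.  Cross-correlations of detectors seeing the *same*
polarization contain a rotational-diffusion decay (tens to hundreds of ns for
a GFP-sized probe) that is absent from crossed-polarization pairs, so the
difference between the two curve families isolates molecular rotation — a
direct, binding-insensitive readout of local viscosity.  The model is a
product of rotation, triplet and (two-component anomalous) translation terms:

    G_parallel(tau) = G_rot * G_trip * G_trans
    G_crossed(tau)  =         G_trip * G_trans

    G_rot  = 1 + fR*exp(-tau/tauR)
    G_trip = 1 + fT*exp(-tau/tauT)
    G_trans = f1/N * (1 + (tau/tauD1)**a1)**-1 * (1 + (tau/tauD1)**a1/kappa**2)**-0.5
            + (1-f1)/N * (same with tauD2, a2)

``kappa`` is the axial-to-lateral focus aspect ratio, fixed during fitting.
All times are in seconds internally.

The estimator is a multi-tau (quasi-logarithmic) correlator: lag spacing
doubles per octave so a single curve spans sub-bin to multi-second lags.
Curves are computed per 5-s window after high-pass detrending (removal of
fluctuations slower than 100 ms, which reflect stage drift and vibrations)
and averaged, with per-lag SDs across windows retained as fit weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "PolFCSParams",
    "CorrelationCurve",
    "PolFCSFitResult",
    "multitau_correlate",
    "multitau_lags",
    "model_correlation",
    "global_fit_polfcs",
]


@dataclass(frozen=True)
class PolFCSParams:
    """Model parameters; all times in seconds."""

    N: float = 1.0
    fR: float = 0.0
    tauR: float = 100e-9
    fT: float = 0.0
    tauT: float = 5e-6
    f1: float = 1.0
    tauD1: float = 1e-3
    tauD2: float = 50e-3
    alpha1: float = 1.0
    alpha2: float = 1.0
    kappa: float = 5.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("particle number N must be > 0")
        if not (0.0 <= self.f1 <= 1.0):
            raise ValueError("f1 must lie in [0, 1]")
        if min(self.tauR, self.tauT, self.tauD1, self.tauD2) <= 0:
            raise ValueError("all correlation times must be > 0")
        if self.fR < 0 or self.fT < 0:
            raise ValueError("fR and fT must be >= 0")
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("anomaly exponents must be > 0")
        if not (self.tauR < self.tauT < self.tauD1 <= self.tauD2 * (1 + 1e-12)):
            warnings.warn(
                "time scales violate tauR << tauT << tauD1 <= tauD2; "
                "the rotational term may not be separable",
                stacklevel=2,
            )


@dataclass
class CorrelationCurve:
    lags: np.ndarray  # s
    G: np.ndarray
    sd: np.ndarray
    mode: str  # "parallel" | "crossed"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")
        if self.mode not in ("parallel", "crossed"):
            raise ValueError("mode must be 'parallel' or 'crossed'")


def model_correlation(params: PolFCSParams, lags: np.ndarray, mode: str) -> np.ndarray:
    """Evaluate the Pol-FCS model; parallel and crossed differ only by G_rot."""
    tau = np.asarray(lags, dtype=float)
    x1 = (tau / params.tauD1) ** params.alpha1
    x2 = (tau / params.tauD2) ** params.alpha2
    k2 = params.kappa**2
    g_trans = (
        params.f1 / params.N / (1.0 + x1) / np.sqrt(1.0 + x1 / k2)
        + (1.0 - params.f1) / params.N / (1.0 + x2) / np.sqrt(1.0 + x2 / k2)
    )
    g = (1.0 + params.fT * np.exp(-tau / params.tauT)) * g_trans
    if mode == "parallel":
        g = (1.0 + params.fR * np.exp(-tau / params.tauR)) * g
    elif mode != "crossed":
        raise ValueError("mode must be 'parallel' or 'crossed'")
    return g


# -- multi-tau correlator ----------------------------------------------------

def multitau_lags(bin_width: float, n_samples: int, m: int = 16) -> np.ndarray:
    """Quasi-logarithmic lag grid: linear up to m bins, then doubling per octave."""
    lags = list(range(1, m + 1))
    step = 2
    base = m
    length = n_samples
    while True:
        length = length // 2
        if length < 2 * m:
            break
        for j in range(m // 2 + 1, m + 1):
            lags.append(j * step)
        step *= 2
    return np.asarray(lags, dtype=float) * bin_width


def _detrend(x: np.ndarray, bin_width: float, cutoff_s: float) -> np.ndarray:
    """Remove Fourier components slower than ``cutoff_s`` (keeping the mean)."""
    if cutoff_s is None or cutoff_s <= 0:
        return x
    n = x.size
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=bin_width)
    kill = (freqs > 0) & (freqs < 1.0 / cutoff_s)
    X[kill] = 0.0
    return np.fft.irfft(X, n=n)


def _window_multitau(a: np.ndarray, b: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """One window's multi-tau estimate; returns (lags_in_bins, G).

    Normalization uses the full-window monitor means (preserved under
    coarsening): normalizing by the overlapping-segment means instead would
    bias deep levels by O(1/segment length).
    """
    lags: list[int] = []
    G: list[float] = []
    level = 0
    aa, bb = a.astype(float), b.astype(float)
    norm = a.mean() * b.mean()
    scale = 1
    while aa.size >= 2 * m:
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            x = aa[:-k]
            y = bb[k:]
            if norm <= 0:
                G.append(0.0)
            else:
                G.append(float((x * y).mean() / norm - 1.0))
            lags.append(k * scale)
        # coarsen by 2 for the next octave
        ntrim = (aa.size // 2) * 2
        aa = 0.5 * (aa[:ntrim:2] + aa[1:ntrim:2])
        bb = 0.5 * (bb[:ntrim:2] + bb[1:ntrim:2])
        scale *= 2
        level += 1
    return np.asarray(lags), np.asarray(G)


def multitau_correlate(
    trace_a: np.ndarray,
    trace_b: np.ndarray | None = None,
    *,
    bin_width: float,
    window_s: float = 5.0,
    detrend_cutoff_s: float = 0.1,
    m: int = 16,
    mode: str = "crossed",
) -> CorrelationCurve:
    """Windowed multi-tau (cross-)correlation of binned intensity traces.

    The trace is split into windows of ``window_s``; each window is high-pass
    detrended, correlated with symmetric normalization (covariance of relative
    fluctuations), and the windows are averaged with per-lag SDs.
    """
    a = np.asarray(trace_a, dtype=float)
    b = a if trace_b is None else np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1D arrays of equal length")
    wlen = int(round(window_s / bin_width))
    if wlen < 4 * m:
        raise ValueError("window too short for the requested lag cascade")
    n_win = a.size // wlen
    if n_win < 1:
        raise ValueError("trace shorter than one window")

    curves = []
    for w in range(n_win):
        sl = slice(w * wlen, (w + 1) * wlen)
        aw = _detrend(a[sl], bin_width, detrend_cutoff_s)
        bw = aw if trace_b is None else _detrend(b[sl], bin_width, detrend_cutoff_s)
        lag_bins, G = _window_multitau(aw, bw, m)
        curves.append(G)
    stack = np.vstack(curves)
    Gm = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n_win > 1 else np.zeros_like(Gm)
    return CorrelationCurve(lags=lag_bins * bin_width, G=Gm, sd=sd, mode=mode)


# -- global fit --------------------------------------------------------------

@dataclass(frozen=True)
class PolFCSFitResult:
    params: PolFCSParams
    stderr: dict
    redchi: float
    tauR_identifiable: bool
    message: str


def global_fit_polfcs(
    parallel: CorrelationCurve,
    crossed: CorrelationCurve,
    *,
    kappa: float,
    components: int = 2,
    fit_anomaly: bool = True,
) -> PolFCSFitResult:
    """Global fit of the parallel and crossed curves with shared parameters.

    All parameters are shared; only the rotational factor distinguishes the
    two modes, so the rotational term is constrained by their difference while
    triplet and translation are constrained mostly by the crossed curve.
    Residuals are weighted by the per-lag SDs (floored at 1% of the curve
    maximum to keep empty-window lags from dominating).  ``tauR`` is flagged
    unidentifiable when the fitted rotational amplitude is consistent with
    zero.
    """
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")

    g0 = max(crossed.G.max(), 1e-12)
    params = lmfit.Parameters()
    params.add("N", value=1.0 / g0, min=1e-6)
    params.add("fR", value=0.2, min=0.0, max=5.0)
    params.add("tauR", value=100e-9, min=1e-9, max=1e-5)  # 1 ns .. 10 us
    params.add("fT", value=0.1, min=0.0, max=5.0)
    params.add("tauT", value=5e-6, min=1e-7, max=1e-4)  # 0.1 .. 100 us
    params.add("tauD1", value=1e-3, min=1e-6, max=10.0)
    params.add("alpha1", value=1.0, min=0.2, max=2.0, vary=fit_anomaly)
    if components == 2:
        params.add("f1", value=0.7, min=0.0, max=1.0)
        params.add("tauD2", value=50e-3, min=1e-6, max=10.0)
        params.add("alpha2", value=1.0, min=0.2, max=2.0, vary=fit_anomaly)
    else:
        params.add("f1", value=1.0, vary=False)
        params.add("tauD2", value=1.0, vary=False)
        params.add("alpha2", value=1.0, vary=False)

    def weights(curve: CorrelationCurve) -> np.ndarray:
        floor = 0.01 * max(curve.G.max(), 1e-12)
        return np.maximum(curve.sd, floor)

    w_par, w_cr = weights(parallel), weights(crossed)

    def build(p) -> PolFCSParams:
        v = p.valuesdict()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PolFCSParams(
                N=v["N"], fR=v["fR"], tauR=v["tauR"], fT=v["fT"], tauT=v["tauT"],
                f1=v["f1"], tauD1=v["tauD1"], tauD2=v["tauD2"],
                alpha1=v["alpha1"], alpha2=v["alpha2"], kappa=kappa,
            )

    def resid(p):
        mp = build(p)
        r1 = (model_correlation(mp, parallel.lags, "parallel") - parallel.G) / w_par
        r2 = (model_correlation(mp, crossed.lags, "crossed") - crossed.G) / w_cr
        return np.concatenate([r1, r2])

    res = lmfit.minimize(resid, params)
    if not res.success:
        raise RuntimeError(f"Pol-FCS global fit did not converge: {res.message}")
    fitted = build(res.params)
    fr = res.params["fR"]
    identifiable = fitted.fR > 1e-3 and not (
        fr.stderr is not None and fr.stderr > 0 and fitted.fR < 2 * fr.stderr
    )
    if not identifiable:
        warnings.warn("rotational amplitude ~ 0: tauR is unidentifiable", stacklevel=2)
    stderr = {k: res.params[k].stderr for k in res.params}
    return PolFCSFitResult(
        params=fitted,
        stderr=stderr,
        redchi=float(res.redchi),
        tauR_identifiable=bool(identifiable),
        message=str(res.message),
    )
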