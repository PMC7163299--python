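"""Image correlation spectroscopy of chromocenter substructure.

ICS quantifies the characteristic size of intensity clusters in an image from
its spatial autocorrelation

    G(dx, dy) = < dI(x, y) * dI(x+dx, y+dy) > / <I>^2,   dI = I - <I>,

radially averaged to G(d) and fitted with one or two stretched exponentials

    G(d) = a1*exp(-(d/lambda1)**n1) + a2*exp(-(d/lambda2)**n2).

The correlation lengths ``lambda`` correspond to cluster radii (the reported
cluster size is the full diameter ``2*lambda1`` in physical units); the
exponents ``n`` describe the "fuzziness" of each component — large ``n`` means
equally sized, sharp-edged objects, small ``n`` a broad size distribution or
soft edges.  The inverse amplitude is a measure of cluster abundance.

Shifts are non-periodic, averaged over overlapping pixel pairs only: the
rectangularized field is not periodic, so wraparound correlations would be
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "IcsSegmentation",
    "RadialCorrelation",
    "ICSFit",
    "segment_for_ics",
    "rectangularize",
    "spatial_autocorrelation",
    "radial_average",
    "fit_ics",
]


@dataclass(frozen=True)
class IcsSegmentation:
    nucleus_mask: np.ndarray
    chromocenter_mask: np.ndarray
    q_nucleus: float = 0.40
    q_chromocenter: float = 0.90


@dataclass(frozen=True)
class RadialCorrelation:
    d: np.ndarray  # shift length, pixels
    G: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class ICSFit:
    a1: float
    lambda1: float
    n1: float
    a2: float
    lambda2: float
    n2: float
    pixel_size: float
    stderr: dict
    rss: float
    n_components: int

    @property
    def cluster_diameter(self) -> float:
        """Full cluster diameter 2*lambda1*pixel_size (same units as pixel_size)."""
        return 2.0 * self.lambda1 * self.pixel_size


def segment_for_ics(
    image: np.ndarray, q_nucleus: float = 0.40, q_chromocenter: float = 0.90
) -> IcsSegmentation:
    """Quantile segmentation: nucleus over the whole image, chromocenters
    within the nucleus.

    Pixels strictly above the quantile threshold are kept (ties at the
    threshold are excluded, so a constant image yields an empty mask).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("expected a nonnegative single-channel 2D image")
    nuc_thr = np.quantile(img, q_nucleus)
    nucleus = img > nuc_thr
    if not nucleus.any():
        raise ValueError("empty nucleus mask (image may be constant)")
    cc_thr = np.quantile(img[nucleus], q_chromocenter)
    chromo = nucleus & (img > cc_thr)
    if not chromo.any():
        raise ValueError("empty chromocenter mask (nuclear intensities may be constant)")
    return IcsSegmentation(nucleus, chromo, q_nucleus, q_chromocenter)


def rectangularize(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bounding-box crop with off-mask pixels filled by the on-mask mean.

    The fill value equals the mean inside the mask, so the filled pixels carry
    no intensity fluctuation and the crop's mean equals the masked mean.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub = img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()
    m = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    sub[~m] = img[mask].mean()
    return sub


def spatial_autocorrelation(
    image: np.ndarray, max_shift: int | None = None
) -> tuple[np.ndarray, np.ndarray, RadialCorrelation]:
    """Non-periodic spatial autocorrelation and its radial average.

    Returns ``(G2, n_pairs2, radial)`` where ``G2[m + dy, m + dx]`` is the
    correlation at shift (dx, dy) for ``m = max_shift`` and ``n_pairs2`` the
    number of overlapping pixel pairs entering each value.  The average
    intensity is that of the whole (rectangularized) image; the zero shift
    gives the population variance over mean squared.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("expected a finite 2D image")
    mean = img.mean()
    if mean <= 0:
        raise ValueError("image mean must be > 0")
    F = img - mean
    ny, nx = F.shape
    m = max_shift if max_shift is not None else min(ny, nx) // 2
    m = int(min(m, ny - 1, nx - 1))
    G2 = np.zeros((2 * m + 1, 2 * m + 1))
    npairs = np.zeros_like(G2)
    for dy in range(-m, m + 1):
        ys = slice(max(0, -dy), ny - max(0, dy))
        yt = slice(max(0, dy), ny - max(0, -dy))
        for dx in range(-m, m + 1):
            xs = slice(max(0, -dx), nx - max(0, dx))
            xt = slice(max(0, dx), nx - max(0, -dx))
            a = F[ys, xs]
            b = F[yt, xt]
            npairs[m + dy, m + dx] = a.size
            G2[m + dy, m + dx] = (a * b).sum() / a.size / mean**2
    return G2, npairs, radial_average(G2, npairs)


def radial_average(G2: np.ndarray, n_pairs: np.ndarray) -> RadialCorrelation:
    """Pair-count-weighted radial average with integer shift-length bins."""
    m = G2.shape[0] // 2
    dy, dx = np.mgrid[-m : m + 1, -m : m + 1]
    d = np.rint(np.hypot(dx, dy)).astype(int)
    nbins = d.max() + 1
    w = n_pairs.ravel()
    sums = np.bincount(d.ravel(), weights=(G2 * n_pairs).ravel(), minlength=nbins)
    counts = np.bincount(d.ravel(), weights=w, minlength=nbins)
    keep = counts > 0
    return RadialCorrelation(
        d=np.arange(nbins)[keep].astype(float),
        G=sums[keep] / counts[keep],
        n_pairs=counts[keep],
    )


def _ics_model(d, a1, lambda1, n1, a2, lambda2, n2):
    return a1 * np.exp(-((d / lambda1) ** n1)) + a2 * np.exp(-((d / lambda2) ** n2))


def fit_ics(
    rc: RadialCorrelation,
    components: int | str = "auto",
    *,
    pixel_size: float = 15.0,
    include_d0: bool = True,
    auto_improvement: float = 0.20,
) -> ICSFit:
    """Fit the radial correlation with one or two stretched exponentials.

    ``components='auto'`` accepts the second component only if it improves the
    residual sum of squares by more than ``auto_improvement`` (default 20%).
    ``pixel_size`` (nm/pixel) converts ``lambda1`` to the physical cluster
    diameter ``2*lambda1*pixel_size``.
    """
    d = np.asarray(rc.d, dtype=float)
    G = np.asarray(rc.G, dtype=float)
    if not include_d0:
        keep = d > 0
        d, G = d[keep], G[keep]
    if d.size < 10:
        raise ValueError("need at least 10 radial bins to fit")

    def run(two: bool) -> lmfit.minimizer.MinimizerResult:
        params = lmfit.Parameters()
        g0 = max(G.max(), 1e-12)
        # crude initial length: first bin where G falls below g0/e
        below = np.nonzero(G < g0 / np.e)[0]
        lam0 = d[below[0]] if below.size else max(d.max() / 4, 1.0)
        lam0 = max(lam0, 0.5)
        params.add("a1", value=0.7 * g0 if two else g0, min=0)
        params.add("lambda1", value=lam0, min=1e-3)
        params.add("n1", value=2.0, min=0.05, max=10)
        if two:
            params.add("a2", value=0.3 * g0, min=0)
            params.add("lambda2", value=min(5 * lam0, d.max()), min=1e-3)
            params.add("n2", value=1.0, min=0.05, max=10)
        else:
            params.add("a2", value=0.0, vary=False)
            params.add("lambda2", value=1.0, vary=False)
            params.add("n2", value=1.0, vary=False)

        def resid(p):
            v = p.valuesdict()
            return _ics_model(d, v["a1"], v["lambda1"], v["n1"], v["a2"], v["lambda2"], v["n2"]) - G

        return lmfit.minimize(resid, params)

    if components == "auto":
        res1 = run(False)
        res2 = run(True)
        use2 = res2.chisqr < (1.0 - auto_improvement) * res1.chisqr
        res = res2 if use2 else res1
        ncomp = 2 if use2 else 1
    elif int(components) in (1, 2):
        ncomp = int(components)
        res = run(ncomp == 2)
    else:
        raise ValueError("components must be 1, 2, or 'auto'")
    if not res.success:
        raise RuntimeError(f"ICS fit did not converge: {res.message}")

    v = res.params.valuesdict()
    # order so component 1 is the short correlation length
    if ncomp == 2 and v["lambda2"] < v["lambda1"]:
        v = dict(
            a1=v["a2"], lambda1=v["lambda2"], n1=v["n2"],
            a2=v["a1"], lambda2=v["lambda1"], n2=v["n1"],
        )
    stderr = {k: (res.params[k].stderr if k in res.params else None) for k in
              ("a1", "lambda1", "n1", "a2", "lambda2", "n2")}
    return ICSFit(
        a1=v["a1"], lambda1=v["lambda1"], n1=v["n1"],
        a2=v["a2"], lambda2=v["lambda2"], n2=v["n2"],
        pixel_size=pixel_size, stderr=stderr, rss=float(res.chisqr),
        n_components=ncomp,
    )


def ics_pipeline(
    image: np.ndarray,
    segmentation_image: np.ndarray | None = None,
    *,
    components: int | str = "auto",
    pixel_size: float = 15.0,
    max_shift: int | None = None,
) -> tuple[ICSFit, RadialCorrelation]:
    """Segment, rectangularize, correlate and fit in one call.

    ``segmentation_image`` (e.g. the DAPI channel) drives the masks; the
    correlation itself is computed on ``image``.
    """
    seg = segment_for_ics(segmentation_image if segmentation_image is not None else image)
    rect = rectangularize(np.asarray(image, float), seg.chromocenter_mask)
    _, _, rc = spatial_autocorrelation(rect, max_shift=max_shift)
    fit = fit_ics(rc, components, pixel_size=pixel_size)
    return fit, rc
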