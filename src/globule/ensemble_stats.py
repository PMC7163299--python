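"""Ensemble fits and rule-based image quantification.

Covers the remaining bespoke analyses around the core biophysical models:

* Hill fits of turbidity titrations (in-vitro droplet formation), optionally
  with a plateau shared between proteins;
* two-exponential FRAP fits at a lacO tethering array with the second time
  constant fixed to a freely diffusing control, separating stably bound,
  transiently bound and fast-diffusing pools without modelling diffusion;
* co-recruitment ratios (molecules recruited to an array per directly
  tethered molecule, using GFP as the unity control);
* the dose-response segmentation/grouping pipeline: Otsu nuclei, chromocenter
  and major-satellite thresholds, and low/medium/high marker groups cut at
  the 40th/60th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit
from scipy import optimize
from skimage import filters, measure

__all__ = [
    "HillParams",
    "LacoFrapFit",
    "CellMeasurement",
    "hill",
    "fit_hill_turbidity",
    "fit_laco_frap",
    "corecruitment_ratio",
    "segment_and_group",
    "group_by_percentiles",
]


# -- turbidity ---------------------------------------------------------------

@dataclass(frozen=True)
class HillParams:
    """t(c) = a / (1 + (c_sat/c)**n): plateau a, half-saturation c_sat, slope n."""

    a: float
    c_sat: float
    n: float
    stderr: dict | None = None
    c_sat_in_range: bool = True

    def __call__(self, c: np.ndarray) -> np.ndarray:
        return hill(c, self.a, self.c_sat, self.n)


def hill(c: np.ndarray, a: float, c_sat: float, n: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return a / (1.0 + (c_sat / c) ** n)


def fit_hill_turbidity(
    datasets: list[tuple[np.ndarray, np.ndarray, float | np.ndarray]],
    share_plateau: bool = False,
) -> list[HillParams]:
    """Fit Hill curves to one or more blank-subtracted turbidity titrations.

    Each dataset is ``(concentrations_uM, turbidity, blank)``; the blank
    (buffer turbidity, scalar or per-point) is subtracted before fitting.
    With ``share_plateau`` the plateau ``a`` is a single joint parameter
    across datasets, as when comparing tagged and untagged protein measured
    in the same buffer.
    """
    prepped = []
    for conc, turb, blank in datasets:
        c = np.asarray(conc, dtype=float)
        y = np.asarray(turb, dtype=float) - np.asarray(blank, dtype=float)
        if np.unique(c).size < 5:
            raise ValueError("need >= 5 distinct concentrations per dataset")
        if np.all(np.abs(y) < 1e-12) or y.max() <= 0:
            raise ValueError("no signal: turbidity does not exceed the blank")
        prepped.append((c, y))

    params = lmfit.Parameters()
    for i, (c, y) in enumerate(prepped):
        tag = f"_{i}"
        if i == 0 or not share_plateau:
            params.add(f"a{tag}", value=float(y.max()), min=1e-12)
        else:
            params.add(f"a{tag}", expr="a_0")
        half = y.max() / 2
        above = np.nonzero(y > half)[0]
        csat0 = c[above[0]] if above.size else np.median(c)
        params.add(f"csat{tag}", value=float(csat0), min=c.min() / 100, max=c.max() * 100)
        params.add(f"n{tag}", value=2.0, min=0.1, max=20.0)

    def resid(p):
        v = p.valuesdict()
        out = []
        for i, (c, y) in enumerate(prepped):
            out.append(hill(c, v[f"a_{i}"], v[f"csat_{i}"], v[f"n_{i}"]) - y)
        return np.concatenate(out)

    res = lmfit.minimize(resid, params)
    if not res.success:
        raise RuntimeError(f"Hill fit did not converge: {res.message}")
    out = []
    for i, (c, _y) in enumerate(prepped):
        v = res.params
        csat = v[f"csat_{i}"].value
        out.append(
            HillParams(
                a=v[f"a_{i}"].value,
                c_sat=csat,
                n=v[f"n_{i}"].value,
                stderr={k.split("_")[0]: v[f"{k.split('_')[0]}_{i}"].stderr
                        for k in (f"a_{i}", f"csat_{i}", f"n_{i}")},
                c_sat_in_range=bool(c.min() <= csat <= c.max()),
            )
        )
    return out


# -- lacO FRAP ---------------------------------------------------------------

@dataclass(frozen=True)
class LacoFrapFit:
    """Fraction split from the fixed-tau2 two-exponential FRAP fit.

    ``f_transient`` recovers with the free time constant ``tau1`` (exchange at
    the array), ``f_fast`` with the fixed control time constant ``tau2``
    (freely diffusing pool), and ``f_stable = 1 - f_transient - f_fast`` does
    not recover on the observation window.
    """

    f_stable: float
    f_transient: float
    f_fast: float
    tau1: float
    tau2: float
    stderr: dict

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f_transient * (1 - np.exp(-t / self.tau1)) + self.f_fast * (
            1 - np.exp(-t / self.tau2)
        )


def fit_laco_frap(
    times: np.ndarray, signal: np.ndarray, tau2_fixed: float
) -> LacoFrapFit:
    """Two-exponential fit of a double-normalized FRAP curve, tau2 fixed.

    ``times`` start at the bleach (signal 0 there); ``tau2_fixed`` comes from
    an independent freely diffusing control (e.g. GFP) and pins the fast
    component so the slow, binding-dominated component is identifiable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if tau2_fixed <= 0:
        raise ValueError("tau2_fixed must be > 0")

    def model(theta):
        a1, tau1, a2 = theta
        return a1 * (1 - np.exp(-t / tau1)) + a2 * (1 - np.exp(-t / tau2_fixed))

    x0 = [0.4, max(t[-1] / 10, 2 * tau2_fixed), 0.1]
    sol = optimize.least_squares(
        lambda th: model(th) - y,
        x0,
        bounds=([0.0, tau2_fixed, 0.0], [1.0, np.inf, 1.0]),
    )
    if not sol.success:
        raise RuntimeError(f"lacO FRAP fit did not converge: {sol.message}")
    a1, tau1, a2 = sol.x
    errs = _lsq_stderr(sol, y.size)
    return LacoFrapFit(
        f_stable=float(1.0 - a1 - a2),
        f_transient=float(a1),
        f_fast=float(a2),
        tau1=float(tau1),
        tau2=float(tau2_fixed),
        stderr=dict(zip(("f_transient", "tau1", "f_fast"), errs)),
    )


def _lsq_stderr(sol, n_obs: int) -> np.ndarray:
    _, s, VT = np.linalg.svd(sol.jac, full_matrices=False)
    s = np.where(s > s.max() * 1e-12, s, np.inf)
    cov = (VT.T / s**2) @ VT
    sigma2 = 2 * sol.cost / max(n_obs - sol.x.size, 1)
    return np.sqrt(np.diag(cov) * sigma2)


# -- co-recruitment ----------------------------------------------------------

def corecruitment_ratio(
    candidate_array_intensity: float,
    tetR_array_intensity: float,
    control_ratio_gfp: float,
) -> float:
    """Indirectly bound molecules per directly tethered one.

    The candidate's array intensity is normalized to the TetR intensity at the
    array, then to the same ratio measured with GFP (which is only directly
    tethered); the excess over 1 counts molecules recruited on top of the
    tethered layer.  All intensities must be background-subtracted.
    """
    if control_ratio_gfp <= 0:
        raise ValueError("GFP control ratio must be > 0")
    if candidate_array_intensity <= 0 or tetR_array_intensity <= 0:
        raise ValueError("intensities must be background-subtracted and > 0")
    r = (candidate_array_intensity / tetR_array_intensity) / control_ratio_gfp
    return r - 1.0


# -- dose-response segmentation & grouping -----------------------------------

@dataclass
class CellMeasurement:
    cell_id: int
    nucleus_area: float
    compartment_area: float
    means: dict  # channel -> mean intensity, separately for nucleus/compartment
    group: str = "none"


def _segment_nuclei(channel: np.ndarray) -> np.ndarray:
    thr = filters.threshold_otsu(np.asarray(channel, dtype=float), nbins=256)
    lab = measure.label(channel > thr)
    if lab.max() == 0:
        raise ValueError("no nuclei found")
    return lab


def segment_and_group(
    channels: dict[str, np.ndarray],
    mode: str,
    *,
    marker_channel: str | None = None,
    group_percentiles: tuple[float, float] = (40.0, 60.0),
    min_nucleus_area: int = 50,
) -> pd.DataFrame:
    """Per-cell dose-response table.

    ``mode='hp1_overexpression'``: nuclei are segmented in the HP1 channel
    (Otsu) and chromocenters in the DAPI channel at 1.3x the median DAPI
    intensity of each nucleus.  ``mode='dcas9'``: nuclei are segmented in the
    DAPI channel and major-satellite repeats in the dCas9 channel at
    ``median + 0.1*(max - median)`` per nucleus.  Cells are then grouped
    low/medium/high by the marker intensity percentiles (default 40th/60th).

    Returns a DataFrame with one row per nucleus: areas (pixels), mean
    intensity of every channel in the nucleus and in the subcompartment, and
    the group label.  Nuclei whose subcompartment mask is empty keep area 0
    and NaN compartment intensities.
    """
    if mode == "hp1_overexpression":
        seg_channel, sub_channel = "hp1", "dapi"
        marker = marker_channel or "zsgreen"
    elif mode == "dcas9":
        seg_channel, sub_channel = "dapi", "dcas9"
        marker = marker_channel or "dcas9"
    else:
        raise ValueError("mode must be 'hp1_overexpression' or 'dcas9'")
    for ch in (seg_channel, sub_channel, marker):
        if ch not in channels:
            raise ValueError(f"missing channel {ch!r}")
    shapes = {ch: np.asarray(im).shape for ch, im in channels.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channels are not registered: shapes {shapes}")

    labels = _segment_nuclei(np.asarray(channels[seg_channel], dtype=float))
    rows = []
    for region in measure.regionprops(labels):
        if region.area < min_nucleus_area:
            continue
        nuc = labels == region.label
        sub_img = np.asarray(channels[sub_channel], dtype=float)
        vals = sub_img[nuc]
        if mode == "hp1_overexpression":
            thr = 1.3 * np.median(vals)
        else:
            med = np.median(vals)
            thr = med + 0.1 * (vals.max() - med)
        comp = nuc & (sub_img > thr)
        row = {
            "cell_id": region.label,
            "nucleus_area": int(nuc.sum()),
            "compartment_area": int(comp.sum()),
            "compartment_threshold": float(thr),
        }
        for ch, im in channels.items():
            im = np.asarray(im, dtype=float)
            row[f"{ch}_nucleus_mean"] = float(im[nuc].mean())
            row[f"{ch}_compartment_mean"] = float(im[comp].mean()) if comp.any() else np.nan
        row["marker_level"] = row[f"{marker}_nucleus_mean"]
        rows.append(row)
    if not rows:
        raise ValueError("no nuclei passed the size filter")
    df = pd.DataFrame(rows)
    df["group"] = group_by_percentiles(df["marker_level"].to_numpy(), group_percentiles)
    return df


def group_by_percentiles(
    values: np.ndarray, percentiles: tuple[float, float] = (40.0, 60.0)
) -> np.ndarray:
    """Label values low/medium/high at the given percentile cutoffs.

    Percentiles use linear interpolation between order statistics; values at
    or below the lower cutoff are 'low', above the upper cutoff 'high'.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, percentiles)
    out = np.where(v <= lo, "low", np.where(v <= hi, "medium", "high"))
    return out
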