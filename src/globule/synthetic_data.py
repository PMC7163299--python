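"""Synthetic inputs with known ground truth for every analysis in the package.

No experimental datasets accompany the analyses this package implements, so
each pipeline is exercised on forward-modelled data whose generating
parameters are recorded in a machine-readable truth dictionary (and truth
JSON when written to disk).  Recovery tests read ground truth only from that
record.

Reproducibility: a single integer seed expands into independent child
generators via ``numpy.random.SeedSequence(seed).spawn`` — identical spec and
seed give bit-identical output.  Image noise defaults to Poisson (photon
counting); curve noise defaults to Gaussian proportional to the local signal
amplitude.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .boundary_model import (
    BoundaryGeometry,
    HalfBleachModel,
    RecoveryPair,
    halfbleach_curves,
    halfbleach_modes,
    halfbleach_profile,
)
from .ensemble_stats import hill
from .optodroplet import CVSeries, two_step_decay
from .polfcs import CorrelationCurve, PolFCSParams, model_correlation

__all__ = [
    "child_rngs",
    "gen_halfbleach_pair",
    "gen_halfbleach_stack",
    "gen_cluster_image",
    "gen_opto_series",
    "gen_polfcs_curves",
    "gen_diffusion_trace",
    "gen_turbidity_table",
    "gen_nuclei_panel",
    "write_truth",
]


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic derivation of ``n`` independent generators from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


# -- half-bleach FRAP --------------------------------------------------------

def gen_halfbleach_pair(
    model: HalfBleachModel,
    n_frames: int,
    dt: float,
    *,
    n_pre: int = 5,
    noise: float = 0.0,
    background: float = 100.0,
    nucleus_level: float = 1100.0,
    N_B: int = 400,
    N_NB: int = 400,
    rng: np.random.Generator | int | None = None,
) -> tuple[RecoveryPair, dict]:
    """Raw ROI-mean time series for a half-bleached compartment.

    Frame intensities follow the normalization chain in reverse: the bleached
    and non-bleached fluorescent fractions are ``1 - f - (1-f)*c_B`` and
    ``1 - (1-f)*c_NB`` (immobile fraction f), mapped onto raw means between
    ``background`` and ``nucleus_level``.  Gaussian noise of relative size
    ``noise`` is added to the ROI means.
    """
    rng = _rng(rng)
    t_post = np.arange(n_frames - n_pre) * dt
    series = halfbleach_modes(model.p, max(dt / model.tauD, 1e-3))
    cB, cNB = halfbleach_curves(model, t_post / model.tauD, series=series)
    f = model.f_immobile
    F_B = np.concatenate([np.ones(n_pre), 1.0 - f - (1.0 - f) * cB])
    F_NB = np.concatenate([np.ones(n_pre), 1.0 - (1.0 - f) * cNB])

    span = nucleus_level - background
    I_B = background + F_B * span
    I_NB = background + F_NB * span
    if noise > 0:
        I_B = I_B + rng.normal(0, noise * span, I_B.shape)
        I_NB = I_NB + rng.normal(0, noise * span, I_NB.shape)
    times = np.arange(n_frames) * dt
    pair = RecoveryPair(
        times=times,
        signal_B=I_B,
        signal_NB=I_NB,
        N_B=N_B,
        N_NB=N_NB,
        t_bleach=n_pre,
        raw_means={
            "I_B": I_B,
            "I_NB": I_NB,
            "I_Nucleus": np.full(n_frames, nucleus_level),
            "I_BG": np.full(n_frames, background),
        },
        state="raw",
    )
    truth = {
        "kind": "halfbleach_pair",
        "p": model.p,
        "tauD_s": model.tauD,
        "f_immobile": model.f_immobile,
        "n_frames": n_frames,
        "dt_s": dt,
        "n_pre": n_pre,
        "noise": noise,
    }
    return pair, truth


def gen_halfbleach_stack(
    model: HalfBleachModel,
    *,
    shape: tuple[int, int] = (96, 96),
    center: tuple[float, float] | None = None,
    radius_px: float = 28.0,
    background: float = 20.0,
    nucleoplasm: float = 60.0,
    compartment: float = 200.0,
    n_frames: int = 40,
    n_pre: int = 3,
    dt: float = 0.5,
    photon_noise: bool = False,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, dict]:
    """Image stack of a half-bleached circular compartment.

    The left half of the disk (x < center) is bleached at frame ``n_pre``;
    inside the disk the fluorescent-particle density follows the series
    profile, outside it a constant nucleoplasm on a constant camera
    background.  With ``photon_noise`` pixel values are Poisson draws.
    """
    rng = _rng(rng)
    ny, nx = shape
    cy, cx = center if center is not None else ((ny - 1) / 2, (nx - 1) / 2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx) / radius_px
    # angle measured so the left half (x < cx) is phi in (pi, 2*pi): the
    # series' bleached half
    phi = np.mod(np.arctan2(yy - cy, xx - cx) + 0.5 * np.pi, 2 * np.pi)
    inside = r <= 1.0
    nucleus = r <= 1.55  # nucleoplasm ring; beyond it pure camera background

    series = halfbleach_modes(model.p, max(dt / model.tauD, 1e-3))
    frames = np.empty((n_frames, ny, nx), dtype=float)
    r_grid = np.linspace(0, 1, 121)
    phi_grid = np.linspace(0, 2 * np.pi, 181)
    for i in range(n_frames):
        img = np.full(shape, background, dtype=float)
        img[nucleus & ~inside] = nucleoplasm
        if i < n_pre:
            img[inside] = compartment
        else:
            t_over = (i - n_pre) * dt / model.tauD
            prof = halfbleach_profile(model, t_over, phi_grid, r_grid, series=series)
            # bilinear lookup of bleached-particle concentration
            fi = np.interp(phi[inside], phi_grid, np.arange(phi_grid.size) * 1.0)
            ri = np.interp(r[inside], r_grid, np.arange(r_grid.size) * 1.0)
            c = prof[
                np.clip(np.rint(fi).astype(int), 0, phi_grid.size - 1),
                np.clip(np.rint(ri).astype(int), 0, r_grid.size - 1),
            ]
            fluor = 1.0 - np.clip(c, 0.0, 1.0)
            img[inside] = background + (compartment - background) * fluor
        frames[i] = img
    if photon_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    truth = {
        "kind": "halfbleach_stack",
        "p": model.p,
        "tauD_s": model.tauD,
        "radius_px": radius_px,
        "dt_s": dt,
        "n_pre": n_pre,
        "center": [cy, cx],
        "levels": {"background": background, "nucleoplasm": nucleoplasm,
                   "compartment": compartment},
    }
    return frames, truth


# -- STED-like cluster images ------------------------------------------------

def gen_cluster_image(
    *,
    shape: tuple[int, int] = (256, 256),
    nucleus_axes: tuple[float, float] = (110.0, 95.0),
    n_chromocenters: int = 5,
    chromocenter_radius_px: float = 16.0,
    cluster_diameter_nm: float = 120.0,
    pixel_nm: float = 15.0,
    cluster_area_fraction: float = 0.10,
    enrichment: float = 3.0,
    chromocenter_contrast: float = 2.0,
    psf_sigma_px: float = 1.1,
    base_level: float = 150.0,
    background: float = 10.0,
    noise: str | None = "poisson",
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, dict]:
    """STED-like nucleus with clustered chromocenter substructure.

    Chromocenters are disks covering ~10% of the nuclear area at
    ``chromocenter_contrast`` times the nuclear base level (so the 90%
    intensity quantile segments them whole).  The clusters inside them are
    sharp disks of radius ``cluster_diameter_nm/2`` convolved with a Gaussian
    PSF (``psf_sigma_px``; the default ~40 nm FWHM at 15 nm/pixel mimics a
    STED focus): the ICS correlation length of such an object equals its
    radius, so the reported full diameter ``2*lambda1*pixel`` matches
    ``cluster_diameter_nm``.  ``enrichment`` is the cluster level over the
    chromocenter base; cluster centers are placed uniformly inside the disks
    at a density set by ``cluster_area_fraction``.  ``base_level`` is in
    photons (Poisson noise), like a well-exposed STED immunostaining.
    """
    rng = _rng(rng)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    ay, ax_ = nucleus_axes
    nucleus = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax_) ** 2 <= 1.0
    img = np.full(shape, background, dtype=float)
    img[nucleus] = base_level

    centers = []
    placed = 0
    tries = 0
    while placed < n_chromocenters and tries < 500:
        tries += 1
        y0 = rng.uniform(chromocenter_radius_px, ny - chromocenter_radius_px)
        x0 = rng.uniform(chromocenter_radius_px, nx - chromocenter_radius_px)
        if ((y0 - cy) / (ay - chromocenter_radius_px)) ** 2 + (
            (x0 - cx) / (ax_ - chromocenter_radius_px)
        ) ** 2 > 1.0:
            continue
        if any(np.hypot(y0 - a, x0 - b) < 2.5 * chromocenter_radius_px for a, b in centers):
            continue
        centers.append((y0, x0))
        placed += 1

    cc_base = chromocenter_contrast * base_level
    a_cluster = cluster_diameter_nm / (2.0 * pixel_nm)  # cluster radius, px
    n_clusters_per_cc = int(
        cluster_area_fraction * chromocenter_radius_px**2 / a_cluster**2
    )
    amp = (enrichment - 1.0) * cc_base
    clusters = np.zeros(shape)
    for y0, x0 in centers:
        disk = np.hypot(yy - y0, xx - x0) <= chromocenter_radius_px
        img[disk & nucleus] = cc_base
        for _ in range(max(n_clusters_per_cc, 1)):
            rr = chromocenter_radius_px * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            yc, xc = y0 + rr * np.sin(th), x0 + rr * np.cos(th)
            clusters[np.hypot(yy - yc, xx - xc) <= a_cluster] = amp
    img += ndimage.gaussian_filter(clusters, psf_sigma_px) if psf_sigma_px else clusters
    if noise == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    elif noise:
        raise ValueError(f"unknown noise model {noise!r}")
    truth = {
        "kind": "cluster_image",
        "cluster_diameter_nm": cluster_diameter_nm,
        "pixel_nm": pixel_nm,
        "cluster_radius_px": cluster_diameter_nm / (2.0 * pixel_nm),
        "enrichment": enrichment,
        "n_chromocenters": len(centers),
        "chromocenter_centers": centers,
        "chromocenter_radius_px": chromocenter_radius_px,
    }
    return img, truth


# -- optodroplet decay -------------------------------------------------------

def gen_opto_series(
    *,
    k: float,
    plateau: float = 0.0,
    baseline_cv: float = 0.15,
    droplet_cv_amplitude: float = 0.35,
    n_frames: int = 60,
    dt: float = 10.0,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[CVSeries, dict]:
    """Raw CV decay series after light-off, built from the two-step law.

    ``cv(t) = baseline + amplitude * (A(t)/A0)`` with
    ``A(t) = A0(1+kt)exp(-kt) + plateau*A0``; relative Gaussian noise is added
    per frame.  ``times[0]`` is the first frame after the light is switched
    off; ``cv_pre`` records the pre-illumination CV (= baseline).
    """
    rng = _rng(rng)
    t = np.arange(n_frames) * dt
    A = two_step_decay(t, 1.0, k, plateau)
    cv = baseline_cv + droplet_cv_amplitude * A
    if noise > 0:
        cv = cv + rng.normal(0, noise * droplet_cv_amplitude, cv.shape)
    series = CVSeries(times=t, cv=cv, cv_pre=baseline_cv, normalized=False)
    truth = {
        "kind": "opto_series",
        "k_per_s": k,
        "tau_s": 1.68 / k,
        "plateau": plateau,
        "baseline_cv": baseline_cv,
        "droplet_cv_amplitude": droplet_cv_amplitude,
        "dt_s": dt,
        "noise": noise,
    }
    return series, truth


# -- Pol-FCS -----------------------------------------------------------------

def gen_polfcs_curves(
    params: PolFCSParams,
    *,
    lag_min: float = 10e-9,
    lag_max: float = 1.0,
    points_per_decade: int = 25,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[CorrelationCurve, CorrelationCurve, dict]:
    """Model parallel/crossed curves on a quasi-log grid with proportional noise."""
    rng = _rng(rng)
    n = int(np.ceil(np.log10(lag_max / lag_min) * points_per_decade)) + 1
    lags = np.geomspace(lag_min, lag_max, n)
    out = []
    for mode in ("parallel", "crossed"):
        g = model_correlation(params, lags, mode)
        sd = noise * np.abs(g) + 1e-4 * noise * g.max()
        gn = g + rng.normal(0, 1, g.shape) * sd if noise > 0 else g.copy()
        out.append(CorrelationCurve(lags=lags.copy(), G=gn, sd=sd, mode=mode))
    truth = {
        "kind": "polfcs_curves",
        "tauR_ns": params.tauR * 1e9,
        "tauT_us": params.tauT * 1e6,
        "fR": params.fR,
        "fT": params.fT,
        "N": params.N,
        "f1": params.f1,
        "tauD1_ms": params.tauD1 * 1e3,
        "tauD2_ms": params.tauD2 * 1e3,
        "alpha1": params.alpha1,
        "alpha2": params.alpha2,
        "kappa": params.kappa,
        "noise": noise,
    }
    return out[0], out[1], truth


def gen_diffusion_trace(
    *,
    D: float = 1.0,  # um^2/s
    waist_um: float = 0.25,
    n_particles: int = 64,
    box_um: float = 3.0,
    brightness_hz: float = 2e4,
    duration_s: float = 20.0,
    bin_width: float = 1e-4,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, dict]:
    """Photon-count trace from 2D Brownian particles in a Gaussian focus.

    Used only to validate the multi-tau correlator: the correlation amplitude
    must approach 1/N_eff with ``N_eff = C * pi * waist**2`` the mean number
    of particles in the effective focal area.
    """
    rng = _rng(rng)
    n_bins = int(round(duration_s / bin_width))
    pos = rng.uniform(-box_um / 2, box_um / 2, size=(n_particles, 2))
    step = np.sqrt(2 * D * bin_width)
    counts = np.empty(n_bins)
    half = box_um / 2
    for i in range(n_bins):
        pos += rng.normal(0, step, pos.shape)
        pos = (pos + half) % box_um - half  # periodic wrap
        w = np.exp(-2 * (pos**2).sum(axis=1) / waist_um**2)
        counts[i] = rng.poisson(brightness_hz * bin_width * w.sum())
    conc = n_particles / box_um**2
    truth = {
        "kind": "diffusion_trace",
        "N_eff": conc * np.pi * waist_um**2,
        "tauD_s": waist_um**2 / (4 * D),
        "bin_width_s": bin_width,
    }
    return counts, truth


# -- turbidity tables --------------------------------------------------------

def gen_turbidity_table(
    hill_params: dict[str, tuple[float, float, float]],
    *,
    concentrations: np.ndarray | None = None,
    replicates: int = 3,
    cv_noise: float = 0.05,
    blank: float = 0.05,
    rng: np.random.Generator | int | None = None,
):
    """Replicate turbidity titrations from Hill ground truth.

    ``hill_params`` maps protein name -> (a, c_sat_uM, n).  Returns a pandas
    DataFrame with columns protein, conc_uM, replicate, od600 (blank added
    back so analyses must subtract it) and the truth dict.
    """
    import pandas as pd

    rng = _rng(rng)
    conc = (
        np.asarray(concentrations, dtype=float)
        if concentrations is not None
        else np.geomspace(2.0, 200.0, 8)
    )
    rows = []
    for protein, (a, c_sat, n) in hill_params.items():
        clean = hill(conc, a, c_sat, n)
        for rep in range(replicates):
            noisy = clean * (1 + rng.normal(0, cv_noise, conc.shape))
            for c, y in zip(conc, noisy):
                rows.append(
                    {"protein": protein, "conc_uM": c, "replicate": rep,
                     "od600": y + blank}
                )
    truth = {
        "kind": "turbidity_table",
        "hill": {k: {"a": v[0], "c_sat_uM": v[1], "n": v[2]}
                 for k, v in hill_params.items()},
        "blank": blank,
        "replicates": replicates,
        "cv_noise": cv_noise,
    }
    return pd.DataFrame(rows), truth


# -- nuclei panels for dose-response ----------------------------------------

def gen_nuclei_panel(
    population: str,
    n_cells: int = 30,
    *,
    shape: tuple[int, int] = (112, 112),
    base_area_px: float = 120.0,
    marker_range: tuple[float, float] = (50.0, 250.0),
    rng: np.random.Generator | int | None = None,
):
    """Single-nucleus image set contrasting the two buffering regimes.

    ``population='size_buffering'`` (globule-like): chromocenter area constant,
    internal marker intensity proportional to expression.
    ``population='concentration_buffering'`` (droplet-like): internal
    concentration constant, area proportional to expression.  Returns a list
    of channel dicts (dapi, hp1, zsgreen) plus the truth dict.
    """
    rng = _rng(rng)
    if population not in ("size_buffering", "concentration_buffering"):
        raise ValueError("unknown population kind")
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    # the nucleus occupies a minority of the field, as in a real confocal
    # frame; a bright-subcompartment class must not outweigh the background
    # class when nuclei are segmented by Otsu's threshold
    nucleus = np.hypot(yy - cy, xx - cx) <= min(ny, nx) * 0.27
    cells = []
    markers = np.geomspace(*marker_range, n_cells)
    rng.shuffle(markers)
    for marker in markers:
        rel = marker / marker_range[0]
        if population == "size_buffering":
            # globule-like: area fixed, internal concentration tracks expression
            area = base_area_px
            nucleoplasm = 30.0 * rel
            cc_level = 2.5 * nucleoplasm
        else:
            # droplet-like: internal concentration fixed, area grows
            area = base_area_px * rel
            nucleoplasm = 40.0
            cc_level = 80.0
        r_cc = np.sqrt(area / np.pi)
        oy = rng.uniform(-5, 5)
        ox = rng.uniform(-5, 5)
        cc = np.hypot(yy - cy - oy, xx - cx - ox) <= r_cc
        dapi = np.where(nucleus, 100.0, 5.0)
        dapi[cc & nucleus] = 200.0
        hp1 = np.where(nucleus, nucleoplasm, 2.0)
        hp1[cc & nucleus] = cc_level
        zsgreen = np.where(nucleus, marker, 1.0)
        cells.append({"dapi": dapi, "hp1": hp1, "zsgreen": zsgreen,
                      "marker": float(marker),
                      "cc_area": int((cc & nucleus).sum())})
    truth = {
        "kind": "nuclei_panel",
        "population": population,
        "n_cells": n_cells,
        "base_area_px": base_area_px,
        "marker_range": list(marker_range),
    }
    return cells, truth
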