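"""FRAP double-normalization and one-phase association recovery fitting.

The correction pipeline follows the four-step scheme used for granule FRAP:

1.  **PCV** (photobleach correction value): the mean pre-bleach intensity of
    an *unbleached* reference granule divided by that granule's intensity in
    each frame.  Because acquisition photobleaching multiplies every granule
    by the same per-frame factor, multiplying by PCV cancels it exactly.
2.  **CAI** (corrected average intensity): bleached-granule intensity times
    the PCV.
3.  **BCFI** (background-corrected fluorescence intensity): CAI minus the
    background (diffuse cytoplasm) ROI intensity of the same frame.
4.  **FCV** (final corrected value): BCFI divided by the mean pre-bleach
    BCFI, times 100 — a recovery profile in percent of pre-bleach signal.

The post-bleach FCV is then fit with a one-phase association
``Y(t) = Y0 + (P - Y0) (1 - exp(-K (t - t0)))`` yielding the plateau ``P``,
half-time ``t_half = ln2 / K`` and the bleach-depth-normalized mobile
fraction ``Fm = (P - Y0) / (100 - Y0)`` (equal to ``P/100`` for a complete
bleach).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import GeometryError, ImageStack, Roi
from .synth import FrapTraceRaw


class NormalizationError(ValueError):
    """Trace cannot be normalized (non-positive reference or baseline)."""


@dataclass
class FrapTraceNormalized:
    """Per-frame corrected FRAP trace (PCV, CAI, BCFI, FCV)."""

    pcv: np.ndarray
    cai: np.ndarray
    bcfi: np.ndarray
    fcv: np.ndarray
    times_s: np.ndarray
    n_pre: int


@dataclass
class FrapFit:
    """One-phase association fit of a normalized recovery curve.

    ``Fm`` is bleach-depth normalized: the fraction of the *bleached* signal
    that recovers.  ``Fm`` slightly above 1 (discrete/noisy overshoot) is
    tolerated up to 1.05 and flagged via ``overshoot``.
    """

    Y0: float
    P: float
    K: float
    t_half_s: float
    Fm: float
    rss: float
    converged: bool
    overshoot: bool = False


def extract_traces(
    stack: ImageStack,
    rois: dict[str, Roi],
    follow: bool = False,
    search_radius_px: float | None = None,
) -> FrapTraceRaw:
    """Per-frame spatial means of the bleached/unbleached/background ROIs.

    With ``follow=True`` the bleached and unbleached circle ROIs are
    re-centered each frame on the local intensity centroid within a search
    window, tracking granules that drift in x/y.  Frames where the bleached
    granule reads below the background mean are flagged in ``excluded``
    (granule dropped out of the focal plane).
    """
    for key in ("bleached", "unbleached", "background"):
        if key not in rois:
            raise GeometryError(f"missing ROI {key!r}")
    if stack.shape[2] != 1:
        raise GeometryError("FRAP extraction expects a single channel")
    h, w = stack.shape[3], stack.shape[4]
    n = stack.n_frames

    def _check(roi: Roi) -> None:
        if roi.kind == "circle":
            cy, cx = roi.center
            if not (0 <= cy < h and 0 <= cx < w):
                raise GeometryError(f"ROI {roi.label!r} outside image")

    means = {k: np.zeros(n) for k in ("bleached", "unbleached", "background")}
    centers = {k: rois[k].center if rois[k].kind == "circle" else None
               for k in ("bleached", "unbleached")}
    for k in ("bleached", "unbleached", "background"):
        _check(rois[k])
    bg_mask = rois["background"].mask((h, w))

    def _stencil(roi: Roi) -> np.ndarray:
        # fixed pixel-offset stencil; translating it with the (sub-pixel)
        # center keeps the moved ROI's shape and pixel count identical
        r = int(np.ceil(roi.radius))
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        keep = dy**2 + dx**2 <= roi.radius**2
        return np.column_stack([dy[keep], dx[keep]]).astype(float)

    stencils = {k: _stencil(rois[k]) if rois[k].kind == "circle" else None
                for k in ("bleached", "unbleached")}
    from scipy.ndimage import map_coordinates

    for t in range(n):
        img = stack.max_z(t=t)
        for k in ("bleached", "unbleached"):
            roi = rois[k]
            if roi.kind == "circle":
                if follow:
                    sr = search_radius_px or 2 * roi.radius
                    cy, cx = centers[k]
                    y0, y1 = int(max(0, cy - sr)), int(min(h, cy + sr + 1))
                    x0, x1 = int(max(0, cx - sr)), int(min(w, cx + sr + 1))
                    # centroid of the background-suppressed search window
                    win = np.clip(
                        img[y0:y1, x0:x1] - np.median(img[y0:y1, x0:x1]),
                        0, None)
                    tot = win.sum()
                    if tot > 0:
                        yy, xx = np.mgrid[y0:y1, x0:x1]
                        centers[k] = (float((yy * win).sum() / tot),
                                      float((xx * win).sum() / tot))
                coords = stencils[k] + np.asarray(centers[k])
                means[k][t] = map_coordinates(
                    img, [coords[:, 0], coords[:, 1]], order=1, mode="nearest"
                ).mean()
            else:
                means[k][t] = img[roi.mask((h, w))].mean()
        means["background"][t] = img[bg_mask].mean()
    excluded = means["bleached"] < means["background"]
    return FrapTraceRaw(
        times_s=stack.times_s,
        bleached=means["bleached"],
        unbleached=means["unbleached"],
        background=means["background"],
        n_pre=2,
        excluded=excluded,
    )


def normalize_trace(raw: FrapTraceRaw) -> FrapTraceNormalized:
    """Apply the four-step PCV/CAI/BCFI/FCV correction to a raw trace."""
    if np.any(raw.unbleached <= 0):
        raise NormalizationError("unbleached reference trace must be > 0")
    pre = slice(0, raw.n_pre)
    pcv = raw.unbleached[pre].mean() / raw.unbleached
    cai = raw.bleached * pcv
    bcfi = cai - raw.background  # per-frame background subtraction
    bcfi_init = bcfi[pre].mean()
    if bcfi_init <= 0:
        raise NormalizationError(
            f"mean pre-bleach BCFI is {bcfi_init:.3g} <= 0; check ROI placement"
        )
    fcv = 100.0 * bcfi / bcfi_init
    return FrapTraceNormalized(pcv=pcv, cai=cai, bcfi=bcfi, fcv=fcv,
                               times_s=raw.times_s, n_pre=raw.n_pre)


def one_phase_association(t, Y0, P, K, t0=0.0):
    """``Y(t) = Y0 + (P - Y0) (1 - exp(-K (t - t0)))``."""
    return Y0 + (P - Y0) * (1.0 - np.exp(-K * (t - t0)))


def fit_recovery(
    norm: FrapTraceNormalized,
    times_s: np.ndarray | None = None,
    n_pre: int | None = None,
    exclude: np.ndarray | None = None,
) -> FrapFit:
    """Least-squares one-phase association fit over the post-bleach FCV.

    ``t0`` is the timestamp of the first post-bleach frame.  Initial guesses:
    ``Y0`` = first post-bleach value, ``P`` = mean of the last 10 frames,
    ``K`` from the time to the half-way point.  Bounds: ``K`` in (1e-6, 10]
    1/s, ``P`` in [Y0 guess, 200].  Non-convergence returns best-effort
    parameters with ``converged=False``; never raises.
    """
    times_s = np.asarray(times_s if times_s is not None else norm.times_s, float)
    n_pre = n_pre if n_pre is not None else norm.n_pre
    y = np.asarray(norm.fcv, float)[n_pre:]
    t = times_s[n_pre:]
    if exclude is not None:
        keep = ~np.asarray(exclude, bool)[n_pre:]
        y, t = y[keep], t[keep]
    if len(y) < 10:
        raise ValueError("need at least 10 post-bleach frames")
    t0 = t[0]

    y0_guess = float(y[0])
    p_guess = float(np.mean(y[-10:]))
    # time to mid-recovery -> K guess
    mid = y0_guess + 0.5 * (p_guess - y0_guess)
    above = np.nonzero(y >= mid)[0]
    if p_guess > y0_guess and len(above):
        t_mid = max(t[above[0]] - t0, times_s[1] - times_s[0])
        k_guess = np.log(2.0) / t_mid
    else:
        k_guess = 0.05
    k_guess = float(np.clip(k_guess, 1e-5, 10.0))

    lo = [-50.0, min(y0_guess, p_guess) - 1e-9, 1e-6]
    hi = [max(y0_guess, 100.0) + 50.0, 200.0, 10.0]
    p0 = [y0_guess, np.clip(p_guess, lo[1] + 1e-9, 200.0), k_guess]
    converged = True
    try:
        popt, _ = curve_fit(
            lambda tt, Y0, P, K: one_phase_association(tt, Y0, P, K, t0),
            t, y, p0=p0, bounds=(lo, hi), maxfev=20000,
        )
        Y0, P, K = map(float, popt)
    except Exception:
        converged = False
        Y0, P, K = map(float, p0)
    resid = y - one_phase_association(t, Y0, P, K, t0)
    rss = float(resid @ resid)
    t_half = float(np.log(2.0) / K)
    denom = 100.0 - Y0
    Fm = float((P - Y0) / denom) if abs(denom) > 1e-9 else float("nan")
    overshoot = Fm > 1.0
    if Fm > 1.05 or Fm < 0:
        converged = converged and False
    return FrapFit(Y0=Y0, P=P, K=K, t_half_s=t_half, Fm=Fm, rss=rss,
                   converged=converged, overshoot=overshoot)


def analyze_trace(raw: FrapTraceRaw) -> tuple[FrapTraceNormalized, FrapFit]:
    """Normalize then fit one raw trace."""
    norm = normalize_trace(raw)
    fit = fit_recovery(norm, exclude=raw.excluded)
    return norm, fit


def frap_batch(
    fits: dict[str, list[FrapFit]],
    curves: dict[str, list[FrapTraceNormalized]] | None = None,
) -> dict[str, dict]:
    """Group summaries: mean +/- SE of Fm and t_half per group, and the mean
    recovery curve with per-timepoint SE when curves are supplied.

    SE of a single-trace group is reported as 0 with ``se_defined=False``.
    """
    out: dict[str, dict] = {}
    for group, group_fits in fits.items():
        if not group_fits:
            raise ValueError(f"group {group!r} has no traces")
        fm = np.array([f.Fm for f in group_fits])
        th = np.array([f.t_half_s for f in group_fits])
        n = len(group_fits)
        se = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rec: dict = dict(
            n=n, Fm_mean=float(fm.mean()), Fm_se=se(fm),
            t_half_mean=float(th.mean()), t_half_se=se(th),
            se_defined=n > 1,
        )
        if curves and group in curves:
            fcvs = np.vstack([c.fcv for c in curves[group]])
            rec["curve_mean"] = fcvs.mean(axis=0)
            rec["curve_se"] = (fcvs.std(axis=0, ddof=1) / np.sqrt(n)
                               if n > 1 else np.zeros(fcvs.shape[1]))
            rec["times_s"] = curves[group][0].times_s
        out[group] = rec
    return out
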