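"""Seeded synthetic-microscopy generators with paired ground truth.

Each generator emulates one input modality of the quantification pipeline —
punctate-granule cell scenes, FRAP intensity traces, neurite transport
tracks, two-channel colocalization scenes, smFISH spot scenes, and
dual-luciferase plates — under the acquisition settings used for the real
data (0.084 um pixels, 1.0878 s FRAP frames with 2 pre-bleach frames and
200 post-bleach frames, 4.84 s transport frames).  Every scene is paired
with a :class:`GroundTruth` sufficient to score the corresponding analysis
with no extra information, and identical (parameters, seed) reproduce the
scene bit-exactly.

Noise model: Poisson shot noise on the signal plus additive Gaussian read
noise.  ``snr`` is defined as (peak amplitude above background) divided by
the background standard deviation sqrt(background + read_sd**2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageStack, Roi

# default camera model for rendered scenes (raw counts)
CYTO_LEVEL = 50.0
READ_SD = 3.0
PIXEL_SIZE_UM = 0.084  # 3x3 px = 0.252 um


class PackingError(RuntimeError):
    """Could not place the requested number of non-overlapping granules."""


@dataclass
class GroundTruth:
    """Generator provenance: name, full parameter set, per-object truth, seed."""

    generator: str
    params: dict
    truth: dict
    seed: int


def _bg_sigma(cyto_level: float = CYTO_LEVEL, read_sd: float = READ_SD) -> float:
    return float(np.sqrt(cyto_level + read_sd**2))


def _apply_noise(signal: np.ndarray, rng: np.random.Generator,
                 read_sd: float = READ_SD) -> np.ndarray:
    noisy = rng.poisson(np.clip(signal, 0, None)).astype(float)
    noisy += rng.normal(0.0, read_sd, size=signal.shape)
    return np.clip(noisy, 0, None)


def _add_gaussian(img: np.ndarray, y: float, x: float, amp: float,
                  sy: float, sx: float, theta: float = 0.0) -> None:
    """Add a (possibly rotated, anisotropic) Gaussian spot in place."""
    h, w = img.shape
    r = int(np.ceil(4 * max(sy, sx)))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - y, xx - x
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dy + st * dx
    v = -st * dy + ct * dx
    img[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((u / sy) ** 2 + (v / sx) ** 2))


# ---------------------------------------------------------------------------
# Granule scenes
# ---------------------------------------------------------------------------


def gen_granule_scene(
    n_granules: int = 12,
    cell_diameter_um: float = 10.0,
    granule_radius_um: tuple[float, float] = (0.25, 0.04),
    amorphic_fraction: float = 0.0,
    snr: float = 10.0,
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[ImageStack, Roi, GroundTruth]:
    """Single-plane cell with punctate granules over diffuse cytoplasm.

    Circular granules are isotropic Gaussian spots; amorphic granules are
    elongated blobs (axis ratio >= 3).  Granules are placed inside the cell
    mask without overlap by rejection sampling.  Returns the scene, the cell
    ROI (circle), and the ground truth listing every granule with its class.
    """
    if n_granules < 0:
        raise ValueError("n_granules must be >= 0")
    rng = np.random.default_rng(seed)
    mu_r, sd_r = granule_radius_um
    cell_r_px = cell_diameter_um / 2 / pixel_size_um
    margin = 20
    size = int(np.ceil(2 * cell_r_px)) + 2 * margin
    cy = cx = size / 2

    amp = snr * _bg_sigma()
    granules: list[dict] = []
    placed: list[tuple[float, float, float]] = []  # (y, x, exclusion radius px)
    n_amorphic = int(round(amorphic_fraction * n_granules))
    tries = 0
    while len(granules) < n_granules:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"placed {len(granules)}/{n_granules} granules in {max_tries} tries"
            )
        r_um = max(0.1, rng.normal(mu_r, sd_r))
        sigma_px = r_um / pixel_size_um
        amorphic = len(granules) < n_amorphic
        # amorphic blobs are elongated (axis ratio >= 3) at roughly equal area
        ratio = rng.uniform(3.0, 4.5) if amorphic else 1.0
        sy, sx = sigma_px * np.sqrt(ratio), sigma_px / np.sqrt(ratio)
        theta = rng.uniform(0, np.pi) if amorphic else 0.0
        extent = 2.2 * max(sy, sx)
        if extent + 4 > cell_r_px:  # blob cannot fit inside the cell
            continue
        rad = rng.uniform(0, cell_r_px - extent - 2)
        ang = rng.uniform(0, 2 * np.pi)
        y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        if any(np.hypot(y - py, x - px_) < extent + pr for py, px_, pr in placed):
            continue
        placed.append((y, x, extent))
        granules.append(
            dict(y=y, x=x, sigma_y_px=sy, sigma_x_px=sx, theta=theta,
                 radius_um=r_um, amplitude=amp,
                 morphology="amorphic" if amorphic else "circular")
        )

    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_r_px**2
    img[cell] = CYTO_LEVEL
    for g in granules:
        _add_gaussian(img, g["y"], g["x"], g["amplitude"],
                      g["sigma_y_px"], g["sigma_x_px"], g["theta"])
    img = _apply_noise(img, rng)

    stack = ImageStack(img[None, None, None], pixel_size_um=pixel_size_um)
    cell_roi = Roi("circle", center=(cy, cx), radius=cell_r_px, label="cell")
    params = dict(
        n_granules=n_granules, cell_diameter_um=cell_diameter_um,
        granule_radius_um=granule_radius_um, amorphic_fraction=amorphic_fraction,
        snr=snr, pixel_size_um=pixel_size_um,
    )
    gt = GroundTruth("granule_scene", params, dict(granules=granules), seed)
    return stack, cell_roi, gt


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


@dataclass
class FrapTraceRaw:
    """Per-frame mean ROI intensities for a FRAP movie.

    ``bleached`` is the photobleached granule, ``unbleached`` a reference
    granule used for acquisition-bleach correction, ``background`` diffuse
    cytoplasm.  The first ``n_pre`` frames precede the bleach event.
    """

    times_s: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray
    background: np.ndarray
    n_pre: int = 2
    excluded: np.ndarray | None = None  # frames flagged out-of-focus

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.unbleached = np.asarray(self.unbleached, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = len(self.times_s)
        if not (len(self.bleached) == len(self.unbleached) == len(self.background) == n):
            raise ValueError("trace arrays must have equal length")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-bleach frame")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


def frap_truth_signal(
    times_s: np.ndarray, n_pre: int, Fm: float, t_half_s: float, bleach_depth: float
) -> np.ndarray:
    """Noise-free recovery signal: 100 pre-bleach, one-phase association after.

    Post-bleach: ``S(t) = Y0 + (P - Y0) * (1 - exp(-K (t - t0)))`` with
    ``Y0 = 100 (1 - bleach_depth)``, ``P = Y0 + Fm (100 - Y0)`` and
    ``K = ln2 / t_half_s``; ``t0`` is the first post-bleach time.
    """
    times_s = np.asarray(times_s, dtype=float)
    S = np.full_like(times_s, 100.0)
    Y0 = 100.0 * (1.0 - bleach_depth)
    P = Y0 + Fm * (100.0 - Y0)
    K = np.log(2.0) / t_half_s
    t0 = times_s[n_pre]
    post = times_s[n_pre:]
    S[n_pre:] = Y0 + (P - Y0) * (1.0 - np.exp(-K * (post - t0)))
    return S


def gen_frap_trace(
    Fm: float,
    t_half_s: float,
    bleach_depth: float = 1.0,
    drift_per_frame: float = 0.0,
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    n_pre: int = 2,
    n_post: int = 200,
    dt_s: float = 1.0878,
    seed: int = 0,
) -> tuple[FrapTraceRaw, GroundTruth]:
    """Synthetic FRAP trace under the standard acquisition settings.

    The observed bleached and unbleached traces are the truth signals scaled
    by a shared per-frame acquisition-photobleaching factor
    ``d = 1 - drift_per_frame`` raised to the frame index, plus a constant
    background level and Gaussian noise.  The unbleached truth signal is
    constant 100; the background ROI reads ``background_level``.
    """
    if not (0 <= Fm <= 1 and t_half_s > 0 and 0 <= bleach_depth <= 1
            and 0 <= drift_per_frame < 1):
        raise ValueError("parameter out of range")
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    times = np.arange(n) * dt_s
    S = frap_truth_signal(times, n_pre, Fm, t_half_s, bleach_depth)
    d = (1.0 - drift_per_frame) ** np.arange(n)
    noise = lambda: rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    bleached = S * d + background_level + noise()
    unbleached = 100.0 * d + background_level + noise()
    background = np.full(n, background_level) + noise()
    raw = FrapTraceRaw(times, bleached, unbleached, background, n_pre=n_pre)
    Y0 = 100.0 * (1.0 - bleach_depth)
    P = Y0 + Fm * (100.0 - Y0)
    params = dict(Fm=Fm, t_half_s=t_half_s, bleach_depth=bleach_depth,
                  drift_per_frame=drift_per_frame, background_level=background_level,
                  noise_sd=noise_sd, n_pre=n_pre, n_post=n_post, dt_s=dt_s)
    truth = dict(Y0=Y0, P=P, K=np.log(2.0) / t_half_s, Fm=Fm, t_half_s=t_half_s,
                 signal=S)
    return raw, GroundTruth("frap_trace", params, truth, seed)


def render_frap_movie(
    raw_truth: GroundTruth,
    roi_radius_px: float = 5.0,
    granule_sigma_px: float = 3.0,
    drift_px_total: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, dict[str, Roi]]:
    """Render a FRAP trace as a small movie with bleached/unbleached granules.

    The bleached granule may drift linearly by ``drift_px_total`` pixels over
    the movie (exercises ROI following).  Returns the movie and the three
    labeled ROIs at their frame-0 positions.
    """
    p = raw_truth.params
    n = p["n_pre"] + p["n_post"]
    times = np.arange(n) * p["dt_s"]
    S = frap_truth_signal(times, p["n_pre"], p["Fm"], p["t_half_s"], p["bleach_depth"])
    d = (1.0 - p["drift_per_frame"]) ** np.arange(n)
    rng = np.random.default_rng(seed)
    size = 96
    pos_b0 = np.array([size * 0.35, size * 0.30])
    pos_u = np.array([size * 0.65, size * 0.70])
    frames = np.zeros((n, size, size))
    bg = max(p["background_level"], 0.0)
    for i in range(n):
        img = np.full((size, size), bg)
        shift = drift_px_total * i / max(n - 1, 1)
        _add_gaussian(img, pos_b0[0] + shift, pos_b0[1] + shift,
                      S[i] * d[i], granule_sigma_px, granule_sigma_px)
        _add_gaussian(img, pos_u[0], pos_u[1], 100.0 * d[i],
                      granule_sigma_px, granule_sigma_px)
        if p["noise_sd"] > 0:
            img += rng.normal(0, p["noise_sd"], img.shape)
        frames[i] = np.clip(img, 0, None)
    stack = ImageStack(frames[:, None, None], pixel_size_um=PIXEL_SIZE_UM,
                       frame_interval_s=p["dt_s"])
    rois = {
        "bleached": Roi("circle", center=tuple(pos_b0), radius=roi_radius_px,
                        label="bleached"),
        "unbleached": Roi("circle", center=tuple(pos_u), radius=roi_radius_px,
                          label="unbleached"),
        "background": Roi("circle", center=(size * 0.15, size * 0.85),
                          radius=roi_radius_px, label="background"),
    }
    return stack, rois


# ---------------------------------------------------------------------------
# Transport tracks
# ---------------------------------------------------------------------------


def gen_transport_tracks(
    n_tracks: int = 100,
    fractions: dict[str, float] | None = None,
    speed_um_s: tuple[float, float] = (0.5, 0.1),
    burst: dict | None = None,
    neurite_length_um: float = 50.0,
    n_frames: int = 100,
    dt_s: float = 4.84,
    pixel_size_um: float = 0.138,
    jitter_um: float = 0.15,
    seed: int = 0,
    render_movie: bool = False,
) -> tuple[list[dict], GroundTruth, ImageStack | None]:
    """Along-neurite granule tracks: stationary, anterograde, or retrograde.

    Positions are 1-D along-axis coordinates (um from the soma, increasing
    away).  Stationary tracks jitter with sub-threshold amplitude; motile
    tracks drift at a per-track speed drawn from ``speed_um_s`` (mean, sd),
    signed by direction, optionally with short rapid bursts.  If
    ``render_movie``, a single-z movie with each granule as a Gaussian spot
    on a straight horizontal neurite is also returned.
    """
    fractions = fractions or {"stationary": 0.6, "anterograde": 0.25,
                              "retrograde": 0.15}
    tot = sum(fractions.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(
        ["stationary", "anterograde", "retrograde"], size=n_tracks,
        p=[fractions.get("stationary", 0), fractions.get("anterograde", 0),
           fractions.get("retrograde", 0)],
    )
    burst = burst or {"probability": 0.0, "speed_multiplier": 4.0,
                      "duration_frames": 3}
    tracks: list[dict] = []
    for i, cls in enumerate(classes):
        start = rng.uniform(0.15, 0.85) * neurite_length_um
        if cls == "stationary":
            # zero-mean jitter steps well below the speed floor
            steps = rng.normal(0.0, jitter_um, n_frames - 1)
            speed = 0.0
        else:
            speed = max(0.25, rng.normal(*speed_um_s))
            sign = 1.0 if cls == "anterograde" else -1.0
            steps = np.full(n_frames - 1, sign * speed * dt_s)
            steps += rng.normal(0.0, jitter_um * 0.3, n_frames - 1)
            if rng.random() < burst["probability"]:
                j = rng.integers(0, n_frames - 1 - burst["duration_frames"])
                steps[j : j + burst["duration_frames"]] *= burst["speed_multiplier"]
        s = start + np.concatenate([[0.0], np.cumsum(steps)])
        # neurite_length_um bounds the rendered field, not the coordinates:
        # clipping would freeze fast tracks at the ends and corrupt the truth
        tracks.append(dict(track_id=i, s_um=s, cls=cls, speed_um_s=speed))

    movie = None
    if render_movie:
        w = int(np.ceil(neurite_length_um / pixel_size_um)) + 10
        h = 15
        amp = 10.0 * _bg_sigma(10.0, 1.0)
        frames = np.zeros((n_frames, h, w))
        for t in range(n_frames):
            img = np.full((h, w), 10.0)
            for tr in tracks:
                _add_gaussian(img, h / 2, 5 + tr["s_um"][t] / pixel_size_um,
                              amp, 1.5, 1.5)
            frames[t] = _apply_noise(img, rng, read_sd=1.0)
        movie = ImageStack(frames[:, None, None], pixel_size_um=pixel_size_um,
                           frame_interval_s=dt_s)
    params = dict(n_tracks=n_tracks, fractions=fractions, speed_um_s=speed_um_s,
                  burst=burst, neurite_length_um=neurite_length_um,
                  n_frames=n_frames, dt_s=dt_s, pixel_size_um=pixel_size_um,
                  jitter_um=jitter_um)
    gt = GroundTruth("transport_tracks", params,
                     dict(classes=list(classes),
                          speeds=[t["speed_um_s"] for t in tracks]), seed)
    return tracks, gt, movie


# ---------------------------------------------------------------------------
# Two-channel colocalization scenes
# ---------------------------------------------------------------------------


def gen_two_channel_scene(
    n_shared: int = 15,
    n_only_a: int = 5,
    n_only_b: int = 5,
    snr: float = 10.0,
    size: int = 128,
    sigma_px: float = 2.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Two-channel scene: shared granules at identical coordinates, plus
    channel-specific granules at independent positions.  ``noise=False``
    renders the noiseless signal (snr still sets spot amplitude)."""
    rng = np.random.default_rng(seed)
    amp = snr * _bg_sigma()

    def _positions(k: int) -> np.ndarray:
        return rng.uniform(4 * sigma_px, size - 4 * sigma_px, size=(k, 2))

    shared = _positions(n_shared)
    only_a = _positions(n_only_a)
    only_b = _positions(n_only_b)
    cha = np.full((size, size), CYTO_LEVEL)
    chb = np.full((size, size), CYTO_LEVEL)
    for y, x in np.vstack([shared, only_a]) if (n_shared + n_only_a) else []:
        _add_gaussian(cha, y, x, amp, sigma_px, sigma_px)
    for y, x in np.vstack([shared, only_b]) if (n_shared + n_only_b) else []:
        _add_gaussian(chb, y, x, amp, sigma_px, sigma_px)
    if noise:
        cha = _apply_noise(cha, rng)
        chb = _apply_noise(chb, rng)
    pixels = np.stack([cha, chb])[None, None]  # (1,1,2,y,x)
    stack = ImageStack(pixels, pixel_size_um=PIXEL_SIZE_UM)
    params = dict(n_shared=n_shared, n_only_a=n_only_a, n_only_b=n_only_b,
                  snr=snr, size=size, sigma_px=sigma_px, noise=noise)
    gt = GroundTruth("two_channel_scene", params,
                     dict(shared=shared.tolist(), only_a=only_a.tolist(),
                          only_b=only_b.tolist()), seed)
    return stack, gt


# ---------------------------------------------------------------------------
# smFISH spot scenes
# ---------------------------------------------------------------------------


def gen_spot_scene(
    n_soma: int = 20,
    n_neurite: int = 5,
    soma_radius_um: float = 5.0,
    neurite_length_um: float = 25.0,
    neurite_width_px: int = 5,
    psf_sigma_px: float = 1.3,
    snr: float = 8.0,
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Diffraction-limited spots over a soma disk plus one straight neurite.

    Returns the image, a label mask (1 = soma, 2 = neurite, 0 = outside)
    and a truth listing each spot coordinate with its compartment.
    """
    rng = np.random.default_rng(seed)
    soma_r = soma_radius_um / pixel_size_um
    neur_len = neurite_length_um / pixel_size_um
    h = int(2 * soma_r + 40)
    w = int(2 * soma_r + neur_len + 40)
    cy, cx = h / 2, soma_r + 15
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.uint8)
    neurite_band = (
        (np.abs(yy - cy) <= neurite_width_px // 2)
        & (xx > cx + soma_r)
        & (xx <= cx + soma_r + neur_len)
    )
    mask[neurite_band] = 2
    mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= soma_r**2] = 1  # soma wins overlap

    spots: list[dict] = []
    min_sep = 6 * psf_sigma_px  # spots stay resolvable (detection merges closer)

    def _far_enough(y: float, x: float) -> bool:
        return all(np.hypot(y - s["y"], x - s["x"]) >= min_sep for s in spots)

    while sum(s["compartment"] == "soma" for s in spots) < n_soma:
        ang, rad = rng.uniform(0, 2 * np.pi), soma_r * np.sqrt(rng.uniform())
        y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        if mask[int(round(y)), int(round(x))] == 1 and _far_enough(y, x):
            spots.append(dict(y=y, x=x, compartment="soma"))
    while sum(s["compartment"] == "neurite" for s in spots) < n_neurite:
        x = rng.uniform(cx + soma_r + 8, cx + soma_r + neur_len - 8)
        y = cy + rng.uniform(-1, 1)
        if _far_enough(y, x):
            spots.append(dict(y=y, x=x, compartment="neurite"))

    img = np.full((h, w), 20.0)
    amp = snr * _bg_sigma(20.0, READ_SD)
    for s in spots:
        _add_gaussian(img, s["y"], s["x"], amp, psf_sigma_px, psf_sigma_px)
    img = _apply_noise(img, rng)
    stack = ImageStack(img[None, None, None], pixel_size_um=pixel_size_um)
    params = dict(n_soma=n_soma, n_neurite=n_neurite, soma_radius_um=soma_radius_um,
                  neurite_length_um=neurite_length_um, psf_sigma_px=psf_sigma_px,
                  snr=snr, pixel_size_um=pixel_size_um)
    gt = GroundTruth("spot_scene", params, dict(spots=spots), seed)
    return stack, mask, gt


# ---------------------------------------------------------------------------
# Dual-luciferase plates
# ---------------------------------------------------------------------------


def gen_plate(
    true_repression_fold: dict[str, float] | None = None,
    control: str = "control",
    rluc_mean: float = 1000.0,
    baseline_ratio: float = 0.5,
    noise_cv: float = 0.1,
    n_technical: int = 3,
    seed: int = 0,
) -> tuple["PlateData", GroundTruth]:
    """Dual-luciferase plate with technical replicates.

    FLuc = RLuc * baseline_ratio / fold * lognormal noise; the control
    construct has fold 1, so the control-normalized ratio of a construct
    with repression fold f is 1/f in expectation.
    """
    from .reporter import PlateData, Well

    folds = dict(true_repression_fold or {"FMRP": 4.0})
    folds.setdefault(control, 1.0)
    if folds[control] != 1.0:
        raise ValueError("control construct must have fold 1")
    rng = np.random.default_rng(seed)
    sd_log = np.sqrt(np.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0
    wells = []
    for construct, fold in folds.items():
        for rep in range(n_technical):
            rluc = rluc_mean * (
                np.exp(rng.normal(-sd_log**2 / 2, sd_log)) if noise_cv > 0 else 1.0
            )
            fluc = rluc * baseline_ratio / fold * (
                np.exp(rng.normal(-sd_log**2 / 2, sd_log)) if noise_cv > 0 else 1.0
            )
            wells.append(Well(construct=construct, replicate=rep,
                              fluc=float(fluc), rluc=float(rluc)))
    plate = PlateData(wells=wells, control=control)
    params = dict(true_repression_fold=folds, rluc_mean=rluc_mean,
                  baseline_ratio=baseline_ratio, noise_cv=noise_cv,
                  n_technical=n_technical)
    gt = GroundTruth("plate", params,
                     dict(expected_ratio={c: 1.0 / f for c, f in folds.items()}),
                     seed)
    return plate, gt
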