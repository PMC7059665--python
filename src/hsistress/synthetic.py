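"""Treatment-structured synthetic vegetation hyperspectral scenes.

The study conditions this generator emulates: 512 uniformly spaced bands
over 380-1030 nm; leaf reflectance with the classic pigment absorptions
(blue and red chlorophyll dips, a green bump), a red edge near 715 nm and
an NIR plateau; and three treatment groups of rice seedlings —

* CK: untreated control,
* Q:  quinclorac-stressed (pigment loss raises visible reflectance,
      structural damage lowers NIR reflectance),
* S:  salicylic-acid pretreatment before quinclorac (partial rescue,
      spectrally between CK and Q but much closer to Q).

Scenes are leaf-shaped elliptical regions on a dark background.  The leaf
reflectance is perturbed per pixel by multiplicative/additive scatter and
band-wise Gaussian noise, then inverted through the reflectance calibration
equation with synthetic dark/white reference frames so that the raw-count
path of the pipeline is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hypercube import HyperCube, ReferenceFrame

__all__ = [
    "CK", "Q", "S", "TREATMENT_LABELS", "TREATMENT_NAMES",
    "SceneParams", "Scene",
    "base_vegetation_spectrum", "treatment_spectrum",
    "simulate_scene", "simulate_dataset",
]

# category values used for modelling
CK, Q, S = 1, 2, 3
TREATMENT_LABELS = (CK, Q, S)
TREATMENT_NAMES = {CK: "CK", Q: "Q", S: "S"}

# spectral windows (nm) carrying the treatment contrasts
VISIBLE_REGION = (434.0, 700.0)
NIR_REGION = (750.0, 953.0)


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters; defaults are the study conditions.

    ``visible_shift``/``nir_shift`` are additive reflectance offsets per
    treatment applied on the visible (434-700 nm) and NIR (750-953 nm)
    windows.  The defaults reproduce the reported ordering: CK below Q and
    S in the visible, above them in the NIR, with Q and S mutually close
    (S between CK and Q).
    """

    n_bands: int = 512
    wl_min: float = 380.0
    wl_max: float = 1030.0
    visible_shift: dict = field(
        default_factory=lambda: {CK: 0.00, Q: +0.04, S: +0.03})
    nir_shift: dict = field(
        default_factory=lambda: {CK: 0.00, Q: -0.05, S: -0.04})
    taper_nm: float = 15.0            # half-width of the cosine edge taper
    pixel_noise_sd: float = 0.01      # band-wise Gaussian reflectance noise
    scatter_slope_sd: float = 0.05    # per-pixel multiplicative scatter
    scatter_offset_sd: float = 0.01   # per-pixel additive scatter
    shot_noise_scale: float = 0.3     # counts-domain noise, sd ~ scale*sqrt(counts)
    ref_noise_sd: float = 2.0         # reference-frame noise in counts
    background_reflectance: float = 0.03
    leaf_count: int = 3
    image_rows: int = 64
    image_cols: int = 64
    dark_mean: float = 100.0          # dark reference counts
    white_mean: float = 3000.0        # white reference counts at peak

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)

    def noiseless(self) -> "SceneParams":
        """Copy with every noise source switched off."""
        return replace(self, pixel_noise_sd=0.0, scatter_slope_sd=0.0,
                       scatter_offset_sd=0.0, shot_noise_scale=0.0,
                       ref_noise_sd=0.0)


@dataclass
class Scene:
    """One simulated acquisition: raw cube, references, truth and label."""

    raw: HyperCube
    dark: ReferenceFrame
    white: ReferenceFrame
    truth_mask: np.ndarray
    label: int
    seed: int
    leaf_area_analytic: float  # sum of pi*a*b over placed leaves, in pixels


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def base_vegetation_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Deterministic healthy-leaf reflectance curve.

    A sigmoid red edge (center 715 nm, width 18 nm) lifts a visible
    baseline of 0.08 to an NIR plateau of 0.50; a green bump (550 nm,
    height 0.07, sd 30 nm) sits on the baseline; chlorophyll/carotenoid
    absorptions at 450 nm (depth 0.42, sd 40 nm) and 680 nm (depth 0.40,
    sd 25 nm) act as fractional (multiplicative) dips.  Values are clipped
    to the open unit interval.
    """
    wl = np.asarray(wavelengths, dtype=float)
    continuum = 0.08 + (0.50 - 0.08) * _sigmoid((wl - 715.0) / 18.0)
    continuum = continuum + 0.07 * np.exp(-((wl - 550.0) ** 2) / (2 * 30.0**2))
    dip_blue = 1.0 - 0.42 * np.exp(-((wl - 450.0) ** 2) / (2 * 40.0**2))
    dip_red = 1.0 - 0.40 * np.exp(-((wl - 680.0) ** 2) / (2 * 25.0**2))
    return np.clip(continuum * dip_blue * dip_red, 1e-6, 1.0 - 1e-6)


def _taper_window(wl: np.ndarray, lo: float, hi: float, taper: float) -> np.ndarray:
    """Raised-cosine window supported on [lo, hi], flat in the middle.

    Each transition is a half-cosine ramp lying entirely inside the window
    and reaching the plateau ``2 * taper`` nm in from the edge.  The ramp
    has zero slope at both of its ends, so the shifted spectrum stays
    smooth at the window edges (which for the visible window coincide with
    the analyzed band range) and the low-pass preprocessing chain
    reconstructs it with little bias.
    """
    if taper <= 0:
        return ((wl >= lo) & (wl <= hi)).astype(float)
    span = 2 * taper
    w = np.zeros_like(wl)
    rising = (wl > lo) & (wl < lo + span)
    falling = (wl > hi - span) & (wl < hi)
    inside = (wl >= lo + span) & (wl <= hi - span)
    w[inside] = 1.0
    w[rising] = 0.5 * (1 - np.cos(np.pi * (wl[rising] - lo) / span))
    w[falling] = 0.5 * (1 + np.cos(np.pi * (wl[falling] - (hi - span)) / span))
    return w


def treatment_spectrum(label: int, params: SceneParams | None = None) -> np.ndarray:
    """Mean leaf reflectance of a treatment group on the generator's axis."""
    if params is None:
        params = SceneParams()
    if label not in TREATMENT_LABELS:
        raise ValueError(f"unknown treatment label {label!r}; expected one of "
                         f"{TREATMENT_LABELS}")
    wl = params.wavelengths()
    spec = base_vegetation_spectrum(wl)
    spec = spec + params.visible_shift[label] * _taper_window(
        wl, *VISIBLE_REGION, params.taper_nm)
    spec = spec + params.nir_shift[label] * _taper_window(
        wl, *NIR_REGION, params.taper_nm)
    return np.clip(spec, 1e-6, 1.0 - 1e-6)


def _place_leaves(params: SceneParams, rng: np.random.Generator,
                  max_retries: int = 200) -> tuple[np.ndarray, float]:
    """Place non-overlapping elongated elliptical leaves; returns (mask, area)."""
    rows, cols = params.image_rows, params.image_cols
    mask = np.zeros((rows, cols), dtype=bool)
    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]
    analytic_area = 0.0
    for _ in range(params.leaf_count):
        for attempt in range(max_retries):
            a = rng.uniform(3.0, 4.5)            # semi-minor axis (px)
            b = rng.uniform(14.0, 20.0)          # semi-major axis (px)
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(b, rows - b)
            cx = rng.uniform(b, cols - b)
            ct, st = np.cos(theta), np.sin(theta)
            u = (rr_grid - cy) * ct + (cc_grid - cx) * st
            v = -(rr_grid - cy) * st + (cc_grid - cx) * ct
            leaf = (u / b) ** 2 + (v / a) ** 2 <= 1.0
            if not (leaf & mask).any():
                mask |= leaf
                analytic_area += np.pi * a * b
                break
        else:
            raise RuntimeError(
                f"could not place {params.leaf_count} non-overlapping leaves in a "
                f"{rows}x{cols} image after {max_retries} retries")
    return mask, analytic_area


def _white_reference_shape(wl: np.ndarray) -> np.ndarray:
    # halogen-like illumination: broad, peaked in the NIR
    return 0.5 + 0.5 * np.exp(-((wl - 780.0) ** 2) / (2 * 250.0**2))


def simulate_scene(label: int, params: SceneParams | None = None,
                   seed: int = 0) -> Scene:
    """Simulate one raw acquisition of a scene of the given treatment.

    The reflectance scene is built first (leaves = perturbed treatment
    spectrum, background = flat ``background_reflectance``), then inverted
    through the calibration equation with synthetic dark/white reference
    lines so that ``calibrate_reflectance(raw, dark, white)`` recovers it.
    Fully reproducible from ``seed``.
    """
    if params is None:
        params = SceneParams()
    if label not in TREATMENT_LABELS:
        raise ValueError(f"unknown treatment label {label!r}")
    rng = np.random.default_rng(seed)
    wl = params.wavelengths()
    rows, cols, bands = params.image_rows, params.image_cols, params.n_bands

    mask, analytic_area = _place_leaves(params, rng)
    refl = np.full((rows, cols, bands), params.background_reflectance)
    n_leaf = int(mask.sum())
    spec = treatment_spectrum(label, params)
    slope = rng.normal(0.0, params.scatter_slope_sd, size=(n_leaf, 1))
    offset = rng.normal(0.0, params.scatter_offset_sd, size=(n_leaf, 1))
    noise = rng.normal(0.0, params.pixel_noise_sd, size=(n_leaf, bands))
    refl[mask] = (1.0 + slope) * spec[None, :] + offset + noise

    dark_line = np.full((1, cols, bands), params.dark_mean)
    white_line = params.dark_mean + (params.white_mean - params.dark_mean) \
        * _white_reference_shape(wl)[None, None, :] * np.ones((1, cols, 1))
    if params.ref_noise_sd > 0:
        dark_line = dark_line + rng.normal(0, params.ref_noise_sd, dark_line.shape)
        white_line = white_line + rng.normal(0, params.ref_noise_sd, white_line.shape)

    counts = dark_line + refl * (white_line - dark_line)
    if params.shot_noise_scale > 0:
        counts = counts + rng.normal(
            0.0, params.shot_noise_scale * np.sqrt(np.maximum(counts, 1.0)))

    raw = HyperCube(counts, wl, kind="raw")
    return Scene(
        raw=raw,
        dark=ReferenceFrame(dark_line, role="dark"),
        white=ReferenceFrame(white_line, role="white"),
        truth_mask=mask,
        label=label,
        seed=seed,
        leaf_area_analytic=analytic_area,
    )


def simulate_dataset(n_per_group: int, params: SceneParams | None = None,
                     seed: int = 0) -> list[Scene]:
    """Balanced dataset of ``3 * n_per_group`` scenes, labels grouped CK,Q,S.

    Per-scene seeds are derived deterministically from the master seed via
    a seed sequence, so disjoint master seeds give disjoint scene streams.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if params is None:
        params = SceneParams()
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(3 * n_per_group).astype(np.int64) % (2**31)
    scenes = []
    i = 0
    for label in TREATMENT_LABELS:
        for _ in range(n_per_group):
            scenes.append(simulate_scene(label, params, seed=int(children[i])))
            i += 1
    return scenes
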