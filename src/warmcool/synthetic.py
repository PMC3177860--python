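"""Synthetic chip sets and imaging experiments with known ground truth.

Two generators stand in for data that cannot be redistributed: (1) a
Munsell-like chip array (hue circle x lightness levels) with warm/cool
membership counts whose majority label follows the sign of the chip's L-M
opponent response with controllable noise, and (2) intrinsic-imaging frame
stacks with a realistic trial structure (pre/during/post frames, blocks in
pseudo-random order, control trials), spatially coherent ongoing activity,
vessel-like static artifacts, small frame-to-frame movement, and cortical
response patches holding two displaced spatial modes keyed to the sign of
the stimulus L-M contrast.

Ground truth (spectra, opponent responses, patch geometry, mode assignment)
is always returned alongside the data so downstream stages can be tested
against the generator's manifest rather than against themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .colorimetry import (
    DEFAULT_GRID,
    Chromaticity,
    Spectrum,
    load_default_fundamentals,
    load_default_illuminant,
    cone_contrasts,
    opponent_responses,
    reflected_spd,
    resample_spectrum,
    cone_excitations,
    xy_to_cone_excitations,
)
from .config import defaults
from .imaging import ImagingExperiment, Trial

__all__ = [
    "ChipSetConfig",
    "ChipSet",
    "generate_chip_set",
    "stimulus_colors",
    "stimulus_table",
    "ImagingConfig",
    "generate_imaging_experiment",
]


# ---------------------------------------------------------------------------
# Chip sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipSetConfig:
    """Configuration of the synthetic chip array.

    Defaults mirror the World Color Survey layout: 40 equally spaced hues at
    8 lightness levels, plus one flat-spectrum gray reference chip.  Each
    chip receives ``trials_per_chip`` warm/cool votes; the probability of a
    "warm" vote is the logistic sigma(beta * R_LM), so ``beta`` controls how
    tightly the counts follow the L-M channel (beta = 0: votes are coin
    flips; large beta: the majority label equals sign(R_LM) for every chip
    with R_LM != 0).
    """

    n_hues: int = 40
    n_values: int = 8
    trials_per_chip: int = 100
    beta: float = 60.0
    band_sd_nm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hues * self.n_values < 2:
            raise ValueError("need at least 2 chips")
        if self.trials_per_chip < 1 or self.band_sd_nm <= 0:
            raise ValueError("invalid config")


@dataclass
class ChipSet:
    """Generated chips: table, spectra, and the reference chip id."""

    chips: pd.DataFrame          # chip_id, hue_label, value_label, N_w, N_c,
                                 # C_L, C_M, C_S, R_LM, R_Y
    spectra: np.ndarray          # (n_chips, n_wavelengths) reflectances
    wavelengths: np.ndarray
    reference_id: str
    config: ChipSetConfig


def _chip_reflectance(
    grid: np.ndarray, hue_frac: float, light_frac: float, band_sd: float
) -> np.ndarray:
    """Baseline-plus-Gaussian-band reflectance for one chip.

    The band center sweeps 430..660 nm with hue; baseline and band amplitude
    grow with lightness.  The simplest family that yields a full hue sweep
    with monotone cone-contrast structure.
    """
    center = 430.0 + 230.0 * hue_frac
    base = 0.08 + 0.55 * light_frac
    amp = 0.45 * light_frac
    r = base + amp * np.exp(-0.5 * ((grid - center) / band_sd) ** 2)
    return np.clip(r, 0.0, 1.2)


def generate_chip_set(cfg: ChipSetConfig) -> ChipSet:
    """Generate a chip array with spectra, counts, and ground-truth responses.

    Deterministic given ``cfg.seed``.  The flat-spectrum gray chip at the
    middle lightness level is the designated reference; contrasts and
    opponent responses of every chip are computed against it through the
    packaged illuminant and fundamentals.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = DEFAULT_GRID
    ill = resample_spectrum(load_default_illuminant(), grid)
    fund = load_default_fundamentals()

    mid_light = 0.5
    gray_reflectance = np.full(grid.shape, 0.08 + 0.55 * mid_light)
    ref_exc = cone_excitations(reflected_spd(Spectrum(grid, gray_reflectance), ill), fund)

    ids, spectra, rows = [], [], []
    for h in range(cfg.n_hues):
        for v in range(1, cfg.n_values + 1):
            hue_frac = h / cfg.n_hues
            light_frac = v / (cfg.n_values + 1)
            refl = _chip_reflectance(grid, hue_frac, light_frac, cfg.band_sd_nm)
            exc = cone_excitations(reflected_spd(Spectrum(grid, refl), ill), fund)
            c = cone_contrasts(exc, ref_exc)
            r = opponent_responses(c)
            z = np.clip(cfg.beta * r.R_LM, -700.0, 700.0)
            p_warm = float(1.0 / (1.0 + np.exp(-z)))
            n_w = int(rng.binomial(cfg.trials_per_chip, p_warm))
            chip_id = f"H{h:02d}V{v}"
            ids.append(chip_id)
            spectra.append(refl)
            rows.append({
                "chip_id": chip_id, "hue_label": f"H{h:02d}", "value_label": f"V{v}",
                "N_w": n_w, "N_c": cfg.trials_per_chip - n_w,
                "C_L": c.C_L, "C_M": c.C_M, "C_S": c.C_S,
                "R_LM": r.R_LM, "R_Y": r.R_Y, "is_reference": False,
            })
    # the reference gray itself, included in the set (counts are coin flips)
    n_w = int(rng.binomial(cfg.trials_per_chip, 0.5))
    rows.append({
        "chip_id": "GRAY5", "hue_label": "N", "value_label": "V5",
        "N_w": n_w, "N_c": cfg.trials_per_chip - n_w,
        "C_L": 0.0, "C_M": 0.0, "C_S": 0.0, "R_LM": 0.0, "R_Y": 0.0,
        "is_reference": True,
    })
    ids.append("GRAY5")
    spectra.append(gray_reflectance)
    return ChipSet(
        chips=pd.DataFrame(rows),
        spectra=np.array(spectra),
        wavelengths=grid,
        reference_id="GRAY5",
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Display stimuli
# ---------------------------------------------------------------------------

#: CIE 1931 xy of the nine display colors (two pink variants) and the
#: adaptation gray, all at 9.5 cd/m^2.
STIMULUS_XY = {
    "R": (0.55, 0.33), "O": (0.54, 0.40), "Y": (0.45, 0.47), "L": (0.35, 0.54),
    "G": (0.27, 0.49), "A": (0.23, 0.36), "B": (0.16, 0.08), "P": (0.23, 0.12),
    "K1": (0.43, 0.24), "K2": (0.38, 0.27), "W": (0.32, 0.32), "W2": (0.35, 0.32),
}

STIMULUS_LUMINANCE = 9.5


def stimulus_colors(pink: Literal["K1", "K2"] = "K1", gray: Literal["W", "W2"] = "W") -> pd.DataFrame:
    """The nine-color stimulus set plus the adaptation gray, as chromaticities."""
    labels = ["R", "O", "Y", "L", "G", "A", "B", "P", pink, gray]
    rows = [{"label": lab, "x": STIMULUS_XY[lab][0], "y": STIMULUS_XY[lab][1],
             "Y": STIMULUS_LUMINANCE, "role": ("gray" if lab == gray else "color")}
            for lab in labels]
    return pd.DataFrame(rows)


def stimulus_table(
    pink: Literal["K1", "K2"] = "K1",
    gray: Literal["W", "W2"] = "W",
    matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """The nine colors with cone contrasts and opponent responses vs. the gray.

    Excitations come from the printed chromaticities at 9.5 cd/m^2 through
    the configured XYZ->LMS matrix; contrasts are against the adaptation
    gray.  Returns columns label, x, y, Y, C_L, C_M, C_S, R_LM, R_Y.
    """
    m = defaults()["xyz_to_lms"] if matrix is None else np.asarray(matrix, dtype=float)
    base = stimulus_colors(pink, gray)
    gray_row = base[base["role"] == "gray"].iloc[0]
    ref = xy_to_cone_excitations(Chromaticity(gray_row.x, gray_row.y, gray_row.Y), m)
    rows = []
    for _, r in base[base["role"] == "color"].iterrows():
        exc = xy_to_cone_excitations(Chromaticity(r.x, r.y, r.Y), m)
        c = cone_contrasts(exc, ref)
        o = opponent_responses(c)
        rows.append({"label": r.label, "x": r.x, "y": r.y, "Y": r.Y,
                     "C_L": c.C_L, "C_M": c.C_M, "C_S": c.C_S,
                     "R_LM": o.R_LM, "R_Y": o.R_Y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Imaging experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Configuration of a synthetic imaging session.

    Defaults are desk-scale (128 x 128 px, 3 patches, 10 blocks) while
    keeping the recorded trial structure: 11 pre-stimulation frames, 18
    during, 2 after; one trial per stimulus (including a gray-screen control)
    per block, in pseudo-random order.  Signal amplitudes are fractions of
    the baseline light level; the ongoing-activity field is spatially
    coherent over ``coherent_length`` pixels (required to exceed the patch
    diameter) and comparable in amplitude to weak responses, which is what
    makes the clustering realistically imperfect.
    """

    grid_size: int = 128
    n_patches: int = 3
    patch_diameter: float = 16.0
    template_offset: float = 6.0
    displacement_floor: float = 0.5
    pattern_jitter: float = 1.5
    n_blocks: int = 10
    frames_pre: int = 11
    frames_during: int = 18
    frames_post: int = 2
    noise_sd: float = 1.0e-3
    coherent_sd: float = 1.0e-3
    coherent_length: float = 24.0
    temporal_corr: float = 0.6
    vessel_amplitude: float = 0.12
    n_vessels: int = 4
    response_amplitude: float = 4.0e-3
    response_floor: float = 0.2
    ry_gain: float = 0.15
    jitter_max: int = 2
    baseline_level: float = 1000.0
    pink: Literal["K1", "K2"] = "K1"
    gray: Literal["W", "W2"] = "W"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coherent_length <= self.patch_diameter:
            raise ValueError("coherent_length must exceed patch_diameter")
        if self.grid_size < 8 * int(self.patch_diameter) // 2:
            pass  # loose; placement check below is authoritative
        if min(self.n_patches, self.n_blocks, self.frames_pre,
               self.frames_during, self.frames_post) < 1:
            raise ValueError("invalid config")
        if self.frames_during + self.frames_post < 7:
            raise ValueError("need at least 7 during+post frames")
        if not 0 <= self.temporal_corr < 1:
            raise ValueError("temporal_corr must be in [0, 1)")


def _coherent_field(rng, shape, length, prev=None, rho=0.0):
    """Unit-sd low-spatial-frequency Gaussian field, optionally AR(1) in time."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=length / 2.355,
                                  mode="wrap")
    raw /= raw.std()
    if prev is None or rho == 0.0:
        return raw
    return rho * prev + math.sqrt(1.0 - rho * rho) * raw


def _vessel_mask(rng, size, n_vessels):
    """Dark curvilinear artifact pattern in [0, 1] (1 = vessel core)."""
    img = np.zeros((size, size))
    for _ in range(n_vessels):
        y, x = rng.uniform(0, size, 2)
        ang = rng.uniform(0, 2 * math.pi)
        for _ in range(3 * size):
            iy, ix = int(y) % size, int(x) % size
            img[iy, ix] = 1.0
            ang += rng.normal(0.0, 0.15)
            y += math.sin(ang)
            x += math.cos(ang)
    img = ndimage.gaussian_filter(img, sigma=1.2, mode="wrap")
    peak = img.max()
    return img / peak if peak > 0 else img


def _gaussian_blob(size, cy, cx, sigma):
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-0.5 * (((yy - cy) ** 2 + (xx - cx) ** 2) / sigma**2))


def _place_patches(rng, size, n_patches, diameter, margin):
    centers = []
    for _ in range(10_000):
        cy, cx = rng.uniform(margin, size - margin, 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (2.0 * diameter) ** 2 for y, x in centers):
            centers.append((cy, cx))
            if len(centers) == n_patches:
                return centers
    raise ValueError("could not place patches: grid too small for config")


def generate_imaging_experiment(cfg: ImagingConfig) -> tuple[ImagingExperiment, dict]:
    """Synthesize one imaging session plus its ground-truth manifest.

    Every ground-truth patch holds two displaced Gaussian response templates;
    a stimulus activates the template selected by the sign of its R_LM, with
    an amplitude that grows compressively with |R_LM| (plus a small |R_Y|
    term).  Responses multiply the baseline by (1 - amplitude * template):
    intrinsic activation darkens the image.  Ongoing activity, static
    vessels, per-trial movement jitter, and per-pixel camera noise are
    superimposed.  Bit-reproducible for a given config.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.grid_size
    table = stimulus_table(cfg.pink, cfg.gray)
    rlm = table.set_index("label")["R_LM"]
    ry = table.set_index("label")["R_Y"]
    max_rlm = float(rlm.abs().max())
    max_ry = float(ry.abs().max())

    # static scene
    baseline = cfg.baseline_level * (
        1.0 + 0.05 * _coherent_field(rng, (size, size), cfg.coherent_length)
    )
    baseline *= 1.0 - cfg.vessel_amplitude * _vessel_mask(rng, size, cfg.n_vessels)

    # ground-truth patches: two response modes along a per-patch axis.  A
    # color's blob center sits on the sign(R_LM) side at a distance that
    # grows compressively with |R_LM| (hue-map-like continuous shift), plus
    # a fixed per-(patch, color) positional jitter, so weak-contrast colors
    # occasionally miscluster as in recorded data.
    sigma = cfg.patch_diameter / 4.0
    margin = cfg.patch_diameter + cfg.jitter_max + 4
    centers = _place_patches(rng, size, cfg.n_patches, cfg.patch_diameter, margin)
    half = 0.5 * cfg.template_offset
    axes = [rng.uniform(0, 2 * math.pi) for _ in centers]

    def displacement(color: str) -> float:
        nl = abs(float(rlm[color])) / max_rlm
        sgn = 1.0 if float(rlm[color]) > 0 else -1.0
        return sgn * half * (cfg.displacement_floor
                             + (1 - cfg.displacement_floor) * math.sqrt(nl))

    def amplitude(color: str) -> float:
        nl = abs(float(rlm[color])) / max_rlm
        ny = abs(float(ry[color])) / max_ry
        return cfg.response_amplitude * (
            cfg.response_floor + (1 - cfg.response_floor) * math.sqrt(nl)
        ) * (1.0 + cfg.ry_gain * ny)

    blob_centers: dict[str, list[tuple[float, float]]] = {}
    response_images = {}
    for color in table["label"]:
        img = np.zeros((size, size))
        blob_centers[color] = []
        d = displacement(color)
        for (cy, cx), ang in zip(centers, axes):
            jy, jx = rng.normal(0.0, cfg.pattern_jitter, 2)
            by = cy + d * math.sin(ang) + jy
            bx = cx + d * math.cos(ang) + jx
            blob_centers[color].append((by, bx))
            img += _gaussian_blob(size, by, bx, sigma)
        response_images[color] = amplitude(color) * img

    n_frames = cfg.frames_pre + cfg.frames_during + cfg.frames_post
    # response time course: 0 before, linear ramp over the stimulation
    # period, saturating so the last 5 during + 2 post frames are at plateau
    ramp_len = max(1, cfg.frames_during - 5)
    w = np.zeros(n_frames)
    for k in range(cfg.frames_during):
        w[cfg.frames_pre + k] = min(1.0, (k + 1) / ramp_len)
    w[cfg.frames_pre + cfg.frames_during:] = 1.0

    labels = list(table["label"]) + ["control"]
    trials: list[Trial] = []
    truth_trials = []
    for block in range(cfg.n_blocks):
        order = list(rng.permutation(labels))
        for stim in order:
            jit = (int(rng.integers(-cfg.jitter_max, cfg.jitter_max + 1)),
                   int(rng.integers(-cfg.jitter_max, cfg.jitter_max + 1))) if cfg.jitter_max else (0, 0)
            frames = np.empty((n_frames, size, size), dtype=np.float32)
            field_prev = None
            for t in range(n_frames):
                scene = baseline.copy()
                if stim != "control" and w[t] > 0:
                    scene = scene * (1.0 - w[t] * response_images[stim])
                if cfg.coherent_sd > 0:
                    field_prev = _coherent_field(rng, (size, size), cfg.coherent_length,
                                                 field_prev, cfg.temporal_corr)
                    scene = scene * (1.0 + cfg.coherent_sd * field_prev)
                if jit != (0, 0):
                    scene = np.roll(scene, jit, axis=(0, 1))
                if cfg.noise_sd > 0:
                    scene = scene + cfg.baseline_level * cfg.noise_sd * rng.standard_normal((size, size))
                frames[t] = scene
            trials.append(Trial(stimulus=stim, block=block, frames=frames,
                                n_pre=cfg.frames_pre))
            truth_trials.append({"block": block, "stimulus": stim, "jitter": jit})

    exp = ImagingExperiment(trials=trials, stimulus_table=table)
    truth = {
        "config": asdict(cfg),
        "patch_centers": centers,
        "mode_axes": axes,
        "template_sigma": sigma,
        "amplitudes": {c: amplitude(c) for c in table["label"]},
        "blob_centers": blob_centers,
        "response_images": response_images,
        "mode_by_color": {c: ("positive" if float(rlm[c]) > 0 else "negative")
                          for c in table["label"]},
        "trials": truth_trials,
        "stimulus_table": table,
    }
    return exp, truth
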