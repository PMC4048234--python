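"""Seeded synthetic islet images and cohorts with full ground truth.

The generator emulates the imaging model the scoring pipeline assumes:
an elliptical islet on a dark background, one Gaussian-profile nucleus
blob per cell in the DAPI layer, a stained cytoplasmic annulus per β
cell in the 488 layer and per α cell in the 555 layer, a smooth
multiplicative illumination field, and additive Gaussian noise. Ground
truth (nucleus centres, cell classes, pre-noise stain masks, the true
stained fraction) is recorded before noise is applied, so every
downstream stage can be tested without external data.

Two staining modes exist for the 488 target layer:

* *cells* (default): each β cell stains a fraction of its cytoplasmic
  annulus — this is the biologically shaped mode used for nucleus
  detection and α/β classification tests;
* *target fraction*: ``target_stained_fraction`` requests an exact
  stained non-nuclear islet pixel fraction; stained pixels are laid down
  as random discs kept clear of the nuclei and trimmed to the exact
  count — this gives pixel-exact ground truth for score recovery.

The default canvas is 344×258 px, a quarter-scale version of the
native 1376×1032 acquisition format, to keep generation and tests fast;
full scale is available through the parameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .types import ALPHA, BETA, ChannelStack, IsletMask

#: Pixels this close to a nucleus centre (in units of nucleus_radius) are
#: never stained in target-fraction mode, so detected nucleus regions
#: stay disjoint from true stained pixels.
_STAIN_MARGIN_FACTOR = 1.75


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic islet image.

    Intensity model: background at ``background_level``, stained pixels
    at ``stain_level`` (so with zero noise and no illumination gradient
    every stained pixel equals ``stain_level`` exactly), DAPI blobs
    peaking at ``dapi_level`` with Gaussian profile σ = radius/2.
    """

    height: int = 258
    width: int = 344
    islet_center: tuple[float, float] | None = None   # defaults to canvas centre
    islet_axes: tuple[float, float] = (105.0, 145.0)  # ellipse semi-axes (row, col)
    n_nuclei: int = 40
    nucleus_radius: float = 3.0
    annulus_width: float = 3.0
    beta_fraction: float = 0.7
    stain_fraction_per_beta: float = 1.0
    stain_level: float = 0.7
    background_level: float = 0.1
    dapi_level: float = 0.9
    noise_sd: float = 0.10
    illumination_gradient: float = 0.2
    well_separated: bool = True
    target_stained_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ParameterError("canvas must be at least 8×8 px")
        if not 0 <= self.background_level < self.stain_level <= 1:
            raise ParameterError(
                "need 0 <= background_level < stain_level <= 1 (separable classes)"
            )
        if not 0.0 <= self.beta_fraction <= 1.0:
            raise ParameterError("beta_fraction must lie in [0,1]")
        if not 0.0 <= self.stain_fraction_per_beta <= 1.0:
            raise ParameterError("stain_fraction_per_beta must lie in [0,1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.illumination_gradient < 1.0:
            raise ParameterError("illumination_gradient must lie in [0,1)")
        if self.target_stained_fraction is not None and not (
            0.0 <= self.target_stained_fraction <= 1.0
        ):
            raise ParameterError("target_stained_fraction must lie in [0,1]")
        if self.n_nuclei < 0 or self.nucleus_radius <= 0:
            raise ParameterError("need n_nuclei >= 0 and nucleus_radius > 0")


@dataclass(frozen=True)
class SynthGroundTruth:
    """Everything the generator knows about its own image, pre-noise."""

    nuclei_centers: np.ndarray          # (n, 2) float (row, col)
    cell_class: tuple[str, ...]         # per-nucleus label, beta/alpha
    islet_mask: np.ndarray              # boolean grid
    nuclei_mask: np.ndarray             # boolean grid, union of nucleus discs
    stained_mask_488: np.ndarray        # boolean grid, pre-noise 488 staining
    stained_mask_555: np.ndarray        # boolean grid, pre-noise 555 staining
    true_stained_fraction: float        # stained non-nuclear islet px / islet px

    def __post_init__(self) -> None:
        if len(self.cell_class) != len(self.nuclei_centers):
            raise ParameterError("cell_class length must match nuclei_centers")
        if not 0.0 <= self.true_stained_fraction <= 1.0:
            raise ParameterError("true_stained_fraction must lie in [0,1]")


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _place_nuclei(params: SynthParams, rng: np.random.Generator,
                  center: tuple[float, float]) -> np.ndarray:
    """Rejection-sample nucleus centres inside the (shrunken) islet ellipse."""
    ar = params.islet_axes[0] - params.nucleus_radius - 1
    ac = params.islet_axes[1] - params.nucleus_radius - 1
    if ar <= 0 or ac <= 0:
        raise GenerationError("islet too small for the requested nucleus radius")
    min_sep = (
        2.0 * (params.nucleus_radius + params.annulus_width)
        if params.well_separated
        else 0.0
    )
    centers: list[tuple[float, float]] = []
    max_tries = 2000
    for _ in range(params.n_nuclei):
        for attempt in range(max_tries):
            r = center[0] + ar * (2.0 * rng.random() - 1.0)
            c = center[1] + ac * (2.0 * rng.random() - 1.0)
            if ((r - center[0]) / ar) ** 2 + ((c - center[1]) / ac) ** 2 > 1.0:
                continue
            if min_sep and any(
                (r - r2) ** 2 + (c - c2) ** 2 < min_sep**2 for r2, c2 in centers
            ):
                continue
            centers.append((r, c))
            break
        else:
            raise GenerationError(
                f"cannot place {params.n_nuclei} nuclei at separation "
                f"{min_sep:.1f} px in this islet"
            )
    return np.asarray(centers, dtype=np.float64).reshape(-1, 2)


def _distance_grid(shape: tuple[int, int], centers: np.ndarray) -> np.ndarray:
    """Per-pixel distance to the nearest nucleus centre (inf if none)."""
    dist = np.full(shape, np.inf)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers:
        d = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
        np.minimum(dist, d, out=dist)
    return dist


def _target_fraction_stain(
    params: SynthParams,
    rng: np.random.Generator,
    islet: np.ndarray,
    dist: np.ndarray,
) -> np.ndarray:
    """Lay down stained discs to hit the requested fraction exactly."""
    margin = _STAIN_MARGIN_FACTOR * params.nucleus_radius
    candidates = islet & (dist > margin)
    islet_area = int(islet.sum())
    n_target = int(round(params.target_stained_fraction * islet_area))
    n_avail = int(candidates.sum())
    if n_target > n_avail:
        raise GenerationError(
            f"target stained fraction {params.target_stained_fraction} needs "
            f"{n_target} px but only {n_avail} non-nuclear islet px are available"
        )
    stained = np.zeros_like(islet)
    if n_target == 0:
        return stained
    cand_idx = np.flatnonzero(candidates)
    blob_r = max(2.0, params.nucleus_radius)
    h, w = islet.shape
    count = 0
    guard = 0
    while count < n_target:
        guard += 1
        if guard > 100000:
            raise GenerationError("stain placement failed to converge")
        seed_flat = int(cand_idx[rng.integers(len(cand_idx))])
        r0, c0 = divmod(seed_flat, w)
        rr0 = max(0, int(r0 - blob_r))
        rr1 = min(h, int(r0 + blob_r) + 1)
        cc0 = max(0, int(c0 - blob_r))
        cc1 = min(w, int(c0 + blob_r) + 1)
        ii, jj = np.ogrid[rr0:rr1, cc0:cc1]
        disc = (ii - r0) ** 2 + (jj - c0) ** 2 <= blob_r**2
        window = candidates[rr0:rr1, cc0:cc1] & disc & ~stained[rr0:rr1, cc0:cc1]
        new = int(window.sum())
        if new == 0:
            continue
        if count + new > n_target:
            # trim the last disc to land exactly on the target count
            flat = np.flatnonzero(window)
            keep = flat[: n_target - count]
            trimmed = np.zeros_like(window)
            trimmed.ravel()[keep] = True
            window = trimmed
            new = n_target - count
        stained[rr0:rr1, cc0:cc1] |= window
        count += new
    return stained


def _illumination_field(
    params: SynthParams, rng: np.random.Generator
) -> np.ndarray | None:
    """Smooth multiplicative field in [1-g, 1+g], a low-order polynomial."""
    g = params.illumination_gradient
    if g == 0:
        return None
    u = np.linspace(-1.0, 1.0, params.width)[None, :]
    v = np.linspace(-1.0, 1.0, params.height)[:, None]
    coef = rng.uniform(-1.0, 1.0, size=4)
    poly = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * (u**2 - v**2)
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + g * poly


def generate_islet(
    params: SynthParams,
) -> tuple[ChannelStack, IsletMask, SynthGroundTruth]:
    """Generate one synthetic islet image with ground truth.

    Identical parameters (including the seed) give bit-identical output.
    Raises :class:`~isletquant.errors.GenerationError` when the requested
    nucleus packing or stained fraction is infeasible.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    center = params.islet_center or ((params.height - 1) / 2.0, (params.width - 1) / 2.0)

    islet = _ellipse_mask(shape, center, params.islet_axes)
    if not islet.any():
        raise GenerationError("islet ellipse lies outside the canvas")

    centers = _place_nuclei(params, rng, center)
    n = len(centers)
    n_beta = int(round(params.beta_fraction * n))
    order = rng.permutation(n)
    classes = [ALPHA] * n
    for i in order[:n_beta]:
        classes[i] = BETA

    dist = _distance_grid(shape, centers)
    nuclei_mask = (dist <= params.nucleus_radius) & np.isfinite(dist)

    # --- DAPI layer: Gaussian blob per nucleus -------------------------
    dapi = np.full(shape, params.background_level)
    sigma = params.nucleus_radius / 2.0
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers:
        blob = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma**2))
        dapi = np.maximum(dapi, params.background_level
                          + (params.dapi_level - params.background_level) * blob)

    # --- stained masks -------------------------------------------------
    stained488 = np.zeros(shape, dtype=bool)
    stained555 = np.zeros(shape, dtype=bool)
    if params.target_stained_fraction is not None:
        stained488 = _target_fraction_stain(params, rng, islet, dist)
    outer = params.nucleus_radius + params.annulus_width
    for (r, c), label in zip(centers, classes):
        if params.target_stained_fraction is not None and label == BETA:
            continue  # 488 handled by the target-fraction layer
        d = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
        annulus = (d > params.nucleus_radius) & (d <= outer) & islet & ~nuclei_mask
        if label == BETA:
            frac = params.stain_fraction_per_beta
            if frac < 1.0:
                idx = np.flatnonzero(annulus)
                take = rng.permutation(len(idx))[: int(round(frac * len(idx)))]
                annulus = np.zeros_like(annulus)
                annulus.ravel()[idx[take]] = True
            stained488 |= annulus
        else:
            stained555 |= annulus

    islet_area = int(islet.sum())
    true_frac = int((stained488 & islet & ~nuclei_mask).sum()) / islet_area

    # --- image formation ----------------------------------------------
    ch488 = np.where(stained488, params.stain_level, params.background_level)
    ch555 = np.where(stained555, params.stain_level, params.background_level)
    field = _illumination_field(params, rng)
    layers = []
    for clean in (dapi, ch488, ch555):
        img = clean if field is None else clean * field
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=shape)
        layers.append(np.clip(img, 0.0, 1.0))

    stack = ChannelStack(dapi=layers[0], target488=layers[1], counter555=layers[2])
    truth = SynthGroundTruth(
        nuclei_centers=centers,
        cell_class=tuple(classes),
        islet_mask=islet,
        nuclei_mask=nuclei_mask,
        stained_mask_488=stained488,
        stained_mask_555=stained555,
        true_stained_fraction=true_frac,
    )
    return stack, IsletMask(islet), truth


def generate_cohort(
    n_nd: int = 20,
    n_t2d: int = 20,
    islets_per_patient: int = 9,
    effect: float = 0.8,
    noise: float = 0.3,
    seed: int = 0,
    nd_mean_score: float = 1.8,
    bmi_nd: tuple[float, float] = (26.0, 3.0),
    bmi_t2d: tuple[float, float] = (30.0, 4.0),
    bmi_slope: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic two-group cohort of per-islet area scores.

    Per-islet scores are drawn around the group mean (ND at
    ``nd_mean_score``, T2D lower by ``effect`` score units) with
    between-islet standard deviation ``noise``, clipped to [0, 3]. BMI is
    drawn per patient from group-specific normals (defaults mirror the
    study cohort's printed means/SDs); an optional ``bmi_slope`` couples
    the patient's latent score to BMI for regression experiments.

    Returns a DataFrame with one row per islet
    (``patient_id, group, bmi, islet, area_score``) and a truth record of
    all latent means.
    """
    if n_nd < 2 or n_t2d < 2:
        raise ParameterError("need at least 2 patients per group")
    if islets_per_patient < 1:
        raise ParameterError("islets_per_patient must be >= 1")
    if noise < 0:
        raise ParameterError("noise must be >= 0")
    t2d_mean = nd_mean_score - effect
    for name, mean in (("ND", nd_mean_score), ("T2D", t2d_mean)):
        if not 0.0 <= mean <= 3.0:
            raise ParameterError(
                f"{name} group mean {mean} leaves the [0,3] score range; "
                "reduce the effect or move nd_mean_score"
            )
    rng = np.random.default_rng(seed)
    rows = []
    latent: dict[str, float] = {}
    for group, n_pat, gmean, (bmi_m, bmi_s) in (
        ("ND", n_nd, nd_mean_score, bmi_nd),
        ("T2D", n_t2d, t2d_mean, bmi_t2d),
    ):
        for i in range(n_pat):
            pid = f"S{group}{i + 1:03d}"
            bmi = float(rng.normal(bmi_m, bmi_s))
            mu = gmean + bmi_slope * (bmi - bmi_m)
            latent[pid] = mu
            scores = np.clip(rng.normal(mu, noise, size=islets_per_patient), 0.0, 3.0)
            for k, s in enumerate(scores):
                rows.append(
                    {"patient_id": pid, "group": group, "bmi": bmi,
                     "islet": k, "area_score": float(s)}
                )
    df = pd.DataFrame(rows)
    truth = {
        "nd_mean": nd_mean_score,
        "t2d_mean": t2d_mean,
        "effect": effect,
        "noise": noise,
        "bmi_slope": bmi_slope,
        "patient_means": latent,
    }
    return df, truth
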