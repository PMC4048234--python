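"""Value types shared across the pipeline stages.

All image grids are 2-D ``float64`` arrays with intensities in ``[0, 1]``;
masks are boolean arrays co-registered with their channels. Physical units
enter only through ``pixel_size`` (µm per pixel edge), which is optional
everywhere: all core quantities are defined in pixel units first.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyIsletError, FormatError

#: Channel role names, in canonical order.
ROLES = ("dapi", "target488", "counter555")


def _check_grid(name: str, grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise FormatError(f"{name} must be a 2-D grid, got ndim={grid.ndim}")
    if grid.size == 0:
        raise FormatError(f"{name} is empty")
    lo, hi = float(grid.min()), float(grid.max())
    if lo < 0.0 or hi > 1.0:
        raise FormatError(f"{name} intensities must lie in [0,1], got [{lo}, {hi}]")
    return grid


@dataclass(frozen=True)
class ChannelStack:
    """Three co-registered fluorescence layers of one islet picture.

    ``dapi`` carries the nuclear counterstain, ``target488`` the β-cell
    marker (TMEM27, BACE2 or insulin) and ``counter555`` the α-cell
    counterstain (glucagon).
    """

    dapi: np.ndarray
    target488: np.ndarray
    counter555: np.ndarray
    pixel_size: float | None = None  # µm per pixel edge

    def __post_init__(self) -> None:
        object.__setattr__(self, "dapi", _check_grid("dapi", self.dapi))
        object.__setattr__(self, "target488", _check_grid("target488", self.target488))
        object.__setattr__(self, "counter555", _check_grid("counter555", self.counter555))
        if not (self.dapi.shape == self.target488.shape == self.counter555.shape):
            raise FormatError(
                "channel shapes differ: "
                f"{self.dapi.shape}, {self.target488.shape}, {self.counter555.shape}"
            )

    @property
    def height(self) -> int:
        return self.dapi.shape[0]

    @property
    def width(self) -> int:
        return self.dapi.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    def channel(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise FormatError(f"unknown channel role {role!r}; expected one of {ROLES}")
        return getattr(self, role)


@dataclass(frozen=True)
class IsletMask:
    """Binary mask of the manually segmented islet."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise FormatError(f"islet mask must be 2-D, got ndim={mask.ndim}")
        mask = mask.astype(bool)
        if not mask.any():
            raise EmptyIsletError("islet mask contains no foreground pixels")
        object.__setattr__(self, "mask", mask)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class NucleusSet:
    """Detected cell nuclei: sub-pixel centroids plus the combined pixel mask."""

    centroids: np.ndarray          # (n, 2) float array of (row, col)
    nuclei_mask: np.ndarray        # boolean grid, union of nucleus regions
    areas_px: np.ndarray = field(default=None)  # per-nucleus pixel areas

    def __post_init__(self) -> None:
        cent = np.asarray(self.centroids, dtype=np.float64).reshape(-1, 2)
        mask = np.asarray(self.nuclei_mask).astype(bool)
        if mask.ndim != 2:
            raise FormatError("nuclei_mask must be 2-D")
        h, w = mask.shape
        if cent.size and (
            cent[:, 0].min() < 0 or cent[:, 0].max() > h - 1
            or cent[:, 1].min() < 0 or cent[:, 1].max() > w - 1
        ):
            raise FormatError("a centroid lies outside image bounds")
        areas = self.areas_px
        if areas is None:
            areas = np.zeros(len(cent), dtype=int)
        areas = np.asarray(areas, dtype=int)
        if len(areas) != len(cent):
            raise FormatError("areas_px length must match centroid count")
        object.__setattr__(self, "centroids", cent)
        object.__setattr__(self, "nuclei_mask", mask)
        object.__setattr__(self, "areas_px", areas)

    @property
    def n(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class StainMap:
    """Result of the adaptive stain/background separation of one channel.

    ``cluster_centers`` is the (background, staining) pair of final cluster
    centres of the 1-D two-cluster k-means on the intensity histogram.
    ``threshold`` is the effective pixel threshold (left edge of the first
    stained histogram bin): a pixel is stained iff its intensity is
    ``>= threshold``. A ``degenerate`` map (near-constant image) marks every
    pixel as background and carries ``threshold = inf``.
    """

    stained_mask: np.ndarray
    threshold: float
    cluster_centers: tuple[float, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        mask = np.asarray(self.stained_mask).astype(bool)
        object.__setattr__(self, "stained_mask", mask)
        if not self.degenerate:
            bg, st = self.cluster_centers
            if not bg < st:
                raise FormatError(
                    f"background centre {bg} must be below staining centre {st}"
                )


#: Cell labels emitted by the patch-vote classifier.
BETA, ALPHA, UNCLASSIFIED = "beta", "alpha", "unclassified"


@dataclass(frozen=True)
class CellClassification:
    """Per-nucleus α/β call from majority voting on stained patch pixels."""

    labels: tuple[str, ...]
    counts488: np.ndarray
    counts555: np.ndarray
    patch_radius: float

    def __post_init__(self) -> None:
        c488 = np.asarray(self.counts488, dtype=int)
        c555 = np.asarray(self.counts555, dtype=int)
        if not (len(self.labels) == len(c488) == len(c555)):
            raise FormatError("labels and patch counts must have equal length")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts488", c488)
        object.__setattr__(self, "counts555", c555)

    @property
    def n_beta(self) -> int:
        return sum(1 for l in self.labels if l == BETA)

    @property
    def n_alpha(self) -> int:
        return sum(1 for l in self.labels if l == ALPHA)

    @property
    def n_unclassified(self) -> int:
        return sum(1 for l in self.labels if l == UNCLASSIFIED)


@dataclass(frozen=True)
class IsletFeatures:
    """Per-islet output of the automated pipeline.

    ``area_score`` is the stained non-nuclear pixel fraction of the islet
    mapped linearly onto the pathologist's [0, 3] scale; ``beta_density`` is
    β-cells per 10⁴ px² (and per mm² when the pixel size is known).
    """

    area_score: float
    stained_fraction: float
    islet_size_px: int
    islet_size_um2: float | None
    n_beta: int
    n_alpha: int
    n_unclassified: int
    beta_density: float                 # β-cells per 10^4 px²
    beta_density_per_mm2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_score <= 3.0:
            raise FormatError(f"area_score {self.area_score} outside [0,3]")
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise FormatError("stained_fraction outside [0,1]")
        if self.beta_density < 0:
            raise FormatError("beta_density must be non-negative")


#: Closed vocabularies for the cohort metadata table.
GROUPS = ("ND", "T2D")
GENDERS = ("M", "F")
SOURCES = ("Surgery", "Autopsy", "Cadaveric donor")
LOCATIONS = ("head", "body", "tail", "not specified")
MARKERS = ("tmem27", "bace2", "insulin")


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical cohort table."""

    patient_id: str
    group: str
    gender: str
    age: float
    bmi: float
    treatment: str
    source: str
    location: str
    n_islets_tmem27: int
    n_islets_bace2: int
    n_islets_insulin: int

    def __post_init__(self) -> None:
        from .errors import ValidationError

        if self.group not in GROUPS:
            raise ValidationError(f"{self.patient_id}: unknown group {self.group!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"{self.patient_id}: unknown gender {self.gender!r}")
        if self.source not in SOURCES:
            raise ValidationError(f"{self.patient_id}: unknown source {self.source!r}")
        if self.location not in LOCATIONS:
            raise ValidationError(
                f"{self.patient_id}: unknown location {self.location!r}"
            )
        for name in ("n_islets_tmem27", "n_islets_bace2", "n_islets_insulin"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(
                    f"{self.patient_id}: {name} must be a non-negative integer, got {v}"
                )
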