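"""Image, mask and table input/output.

Reads composite RGB or three-file fluorescence images (TIFF/PNG, 8- or
16-bit), binary islet masks, the cohort metadata table, and writes/reads
the per-islet features table. Integer images are normalised to ``[0, 1]``
by dividing by their dtype maximum, so downstream thresholds are
bit-depth independent.

The default plane-to-role mapping follows the standard fluorophore
display convention: red → 555 counterstain, green → 488 target,
blue → DAPI. It is configuration-driven and can be permuted freely.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import (
    EmptyIsletError,
    FormatError,
    InputError,
    ParameterError,
    ValidationError,
)
from .types import ROLES, ChannelStack, IsletFeatures, IsletMask, PatientRecord

#: role → plane index in an RGB composite (red=0, green=1, blue=2)
DEFAULT_CHANNEL_MAP: dict[str, int] = {"counter555": 0, "target488": 1, "dapi": 2}

_FEATURE_COLUMNS = [
    "patient_id",
    "area_score",
    "stained_fraction",
    "islet_size_px",
    "islet_size_um2",
    "n_beta",
    "n_alpha",
    "n_unclassified",
    "beta_density",
    "beta_density_per_mm2",
]


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            return np.asarray(tifffile.imread(path))
        return np.asarray(Image.open(path))
    except InputError:
        raise
    except Exception as exc:  # corrupt file, unknown codec
        raise FormatError(f"cannot decode image {path}: {exc}") from exc


def _normalize(arr: np.ndarray, origin: str) -> np.ndarray:
    """Map an integer image onto [0,1] by its dtype maximum; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    if np.issubdtype(arr.dtype, np.bool_):
        return arr.astype(np.float64)
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise FormatError(f"{origin}: float image intensities must lie in [0,1]")
    return arr


def _validate_channel_map(channel_map: Mapping[str, int] | None) -> dict[str, int]:
    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    if set(cmap) != set(ROLES) or sorted(cmap.values()) != [0, 1, 2]:
        raise ParameterError(
            f"channel map must assign roles {ROLES} to planes 0..2, got {cmap}"
        )
    return cmap


def load_channels(
    path,
    layout: str = "rgb_composite",
    channel_map: Mapping[str, int] | None = None,
    pixel_size: float | None = None,
) -> ChannelStack:
    """Load one islet picture as a three-channel stack.

    Parameters
    ----------
    path
        For ``layout="rgb_composite"``: one 3-plane image file. For
        ``layout="three_files"``: a mapping ``{role: path}`` or a sequence
        of three single-plane files in role order
        (``dapi``, ``target488``, ``counter555``).
    layout
        ``"rgb_composite"`` or ``"three_files"``.
    channel_map
        Role → plane index for the composite layout; defaults to
        red→counter555, green→target488, blue→dapi.
    pixel_size
        Physical pixel edge length in µm, attached to the stack.
    """
    if layout == "rgb_composite":
        cmap = _validate_channel_map(channel_map)
        arr = _read_array(path)
        if arr.ndim != 3:
            raise FormatError(f"{path}: composite image must have 3 planes, got shape {arr.shape}")
        if arr.shape[-1] == 3:
            planes = [arr[..., i] for i in range(3)]
        elif arr.shape[0] == 3:
            planes = [arr[i] for i in range(3)]
        else:
            raise FormatError(f"{path}: cannot identify a 3-plane axis in shape {arr.shape}")
        grids = {role: _normalize(planes[idx], str(path)) for role, idx in cmap.items()}
    elif layout == "three_files":
        if isinstance(path, Mapping):
            try:
                paths = {role: path[role] for role in ROLES}
            except KeyError as exc:
                raise ParameterError(f"three_files mapping missing role {exc}") from exc
        elif isinstance(path, Sequence) and not isinstance(path, (str, Path)):
            if len(path) != 3:
                raise ParameterError("three_files layout expects exactly three paths")
            paths = dict(zip(ROLES, path))
        else:
            raise ParameterError("three_files layout expects a mapping or a 3-sequence of paths")
        grids = {}
        for role, p in paths.items():
            a = _read_array(p)
            if a.ndim != 2:
                raise FormatError(f"{p}: single-channel image must be 2-D, got shape {a.shape}")
            grids[role] = _normalize(a, str(p))
    else:
        raise ParameterError(f"unknown layout {layout!r}")
    return ChannelStack(pixel_size=pixel_size, **grids)


def save_channels(
    stack: ChannelStack,
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    dtype=np.uint16,
) -> None:
    """Write a stack as an RGB composite (TIFF any depth, PNG 8-bit only).

    Quantisation inverts :func:`load_channels` exactly, so load → save →
    load is the identity for images that originated as 8/16-bit files.
    """
    cmap = _validate_channel_map(channel_map)
    path = Path(path)
    info = np.iinfo(dtype)
    planes = np.empty((stack.height, stack.width, 3), dtype=dtype)
    for role, idx in cmap.items():
        planes[..., idx] = np.round(stack.channel(role) * info.max).astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, planes)
    else:
        if dtype != np.uint8:
            raise ParameterError("PNG composites are written as 8-bit; use TIFF for 16-bit")
        Image.fromarray(planes, mode="RGB").save(path)


def load_islet_mask(path: str | Path, dims: tuple[int, int]) -> IsletMask:
    """Load the pathologist's islet segmentation; any nonzero pixel is islet."""
    arr = _read_array(path)
    if arr.ndim == 3:  # tolerate RGB masks: any nonzero plane marks islet
        arr = arr.max(axis=-1 if arr.shape[-1] in (3, 4) else 0)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-plane, got shape {arr.shape}")
    if tuple(arr.shape) != tuple(dims):
        raise FormatError(f"{path}: mask shape {arr.shape} does not match expected {tuple(dims)}")
    mask = arr > 0
    if not mask.any():
        raise EmptyIsletError(f"{path}: islet mask is empty")
    return IsletMask(mask)


def save_islet_mask(islet: IsletMask, path: str | Path) -> None:
    arr = (islet.mask.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def load_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read the cohort metadata CSV into validated patient records."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str, "treatment": str}, keep_default_na=False)
    missing = [c for c in PatientRecord.__dataclass_fields__ if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    group=str(row["group"]),
                    gender=str(row["gender"]),
                    age=float(row["age"]),
                    bmi=float(row["bmi"]),
                    treatment=str(row["treatment"]),
                    source=str(row["source"]),
                    location=str(row["location"]),
                    n_islets_tmem27=int(row["n_islets_tmem27"]),
                    n_islets_bace2=int(row["n_islets_bace2"]),
                    n_islets_insulin=int(row["n_islets_insulin"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
        except ValueError as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: table has no data rows")
    return records


def load_reference_cohort() -> list[PatientRecord]:
    """Load the packaged transcription of the study's clinical cohort table."""
    with resources.as_file(resources.files("isletquant.data") / "table1.csv") as p:
        return load_cohort_table(p)


def write_features_table(
    records: Sequence[tuple[str, IsletFeatures]], path: str | Path
) -> None:
    """Write one CSV row per islet: ``(patient_id, features)`` pairs.

    Column order is stable; values round-trip through
    :func:`read_features_table` to better than 1e-6.
    """
    if not records:
        raise ParameterError("cannot write an empty features table")
    rows = []
    for patient_id, feats in records:
        d = asdict(feats)
        d["patient_id"] = patient_id
        rows.append(d)
    df = pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
    try:
        df.to_csv(path, index=False, float_format="%.8g")
    except OSError as exc:
        raise InputError(f"cannot write features table to {path}: {exc}") from exc


def read_features_table(path: str | Path) -> pd.DataFrame:
    """Read a per-islet features CSV back into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns {missing}")
    return df
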