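"""HU-valued image I/O and intensity windowing.

Images are Hounsfield-unit arrays: water = 0, air about -1000.  Networks
operate on a linear remap of a configurable HU window onto [-1, 1]; the
default window is [-1000, 1000] HU.  2-D slices are the unit of processing;
a 3-D volume is treated as a stack of axial slices.

Supported formats: NPZ archives (keys ``data``/``spacing``/``window``),
NIfTI via nibabel, 16-bit grayscale PNG with a JSON sidecar declaring its
HU window, and DICOM series directories via pydicom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ContractError, FormatError, GeometryError

__all__ = [
    "ImageVolume",
    "IntensityWindow",
    "DEFAULT_WINDOW",
    "load_volume",
    "save_volume",
    "normalize",
    "denormalize",
]

MODALITY_TAGS = ("pct", "cbct", "scbct")


@dataclass(frozen=True)
class IntensityWindow:
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ConfigurationError("window requires low < high")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


DEFAULT_WINDOW = IntensityWindow(-1000.0, 1000.0)


@dataclass
class ImageVolume:
    """A HU-valued 2-D slice or 3-D axial stack with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple = None
    modality_tag: str = "pct"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ContractError("data must be 2-D (H, W) or 3-D (D, H, W)")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("image contains non-finite values")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ContractError("spacing length must match dimensionality")
        if self.modality_tag not in MODALITY_TAGS:
            raise ContractError(f"modality_tag must be one of {MODALITY_TAGS}")

    @property
    def shape(self):
        return self.data.shape

    def slices(self):
        """Iterate 2-D slices (a 2-D volume yields itself once)."""
        if self.data.ndim == 2:
            yield self
        else:
            for i in range(self.data.shape[0]):
                yield ImageVolume(self.data[i], self.spacing[1:], self.modality_tag)

    def require_network_size(self, min_side: int = 8):
        h, w = self.data.shape[-2:]
        if h < min_side or w < min_side:
            raise ContractError(f"slice size {h}x{w} below minimum {min_side}")


def normalize(img, window: IntensityWindow = DEFAULT_WINDOW) -> np.ndarray:
    """Linear map window.low -> -1, window.high -> +1, clipped outside."""
    data = img.data if isinstance(img, ImageVolume) else np.asarray(img, dtype=np.float64)
    x = (data - window.center) / (window.width / 2.0)
    return np.clip(x, -1.0, 1.0)


def denormalize(x, window: IntensityWindow = DEFAULT_WINDOW,
                modality_tag: str = "scbct", spacing=None) -> ImageVolume:
    """Inverse of :func:`normalize` on the clipped range."""
    x = np.asarray(x, dtype=np.float64)
    hu = np.clip(x, -1.0, 1.0) * (window.width / 2.0) + window.center
    return ImageVolume(hu, spacing=spacing, modality_tag=modality_tag)


# ---------------------------------------------------------------------------
# format back-ends
# ---------------------------------------------------------------------------

def _load_npz(path: Path) -> ImageVolume:
    with np.load(path) as f:
        if "data" not in f:
            raise FormatError(f"{path}: missing 'data' key")
        data = f["data"]
        spacing = tuple(f["spacing"]) if "spacing" in f else None
        tag = str(f["modality_tag"]) if "modality_tag" in f else "pct"
    return ImageVolume(data, spacing, tag)


def _save_npz(path: Path, vol: ImageVolume, window: IntensityWindow):
    np.savez(
        path,
        data=vol.data.astype(np.float32),
        spacing=np.asarray(vol.spacing),
        window=np.asarray([window.low, window.high]),
        modality_tag=np.asarray(vol.modality_tag),
    )


def _load_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[: data.ndim]
    return ImageVolume(data, tuple(zooms))


def _save_nifti(path: Path, vol: ImageVolume):
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0] * (4 - len(vol.spacing)))
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def _load_png(path: Path) -> ImageVolume:
    import imageio.v3 as iio

    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing window sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    window = IntensityWindow(*meta["window"])
    raw = iio.imread(path).astype(np.float64)
    maxval = float(meta.get("max_value", 65535))
    hu = raw / maxval * window.width + window.low
    return ImageVolume(hu, meta.get("spacing"))


def _save_png(path: Path, vol: ImageVolume, window: IntensityWindow):
    import imageio.v3 as iio

    if vol.data.ndim != 2:
        raise FormatError("PNG export supports single slices only")
    x = np.clip((vol.data - window.low) / window.width, 0.0, 1.0)
    iio.imwrite(path, np.round(x * 65535).astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "window": [window.low, window.high],
        "max_value": 65535,
        "spacing": list(vol.spacing),
    }))


def _load_dicom_dir(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise FormatError(f"{path}: no DICOM files found")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        order = int(getattr(ds, "InstanceNumber", len(slices)))
        slices.append((order, arr * slope + intercept, ds))
    slices.sort(key=lambda s: s[0])
    shapes = {s[1].shape for s in slices}
    if len(shapes) > 1:
        raise GeometryError(f"{path}: mixed slice sizes {sorted(shapes)}")
    ds = slices[0][2]
    px = getattr(ds, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(ds, "SliceThickness", 1.0))
    data = np.stack([s[1] for s in slices])
    return ImageVolume(data, (dz, float(px[0]), float(px[1])))


_EXT_FORMAT = {
    ".npz": "npz",
    ".nii": "nifti",
    ".gz": "nifti",
    ".png": "png",
}


def _infer_format(path: Path, fmt):
    if fmt is not None:
        return fmt
    if path.is_dir():
        return "dicom_dir"
    return _EXT_FORMAT.get(path.suffix.lower())


def load_volume(path, format: str | None = None) -> ImageVolume:
    """Read an HU volume; format inferred from the path when not given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    loaders = {
        "npz": _load_npz,
        "nifti": _load_nifti,
        "png": _load_png,
        "dicom_dir": _load_dicom_dir,
    }
    if fmt not in loaders:
        raise FormatError(f"unsupported format for {path}")
    try:
        return loaders[fmt](path)
    except (FormatError, GeometryError, ContractError):
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"failed to read {path}: {exc}") from exc


def save_volume(path, vol: ImageVolume, format: str | None = None,
                window: IntensityWindow = DEFAULT_WINDOW) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        _save_npz(path, vol, window)
    elif fmt == "nifti":
        _save_nifti(path, vol)
    elif fmt == "png":
        _save_png(path, vol, window)
    else:
        raise FormatError(f"unsupported output format for {path}")
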