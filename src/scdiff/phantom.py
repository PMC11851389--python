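"""Synthetic thorax phantoms and CBCT-style artifact fabrication.

The simulator rasterizes additive-ellipse HU phantoms (lung around
-800 HU, soft tissue around 0-60 HU, bone several hundred HU), projects
them with a parallel-beam Radon transform, and reconstructs with filtered
backprojection (both via scikit-image).  CBCT-like degradations are then
layered on: sparse-view reconstruction (streaks), a low-order polynomial
shading field (spatially varying HU bias), a global HU offset, and
additive Gaussian noise.  Training sets are made unpaired by drawing the
pCT and CBCT halves from disjoint synthetic subjects; the test set keeps
its ground-truth pairs for evaluation.

Parallel-beam (not cone-beam) geometry is a deliberate simplification: the
slice-level streak/shading phenomenology it produces is what the
correction method consumes, at a fraction of the cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import radon as _sk_radon
from skimage.transform import iradon as _sk_iradon

from .errors import ConfigurationError, ContractError
from .volumes import ImageVolume

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "ProjectionGeometry",
    "ArtifactSpec",
    "lung_phantom_spec",
    "default_geometry",
    "lung_artifact_spec",
    "make_phantom",
    "radon_project",
    "fbp_reconstruct",
    "make_cbct_from_pct",
    "build_unpaired_dataset",
    "UnpairedDataset",
    "fov_mask",
]

MU_WATER = 0.0205  # 1/mm at ~70 keV; only relative contrast matters here

HU_MIN, HU_MAX = -1000.0, 2000.0


@dataclass(frozen=True)
class Ellipse:
    """Additive ellipse in the unit field of view [-1, 1]^2."""

    center: tuple
    axes: tuple        # semi-axes (a, b) in FOV units
    rotation_deg: float
    hu: float

    def __post_init__(self):
        cx, cy = self.center
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ConfigurationError("ellipse semi-axes must be positive")
        if abs(cx) + max(a, b) > 1.0 + 1e-9 or abs(cy) + max(a, b) > 1.0 + 1e-9:
            raise ConfigurationError("ellipse extends outside the field of view")
        if not HU_MIN <= self.hu <= HU_MAX:
            raise ConfigurationError(f"HU value {self.hu} outside [{HU_MIN}, {HU_MAX}]")


@dataclass(frozen=True)
class PhantomSpec:
    ellipses: tuple
    background: float = -1000.0
    center_jitter: float = 0.0   # per-sample sd of center perturbation (FOV units)
    axes_jitter: float = 0.0     # relative sd of semi-axis perturbation
    hu_jitter: float = 0.0       # sd of HU perturbation
    seed: int = 0


@dataclass(frozen=True)
class ProjectionGeometry:
    n_angles: int = 360
    angle_range: float = 180.0

    def __post_init__(self):
        if self.n_angles < 1:
            raise ConfigurationError("n_angles must be >= 1")

    @property
    def angles(self) -> np.ndarray:
        return np.linspace(0.0, self.angle_range, self.n_angles, endpoint=False)


@dataclass(frozen=True)
class ArtifactSpec:
    sparse_views: int = 45
    shading_amplitude: float = 40.0  # HU
    hu_offset: float = 25.0          # HU
    noise_sigma: float = 20.0        # HU
    seed: int = 0

    def __post_init__(self):
        if self.sparse_views < 4:
            raise ConfigurationError("sparse_views must be >= 4")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be nonnegative")


def lung_phantom_spec(seed: int = 0, jitter: bool = True) -> PhantomSpec:
    """Simplified axial thorax: body, two lungs, spine, sternum, nodules."""
    ellipses = (
        Ellipse((0.0, 0.0), (0.88, 0.64), 0.0, 1040.0),      # body: -1000 -> +40
        Ellipse((-0.38, 0.02), (0.32, 0.42), 8.0, -840.0),   # left lung -> ~-800
        Ellipse((0.38, 0.02), (0.32, 0.42), -8.0, -840.0),   # right lung -> ~-800
        Ellipse((0.0, 0.48), (0.09, 0.11), 0.0, 660.0),      # spine -> ~700
        Ellipse((0.0, -0.52), (0.12, 0.05), 0.0, 260.0),     # sternum -> ~300
        Ellipse((-0.34, -0.10), (0.05, 0.05), 0.0, 860.0),   # nodule in lung -> ~20
        Ellipse((0.42, 0.18), (0.04, 0.06), 20.0, 880.0),    # nodule -> ~40
    )
    j = 1.0 if jitter else 0.0
    return PhantomSpec(ellipses=ellipses, background=-1000.0,
                       center_jitter=0.02 * j, axes_jitter=0.05 * j,
                       hu_jitter=15.0 * j, seed=seed)


def default_geometry(size: int) -> ProjectionGeometry:
    return ProjectionGeometry(n_angles=max(360, size), angle_range=180.0)


def lung_artifact_spec(seed: int = 0) -> ArtifactSpec:
    """Default degradation preset (sparse views + shading + offset + noise)."""
    return ArtifactSpec(seed=seed)


# ---------------------------------------------------------------------------
# phantom rasterization
# ---------------------------------------------------------------------------

def _pixel_grid(size: int):
    """Pixel-center coordinates with the origin exactly on pixel size // 2."""
    c = (np.arange(size) - size // 2) / (size // 2)
    return np.meshgrid(c, c, indexing="ij")


def _jittered(spec: PhantomSpec, rng: np.random.Generator) -> list[Ellipse]:
    out = []
    for e in spec.ellipses:
        cx, cy = e.center
        a, b = e.axes
        cx = cx + rng.normal(0, spec.center_jitter) if spec.center_jitter else cx
        cy = cy + rng.normal(0, spec.center_jitter) if spec.center_jitter else cy
        if spec.axes_jitter:
            a = a * (1 + rng.normal(0, spec.axes_jitter))
            b = b * (1 + rng.normal(0, spec.axes_jitter))
        hu = e.hu + rng.normal(0, spec.hu_jitter) if spec.hu_jitter else e.hu
        # keep the jittered ellipse inside the FOV and the HU range
        a, b = max(abs(a), 1e-3), max(abs(b), 1e-3)
        allowed = 1.0 - max(abs(cx), abs(cy)) - 1e-6
        if max(a, b) > allowed:
            shrink = allowed / max(a, b)
            a, b = a * shrink, b * shrink
        hu = float(np.clip(hu, HU_MIN, HU_MAX))
        out.append(Ellipse((cx, cy), (a, b), e.rotation_deg, hu))
    return out


def make_phantom(spec: PhantomSpec, size: int,
                 rng: np.random.Generator | None = None,
                 supersample: int = 4) -> ImageVolume:
    """Rasterize the additive-ellipse phantom on a size x size grid.

    Rasterization is supersampled and block-averaged: edge pixels take
    partial-volume values as in real CT, which also keeps the phantom
    band-limited enough for filtered backprojection to reproduce it.
    """
    if size < 32:
        raise ConfigurationError("phantom size must be >= 32")
    ellipses = list(spec.ellipses) if rng is None else _jittered(spec, rng)
    n = size * supersample
    # subpixel centers placed so each block averages around the coarse
    # pixel-center coordinate used by _pixel_grid
    pix = (np.arange(n) + 0.5) / supersample - 0.5
    c = (pix - size // 2) / (size // 2)
    ys, xs = np.meshgrid(c, c, indexing="ij")
    img = np.full((n, n), float(spec.background))
    for e in ellipses:
        cx, cy = e.center
        a, b = e.axes
        phi = np.deg2rad(e.rotation_deg)
        xr = (xs - cx) * np.cos(phi) + (ys - cy) * np.sin(phi)
        yr = -(xs - cx) * np.sin(phi) + (ys - cy) * np.cos(phi)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += e.hu
    if supersample > 1:
        img = img.reshape(size, supersample, size, supersample).mean(axis=(1, 3))
    return ImageVolume(np.clip(img, HU_MIN, HU_MAX), modality_tag="pct")


# ---------------------------------------------------------------------------
# projection / reconstruction
# ---------------------------------------------------------------------------

def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    return MU_WATER * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    return (np.asarray(mu, dtype=np.float64) / MU_WATER - 1.0) * 1000.0


def radon_project(img: ImageVolume, geom: ProjectionGeometry) -> np.ndarray:
    """Parallel-beam sinogram (n_angles x n_detectors) of the HU image.

    The rasterization grid places the object center on pixel ``N // 2``,
    matching the rotation-center convention of the underlying transform.
    """
    data = img.data if isinstance(img, ImageVolume) else np.asarray(img)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise ContractError("radon_project expects a square 2-D slice")
    mu = hu_to_mu(data)
    sino = _sk_radon(mu, theta=geom.angles, circle=False)
    return sino.T  # (n_angles, n_detectors)


def fbp_reconstruct(sinogram: np.ndarray, geom: ProjectionGeometry, size: int) -> ImageVolume:
    """Ramp-filtered backprojection back onto a size x size HU grid."""
    sinogram = np.asarray(sinogram, dtype=np.float64)
    if sinogram.shape[0] != geom.n_angles:
        raise ContractError("sinogram angle count does not match geometry")
    mu = _sk_iradon(sinogram.T, theta=geom.angles, filter_name="ramp",
                    interpolation="cubic", circle=False, output_size=size)
    # reconstruction over/undershoot is kept (clipping would bias the mean)
    return ImageVolume(mu_to_hu(mu), modality_tag="cbct")


def fov_mask(size: int, radius: float = 0.95) -> np.ndarray:
    """Boolean mask of the inscribed circular field of view."""
    ys, xs = _pixel_grid(size)
    return xs**2 + ys**2 <= radius**2


def _shading_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order 2-D polynomial bias field, bounded by `amplitude` HU."""
    if amplitude == 0:
        return np.zeros((size, size))
    ys, xs = _pixel_grid(size)
    basis = [xs, ys, xs * ys, xs**2 - 0.5, ys**2 - 0.5]
    coef = rng.uniform(-1, 1, len(basis))
    fieldv = sum(c * b for c, b in zip(coef, basis))
    peak = np.abs(fieldv).max()
    return amplitude * fieldv / peak if peak > 0 else fieldv


def make_cbct_from_pct(pct: ImageVolume, art: ArtifactSpec,
                       geom: ProjectionGeometry,
                       rng: np.random.Generator | None = None) -> ImageVolume:
    """Degrade a clean slice into a CBCT-like slice (deterministic given seed)."""
    rng = np.random.default_rng(art.seed) if rng is None else rng
    size = pct.data.shape[-1]
    views = min(art.sparse_views, geom.n_angles)
    sparse_geom = ProjectionGeometry(n_angles=views, angle_range=geom.angle_range)
    sino = radon_project(pct, sparse_geom)
    recon = fbp_reconstruct(sino, sparse_geom, size).data
    out = recon + _shading_field(size, art.shading_amplitude, rng) + art.hu_offset
    if art.noise_sigma > 0:
        out = out + rng.normal(0.0, art.noise_sigma, out.shape)
    return ImageVolume(out, spacing=pct.spacing, modality_tag="cbct")


# ---------------------------------------------------------------------------
# unpaired dataset fabrication
# ---------------------------------------------------------------------------

@dataclass
class UnpairedDataset:
    """Unpaired training slices plus a paired test split."""

    train_pct: list
    train_cbct: list
    test_pct: list
    test_cbct: list
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("train_pct", "train_cbct", "test_pct", "test_cbct"):
            vols = getattr(self, name)
            np.savez_compressed(
                out_dir / f"{name}.npz",
                data=np.stack([v.data for v in vols]).astype(np.float32),
            )
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def load(cls, out_dir):
        out_dir = Path(out_dir)
        kwargs = {}
        for name, tag in (("train_pct", "pct"), ("train_cbct", "cbct"),
                          ("test_pct", "pct"), ("test_cbct", "cbct")):
            with np.load(out_dir / f"{name}.npz") as f:
                kwargs[name] = [ImageVolume(d, modality_tag=tag) for d in f["data"]]
        manifest = json.loads((out_dir / "manifest.json").read_text())
        return cls(manifest=manifest, **kwargs)


def build_unpaired_dataset(n_subjects: int, slices_per_subject: int,
                           size: int = 64,
                           phantom: PhantomSpec | None = None,
                           artifact: ArtifactSpec | None = None,
                           geom: ProjectionGeometry | None = None,
                           n_test_subjects: int = 1,
                           seed: int = 0) -> UnpairedDataset:
    """Fabricate unpaired train splits and a paired test split.

    Training pCT and CBCT come from disjoint subject groups (the method
    requires unpaired data); test CBCT slices are derived from their own
    pCT so ground truth is available for evaluation.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects to form an unpaired split")
    phantom = lung_phantom_spec() if phantom is None else phantom
    artifact = lung_artifact_spec() if artifact is None else artifact
    geom = default_geometry(size) if geom is None else geom

    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]

    subjects = []
    for sid, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        pcts, cbcts = [], []
        for _ in range(slices_per_subject):
            pct = make_phantom(phantom, size, rng)
            cbct = make_cbct_from_pct(pct, artifact, geom, rng)
            pcts.append(pct)
            cbcts.append(cbct)
        subjects.append((sid, pcts, cbcts))

    n_train = n_subjects - n_test_subjects
    half = max(1, n_train // 2)
    train_pct = [s for _, pcts, _ in subjects[:half] for s in pcts]
    train_cbct = [s for _, _, cbcts in subjects[half:n_train] for s in cbcts]
    test_pct = [s for _, pcts, _ in subjects[n_train:] for s in pcts]
    test_cbct = [s for _, _, cbcts in subjects[n_train:] for s in cbcts]

    manifest = {
        "seed": seed,
        "size": size,
        "n_subjects": n_subjects,
        "slices_per_subject": slices_per_subject,
        "pct_subjects": [s[0] for s in subjects[:half]],
        "cbct_subjects": [s[0] for s in subjects[half:n_train]],
        "test_subjects": [s[0] for s in subjects[n_train:]],
        "phantom": {"n_ellipses": len(phantom.ellipses),
                    "background": phantom.background,
                    "jitter": [phantom.center_jitter, phantom.axes_jitter,
                               phantom.hu_jitter]},
        "artifact": asdict(artifact),
        "geometry": asdict(geom),
    }
    return UnpairedDataset(train_pct, train_cbct, test_pct, test_cbct, manifest)
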