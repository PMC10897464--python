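"""Digital breast phantom and multi-echo CSE signal simulation.

The phantom is procedural: a half-ellipsoid breast attached to a posterior
chest-wall slab, a subcutaneous-fat shell on the breast surface, an inner
fibroglandular core, adipose tissue elsewhere in the breast, and an optional
spherical tumour.  Ground-truth fat fraction, triglyceride double-bond
content (ndb, nmidb), off-resonance field and R2* are drawn per voxel so the
chemical-shift fitting can be validated against known truth.

Near the tumour the adipose composition is deregulated: ndb is reduced with
an exponential decay in physical distance from the tumour surface, shifting
the fatty-acid balance away from MUFA/PUFA toward SFA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .spectral import TriglycerideSpectrum, NMIDB_COEFF, signal_model

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "PhantomTruth",
    "EchoSeries",
    "generate_phantom",
    "simulate_echo_series",
    "LABELS",
]

#: Tissue label coding shared across the pipeline.
LABELS = {
    "background": 0,
    "chest_wall": 1,
    "subcutaneous_fat": 2,
    "fibroglandular": 3,
    "adipose": 4,
    "tumour": 5,
}

#: Echo timing of the CSE acquisition being emulated (ms).
TE_FIRST_MS = 1.14
TE_SPACING_MS = 1.14
MAX_ECHOES = 174


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue truth distribution: mean/SD of fat fraction, ndb, nmidb
    and a (deterministic) R2* in 1/s."""

    ff_mean: float
    ff_sd: float
    ndb_mean: float
    ndb_sd: float
    nmidb_mean: float
    nmidb_sd: float
    r2star: float


def _default_tissues() -> dict[str, TissueParams]:
    # Breast adipose at ndb 2.0 under nmidb = 0.093 ndb^2 gives
    # MUFA/PUFA/SFA of roughly 0.42/0.12/0.46, typical of postmenopausal
    # breast fat.  Lean tissues carry little fat; their composition values
    # matter only through the small fat signal they contribute.
    adipose = TissueParams(0.90, 0.03, 2.0, 0.10, NMIDB_COEFF * 4.0, 0.02, 45.0)
    return {
        "chest_wall": TissueParams(0.10, 0.03, 2.0, 0.15, 0.37, 0.05, 35.0),
        "subcutaneous_fat": adipose,
        "fibroglandular": TissueParams(0.15, 0.05, 2.0, 0.15, 0.37, 0.05, 30.0),
        "adipose": adipose,
        "tumour": TissueParams(0.05, 0.02, 2.0, 0.15, 0.37, 0.05, 35.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the digital breast phantom.

    Geometry is in millimetres on a grid of ``grid_shape`` voxels with
    ``voxel_spacing_mm`` spacing (defaults match a 64x64 matrix at
    3.75x3.75 mm with 30 slices of 4 mm).  The breast is a half-ellipsoid
    with semi-axes ``breast_semiaxes_mm`` whose flat face sits on the chest
    wall slab of thickness ``chest_wall_mm`` at the posterior (high-y) edge.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 30)
    voxel_spacing_mm: tuple[float, float, float] = (3.75, 3.75, 4.0)
    breast_semiaxes_mm: tuple[float, float, float] = (90.0, 150.0, 52.0)
    chest_wall_mm: float = 22.0
    subcutaneous_mm: float = 7.5
    fibroglandular_fraction: float = 0.45
    tumour_centre_mm: tuple[float, float, float] | None = None
    tumour_radius_mm: float = 10.0
    tissue_composition: Mapping[str, TissueParams] = field(
        default_factory=_default_tissues
    )
    rim_effect_amplitude: float = 0.4   # ndb decrement at the tumour surface
    rim_effect_scale_mm: float = 10.0   # exponential decay length
    field_map_coeffs_hz: tuple[float, ...] = (5.0, 10.0, -8.0, 4.0, 6.0, -5.0, 3.0)
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if self.tumour_radius_mm < 0:
            raise ValueError("tumour radius must be non-negative")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for name, t in self.tissue_composition.items():
            if not 0.0 <= t.ff_mean <= 1.0:
                raise ValueError(f"fat-fraction mean for {name} outside [0, 1]")

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm))


@dataclass
class PhantomTruth:
    """Label volume plus ground-truth parameter volumes on one grid."""

    labels: np.ndarray          # int, coding per LABELS
    fat_fraction: np.ndarray
    ndb: np.ndarray
    nmidb: np.ndarray
    field_hz: np.ndarray
    r2star: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    spec: PhantomSpec | None = None

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


@dataclass
class EchoSeries:
    """Complex 4-D multi-echo image stack (x, y, z, echo)."""

    signal: np.ndarray
    echo_times_ms: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.ndim != 1 or te.size < 1:
            raise ValueError("echo_times_ms must be a 1-D vector")
        if te.size > 1:
            d = np.diff(te)
            if np.any(d <= 0) or not np.allclose(d, d[0]):
                raise ValueError("echo times must be strictly increasing and "
                                 "uniformly spaced")
        if self.signal.shape[-1] != te.size:
            raise ValueError("signal echo axis inconsistent with echo_times_ms")
        self.echo_times_ms = te

    @property
    def n_echoes(self) -> int:
        return self.echo_times_ms.size


def _voxel_centres_mm(shape, spacing):
    """Physical coordinates of voxel centres along each axis."""
    return [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the label volume and ground-truth maps.

    Deterministic for a given ``spec`` (including its ``seed``).  With
    ``tumour_radius_mm == 0`` no tumour is placed (a healthy-control breast).
    Raises ``ValueError`` if the requested tumour sphere is not fully inside
    the breast tissue.
    """
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_mm
    xs, ys, zs = _voxel_centres_mm(shape, spacing)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    fov = spec.fov_mm

    labels = np.zeros(shape, dtype=np.int16)

    # posterior chest-wall slab
    y_chest = fov[1] - spec.chest_wall_mm
    labels[Y >= y_chest] = LABELS["chest_wall"]

    # half-ellipsoid breast anterior of the chest wall
    ax, ay, az = spec.breast_semiaxes_mm
    cx, cz = fov[0] / 2.0, fov[2] / 2.0
    ell = ((X - cx) / ax) ** 2 + ((Y - y_chest) / ay) ** 2 + ((Z - cz) / az) ** 2
    breast = (ell <= 1.0) & (Y < y_chest)
    labels[breast] = LABELS["adipose"]

    # subcutaneous shell: breast voxels within subcutaneous_mm of the
    # anterior breast surface (distance measured inside the breast mask,
    # chest side excluded so the shell follows the skin only)
    interior = breast | (Y >= y_chest)
    depth = ndimage.distance_transform_edt(interior, sampling=spacing)
    subcut = breast & (depth <= spec.subcutaneous_mm)
    labels[subcut] = LABELS["subcutaneous_fat"]

    # fibroglandular core: scaled inner ellipsoid biased toward the chest
    f = spec.fibroglandular_fraction
    y_fg = y_chest - 0.35 * ay
    fg = (((X - cx) / (f * ax)) ** 2
          + ((Y - y_fg) / (f * ay)) ** 2
          + ((Z - cz) / (f * az)) ** 2) <= 1.0
    fg &= labels == LABELS["adipose"]
    labels[fg] = LABELS["fibroglandular"]

    # tumour sphere
    if spec.tumour_radius_mm > 0:
        if spec.tumour_centre_mm is None:
            centre = (cx, y_chest - 0.45 * ay, cz)
        else:
            centre = spec.tumour_centre_mm
        r = np.sqrt((X - centre[0]) ** 2 + (Y - centre[1]) ** 2
                    + (Z - centre[2]) ** 2)
        tum = r <= spec.tumour_radius_mm
        if not tum.any():
            raise ValueError("tumour sphere covers no voxel centres")
        inside = np.isin(labels[tum],
                         [LABELS["adipose"], LABELS["fibroglandular"],
                          LABELS["subcutaneous_fat"]])
        if not inside.all():
            raise ValueError("tumour sphere extends outside the breast")
        labels[tum] = LABELS["tumour"]

    rng = np.random.default_rng(spec.seed)
    fat_fraction = np.zeros(shape)
    ndb = np.zeros(shape)
    nmidb = np.zeros(shape)
    r2star = np.zeros(shape)
    for name, code in LABELS.items():
        if name == "background":
            continue
        t = spec.tissue_composition[name]
        m = labels == code
        n = int(m.sum())
        if n == 0:
            continue
        fat_fraction[m] = np.clip(rng.normal(t.ff_mean, t.ff_sd, n), 0.0, 1.0)
        ndb[m] = np.maximum(rng.normal(t.ndb_mean, t.ndb_sd, n), 0.0)
        nmidb[m] = np.maximum(rng.normal(t.nmidb_mean, t.nmidb_sd, n), 0.0)
        r2star[m] = t.r2star

    # peri-tumoural composition shift: ndb decremented by
    # amplitude * exp(-d / scale), d = distance to the tumour surface;
    # nmidb follows quadratically so the empirical relation keeps its shape.
    if spec.tumour_radius_mm > 0 and spec.rim_effect_amplitude != 0.0:
        tum_mask = labels == LABELS["tumour"]
        dist = ndimage.distance_transform_edt(~tum_mask, sampling=spacing)
        affected = np.isin(labels, [LABELS["adipose"], LABELS["fibroglandular"],
                                    LABELS["subcutaneous_fat"]])
        shift = spec.rim_effect_amplitude * np.exp(-dist / spec.rim_effect_scale_mm)
        old = ndb[affected]
        new = np.maximum(old - shift[affected], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio2 = np.where(old > 0, (new / np.maximum(old, 1e-12)) ** 2, 0.0)
        ndb[affected] = new
        nmidb[affected] = nmidb[affected] * ratio2

    # composition fractions must be realisable: 2 nmidb <= ndb
    nmidb = np.minimum(nmidb, ndb / 2.0)

    # smooth off-resonance field: polynomial in normalised coordinates
    u = 2.0 * X / fov[0] - 1.0
    v = 2.0 * Y / fov[1] - 1.0
    w = 2.0 * Z / fov[2] - 1.0
    basis = [np.ones_like(u), u, v, w, u * u, v * v, w * w, u * v, u * w, v * w]
    field_hz = np.zeros(shape)
    for c, b in zip(spec.field_map_coeffs_hz, basis):
        field_hz += c * b

    return PhantomTruth(labels, fat_fraction, ndb, nmidb, field_hz, r2star,
                        spacing, spec)


def echo_times_ms(n_echoes: int) -> np.ndarray:
    """Echo-time vector: first echo 1.14 ms, spacing 1.14 ms."""
    if not 1 <= n_echoes <= MAX_ECHOES:
        raise ValueError(f"n_echoes must be in [1, {MAX_ECHOES}]")
    return TE_FIRST_MS + TE_SPACING_MS * np.arange(n_echoes)


def simulate_echo_series(truth: PhantomTruth,
                         spectrum: TriglycerideSpectrum | None = None,
                         n_echoes: int = 16,
                         snr: float | None = None,
                         seed: int = 0) -> EchoSeries:
    """Simulate the multi-echo complex signal from ground truth.

    Per voxel the noiseless signal is

        s(TE) = [W + F c(TE; CL, ndb, nmidb)] exp(i 2 pi psi TE) exp(-R2* TE)

    with W = 1 - fat_fraction and F = fat_fraction.  i.i.d. complex Gaussian
    noise is added with standard deviation (mean adipose first-echo
    magnitude) / snr per real/imaginary channel; ``snr=np.inf`` gives a
    noiseless series.  Slices share the phantom's single field map
    (a 2-D multi-slice acquisition).
    """
    if spectrum is None:
        spectrum = TriglycerideSpectrum()
    if n_echoes < 3:
        raise ValueError("at least 3 echoes are required")
    te = echo_times_ms(n_echoes)
    if snr is None:
        snr = truth.spec.snr if truth.spec is not None else 50.0

    tissue = truth.labels > 0
    ff = truth.fat_fraction
    sig = np.zeros(truth.labels.shape + (n_echoes,), dtype=complex)
    sig[tissue] = signal_model(1.0 - ff[tissue], ff[tissue],
                               truth.ndb[tissue], truth.nmidb[tissue],
                               truth.field_hz[tissue], truth.r2star[tissue],
                               te, spectrum)

    if np.isfinite(snr):
        adipose = truth.tissue_mask("adipose")
        ref = np.abs(sig[..., 0])[adipose].mean() if adipose.any() else 1.0
        sd = ref / snr
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sd, sig.shape) + 1j * rng.normal(0.0, sd, sig.shape)
        sig = sig + noise

    return EchoSeries(sig, te, truth.voxel_spacing_mm)
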