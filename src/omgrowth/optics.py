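"""Virtual widefield fluorescence microscope for simulated membranes.

The light-labelled material on the unwrapped strip is rasterized at
sub-pixel resolution as fluorophore density, wrapped onto the 3D cylinder
(so each surface element acquires a defocus equal to its height above the
focal plane through the cylinder axis), convolved slice-by-slice with a
defocus-dependent point-spread function, integrated onto camera pixels and
optionally degraded with shot and read noise.

The default PSF is the defocused-Gaussian approximation of a widefield
objective: lateral width sigma(z) = sigma0*sqrt(1 + (z/z_R)^2) with
sigma0 = 0.21*lambda/NA and z_R = 2*lambda*n/NA^2 (n = 1.515 immersion),
with an in-focus kernel of unit integral attenuated by a Strehl-like factor
1/(1 + (z/z_R)^2) out of focus. Defaults mirror a 100X/1.4NA objective at
575 nm emission on a camera with 6.8 µm pixels (68 nm in the sample plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .flowfield import CylinderGeom, unwrap_ring

__all__ = [
    "OpticsConfig",
    "NoiseModel",
    "Micrograph",
    "psf_sigma",
    "psf_kernel",
    "render_micrograph",
    "apply_camera_noise",
    "save_tiff",
]

IMMERSION_INDEX = 1.515


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise on the signal, then Gaussian read noise.

    ``photon_scale`` converts labelled area to expected photon counts
    (counts per µm² of labelled material); ``read_noise`` is the additive
    Gaussian sd in counts; ``offset`` a constant background level.
    """

    photon_scale: float = 5.0e4
    read_noise: float = 2.0
    offset: float = 100.0


@dataclass(frozen=True)
class OpticsConfig:
    na: float = 1.4
    wavelength_nm: float = 575.0
    magnification: float = 100.0
    camera_pixel_um: float = 6.8
    psf_model: str = "gaussian"
    z_layers: int = 13
    oversample: int = 4
    margin_um: float = 0.5
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if min(self.na, self.wavelength_nm, self.magnification, self.camera_pixel_um) <= 0:
            raise ValueError("optical parameters must be positive")
        if self.psf_model not in ("gaussian", "born_wolf"):
            raise ValueError(f"unknown psf model {self.psf_model!r}")
        if self.psf_model == "born_wolf":
            raise NotImplementedError(
                "Born-Wolf scalar PSF is an extension stub; use 'gaussian'"
            )

    @property
    def sample_pixel_um(self) -> float:
        """Camera pixel mapped to the sample plane (µm)."""
        return self.camera_pixel_um / self.magnification

    @property
    def sigma0_nm(self) -> float:
        """In-focus lateral PSF sd, 0.21·λ/NA (nm)."""
        return 0.21 * self.wavelength_nm / self.na

    @property
    def z_rayleigh_nm(self) -> float:
        """Axial defocus scale z_R = 2λn/NA² (nm)."""
        return 2.0 * self.wavelength_nm * IMMERSION_INDEX / self.na**2

    @property
    def rayleigh_radius_nm(self) -> float:
        """Lateral resolution limit 0.61·λ/NA (nm)."""
        return 0.61 * self.wavelength_nm / self.na


def psf_sigma(optics: OpticsConfig, defocus_nm: float) -> float:
    """Lateral PSF sd (nm) at the given defocus."""
    return optics.sigma0_nm * math.sqrt(1.0 + (defocus_nm / optics.z_rayleigh_nm) ** 2)


def _strehl(optics: OpticsConfig, defocus_nm: float) -> float:
    return 1.0 / (1.0 + (defocus_nm / optics.z_rayleigh_nm) ** 2)


def psf_kernel(
    optics: OpticsConfig, defocus_nm: float = 0.0, pixel_nm: float | None = None
) -> np.ndarray:
    """Discrete 2D PSF slice at the given defocus.

    The in-focus kernel integrates to 1; out-of-focus slices integrate to
    the Strehl-like attenuation factor ≤ 1. Kernel support is ±4σ.
    """
    if pixel_nm is None:
        pixel_nm = optics.sample_pixel_um * 1000.0 / optics.oversample
    sig = psf_sigma(optics, defocus_nm) / pixel_nm
    half = max(int(math.ceil(4.0 * sig)), 1)
    ax = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (ax / sig) ** 2)
    k = np.outer(g, g)
    return k / k.sum() * _strehl(optics, defocus_nm)


@dataclass
class Micrograph:
    """A simulated camera frame with calibrated sample-plane pixel size."""

    data: np.ndarray
    pixel_nm: float
    t: float = 0.0
    x0_um: float = 0.0  # sample-plane x of the centre of column 0
    eta0_um: float = 0.0  # sample-plane lateral (projected) coord of row 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def x_coords_um(self) -> np.ndarray:
        return self.x0_um + np.arange(self.data.shape[1]) * self.pixel_nm / 1000.0

    def eta_coords_um(self) -> np.ndarray:
        return self.eta0_um + np.arange(self.data.shape[0]) * self.pixel_nm / 1000.0

    def row_of_eta(self, eta_um: float) -> int:
        """Row index closest to projected lateral coordinate η (µm)."""
        return int(round((eta_um - self.eta0_um) / (self.pixel_nm / 1000.0)))


def _rasterize_light(state, geom: CylinderGeom, x0: float, nx: int, sub: float):
    """Fluorophore density (µm² of labelled area per cell) on the strip raster.

    Rows are arc-length bins around the circumference (period P), columns
    axial bins of width ``sub`` µm.
    """
    P = geom.P
    ny = max(int(round(P / sub)), 1)
    dy_arc = P / ny
    density = np.zeros((ny, nx))
    for p in state.patches:
        if p.label != "light":
            continue
        verts = unwrap_ring(p.vertices, P)
        # oversample the polygon mask on a finer lattice for subpixel accuracy
        rr_f = verts[:, 1] / dy_arc
        cc_f = (verts[:, 0] - x0) / sub
        rr, cc = draw_polygon(rr_f, cc_f)
        if len(rr) == 0:
            # polygon smaller than the raster: deposit its whole area at its
            # centroid bin
            cy = int(np.floor(verts[:, 1].mean() / dy_arc)) % ny
            cx = int(np.floor((verts[:, 0].mean() - x0) / sub))
            if 0 <= cx < nx:
                from .flowfield import polygon_area

                density[cy, cx] += polygon_area(verts)
            continue
        keep = (cc >= 0) & (cc < nx)
        cell = dy_arc * sub
        if keep.all():
            # conserve the exact polygon area against raster quantization
            from .flowfield import polygon_area

            cell *= polygon_area(verts) / (len(rr) * cell)
        density[rr[keep] % ny, cc[keep]] += cell
    return density, ny, dy_arc


def render_micrograph(
    state,
    optics: OpticsConfig | None = None,
    rng: np.random.Generator | None = None,
    focus_offset_um: float = 0.0,
) -> Micrograph:
    """Render the light-labelled material of a simulation state to a frame.

    The focal plane passes through the cylinder axis (plus
    ``focus_offset_um``), so the near and far membrane surfaces sit at
    defocus ±R and the left/right tangent surfaces at defocus ≈ 0, which is
    what makes the cell periphery bright in widefield. With ``rng`` given,
    camera noise is applied; otherwise the clean signal plus the constant
    background offset is returned.
    """
    if optics is None:
        optics = OpticsConfig()
    geom = state.geom
    R, P = geom.R, geom.P
    sub = optics.sample_pixel_um / optics.oversample  # µm
    margin = optics.margin_um

    x0 = geom.x_left - margin
    nx_cam = int(math.ceil((geom.length + 2 * margin) / optics.sample_pixel_um))
    nx = nx_cam * optics.oversample
    eta0 = -R - margin
    ne_cam = int(math.ceil((2 * R + 2 * margin) / optics.sample_pixel_um))
    ne = ne_cam * optics.oversample

    density, ny, dy_arc = _rasterize_light(state, geom, x0, nx, sub)

    # wrap the strip onto the cylinder: arc coordinate theta = y/R maps to
    # projected lateral eta = R sin(theta) at defocus z = R cos(theta)
    theta = (np.arange(ny) + 0.5) * dy_arc / R
    eta = R * np.sin(theta)
    z_nm = (R * np.cos(theta) + focus_offset_um) * 1000.0
    eta_idx = np.clip(((eta - eta0) / sub).astype(int), 0, ne - 1)

    zmax = (R + abs(focus_offset_um)) * 1000.0
    edges = np.linspace(-zmax - 1.0, zmax + 1.0, optics.z_layers + 1)
    band = np.digitize(z_nm, edges) - 1

    highres = np.zeros((ne, nx))
    for b in range(optics.z_layers):
        rows = np.nonzero(band == b)[0]
        if len(rows) == 0:
            continue
        layer = np.zeros((ne, nx))
        np.add.at(layer, eta_idx[rows], density[rows])
        zc = float(np.mean(z_nm[rows]))
        sig_px = psf_sigma(optics, zc) / (sub * 1000.0)
        highres += gaussian_filter(layer, sig_px, mode="constant") * _strehl(
            optics, zc
        )

    o = optics.oversample
    signal = highres.reshape(ne_cam, o, nx_cam, o).sum(axis=(1, 3))
    signal *= optics.noise.photon_scale

    if rng is not None:
        img = apply_camera_noise(signal, optics.noise, rng)
    else:
        img = signal + optics.noise.offset

    return Micrograph(
        data=img,
        pixel_nm=optics.sample_pixel_um * 1000.0,
        t=state.t,
        x0_um=x0 + optics.sample_pixel_um / 2.0,
        eta0_um=eta0 + optics.sample_pixel_um / 2.0,
        meta={
            "x_left_um": geom.x_left,
            "x_right_um": geom.x_right,
            "R_um": R,
            "seed": getattr(state, "seed", None),
            "optics": {
                "na": optics.na,
                "wavelength_nm": optics.wavelength_nm,
                "magnification": optics.magnification,
                "camera_pixel_um": optics.camera_pixel_um,
                "z_layers": optics.z_layers,
            },
        },
    )


def apply_camera_noise(
    signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on the expected counts, plus offset and read noise."""
    shot = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
    return shot + noise.offset + rng.normal(0.0, noise.read_noise, signal.shape)


def save_tiff(
    micrographs: "Micrograph | Sequence[Micrograph]", path: str | Path
) -> Path:
    """Write one frame or a time series as (multi-page) 32-bit float TIFF."""
    import tifffile

    if isinstance(micrographs, Micrograph):
        micrographs = [micrographs]
    # frames of a growing cell differ in extent; pad each to the common
    # canvas (centred) with its own background level
    ny = max(m.data.shape[0] for m in micrographs)
    nx = max(m.data.shape[1] for m in micrographs)
    padded = []
    for m in micrographs:
        dy, dx = ny - m.data.shape[0], nx - m.data.shape[1]
        padded.append(
            np.pad(
                m.data,
                ((dy // 2, dy - dy // 2), (dx // 2, dx - dx // 2)),
                constant_values=float(np.median(m.data)),
            )
        )
    stack = np.stack(padded).astype(np.float32)
    px_um = micrographs[0].pixel_nm / 1000.0
    path = Path(path)
    tifffile.imwrite(
        path,
        stack,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={
            "axes": "TYX" if stack.ndim == 3 else "YX",
            "pixel_size_um": px_um,
            "times_s": [m.t for m in micrographs],
        },
    )
    return path
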