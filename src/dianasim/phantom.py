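"""Digital phantom, ROI masks, and the ROI / non-ROI k-space decomposition.

The simulation model splits the baseline image into an activated part S1
(signal inside the ROI, zero elsewhere) and a static part S2 (zero inside
the ROI).  Their Fourier transforms are the two k-space contributions that
the synthesis engine mixes line by line: only the ROI contribution is
modulated by the neuronal response and the hemodynamic background.

Fourier convention
------------------
All transforms are orthonormal (``norm="ortho"``) and *centered*: the DC
sample sits at index ``n // 2`` on each axis (``fftshift`` layout).  Row
index is the phase-encode axis.  Under this layout a descending 80-line
acquisition reaches the DC line at the 40th acquired line (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


def image_to_kspace(image: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D FFT (image -> k-space, DC at ``n // 2``)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))


def kspace_to_image(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`image_to_kspace`; returns a complex image."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace), norm="ortho"))


@dataclass(frozen=True)
class Phantom:
    """Baseline 2-D signal-intensity image (arbitrary units).

    Parameters
    ----------
    image
        Non-negative real array, shape ``(n_pe, n_ro)``.
    pixel_size_mm
        In-plane pixel size; metadata only.
    """

    image: np.ndarray
    pixel_size_mm: float = 0.25

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("phantom image must be 2-D")
        if not np.all(np.isfinite(img)):
            raise ValueError("phantom image must be finite")
        if np.any(img < 0):
            raise ValueError("phantom image must be non-negative")
        if not np.any(img > 0):
            raise ValueError("phantom image must contain signal")
        object.__setattr__(self, "image", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class ROISet:
    """Activation and control region masks (same shape as the phantom).

    The two masks are disjoint; in "matched" mode (the default builder) they
    contain the same number of voxels so on/off statistics are comparable.
    """

    active_mask: np.ndarray
    control_mask: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.active_mask, dtype=bool)
        c = np.asarray(self.control_mask, dtype=bool)
        if a.shape != c.shape:
            raise ValueError("active and control masks must share a shape")
        if not a.any() or not c.any():
            raise ValueError("masks must be non-empty")
        if np.any(a & c):
            raise ValueError("active and control masks overlap")
        object.__setattr__(self, "active_mask", a)
        object.__setattr__(self, "control_mask", c)

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    @property
    def n_control(self) -> int:
        return int(self.control_mask.sum())


@dataclass(frozen=True)
class KSpaceSplit:
    """k-space contributions of the ROI-only image (``k_active``, the paper
    community's K1) and the ROI-zeroed image (``k_rest``, K2).

    ``kspace_to_image(k_active + k_rest)`` reproduces the phantom image.
    """

    k_active: np.ndarray
    k_rest: np.ndarray

    def __post_init__(self) -> None:
        if self.k_active.shape != self.k_rest.shape:
            raise ValueError("k_active and k_rest must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.k_active.shape

    def with_rest_zeroed(self) -> "KSpaceSplit":
        """Copy with the non-ROI contribution removed (ghost visualization)."""
        return KSpaceSplit(self.k_active, np.zeros_like(self.k_rest))


@dataclass(frozen=True)
class ROISpec:
    """Geometric description of the two circular ROIs (row, col, radius)."""

    active_center: tuple[float, float] = (40.0, 40.0)
    control_center: tuple[float, float] = (20.0, 20.0)
    radius: float = 3.5


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    # Translate one common footprint so matched ROIs have identical counts.
    r0, c0 = int(round(center[0])), int(round(center[1]))
    rr = np.arange(-int(np.ceil(radius)), int(np.ceil(radius)) + 1)
    dr, dc = np.meshgrid(rr, rr, indexing="ij")
    foot = dr * dr + dc * dc <= radius * radius
    rows = r0 + dr[foot]
    cols = c0 + dc[foot]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise ValueError("ROI extends outside the image support")
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    return mask


def build_phantom(
    shape: tuple[int, int] = (80, 80),
    roi_spec: ROISpec | None = None,
    seed: int = 0,
) -> tuple[Phantom, ROISet]:
    """Build a smooth brain-like phantom and matched active/control ROIs.

    The image is a composite of graded ellipses (an outer "head" plus two
    internal structures) with a faint smooth random texture, standing in for
    an averaged stimulus-off baseline image.  Deterministic for fixed seed.
    """
    if roi_spec is None:
        roi_spec = ROISpec()
    n_pe, n_ro = shape
    if n_pe < 8 or n_ro < 8:
        raise ValueError("matrix must be at least 8x8")

    r = (np.arange(n_pe) - n_pe / 2.0 + 0.5)[:, None]
    c = (np.arange(n_ro) - n_ro / 2.0 + 0.5)[None, :]
    img = np.zeros(shape, dtype=float)

    def ellipse(cr, cc, ar, ac, amp):
        return amp * (((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0)

    img += ellipse(0, 0, 0.42 * n_pe, 0.46 * n_ro, 1.0)          # head
    img += ellipse(-0.12 * n_pe, 0.10 * n_ro, 0.16 * n_pe, 0.18 * n_ro, 0.25)
    img += ellipse(0.15 * n_pe, -0.12 * n_ro, 0.10 * n_pe, 0.12 * n_ro, -0.15)

    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    support = img > 0
    img[support] *= 1.0 + 0.05 * texture[support]
    img = ndimage.gaussian_filter(img, sigma=1.0)
    img = np.clip(img, 0.0, None)

    active = _disk_mask(shape, roi_spec.active_center, roi_spec.radius)
    control = _disk_mask(shape, roi_spec.control_center, roi_spec.radius)
    if np.any(active & control):
        raise ValueError("active and control ROI specs overlap")
    phantom = Phantom(image=img)
    if not np.all(phantom.image[active] > 0) or not np.all(phantom.image[control] > 0):
        raise ValueError("ROIs must lie on positive phantom signal")
    return phantom, ROISet(active_mask=active, control_mask=control)


def split_kspace(phantom: Phantom, roi: ROISet) -> KSpaceSplit:
    """Decompose the phantom into ROI-only and ROI-zeroed k-space parts.

    ``k_active = FT(image * active_mask)``; ``k_rest = FT(image * ~active_mask)``.
    """
    if roi.active_mask.shape != phantom.shape:
        raise ValueError("mask shape does not match phantom shape")
    s1 = phantom.image * roi.active_mask
    s2 = phantom.image * (~roi.active_mask)
    return KSpaceSplit(k_active=image_to_kspace(s1), k_rest=image_to_kspace(s2))


# ---------------------------------------------------------------------------
# NIfTI I/O (single 2-D slice stored as an (n_pe, n_ro, 1) volume)

def save_image_nifti(path, image: np.ndarray, pixel_size_mm: float = 0.25) -> None:
    data = np.asarray(image, dtype=np.float64)[..., None]
    affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_image_nifti(path) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return vol[..., 0]
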