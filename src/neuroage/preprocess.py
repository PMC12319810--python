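"""Preprocessing contract producing the fixed-size normalized input volume.

The canonical chain is: skull-strip (mask application) -> bias-field
removal -> rigid alignment to a template grid -> z-score over nonzero
voxels -> crop/pad to the network input dimensions, default
(160, 192, 160) at 1 mm isotropic. Skull stripping, N4 bias correction and
rigid registration are normally performed by dedicated external tools;
this module fixes their input/output contracts and ships self-contained
fallbacks (mask multiplication, a low-order polynomial log-intensity field
fit, and center-of-mass + principal-axes alignment) so the full pipeline
runs and is testable with no external binaries. External tools can be
substituted through the ``external_hook`` registration mode at the same
contract.

Conventions fixed here: voxel indices are 0-based with axis order
(sagittal, coronal, axial) matching the (160, 192, 160) triple; z-scoring
uses the population (divide-by-N) standard deviation; intensity resampling
is trilinear; crop/pad centers the foreground bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateInputError, DomainError, ShapeError

__all__ = [
    "PreprocessConfig",
    "RigidTransform",
    "strip_with_mask",
    "remove_bias_field",
    "rigid_align",
    "zscore_nonzero",
    "crop_pad",
    "preprocess_volume",
]

DEFAULT_TARGET_DIMS = (160, 192, 160)


@dataclass(frozen=True)
class PreprocessConfig:
    target_dims: tuple[int, int, int] = DEFAULT_TARGET_DIMS
    bias_poly_order: int = 2
    registration_mode: str = "internal_rigid"  # identity | internal_rigid | external_hook
    zscore_epsilon: float = 1e-8

    def __post_init__(self):
        if any(d <= 0 for d in self.target_dims):
            raise ConfigError("target_dims must be positive")
        if self.bias_poly_order < 0:
            raise ConfigError("bias_poly_order must be >= 0")
        if self.registration_mode not in (
            "identity", "internal_rigid", "external_hook"
        ):
            raise ConfigError(
                f"unknown registration mode {self.registration_mode!r}"
            )


def strip_with_mask(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Zero all voxels outside the brain mask; inside is untouched."""
    volume = np.asarray(volume)
    brain_mask = np.asarray(brain_mask)
    if volume.shape != brain_mask.shape:
        raise ShapeError(
            f"mask shape {brain_mask.shape} != volume shape {volume.shape}"
        )
    return np.where(brain_mask.astype(bool), volume, 0.0)


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix up to total degree ``order`` on [-1,1]^3."""
    cols = [np.ones(coords.shape[0])]
    for degree in range(1, order + 1):
        for combo in combinations_with_replacement(range(3), degree):
            col = np.ones(coords.shape[0])
            for axis in combo:
                col = col * coords[:, axis]
            cols.append(col)
    return np.stack(cols, axis=1)


def remove_bias_field(
    volume: np.ndarray, order: int = 2, n_iter: int = 5
) -> np.ndarray:
    """Remove a smooth multiplicative intensity trend (N4-style fallback).

    Fits a polynomial of total degree ``order`` to the log-intensities of
    the dominant bright-tissue voxels (an intensity band around the upper
    half of the nonzero histogram, iteratively re-derived so anatomy
    contaminates the fit as little as possible), divides it out, and
    rescales so the mean over nonzero voxels is preserved. ``order`` 0
    reduces to a global rescale, i.e. the identity after mean restoration.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise DomainError("bias-field removal expects a nonnegative volume")
    nz = volume > 0
    if not nz.any():
        raise DomainError("all-zero volume")
    original_mean = float(volume[nz].mean())
    if order == 0:
        return volume.copy()

    shape = np.array(volume.shape)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )
    coords = np.stack([g.ravel() for g in grids], axis=1)

    current = volume.copy()
    for _ in range(n_iter):
        vals = current[nz]
        # dominant-tissue intensity mode; a band around it keeps the fit
        # on one tissue class so anatomy does not masquerade as field
        hist, edges = np.histogram(vals, bins=64)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        band = nz & (current >= 0.8 * mode) & (current <= 1.2 * mode)
        if np.count_nonzero(band) < 16:
            break
        design = _poly_design(coords[band.ravel()], order)
        coef, *_ = np.linalg.lstsq(design, np.log(current[band]), rcond=None)
        field = (_poly_design(coords, order) @ coef).reshape(volume.shape)
        field -= field[nz].mean()
        current[nz] = current[nz] / np.exp(field[nz])
    current[nz] *= original_mean / current[nz].mean()
    return current


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (template->moving direction map) and translation in voxels."""

    rotation: np.ndarray
    translation_vox: np.ndarray

    @property
    def rotation_angle_deg(self) -> float:
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _intensity_moments(volume: np.ndarray):
    w = volume.astype(float)
    total = w.sum()
    if total <= 0:
        raise DomainError("empty foreground")
    grids = np.meshgrid(*[np.arange(s) for s in volume.shape], indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    wf = w.ravel() / total
    com = wf @ coords
    centered = coords - com
    cov = (centered * wf[:, None]).T @ centered
    return com, cov


def _principal_axes(cov: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return eigvecs[:, order]


def rigid_align(
    moving: np.ndarray,
    template: np.ndarray,
    mode: str = "internal_rigid",
    external_hook: Callable | None = None,
) -> tuple[np.ndarray, RigidTransform]:
    """Rigidly align ``moving`` onto the template grid (6 DOF).

    The internal method matches intensity centers of mass (translation)
    and principal axes of the second intensity moments (rotation), then
    resamples trilinearly onto the template grid. ``identity`` mode only
    resamples/crops onto the template grid; ``external_hook`` delegates to
    a user-supplied callable with the same signature contract.

    Returns the aligned volume and the recovered transform.
    """
    moving = np.asarray(moving, dtype=float)
    template = np.asarray(template, dtype=float)
    if not (moving > 0).any() or not (template > 0).any():
        raise DomainError("rigid_align requires nonempty foreground")

    if mode == "external_hook":
        if external_hook is None:
            raise ConfigError("external_hook mode requires a hook callable")
        return external_hook(moving, template)
    if mode == "identity":
        identity = RigidTransform(np.eye(3), np.zeros(3))
        out = _resample(moving, np.eye(3), np.zeros(3), template.shape)
        return out, identity
    if mode != "internal_rigid":
        raise ConfigError(f"unknown registration mode {mode!r}")

    com_m, cov_m = _intensity_moments(moving)
    com_t, cov_t = _intensity_moments(template)
    axes_m = _principal_axes(cov_m)
    axes_t = _principal_axes(cov_t)
    # resolve per-axis sign ambiguity toward the smallest rotation
    for i in range(3):
        if axes_m[:, i] @ axes_t[:, i] < 0:
            axes_m[:, i] = -axes_m[:, i]
    rotation = axes_m @ axes_t.T
    if np.linalg.det(rotation) < 0:
        axes_m[:, 2] = -axes_m[:, 2]
        rotation = axes_m @ axes_t.T

    offset = com_m - rotation @ com_t
    aligned = _resample(moving, rotation, offset, template.shape)
    transform = RigidTransform(
        rotation=rotation, translation_vox=com_m - com_t
    )
    return aligned, transform


def _resample(volume, matrix, offset, output_shape):
    return ndimage.affine_transform(
        volume, matrix, offset=offset, output_shape=output_shape,
        order=1, mode="constant", cval=0.0,
    )


def zscore_nonzero(volume: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Z-score over nonzero voxels; zero voxels stay exactly zero.

    Uses the population (divide-by-N) standard deviation. After the
    transform the originally-nonzero voxels have mean 0 and standard
    deviation 1.
    """
    volume = np.asarray(volume, dtype=float)
    nz = volume != 0
    values = volume[nz]
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateInputError(
            "z-scoring needs at least two distinct nonzero values"
        )
    sd = float(values.std())  # population convention
    if sd < epsilon:
        raise DegenerateInputError(f"nonzero-voxel sd {sd} below epsilon")
    out = np.zeros_like(volume)
    out[nz] = (values - values.mean()) / sd
    return out


def crop_pad(volume: np.ndarray, target_dims=DEFAULT_TARGET_DIMS) -> np.ndarray:
    """Center the foreground bounding box in a volume of ``target_dims``.

    Pads with zeros; axes longer than the target are center-cropped around
    the foreground box. Total foreground is conserved whenever the
    bounding box fits inside the target dimensions.
    """
    volume = np.asarray(volume)
    target = tuple(int(t) for t in target_dims)
    if any(t <= 0 for t in target):
        raise ConfigError("target_dims must be positive")
    out = np.zeros(target, dtype=volume.dtype)
    nz = np.nonzero(volume)
    if nz[0].size == 0:
        return out
    in_slices, out_slices = [], []
    for axis in range(3):
        lo, hi = int(nz[axis].min()), int(nz[axis].max())
        center = (lo + hi + 1) / 2.0
        start = int(np.floor(center - target[axis] / 2.0 + 0.5))
        in_start = max(start, 0)
        in_stop = min(start + target[axis], volume.shape[axis])
        out_start = in_start - start
        in_slices.append(slice(in_start, in_stop))
        out_slices.append(slice(out_start, out_start + (in_stop - in_start)))
    out[tuple(out_slices)] = volume[tuple(in_slices)]
    return out


def preprocess_volume(
    volume: np.ndarray,
    brain_mask: np.ndarray | None = None,
    template: np.ndarray | None = None,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Full preprocessing chain producing the network-ready volume.

    Applies, in order: skull-strip (if a mask is given), bias-field
    removal, rigid alignment (if a template is given and the mode is not
    ``identity``), z-score over nonzero voxels, and crop/pad to the target
    dimensions.
    """
    config = config or PreprocessConfig()
    out = np.asarray(volume, dtype=float)
    if brain_mask is not None:
        out = strip_with_mask(out, brain_mask)
    if config.bias_poly_order > 0:
        out = remove_bias_field(out, order=config.bias_poly_order)
    if template is not None and config.registration_mode != "identity":
        out, _ = rigid_align(out, template, mode=config.registration_mode)
    out = zscore_nonzero(out, epsilon=config.zscore_epsilon)
    return crop_pad(out, config.target_dims)
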