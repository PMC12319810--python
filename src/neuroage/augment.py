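"""Training-time stochastic augmentation for 3D volumes.

Ten transforms are supported: spatial (small rotations up to 0.1 rad per
axis, a small affine with translation and shear, isotropic zoom within
5% of unity), intensity (contrast scaling, gamma, a smooth multiplicative
bias field, additive Gaussian noise, patch swapping) and acquisition
artifacts (motion via k-space line phase perturbation, ghosting via
periodic k-space modulation). Each transform is independently gated by a
Bernoulli draw with probability ``gate_p`` (default 0.2) at every
training iteration.

Sampling and application are split: ``sample_plan`` draws all parameters
(including sub-seeds for the stochastic transforms) into an
``AugmentPlan``, and ``apply_plan`` executes the plan deterministically,
so an iteration is fully reproducible from its plan. Transforms are
applied spatial -> intensity -> artifacts, so artifact patterns are never
re-interpolated. Every transform preserves the volume shape; the motion
and ghosting operators preserve the background-zero property only
approximately (ringing can leak small values into the background), which
is accepted and documented rather than asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ShapeError

__all__ = [
    "TRANSFORM_ORDER",
    "AugmentConfig",
    "PlannedTransform",
    "AugmentPlan",
    "sample_plan",
    "apply_plan",
]

TRANSFORM_ORDER = (
    "rotation",
    "affine",
    "zoom",
    "contrast",
    "gamma",
    "bias_field",
    "noise",
    "patch_swap",
    "motion",
    "ghosting",
)

_MAX_SUBSEED = 2**31 - 1


@dataclass(frozen=True)
class AugmentConfig:
    gate_p: float = 0.2
    rot_max_rad: float = 0.1
    zoom_max_frac: float = 0.05
    translation_max_vox: float = 2.0
    shear_max: float = 0.02
    contrast_range: tuple[float, float] = (0.75, 1.25)
    gamma_range: tuple[float, float] = (0.7, 1.5)
    bias_field_max_amp: float = 0.3  # max |log field|
    noise_sd_range: tuple[float, float] = (0.01, 0.1)
    patch_swap_count: int = 8
    patch_size: int = 8
    motion_line_frac: float = 0.1
    motion_phase_max: float = 0.5
    ghosting_max_intensity: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.gate_p <= 1.0:
            raise ConfigError("gate_p must be in [0, 1]")
        if self.rot_max_rad < 0 or self.zoom_max_frac < 0:
            raise ConfigError("rotation/zoom bounds must be nonnegative")


@dataclass(frozen=True)
class PlannedTransform:
    name: str
    params: dict
    applied: bool


@dataclass(frozen=True)
class AugmentPlan:
    transforms: tuple[PlannedTransform, ...]

    @property
    def applied_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.transforms if t.applied)

    def get(self, name: str) -> PlannedTransform:
        for t in self.transforms:
            if t.name == name:
                return t
        raise KeyError(name)


def sample_plan(config: AugmentConfig, rng: np.random.Generator) -> AugmentPlan:
    """Draw one augmentation plan.

    Each transform's ``applied`` flag is an independent Bernoulli(gate_p)
    draw; parameters are sampled uniformly within the configured bounds
    whether or not the transform fires, so parameter statistics can be
    audited independently of the gate.
    """
    samplers = {
        "rotation": lambda: {
            "angles_rad": rng.uniform(
                -config.rot_max_rad, config.rot_max_rad, size=3
            ).tolist()
        },
        "affine": lambda: {
            "translation_vox": rng.uniform(
                -config.translation_max_vox, config.translation_max_vox, size=3
            ).tolist(),
            "shear": rng.uniform(-config.shear_max, config.shear_max, size=3).tolist(),
        },
        "zoom": lambda: {
            "factor": float(
                rng.uniform(1.0 - config.zoom_max_frac, 1.0 + config.zoom_max_frac)
            )
        },
        "contrast": lambda: {"factor": float(rng.uniform(*config.contrast_range))},
        "gamma": lambda: {"gamma": float(rng.uniform(*config.gamma_range))},
        "bias_field": lambda: {
            "amplitude": float(rng.uniform(0.0, config.bias_field_max_amp)),
            "seed": int(rng.integers(_MAX_SUBSEED)),
        },
        "noise": lambda: {
            "sd": float(rng.uniform(*config.noise_sd_range)),
            "seed": int(rng.integers(_MAX_SUBSEED)),
        },
        "patch_swap": lambda: {
            "count": int(config.patch_swap_count),
            "size": int(config.patch_size),
            "seed": int(rng.integers(_MAX_SUBSEED)),
        },
        "motion": lambda: {
            "axis": int(rng.integers(3)),
            "line_frac": float(rng.uniform(0.0, config.motion_line_frac)),
            "phase_max": float(rng.uniform(0.0, config.motion_phase_max)),
            "seed": int(rng.integers(_MAX_SUBSEED)),
        },
        "ghosting": lambda: {
            "axis": int(rng.integers(3)),
            "period": int(rng.integers(2, 6)),
            "intensity": float(rng.uniform(0.0, config.ghosting_max_intensity)),
        },
    }
    planned = []
    for name in TRANSFORM_ORDER:
        params = samplers[name]()
        applied = bool(rng.random() < config.gate_p)
        planned.append(PlannedTransform(name=name, params=params, applied=applied))
    return AugmentPlan(transforms=tuple(planned))


def apply_plan(volume: np.ndarray, plan: AugmentPlan) -> np.ndarray:
    """Apply a sampled plan; deterministic given the plan.

    The output shape always equals the input shape; a plan in which no
    transform fired returns a bit-identical copy.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ShapeError(f"expected a 3D volume, got shape {volume.shape}")
    out = volume.copy()
    for t in plan.transforms:
        if not t.applied:
            continue
        out = _APPLIERS[t.name](out, t.params)
        if out.shape != volume.shape:  # pragma: no cover - internal contract
            raise ShapeError(f"transform {t.name} changed the volume shape")
    return out


def _center_affine(volume, matrix, shift=None):
    center = (np.array(volume.shape) - 1) / 2.0
    offset = center - matrix @ center
    if shift is not None:
        offset = offset + shift
    return ndimage.affine_transform(
        volume, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )


def _rotation_matrix(angles):
    ax, ay, az = angles
    rx = np.array(
        [[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]]
    )
    ry = np.array(
        [[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]]
    )
    rz = np.array(
        [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
    )
    return rz @ ry @ rx


def _apply_rotation(volume, params):
    return _center_affine(volume, _rotation_matrix(params["angles_rad"]))


def _apply_affine(volume, params):
    matrix = np.eye(3)
    sx, sy, sz = params["shear"]
    matrix[0, 1] = sx
    matrix[1, 2] = sy
    matrix[0, 2] = sz
    return _center_affine(volume, matrix, shift=np.asarray(params["translation_vox"]))


def _apply_zoom(volume, params):
    # affine_transform maps output->input, so the matrix uses 1/factor
    matrix = np.eye(3) / params["factor"]
    return _center_affine(volume, matrix)


def _apply_contrast(volume, params):
    nz = volume != 0
    if not nz.any():
        return volume
    mean = volume[nz].mean()
    out = volume.copy()
    out[nz] = mean + params["factor"] * (volume[nz] - mean)
    return out


def _apply_gamma(volume, params):
    nz = volume != 0
    if not nz.any():
        return volume
    vals = volume[nz]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return volume
    out = volume.copy()
    out[nz] = lo + (hi - lo) * ((vals - lo) / (hi - lo)) ** params["gamma"]
    return out


def _apply_bias_field(volume, params):
    rng = np.random.default_rng(params["seed"])
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in volume.shape], indexing="ij"
    )
    coefs = rng.uniform(-1.0, 1.0, size=(3, 2))
    log_field = sum(
        coefs[i, 0] * grids[i] + coefs[i, 1] * grids[i] ** 2 for i in range(3)
    )
    peak = np.abs(log_field).max()
    if peak > 0:
        log_field *= params["amplitude"] / peak
    return volume * np.exp(log_field)


def _apply_noise(volume, params):
    rng = np.random.default_rng(params["seed"])
    return volume + rng.normal(0.0, params["sd"], size=volume.shape)


def _apply_patch_swap(volume, params):
    rng = np.random.default_rng(params["seed"])
    out = volume.copy()
    size = min(params["size"], *volume.shape)
    for _ in range(params["count"]):
        a = [rng.integers(0, s - size + 1) for s in volume.shape]
        b = [rng.integers(0, s - size + 1) for s in volume.shape]
        sl_a = tuple(slice(c, c + size) for c in a)
        sl_b = tuple(slice(c, c + size) for c in b)
        patch = out[sl_a].copy()
        out[sl_a] = out[sl_b]
        out[sl_b] = patch
    return out


def _apply_motion(volume, params):
    rng = np.random.default_rng(params["seed"])
    axis = params["axis"]
    k = np.fft.fftn(volume)
    n = volume.shape[axis]
    n_lines = int(round(params["line_frac"] * n))
    if n_lines == 0:
        return volume.copy()
    lines = rng.choice(n, size=n_lines, replace=False)
    phases = rng.uniform(-params["phase_max"], params["phase_max"], size=n_lines)
    shape = [1, 1, 1]
    shape[axis] = n
    mod = np.ones(n, dtype=complex)
    mod[lines] = np.exp(1j * phases)
    k *= mod.reshape(shape)
    return np.real(np.fft.ifftn(k))


def _apply_ghosting(volume, params):
    axis = params["axis"]
    k = np.fft.fftn(volume)
    n = volume.shape[axis]
    mod = np.ones(n)
    mod[:: params["period"]] = 1.0 - params["intensity"]
    mod[0] = 1.0  # keep the DC component so global intensity is preserved
    shape = [1, 1, 1]
    shape[axis] = n
    k *= mod.reshape(shape)
    return np.real(np.fft.ifftn(k))


_APPLIERS = {
    "rotation": _apply_rotation,
    "affine": _apply_affine,
    "zoom": _apply_zoom,
    "contrast": _apply_contrast,
    "gamma": _apply_gamma,
    "bias_field": _apply_bias_field,
    "noise": _apply_noise,
    "patch_swap": _apply_patch_swap,
    "motion": _apply_motion,
    "ghosting": _apply_ghosting,
}
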