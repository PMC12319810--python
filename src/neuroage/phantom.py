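"""Age-parameterized synthetic brain phantoms and cohort generators.

The phantom is a concentric-ellipsoid "brain": a gray-matter ribbon
enclosing a white-matter compartment that itself contains a CSF-filled
ventricular ellipsoid, on an exactly-zero background. Age is encoded
structurally and monotonically:

* the ventricle radius grows linearly with age (ventricular enlargement),
* the gray-matter ribbon thins linearly with age (cortical thinning),
* the gray/white contrast narrows slightly with age (intensity texture).

Analytic geometry makes these trends assertable voxel-by-voxel, and a
linear readout of two hand-computed features (ventricle voxel count and
ribbon thickness) recovers the generating age, so every downstream stage
of the pipeline is trainable and testable without real MRI. The phantoms
make no claim to anatomical realism and simulate no MR physics.

Cohort generators write NIfTI-1 volumes plus CSV metadata; the
longitudinal multiple-sclerosis generator embeds a configurable true
annual brain-age change rate so the analysis stages can be validated by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DomainError

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "PhantomSpec",
    "PhantomVolume",
    "LesionSpec",
    "LongitudinalMSSpec",
    "generate_phantom",
    "structural_masks",
    "extract_age_features",
    "generate_cohort",
    "generate_longitudinal_ms_cohort",
    "ms_visit_pairs",
    "simulate_lesion_pair",
    "COHORT_COLUMNS",
]

AGE_MIN = 5.0
AGE_MAX = 95.0

COHORT_COLUMNS = [
    "subject_id", "age", "sex", "site", "field_strength", "visit", "path",
]

# Brain outer semi-axes as fractions of the grid dimensions; deliberately
# anisotropic so principal-axes registration is well conditioned.
_BRAIN_AXIS_FRACTIONS = (0.42, 0.46, 0.40)
# Ventricle semi-axis anisotropy (elongated along the second axis).
_VENTRICLE_ANISOTROPY = (1.0, 1.3, 0.9)
# Gray/white contrast narrowing per year of age (intensity units).
_GM_AGING_SLOPE = 0.0008


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, and corruption parameters of the phantom.

    Geometric rates are expressed in voxels; ``None`` for the ventricle
    base radius or growth rate derives a default proportional to the grid
    so the same age signal is present at any resolution.
    """

    grid_dims: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    ventricle_base_radius_vox: float | None = None
    ventricle_growth_rate: float | None = None  # voxel radius per year
    cortical_base_thickness_vox: float = 4.0
    cortical_thinning_rate: float = 0.02  # voxels per year
    base_intensities: dict = field(
        default_factory=lambda: {
            "background": 0.0, "wm": 1.0, "gm": 0.7, "csf": 0.35,
        }
    )
    noise_sd: float = 0.03
    site_gain: dict | None = None  # site label -> multiplicative factor
    lesion_count_range: tuple[int, int] = (1, 5)
    lesion_radius_range_mm: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self):
        if len(self.grid_dims) != 3 or any(d < 16 for d in self.grid_dims):
            raise ConfigError(f"grid_dims must be 3 values >= 16, got {self.grid_dims}")
        if self.voxel_size_mm <= 0:
            raise ConfigError("voxel_size_mm must be positive")
        if self.base_intensities.get("background", 0.0) != 0.0:
            raise ConfigError("background intensity must be exactly 0")
        if any(v < 0 for v in self.base_intensities.values()):
            raise ConfigError("intensities must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        thickness_at_max = (
            self.cortical_base_thickness_vox
            - self.cortical_thinning_rate * AGE_MAX
        )
        if thickness_at_max <= 0.5:
            raise ConfigError(
                "cortical ribbon would vanish within the supported age range"
            )

    @property
    def ventricle_radius_base(self) -> float:
        if self.ventricle_base_radius_vox is not None:
            return self.ventricle_base_radius_vox
        return 0.07 * min(self.grid_dims)

    @property
    def ventricle_growth(self) -> float:
        if self.ventricle_growth_rate is not None:
            return self.ventricle_growth_rate
        return 0.0012 * min(self.grid_dims)

    def ventricle_radius(self, age_years: float) -> float:
        return self.ventricle_radius_base + self.ventricle_growth * age_years

    def cortical_thickness(self, age_years: float) -> float:
        return (
            self.cortical_base_thickness_vox
            - self.cortical_thinning_rate * age_years
        )


@dataclass
class PhantomVolume:
    """A generated scalar volume plus its provenance."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: str = "RAS"
    provenance: dict = field(default_factory=dict)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        center = (np.array(self.data.shape) - 1) / 2.0
        aff[:3, 3] = -center * np.array(self.spacing_mm)
        return aff

    def save(self, path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))
        return path


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes)
    )
    return r2 <= 1.0


def structural_masks(age_years: float, spec: PhantomSpec) -> dict:
    """Analytic tissue masks (brain, gm, wm, ventricle) at a given age."""
    dims = np.array(spec.grid_dims)
    center = (dims - 1) / 2.0
    outer = np.array(_BRAIN_AXIS_FRACTIONS) * dims
    thickness = spec.cortical_thickness(age_years)
    inner = outer - thickness
    vent_r = spec.ventricle_radius(age_years)
    vent = vent_r * np.array(_VENTRICLE_ANISOTROPY)
    if np.any(vent >= inner):
        raise ConfigError("ventricle does not fit inside the white matter")
    shape = tuple(int(d) for d in dims)
    brain = _ellipsoid_mask(shape, center, outer)
    inner_mask = _ellipsoid_mask(shape, center, inner)
    vent_mask = _ellipsoid_mask(shape, center, vent)
    return {
        "brain": brain,
        "gm": brain & ~inner_mask,
        "wm": inner_mask & ~vent_mask,
        "ventricle": vent_mask,
    }


def generate_phantom(
    age_years: float,
    sex: str = "F",
    site: str = "siteA",
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> PhantomVolume:
    """Render one age-parameterized phantom volume.

    Deterministic given all inputs. Sex is carried as metadata only; site
    acts as a multiplicative intensity gain (1.0 for unlisted sites).
    """
    spec = spec or PhantomSpec()
    if not AGE_MIN <= age_years <= AGE_MAX:
        raise DomainError(
            f"age {age_years} outside supported range [{AGE_MIN}, {AGE_MAX}]"
        )
    masks = structural_masks(age_years, spec)
    ints = spec.base_intensities
    gm_intensity = ints["gm"] + _GM_AGING_SLOPE * age_years

    vol = np.zeros(spec.grid_dims, dtype=np.float64)
    vol[masks["wm"]] = ints["wm"]
    vol[masks["gm"]] = gm_intensity
    vol[masks["ventricle"]] = ints["csf"]

    rng = np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, int(round(age_years * 1000))]
    )
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=vol.shape)
        vol[masks["brain"]] += noise[masks["brain"]]
    gain = 1.0 if spec.site_gain is None else float(spec.site_gain.get(site, 1.0))
    vol[masks["brain"]] *= gain
    np.clip(vol, 0.0, None, out=vol)
    vol[~masks["brain"]] = 0.0

    return PhantomVolume(
        data=vol.astype(np.float32),
        spacing_mm=(spec.voxel_size_mm,) * 3,
        provenance={
            "age_years": float(age_years),
            "sex": sex,
            "site": site,
            "seed": int(seed),
            "corruption": [],
            "spec": spec,
        },
    )


def extract_age_features(volume: PhantomVolume) -> tuple[float, float]:
    """Hand-computed image features carrying the age signal.

    Returns ``(ventricle_voxels, gm_ribbon_voxels)``, both measured from
    the image intensities (not the generator's analytic masks): the
    ventricle count is the number of voxels in the CSF intensity band,
    and the gray-matter ribbon count — the volume of the cortical shell —
    is the thinning proxy (the outer surface is age-invariant, so ribbon
    volume is proportional to its mean thickness).
    """
    spec: PhantomSpec = volume.provenance["spec"]
    ints = spec.base_intensities
    age = volume.provenance["age_years"]
    csf_hi = (ints["csf"] + (ints["gm"] + _GM_AGING_SLOPE * age)) / 2.0
    gm_hi = ((ints["gm"] + _GM_AGING_SLOPE * age) + ints["wm"]) / 2.0
    data = volume.data
    vent_voxels = int(np.count_nonzero((data > 0) & (data <= csf_hi)))
    gm_voxels = int(np.count_nonzero((data > csf_hi) & (data < gm_hi)))
    return float(vent_voxels), float(gm_voxels)


def _draw_ages(age_sampler, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(age_sampler):
        ages = np.asarray(age_sampler(rng, n), dtype=float)
    else:
        lo, hi = age_sampler
        ages = rng.uniform(lo, hi, size=n)
    if ages.size and (ages.min() < AGE_MIN or ages.max() > AGE_MAX):
        raise DomainError("sampled ages outside supported range")
    return ages


def generate_cohort(
    n: int,
    age_sampler,
    sites: Sequence[str],
    seed: int,
    spec: PhantomSpec | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Generate ``n`` phantoms with i.i.d. ages and write them to disk.

    ``age_sampler`` is either an ``(age_min, age_max)`` tuple (uniform
    sampling) or a callable ``(rng, n) -> ages``. Sites are assigned
    cyclically; a site label containing "7T" is recorded at 7 Tesla.
    Returns the cohort metadata table (also written as ``metadata.csv``
    when ``out_dir`` is given).
    """
    if n < 0:
        raise DomainError("n must be >= 0")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    ages = _draw_ages(age_sampler, rng, n)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        sid = f"sub-{i:04d}"
        site = sites[i % len(sites)]
        sex = "F" if rng.random() < 0.5 else "M"
        path = ""
        if out_dir is not None:
            vol = generate_phantom(
                ages[i], sex=sex, site=site, seed=_subseed(seed, i), spec=spec
            )
            path = str(vol.save(out_dir / f"{sid}_T1w.nii.gz"))
        rows.append(
            {
                "subject_id": sid,
                "age": float(ages[i]),
                "sex": sex,
                "site": site,
                "field_strength": "7T" if "7T" in site else "3T",
                "visit": 0,
                "path": path,
            }
        )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if out_dir is not None:
        table.to_csv(out_dir / "metadata.csv", index=False)
    return table


def _subseed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([seed, index]).generate_state(1)[0] & 0x7FFFFFFF
    )


@dataclass(frozen=True)
class LongitudinalMSSpec:
    """Conditions of the simulated longitudinal multiple-sclerosis cohort.

    Brain aging is modeled per subject as a constant annual rate: the
    structural (phantom) age at follow-up equals the baseline structural
    age plus ``rate * interval`` exactly, where ``rate`` is drawn around
    ``annual_ba_rate`` with between-subject spread ``annual_ba_rate_sd``
    and shifted by ``worsening_rate_delta`` for subjects flagged as
    experiencing disability worsening. Observed brain ages add Gaussian
    prediction noise of ``prediction_noise_sd`` years. Defaults follow the
    scale of real early/longstanding MS cohorts: baseline brain age about
    4 years above chronological age, a mean rate of 1.15 brain-age years
    per year, and visit intervals of 1.4-4.3 years.
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (20.0, 60.0)
    baseline_bad_mean: float = 4.2
    baseline_bad_sd: float = 6.5
    annual_ba_rate: float = 1.15
    annual_ba_rate_sd: float = 0.7
    visit_interval_range: tuple[float, float] = (1.4, 4.3)
    worsening_prevalence: float = 0.3
    worsening_rate_delta: float = 0.34
    prediction_noise_sd: float = 0.5
    duration_range: tuple[float, float] = (0.3, 20.0)

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        if not 0.0 <= self.worsening_prevalence <= 1.0:
            raise ConfigError("worsening_prevalence must be in [0, 1]")
        lo, hi = self.visit_interval_range
        if lo < 0 or hi < lo:
            raise ConfigError("visit intervals must be nonnegative and ordered")


CLINICAL_COLUMNS = [
    "subject_id", "visit", "date", "edss", "sdmt", "nhpt", "t25fw",
    "disease_duration",
]


def generate_longitudinal_ms_cohort(
    ms_spec: LongitudinalMSSpec,
    phantom_spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir=None,
    write_volumes: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-visit MS cohort with embedded brain-aging rates.

    Returns ``(cohort, clinical)`` tables. The cohort table carries, per
    visit, the chronological age, the exact structural age driving the
    phantom, the noisy observed brain age, and the subject's true annual
    rate; the clinical table carries EDSS/SDMT/9HPT/T25FW visits whose
    deltas cross the disability-worsening thresholds exactly for subjects
    flagged as worsening and stay strictly below them otherwise.

    When ``write_volumes`` is set, phantom volumes are rendered at each
    visit's structural age (clipped into the supported range for
    rendering only; tables keep exact values).
    """
    phantom_spec = phantom_spec or PhantomSpec()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    cohort_rows: list[dict] = []
    clinical_rows: list[dict] = []
    base_date = pd.Timestamp("2020-01-01")
    for i in range(ms_spec.n_subjects):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, i])
        sid = f"ms-{i:04d}"
        sex = "F" if rng.random() < 0.65 else "M"
        site = "ms-site"
        age0 = rng.uniform(*ms_spec.age_range)
        bad0 = rng.normal(ms_spec.baseline_bad_mean, ms_spec.baseline_bad_sd)
        s0 = age0 + bad0
        worsening = bool(rng.random() < ms_spec.worsening_prevalence)
        rate = rng.normal(ms_spec.annual_ba_rate, ms_spec.annual_ba_rate_sd)
        if worsening:
            rate += ms_spec.worsening_rate_delta
        interval = rng.uniform(*ms_spec.visit_interval_range)
        s1 = s0 + rate * interval
        duration = rng.uniform(*ms_spec.duration_range)

        obs_noise = rng.normal(0.0, ms_spec.prediction_noise_sd, size=2)
        structural = (s0, s1)
        chron = (age0, age0 + interval)
        for visit in (0, 1):
            path = ""
            if write_volumes and out_dir is not None:
                render_age = float(np.clip(structural[visit], AGE_MIN, AGE_MAX))
                vol = generate_phantom(
                    render_age, sex=sex, site=site,
                    seed=_subseed(seed, 2 * i + visit), spec=phantom_spec,
                )
                path = str(vol.save(out_dir / f"{sid}_visit{visit}_T1w.nii.gz"))
            cohort_rows.append(
                {
                    "subject_id": sid,
                    "age": float(chron[visit]),
                    "sex": sex,
                    "site": site,
                    "field_strength": "3T",
                    "visit": visit,
                    "path": path,
                    "structural_age": float(structural[visit]),
                    "brain_age_obs": float(structural[visit] + obs_noise[visit]),
                    "true_annual_rate": float(rate),
                    "interval_years": float(interval),
                    "worsening": worsening,
                    "disease_duration": float(duration),
                }
            )
        clinical_rows.extend(
            _clinical_visits(sid, rng, worsening, interval, duration, base_date, i)
        )
    cohort = pd.DataFrame(
        cohort_rows,
        columns=COHORT_COLUMNS
        + [
            "structural_age", "brain_age_obs", "true_annual_rate",
            "interval_years", "worsening", "disease_duration",
        ],
    )
    clinical = pd.DataFrame(clinical_rows, columns=CLINICAL_COLUMNS)
    if out_dir is not None:
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        clinical.to_csv(out_dir / "clinical.csv", index=False)
    return cohort, clinical


def _clinical_visits(
    sid: str,
    rng: np.random.Generator,
    worsening: bool,
    interval: float,
    duration: float,
    base_date: pd.Timestamp,
    index: int,
) -> list[dict]:
    edss0 = rng.integers(2, 14) / 2.0  # 1.0 .. 6.5 on the half-point lattice
    sdmt0 = float(np.round(rng.normal(50.0, 10.0)))
    nhpt0 = float(rng.uniform(18.0, 35.0))
    t25fw0 = float(rng.uniform(4.0, 9.0))

    # stable deltas: strictly below every worsening threshold
    if edss0 < 6.0:
        edss_delta = rng.choice([-0.5, 0.0, 0.5])
    else:
        edss_delta = rng.choice([-0.5, 0.0])
    nhpt_factor = rng.uniform(-0.10, 0.15)
    t25fw_factor = rng.uniform(-0.10, 0.15)
    if worsening:
        branch = rng.integers(0, 3)
        if branch == 0:
            edss_delta = 1.0 if edss0 < 6.0 else 0.5
        elif branch == 1:
            t25fw_factor = rng.uniform(0.20, 0.50)
        else:
            nhpt_factor = rng.uniform(0.20, 0.50)

    date0 = base_date + pd.Timedelta(days=int(index * 3))
    date1 = date0 + pd.Timedelta(days=int(round(interval * 365.25)))
    visits = []
    for visit, (date, edss, sdmt, nhpt, t25fw, dur) in enumerate(
        [
            (date0, edss0, sdmt0, nhpt0, t25fw0, duration),
            (
                date1,
                min(10.0, edss0 + edss_delta),
                sdmt0 + float(np.round(rng.normal(0.0, 3.0))),
                nhpt0 * (1.0 + nhpt_factor),
                t25fw0 * (1.0 + t25fw_factor),
                duration + interval,
            ),
        ]
    ):
        visits.append(
            {
                "subject_id": sid,
                "visit": visit,
                "date": date.date().isoformat(),
                "edss": float(edss),
                "sdmt": float(sdmt),
                "nhpt": float(nhpt),
                "t25fw": float(t25fw),
                "disease_duration": float(dur),
            }
        )
    return visits


def ms_visit_pairs(cohort: pd.DataFrame, clinical: pd.DataFrame | None = None):
    """Assemble per-subject VisitPair objects from the generator tables.

    Uses the observed (noisy) brain ages; attaches clinical visits when a
    clinical table is provided.
    """
    from .ms_analysis import ClinicalVisit, VisitPair

    pairs = []
    for sid, grp in cohort.groupby("subject_id", sort=True):
        grp = grp.sort_values("visit")
        if len(grp) != 2:
            continue
        b, f = grp.iloc[0], grp.iloc[1]
        visits = (None, None)
        if clinical is not None:
            cg = clinical[clinical.subject_id == sid].sort_values("visit")
            visits = tuple(
                ClinicalVisit(
                    subject_id=sid,
                    visit=int(r.visit),
                    edss=float(r.edss),
                    sdmt=float(r.sdmt),
                    nhpt=float(r.nhpt),
                    t25fw=float(r.t25fw),
                )
                for r in cg.itertuples()
            )
        pairs.append(
            VisitPair(
                subject_id=sid,
                baseline_brain_age=float(b.brain_age_obs),
                followup_brain_age=float(f.brain_age_obs),
                interval_years=float(b.interval_years),
                baseline_visit=visits[0],
                followup_visit=visits[1],
            )
        )
    return pairs


@dataclass(frozen=True)
class LesionSpec:
    """White-matter lesion simulation parameters."""

    count_range: tuple[int, int] = (1, 5)
    radius_range_mm: tuple[float, float] = (2.0, 5.0)
    intensity_factor: float = 0.55  # hypointensity relative to local WM

    def __post_init__(self):
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ConfigError("invalid lesion count range")
        if not 0.0 <= self.intensity_factor <= 1.0:
            raise ConfigError("intensity_factor must be in [0, 1]")


def simulate_lesion_pair(
    volume: PhantomVolume,
    lesion_spec: LesionSpec | None = None,
    seed: int = 0,
) -> tuple[PhantomVolume, PhantomVolume, np.ndarray]:
    """Insert hypointense WM lesions and produce a lesion-filled twin.

    Returns ``(lesioned, filled, lesion_mask)``. The lesioned volume
    differs from the original only inside the mask (spherical hypointense
    lesions fully contained in white matter); the filled volume equals the
    lesioned one outside the mask and restores the mean white-matter
    intensity inside it, emulating lesion filling before morphometry.
    """
    lesion_spec = lesion_spec or LesionSpec()
    spec: PhantomSpec = volume.provenance["spec"]
    age = volume.provenance["age_years"]
    wm = structural_masks(age, spec)["wm"]
    rng = np.random.default_rng(seed)
    count = int(rng.integers(lesion_spec.count_range[0],
                             lesion_spec.count_range[1] + 1))
    mask = np.zeros(volume.data.shape, dtype=bool)
    if count > 0:
        radii_mm = rng.uniform(
            lesion_spec.radius_range_mm[0],
            lesion_spec.radius_range_mm[1],
            size=count,
        )
        radii_vox = radii_mm / volume.spacing_mm[0]
        sphere_voxels = (4.0 / 3.0) * np.pi * radii_vox**3
        if sphere_voxels.sum() > np.count_nonzero(wm):
            raise DomainError(
                "requested lesion volume exceeds available white matter"
            )
        # lesions must sit entirely inside WM: candidate centers are WM
        # voxels at least one radius away from any non-WM voxel
        dt = ndimage.distance_transform_edt(wm)
        for r in radii_vox:
            candidates = np.argwhere(dt >= r + 0.5)
            if candidates.size == 0:
                raise DomainError(
                    f"no white-matter location can host a lesion of radius "
                    f"{r:.1f} voxels"
                )
            center = candidates[rng.integers(len(candidates))]
            mask |= _sphere_mask(volume.data.shape, center, r)

    lesioned_data = volume.data.copy()
    lesioned_data[mask] *= lesion_spec.intensity_factor
    filled_data = lesioned_data.copy()
    if mask.any():
        wm_mean = float(volume.data[wm & ~mask].mean())
        filled_data[mask] = wm_mean

    def _with(data, tag):
        prov = dict(volume.provenance)
        prov["corruption"] = list(prov.get("corruption", [])) + [tag]
        return PhantomVolume(
            data=data, spacing_mm=volume.spacing_mm,
            orientation=volume.orientation, provenance=prov,
        )

    return _with(lesioned_data, "lesions"), _with(filled_data, "lesion_filled"), mask


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2
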