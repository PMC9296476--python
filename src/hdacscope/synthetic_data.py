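"""Phantoms, simulated dynamic PET and simulated cohorts.

Everything downstream of acquisition is exercised on data produced here: box
phantoms with labelled regions, dynamic scans whose regional curves follow
the SRTM forward model around a bi-exponential reference, and multivariate
cohorts with the causal structure amyloid -> tau -> HDAC -> {atrophy,
cognition} plus age/sex/education covariates.

All generators are pure functions of (spec, seed): the same inputs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DynamicImage, FrameSchedule, KineticParams, LabelMap
from .kinetics import srtm_forward

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "simulate_reference_tac",
    "simulate_dynamic_pet",
    "simulate_cohort",
    "simulate_sem_dataset",
]

REGION_ROLES = (
    "target",
    "reference_white_matter",
    "reference_cerebellar_gray",
    "background",
)


@dataclass(frozen=True)
class RegionSpec:
    """A box-shaped region: positive integer label, voxel origin and size."""

    label: int
    origin: tuple
    size: tuple
    role: str = "target"

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("region labels must be positive (0 is background)")
        if self.role not in REGION_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if len(self.origin) != 3 or len(self.size) != 3:
            raise ValueError("origin and size must be 3-tuples")
        if any(s <= 0 for s in self.size):
            raise ValueError("region size must be positive along every axis")

    @property
    def slices(self) -> tuple:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.size))


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus a list of labelled box regions."""

    grid_shape: tuple
    voxel_size_mm: float
    regions: tuple

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        regions = tuple(self.regions)
        if not regions:
            raise ValueError("phantom needs at least one region")
        labels = [r.label for r in regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if not any(r.role.startswith("reference") for r in regions):
            raise ValueError("at least one reference-role region is required")
        for r in regions:
            for o, s, g in zip(r.origin, r.size, self.grid_shape):
                if o < 0 or o + s > g:
                    raise ValueError(f"region {r.label} exceeds the grid")
        object.__setattr__(self, "regions", regions)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def reference_labels(self, role: str | None = None):
        return [
            r.label
            for r in self.regions
            if r.role.startswith("reference")
            and (role is None or r.role == role)
        ]


def make_phantom(spec: PhantomSpec) -> LabelMap:
    """Paint the spec's box regions into an integer label map.

    Overlapping regions raise, naming the colliding labels.
    """
    data = np.zeros(spec.grid_shape, dtype=np.int32)
    for r in spec.regions:
        block = data[r.slices]
        if np.any(block != 0):
            clashing = sorted(int(l) for l in np.unique(block) if l != 0)
            raise ValueError(
                f"region {r.label} overlaps previously placed label(s) {clashing}"
            )
        data[r.slices] = r.label
    return LabelMap(data, spec.affine)


def simulate_reference_tac(
    schedule: FrameSchedule, A1: float, lambda1_per_s: float, lambda2_per_s: float
) -> np.ndarray:
    """Frame means of the bi-exponential A1*(exp(-l1 t) - exp(-l2 t)).

    Serves as the reference-region input for SRTM simulations; frame values
    are the exact analytic average of the curve over each frame, so no
    quadrature error enters the simulation.
    """
    l1, l2 = float(lambda1_per_s), float(lambda2_per_s)
    if not (l2 > l1 > 0):
        raise ValueError("need lambda2 > lambda1 > 0")
    t0 = schedule.starts
    t1 = schedule.ends
    d = schedule.durations

    def mean_exp(lam):
        return (np.exp(-lam * t0) - np.exp(-lam * t1)) / (lam * d)

    curve = A1 * (mean_exp(l1) - mean_exp(l2))
    return np.maximum(curve, 0.0)


def simulate_dynamic_pet(
    labelmap: LabelMap,
    region_params: dict,
    ref_tac,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_labels=(),
) -> DynamicImage:
    """Dynamic image whose regional TACs follow the SRTM forward model.

    ``region_params`` maps label -> KineticParams for every non-background,
    non-reference label.  Reference-region kinetics are pinned to (R1=1,
    BP=0), i.e. the reference TAC itself, so the simulation is
    self-consistent.  Gaussian noise with per-frame standard deviation
    ``noise_sd / sqrt(frame duration in s)`` is added i.i.d. per voxel.
    """
    ref_tac = np.asarray(ref_tac, dtype=float)
    reference_labels = set(int(l) for l in reference_labels)
    curves = {}
    for label in labelmap.labels:
        label = int(label)
        if label in reference_labels:
            curves[label] = ref_tac
        elif label in region_params:
            curves[label] = srtm_forward(region_params[label], ref_tac, schedule)
        else:
            raise ValueError(f"no kinetic parameters for label {label}")

    data = np.zeros(labelmap.data.shape + (schedule.n_frames,))
    for label, curve in curves.items():
        data[labelmap.data == label] = curve

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame_sd = noise_sd / np.sqrt(schedule.durations)
        data = data + rng.standard_normal(data.shape) * frame_sd
    return DynamicImage(data, labelmap.affine, schedule)


# ---------------------------------------------------------------------------
# cohorts

# standardized path coefficients of the HDAC-mediation structure; atrophy is
# recorded as grey-matter density (lower = worse) and cognition as MMSE-like
# (lower = worse), so pathology paths are negative and HDAC paths positive.
# The tau -> {atrophy, cognition} direct effects are chosen so the proportion
# of the tau effect mediated through HDAC is 57% and 51% respectively.
DEFAULT_PATHS = {
    ("amyloid", "tau"): 0.65,
    ("amyloid", "hdac"): -0.30,
    ("tau", "hdac"): -0.50,
    ("hdac", "atrophy"): 0.50,
    ("tau", "atrophy"): -0.18859649,   # 0.25/(0.25+x) = 0.57
    ("amyloid", "atrophy"): -0.05,
    ("hdac", "cognition"): 0.50,
    ("tau", "cognition"): -0.24019608,  # 0.25/(0.25+x) = 0.51
    ("amyloid", "cognition"): -0.05,
    ("atrophy", "cognition"): 0.0,
    ("age", "atrophy"): -0.20,
    ("sex", "atrophy"): -0.15,
    ("education", "cognition"): 0.20,
}

DEFAULT_RESIDUAL_SD = {"tau": 0.76, "hdac": 0.70, "atrophy": 0.70, "cognition": 0.70}

# group offsets (z units) applied to the amyloid exogenous variable
DEFAULT_AMYLOID_OFFSET = {"cu_young": -0.8, "cu_elderly": -0.3, "mci": 0.7, "ad": 1.3}

# regional HDAC-tracer SUVR group means (white-matter reference) emulating
# the AD-vulnerable cortices; between-subject SD couples to the hdac variable
DEFAULT_REGION_SUVR = {
    "posterior_cingulate": {"cu_young": 1.16, "cu_elderly": 1.12, "mci": 1.05, "ad": 0.96},
    "precuneus": {"cu_young": 1.14, "cu_elderly": 1.10, "mci": 1.04, "ad": 0.95},
    "inferior_parietal": {"cu_young": 1.12, "cu_elderly": 1.09, "mci": 1.03, "ad": 0.95},
    "lateral_temporal": {"cu_young": 1.10, "cu_elderly": 1.07, "mci": 1.02, "ad": 0.94},
}


@dataclass(frozen=True)
class CohortSpec:
    """Simulated cohort: group sizes, causal paths, SUVR effects, cut points."""

    n_cu_young: int = 25
    n_cu_elderly: int = 28
    n_mci: int = 15
    n_ad: int = 26
    paths: dict = field(default_factory=lambda: dict(DEFAULT_PATHS))
    residual_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    amyloid_offset: dict = field(default_factory=lambda: dict(DEFAULT_AMYLOID_OFFSET))
    region_suvr: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_SUVR.items()})
    region_suvr_sd: float = 0.06
    amyloid_cut: float = 0.5
    tau_cut: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cu_young", "n_cu_elderly", "n_mci", "n_ad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(sd <= 0 for sd in self.residual_sd.values()):
            raise ValueError("residual SDs must be positive")

    @property
    def n_total(self) -> int:
        return self.n_cu_young + self.n_cu_elderly + self.n_mci + self.n_ad


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the linear-Gaussian structural model.

    Exogenous variables (amyloid signal, age, sex, education) are z-scaled;
    group-mean offsets are applied to amyloid afterwards.  Endogenous
    variables cascade through the path coefficients with independent Gaussian
    residuals.  Diagnosis labels are the generating group; biomarker
    positivity columns record the amyloid/tau cut points used.
    """
    rng = np.random.default_rng(spec.seed)
    groups = (
        ["cu_young"] * spec.n_cu_young
        + ["cu_elderly"] * spec.n_cu_elderly
        + ["mci"] * spec.n_mci
        + ["ad"] * spec.n_ad
    )
    n = len(groups)
    b = spec.paths.get

    amyloid = rng.standard_normal(n) + np.array(
        [spec.amyloid_offset[g] for g in groups]
    )
    age = rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n).astype(float)
    education = rng.standard_normal(n)

    def eps(var):
        return rng.standard_normal(n) * spec.residual_sd[var]

    tau = b(("amyloid", "tau"), 0.0) * amyloid + eps("tau")
    hdac = (
        b(("amyloid", "hdac"), 0.0) * amyloid
        + b(("tau", "hdac"), 0.0) * tau
        + eps("hdac")
    )
    atrophy = (
        b(("hdac", "atrophy"), 0.0) * hdac
        + b(("tau", "atrophy"), 0.0) * tau
        + b(("amyloid", "atrophy"), 0.0) * amyloid
        + b(("age", "atrophy"), 0.0) * age
        + b(("sex", "atrophy"), 0.0) * sex
        + eps("atrophy")
    )
    cognition = (
        b(("hdac", "cognition"), 0.0) * hdac
        + b(("tau", "cognition"), 0.0) * tau
        + b(("amyloid", "cognition"), 0.0) * amyloid
        + b(("atrophy", "cognition"), 0.0) * atrophy
        + b(("education", "cognition"), 0.0) * education
        + eps("cognition")
    )

    out = pd.DataFrame(
        {
            "subject": [f"s{i:04d}" for i in range(n)],
            "diagnosis": groups,
            "amyloid": amyloid,
            "tau": tau,
            "hdac": hdac,
            "atrophy": atrophy,
            "cognition": cognition,
            "age": age,
            "sex": sex,
            "education": education,
            "amyloid_positive": (amyloid > spec.amyloid_cut).astype(int),
            "tau_positive": (tau > spec.tau_cut).astype(int),
        }
    )
    for region, means in spec.region_suvr.items():
        mu = np.array([means[g] for g in groups])
        out[f"suvr_{region}"] = mu + spec.region_suvr_sd * hdac
    out.attrs["amyloid_cut"] = spec.amyloid_cut
    out.attrs["tau_cut"] = spec.tau_cut
    return out


def simulate_sem_dataset(model, params: dict, n: int, seed: int = 0) -> pd.DataFrame:
    """Multivariate-normal sample whose population covariance is the model's.

    ``model`` is a :class:`~hdacscope.sem_mediation.PathModel`; ``params``
    assigns a value to every free parameter (lavaan-style names).  The
    implied covariance must be positive definite.
    """
    from .sem_mediation import implied_covariance

    sigma = implied_covariance(model, params)
    # PD check: Cholesky raises on semi-definite/indefinite input
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied covariance is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, sigma.shape[0]))
    return pd.DataFrame(z @ chol.T, columns=list(model.variables))
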