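"""Synthetic L3-slice phantom cohorts with planted survival structure.

The generator emulates the inputs of a body-composition survival study: one
axial CT slice per patient at the third lumbar vertebra with subcutaneous fat
(SAT), skeletal muscle, and a visceral (VAT) region, plus a clinical table
(sex, age, height, BMI, ASA class) and right-censored overall survival drawn
from a Weibull proportional-hazards model.  Effects can be planted on
clinical fields, body-composition indices, or extracted radiomics features so
that every downstream stage is testable without real data.

Geometry is deliberately schematic (concentric ellipses): only HU
distributions, cross-sectional areas, and texture statistics matter to the
downstream analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "TissueTexture",
    "CohortConfig",
    "PatientRecord",
    "PhantomSlice",
    "generate_cohort",
    "simulate_survival",
    "render_phantom",
    "simulate_feature_cohort",
    "write_cohort",
    "read_cohort",
]

# label map values
BACKGROUND, SAT, MUSCLE, VAT_REGION = 0, 1, 2, 3


@dataclass(frozen=True)
class TissueTexture:
    """Per-tissue HU distribution and spatial correlation length (pixels)."""

    mean_hu: float
    sd_hu: float
    corr_len: float = 2.0


# HU means/SDs sit well inside the segmentation windows (muscle -29..150,
# VAT -150..-50, SAT -190..-30) so >=95% of tissue pixels are captured.
DEFAULT_TEXTURE = {
    "muscle": TissueTexture(40.0, 15.0, 2.0),
    "vat": TissueTexture(-100.0, 12.0, 2.0),
    "sat": TissueTexture(-110.0, 12.0, 2.0),
}


def _weibull_scale_for(shape: float, frac_dead: float, horizon: float) -> float:
    """Scale such that a fraction ``frac_dead`` dies by ``horizon`` months."""
    return float(horizon / (-np.log(1.0 - frac_dead)) ** (1.0 / shape))


@dataclass
class CohortConfig:
    """Study-condition knobs for a phantom cohort.

    Defaults mirror a resected pancreatic-cancer population: mean age 67.7
    (SD 10.2) years, mean BMI 25.4 (SD 4.2) kg/m², 53% male, 42% ASA ≥ 3,
    ~45% two-year mortality, administrative censoring at five years.
    """

    n_patients: int = 100
    seed: int = 0
    sex_fraction_male: float = 0.53
    age_mean: float = 67.7
    age_sd: float = 10.2
    bmi_mean: float = 25.4
    bmi_sd: float = 4.2
    asa_ge3_prob: float = 0.42
    height_mean_by_sex: dict = field(
        default_factory=lambda: {"male": 1.77, "female": 1.64}
    )
    height_sd_by_sex: dict = field(
        default_factory=lambda: {"male": 0.07, "female": 0.06}
    )
    baseline_shape: float = 1.2
    baseline_scale: float = dataclasses.field(
        default_factory=lambda: _weibull_scale_for(1.2, 0.45, 24.0)
    )
    censor_time: float = 60.0
    dropout_prob: float = 0.0  # optional uniform(0, censor_time) dropout
    planted_betas: dict = field(default_factory=dict)
    texture_params: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURE))
    image_shape: tuple = (128, 128)
    spacing: tuple = (0.8, 0.8)  # mm; non-2mm so radiomics resampling is real
    site_fractions: dict = field(default_factory=lambda: {"site0": 1.0})

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("sex_fraction_male", "asa_ge3_prob", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("cohort config must set an explicit seed")
        tex = raw.pop("texture_params", None)
        cfg = cls(**raw)
        if tex:
            cfg.texture_params = {
                k: TissueTexture(**v) if isinstance(v, dict) else v
                for k, v in tex.items()
            }
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["texture_params"] = {
            k: dataclasses.asdict(v) if isinstance(v, TissueTexture) else v
            for k, v in self.texture_params.items()
        }
        return d


@dataclass
class PatientRecord:
    id: str
    sex: str  # "male" | "female"
    age: float
    height: float  # m
    bmi: float
    asa_ge3: bool
    site: str = "site0"
    time: float = np.nan  # months
    event: bool = False

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if np.isfinite(self.time) and self.time < 0:
            raise ValueError("survival time must be >= 0")


@dataclass
class PhantomSlice:
    """HU image + pixel spacing + ground-truth compartment labels."""

    hu_image: np.ndarray
    spacing: tuple
    labels: np.ndarray

    def __post_init__(self):
        if self.hu_image.shape != self.labels.shape:
            raise ValueError("hu_image and labels must share a shape")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")


def simulate_survival(linear_predictor, baseline, censor_time, rng,
                      dropout_prob=0.0):
    """Draw one (time, event) pair from a Weibull proportional-hazards model.

    The latent time solves S(t) = exp(-(t/scale)^shape * exp(lp)) = U; the
    observed time is administratively censored at ``censor_time`` (plus an
    optional uniform dropout time).
    """
    shape, scale = baseline["shape"], baseline["scale"]
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be > 0")
    if censor_time < 0:
        raise ValueError("censor_time must be >= 0")
    u = rng.uniform()
    latent = scale * (-np.log(u) / np.exp(linear_predictor)) ** (1.0 / shape)
    cens = censor_time
    if dropout_prob > 0.0 and rng.uniform() < dropout_prob:
        cens = min(cens, rng.uniform(0.0, censor_time))
    time = min(latent, cens)
    return float(time), bool(latent < cens)


def render_phantom(patient: PatientRecord, config: CohortConfig, rng) -> PhantomSlice:
    """Render one elliptical-annulus L3 phantom.

    Outer SAT annulus, muscle annulus, inner VAT region with an organ and a
    bowel-gas hole (labelled background).  Body size and SAT thickness grow
    with BMI so fat areas correlate with BMI; per-tissue correlated Gaussian
    HU fields give controllable texture.
    """
    nr, nc = config.image_shape
    spacing = config.spacing
    g = np.clip(np.sqrt(patient.bmi / 25.4), 0.75, 1.3)
    b_r, a_c = 0.32 * nr * g, 0.38 * nc * g  # body semi-axes in pixels
    sat_frac = np.clip(0.08 + 0.010 * (patient.bmi - 20.0), 0.05, 0.40)
    musc_frac = 0.13
    sat_inner = 1.0 - sat_frac
    musc_inner = sat_inner - musc_frac
    if musc_inner <= 0.1 or min(a_c, b_r) * musc_inner < 4:
        raise ValueError("image too small to contain SAT/muscle/VAT rings")

    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rho = np.sqrt(((rr - nr / 2) / b_r) ** 2 + ((cc - nc / 2) / a_c) ** 2)

    labels = np.zeros((nr, nc), dtype=np.int16)
    labels[(rho <= 1.0) & (rho > sat_inner)] = SAT
    labels[(rho <= sat_inner) & (rho > musc_inner)] = MUSCLE
    labels[rho <= musc_inner] = VAT_REGION

    # interior holes: an "organ" (water-ish HU) and a gas pocket, both
    # excluded from every compartment label
    organ = (((rr - nr / 2 + 0.25 * b_r * musc_inner) / (0.30 * b_r)) ** 2
             + ((cc - nc / 2) / (0.30 * a_c)) ** 2) <= musc_inner ** 2
    gas = (((rr - nr / 2 - 0.35 * b_r * musc_inner) / (0.12 * b_r)) ** 2
           + ((cc - nc / 2 - 0.30 * a_c * musc_inner) / (0.12 * a_c)) ** 2) \
        <= musc_inner ** 2

    hu = np.full((nr, nc), -1000.0)

    def correlated_field(corr_len):
        white = rng.standard_normal((nr, nc))
        if corr_len <= 0:
            return white
        f = gaussian_filter(white, sigma=corr_len, mode="reflect")
        sd = f.std()
        return f / sd if sd > 0 else f

    for name, label in (("sat", SAT), ("muscle", MUSCLE), ("vat", VAT_REGION)):
        tex = config.texture_params[name]
        field_ = correlated_field(tex.corr_len)
        sel = labels == label
        hu[sel] = tex.mean_hu + tex.sd_hu * field_[sel]

    inside = labels == VAT_REGION
    organ &= inside
    gas &= inside
    organ_noise = rng.standard_normal(int(organ.sum()))
    hu[organ] = 40.0 + 10.0 * organ_noise
    hu[gas] = -1000.0
    labels[organ | gas] = BACKGROUND

    return PhantomSlice(hu_image=hu, spacing=tuple(spacing), labels=labels)


def _draw_patients(config: CohortConfig, rng) -> list[PatientRecord]:
    n = config.n_patients
    sexes = np.where(rng.uniform(size=n) < config.sex_fraction_male,
                     "male", "female")
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
    bmis = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 50.0)
    asas = rng.uniform(size=n) < config.asa_ge3_prob
    site_names = list(config.site_fractions)
    probs = np.array([config.site_fractions[s] for s in site_names], float)
    probs = probs / probs.sum()
    sites = rng.choice(site_names, size=n, p=probs)
    patients = []
    for i in range(n):
        sex = str(sexes[i])
        h = rng.normal(config.height_mean_by_sex[sex],
                       config.height_sd_by_sex[sex])
        patients.append(
            PatientRecord(
                id=f"P{i:04d}", sex=sex, age=float(ages[i]),
                height=float(max(h, 1.2)), bmi=float(bmis[i]),
                asa_ge3=bool(asas[i]), site=str(sites[i]),
            )
        )
    return patients


def _planted_feature_matrix(patients, slices, betas, bin_width=25.0):
    """Assemble the per-patient values of every planted-effect feature."""
    from . import bodycomp, radiomics

    clinical = {
        "age": lambda p: p.age,
        "bmi": lambda p: p.bmi,
        "sex_male": lambda p: 1.0 if p.sex == "male" else 0.0,
        "asa_ge3": lambda p: 1.0 if p.asa_ge3 else 0.0,
    }
    bodycomp_keys = {"smi", "vati", "sati", "smra", "sma", "vat_area", "sat_area"}
    cols = {}
    radiomic_keys = [k for k in betas
                     if k not in clinical and k.lower() not in bodycomp_keys]
    for key in betas:
        if key in clinical:
            cols[key] = np.array([clinical[key](p) for p in patients])
    need_bc = [k for k in betas if k.lower() in bodycomp_keys]
    if need_bc or radiomic_keys:
        if slices is None:
            raise ValueError(
                "planted_betas reference image-derived features; cohort must "
                "be generated with images"
            )
    if need_bc:
        rows = [bodycomp.composition_summary(
            s, bodycomp.segment_all(s), height=p.height)
            for p, s in zip(patients, slices)]
        for k in need_bc:
            cols[k] = np.array([getattr(r, k.lower()) for r in rows])
    if radiomic_keys:
        for i, (p, s) in enumerate(zip(patients, slices)):
            fv = radiomics.extract_features(s, bin_width=bin_width)
            for k in radiomic_keys:
                canon = radiomics.normalize_feature_name(k)
                cols.setdefault(k, np.full(len(patients), np.nan))[i] = fv[canon]
    return cols


def generate_cohort(config: CohortConfig, with_images: bool = True):
    """Generate (patients, slices); deterministic given ``config.seed``.

    Planted effects: each feature named in ``config.planted_betas`` is
    z-standardized across the cohort and multiplied by its log-hazard
    coefficient to form the survival linear predictor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _draw_patients(config, rng)
    slices = None
    if with_images:
        slices = [render_phantom(p, config, rng) for p in patients]

    lp = np.zeros(config.n_patients)
    if config.planted_betas:
        cols = _planted_feature_matrix(patients, slices, config.planted_betas)
        for name, beta in config.planted_betas.items():
            x = cols[name]
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            lp = lp + beta * z

    baseline = {"shape": config.baseline_shape, "scale": config.baseline_scale}
    for p, lpi in zip(patients, lp):
        p.time, p.event = simulate_survival(
            lpi, baseline, config.censor_time, rng,
            dropout_prob=config.dropout_prob,
        )
    return patients, slices


def simulate_feature_cohort(n, planted_betas, n_noise=50, seed=0,
                            baseline=None, censor_time=60.0,
                            feature_corr=0.0):
    """Feature-matrix-level cohort: Gaussian features + Weibull-PH survival.

    Used to stress-test the selection stages at scale without rendering
    images.  Planted features are named as given; noise features are
    ``noise_000`` ... and carry zero effect.  ``feature_corr`` adds a shared
    latent factor across all features.

    Returns ``(X, time, event)`` with X a DataFrame.
    """
    rng = np.random.default_rng(seed)
    baseline = baseline or {"shape": 1.2, "scale": _weibull_scale_for(1.2, 0.45, 24.0)}
    names = list(planted_betas) + [f"noise_{i:03d}" for i in range(n_noise)]
    Z = rng.standard_normal((n, len(names)))
    if feature_corr > 0:
        shared = rng.standard_normal((n, 1))
        Z = np.sqrt(1 - feature_corr) * Z + np.sqrt(feature_corr) * shared
    X = pd.DataFrame(Z, columns=names)
    lp = sum(b * X[k].to_numpy() for k, b in planted_betas.items()) \
        if planted_betas else np.zeros(n)
    time = np.empty(n)
    event = np.empty(n, dtype=bool)
    for i in range(n):
        time[i], event[i] = simulate_survival(
            float(np.asarray(lp)[i]) if planted_betas else 0.0,
            baseline, censor_time, rng)
    return X, time, event


# ---------------------------------------------------------------------------
# I/O

COHORT_COLUMNS = ["id", "sex", "age", "height_m", "bmi", "asa_ge3",
                  "site", "time_months", "event"]


def cohort_table(patients) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "sex": [p.sex for p in patients],
            "age": [p.age for p in patients],
            "height_m": [p.height for p in patients],
            "bmi": [p.bmi for p in patients],
            "asa_ge3": [int(p.asa_ge3) for p in patients],
            "site": [p.site for p in patients],
            "time_months": [p.time for p in patients],
            "event": [int(p.event) for p in patients],
        }
    )


def write_cohort(patients, slices, out_dir):
    """Write the cohort table (CSV) and per-patient NIfTI image/label pairs."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_table(patients).to_csv(out / "cohort.csv", index=False)
    if slices is None:
        return out
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for p, s in zip(patients, slices):
        affine = np.diag([s.spacing[0], s.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(s.hu_image.astype(np.float32), affine),
                 img_dir / f"{p.id}_hu.nii")
        nib.save(nib.Nifti1Image(s.labels.astype(np.int16), affine),
                 img_dir / f"{p.id}_labels.nii")
    return out


def read_cohort(in_dir):
    """Read back a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "cohort.csv")
    patients = [
        PatientRecord(
            id=row.id, sex=row.sex, age=row.age, height=row.height_m,
            bmi=row.bmi, asa_ge3=bool(row.asa_ge3), site=row.site,
            time=row.time_months, event=bool(row.event),
        )
        for row in df.itertuples()
    ]
    slices = None
    img_dir = in_dir / "images"
    if img_dir.is_dir():
        slices = []
        for p in patients:
            img = nib.load(img_dir / f"{p.id}_hu.nii")
            lab = nib.load(img_dir / f"{p.id}_labels.nii")
            sp = img.header.get_zooms()[:2]
            slices.append(PhantomSlice(
                hu_image=np.asarray(img.dataobj, dtype=float),
                spacing=(float(sp[0]), float(sp[1])),
                labels=np.asarray(lab.dataobj, dtype=np.int16),
            ))
    return patients, slices
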