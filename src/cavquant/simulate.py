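"""Synthetic multiplex TMA cores and two-cohort clinical tables with known truth.

The image simulator renders a square tissue field partitioned into epithelial
nests (pancytokeratin-positive blobs) and surrounding stroma
(vimentin-positive, pancytokeratin-negative), with DAPI-positive nuclei laid
down densely enough that every stromal pixel has a nucleus nearby — the
geometry the stroma marker logic assumes.  Each channel is rendered as

    intensity = base * (exposure_ms / reference_exposure_ms) [+ noise, clip 0-1]

so intensity is affine in concentration and proportional to exposure time,
which is exactly the model the exposure-normalized score inverts.  Ground
truth (pixel masks and true concentrations) is returned alongside.

The cohort simulator draws per-subject compartment scores around configurable
means (defaults echo the observed medians: benign stroma ~309, tumor stroma
~153, tumor epithelium ~124 score units), with duplicate cores per ROI,
clinical covariates, and censored survival times in which a configurable
log-hazard for lymphovascular invasion is the only systematic effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .quantify import CHANNELS, REFERENCE_EXPOSURE_MS, MultiplexCoreImage


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _default_exposures() -> dict[str, float]:
    return {"dapi": 20.0, "vimentin": 50.0, "panck": 50.0, "cav1": 100.0}


@dataclass
class ImageSimConfig:
    image_size: int = 256
    n_nuclei: int = 400
    nucleus_radius: tuple[float, float] = (4.0, 0.8)  # mean, sd in px
    epithelial_nest_fraction: float = 0.30
    stroma_cav1_conc: float = 0.30
    epi_cav1_conc: float = 0.25
    exposure_times: dict[str, float] = field(default_factory=_default_exposures)
    noise_sd: float = 0.0
    poisson_noise: bool = False
    bleedthrough: float = 0.0  # fraction of panCK signal leaking into vimentin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise InvalidConfigError("image_size must be positive")
        if self.n_nuclei < 0:
            raise InvalidConfigError("n_nuclei must be >= 0")
        if not 0.0 <= self.epithelial_nest_fraction <= 1.0:
            raise InvalidConfigError("epithelial_nest_fraction must be in [0, 1]")
        if not 0.0 <= self.bleedthrough <= 1.0:
            raise InvalidConfigError("bleedthrough must be in [0, 1]")
        if self.stroma_cav1_conc < 0 or self.epi_cav1_conc < 0:
            raise InvalidConfigError("concentrations must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        for c in CHANNELS:
            if self.exposure_times.get(c, 0) <= 0:
                raise InvalidConfigError(f"exposure time for {c!r} must be > 0")


@dataclass
class GroundTruth:
    """True compartment membership and concentrations for one simulated core."""

    stroma_mask: np.ndarray
    epithelium_mask: np.ndarray
    nuclei_mask: np.ndarray
    stroma_cav1_conc: float
    epi_cav1_conc: float
    #: multiplicative gain from concentration to rendered cav1 intensity
    cav1_gain: float


# marker base intensities (at the reference exposure) for positive pixels
_MARKER_BASE = {"dapi": 0.9, "vimentin": 0.8, "panck": 0.8}


def _epithelial_nests(rng: np.ndarray, size: int, fraction: float) -> np.ndarray:
    """Smoothed-noise blobs thresholded at a quantile to hit the area fraction."""
    if fraction <= 0.0:
        return np.zeros((size, size), dtype=bool)
    if fraction >= 1.0:
        return np.ones((size, size), dtype=bool)
    field_ = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16)
    thr = np.quantile(field_, 1.0 - fraction)
    return field_ > thr


def _nuclei(rng, size: int, n: int, radius_mean: float, radius_sd: float) -> np.ndarray:
    """Nuclei as disks on a jittered grid covering the whole field.

    Grid placement (rather than uniform sampling) guarantees that no tissue
    pixel is far from a nucleus, so a modest nucleus-association radius
    recovers the full stroma compartment.
    """
    mask = np.zeros((size, size), dtype=bool)
    if n <= 0:
        return mask
    per_side = max(1, int(math.ceil(math.sqrt(n))))
    spacing = size / per_side
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(per_side):
        for j in range(per_side):
            cy = (i + 0.5) * spacing + rng.uniform(-0.2, 0.2) * spacing
            cx = (j + 0.5) * spacing + rng.uniform(-0.2, 0.2) * spacing
            r = max(1.0, rng.normal(radius_mean, radius_sd))
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def generate_core_image(config: ImageSimConfig) -> tuple[MultiplexCoreImage, GroundTruth]:
    """Render one four-channel core with exact ground-truth masks.

    The whole field is tissue: epithelium nests plus complementary stroma,
    so the two true compartments are disjoint and partition the image.
    Cav-1 intensity on a compartment equals
    ``concentration * exposure / reference`` exactly when noise is zero.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    epi = _epithelial_nests(rng, size, config.epithelial_nest_fraction)
    stroma = ~epi
    nuclei = _nuclei(rng, size, config.n_nuclei, *config.nucleus_radius)

    exp = config.exposure_times
    ref = REFERENCE_EXPOSURE_MS
    channels: dict[str, np.ndarray] = {}
    channels["dapi"] = _MARKER_BASE["dapi"] * nuclei * (exp["dapi"] / ref)
    channels["panck"] = _MARKER_BASE["panck"] * epi * (exp["panck"] / ref)
    channels["vimentin"] = (
        _MARKER_BASE["vimentin"] * stroma * (exp["vimentin"] / ref)
        + config.bleedthrough * channels["panck"]
    )
    cav1_gain = exp["cav1"] / ref
    conc = config.stroma_cav1_conc * stroma + config.epi_cav1_conc * epi
    channels["cav1"] = conc * cav1_gain

    for name in CHANNELS:
        img = channels[name].astype(float)
        if config.poisson_noise:
            # shot noise: variance proportional to signal (1000 photons at intensity 1)
            img = rng.poisson(np.clip(img, 0, None) * 1000.0) / 1000.0
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        if config.noise_sd > 0 or config.poisson_noise:
            img = np.clip(img, 0.0, 1.0)
        channels[name] = img

    image = MultiplexCoreImage(channels=channels, exposure_ms=dict(exp))
    truth = GroundTruth(
        stroma_mask=stroma,
        epithelium_mask=epi,
        nuclei_mask=nuclei,
        stroma_cav1_conc=config.stroma_cav1_conc,
        epi_cav1_conc=config.epi_cav1_conc,
        cav1_gain=cav1_gain,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSimConfig:
    """Conditions for the immunofluorescence-scored cohort.

    Score means default to the observed compartment medians (benign stroma
    about twice tumor stroma); survival is exponential with the
    lymphovascular-invasion flag carrying the only systematic log-hazard.
    """

    n_tumor: int = 105
    n_benign: int = 30
    benign_stroma_mean: float = 308.9
    tumor_stroma_mean: float = 152.6
    tumor_epi_mean: float = 124.0
    benign_epi_mean: float = 200.0
    dispersion: float = 0.28  # between-subject CV of true scores
    core_cv: float = 0.10  # within-subject duplicate-core CV
    duplicate_cores: int = 2
    score_missing_rate: float = 0.0
    censoring_rate: float = 0.25
    #: median OS (months) at covariate zero (LVI-negative); with the default
    #: LVI prevalence and hazard ratio the marginal cohort median lands near
    #: the observed ~50 months
    baseline_median_os: float = 140.0
    max_followup: float = 200.0  # administrative censoring horizon, months
    hazard_log_hr_lvi: float = math.log(3.56)
    lvi_prevalence: float = 0.77
    pathology_review_fraction: float = 0.7  # subset with TIL/cystic/LVI annotation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_benign < 0:
            raise InvalidConfigError("cohort sizes must be >= 0")
        for m in (
            self.benign_stroma_mean,
            self.tumor_stroma_mean,
            self.tumor_epi_mean,
            self.benign_epi_mean,
        ):
            if m < 0:
                raise InvalidConfigError("score means must be >= 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise InvalidConfigError("censoring_rate must be in [0, 1]")
        if not 0.0 <= self.score_missing_rate <= 1.0:
            raise InvalidConfigError("score_missing_rate must be in [0, 1]")
        if self.duplicate_cores < 1:
            raise InvalidConfigError("duplicate_cores must be >= 1")
        if self.dispersion <= 0 or self.core_cv < 0:
            raise InvalidConfigError("dispersion must be > 0, core_cv >= 0")


def _gamma_around(rng, mean: float, cv: float, size=None):
    """Gamma draws with the requested mean and coefficient of variation."""
    if mean == 0:
        return np.zeros(size) if size is not None else 0.0
    if cv <= 0:
        return np.full(size, mean) if size is not None else mean
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


EXPRESSION_COLUMNS = ["subject_id", "core_id", "roi_class", "compartment", "score"]

_ROI_COMPARTMENT = {
    "tumor_stroma": "stroma",
    "tumor_epithelium": "epithelium",
    "benign_stroma": "stroma",
    "benign_epithelium": "epithelium",
}


def _survival(rng, n: int, lvi: np.ndarray, config: CohortSimConfig):
    lam0 = math.log(2.0) / config.baseline_median_os
    lam = lam0 * np.exp(config.hazard_log_hr_lvi * lvi.astype(float))
    t_event = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        lam_c = lam0 * config.censoring_rate / (1.0 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.max_followup)
    os_months = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return os_months, event


def generate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the IF cohort: per-core expression records + clinical table.

    Expression is long-form, one row per subject x ROI x duplicate core.
    The clinical table carries every covariate the downstream annotation and
    statistics stages consume, including raw response fields and diagnosis /
    last-contact dates from which overall survival is recomputed.
    """
    rng = np.random.default_rng(config.seed)
    expr_rows: list[dict] = []
    clin_rows: list[dict] = []

    def add_scores(subject_id: str, roi: str, mean: float) -> None:
        true = _gamma_around(rng, mean, config.dispersion)
        for k in range(config.duplicate_cores):
            score = _gamma_around(rng, true, config.core_cv)
            if config.score_missing_rate > 0 and rng.uniform() < config.score_missing_rate:
                score = np.nan
            expr_rows.append(
                {
                    "subject_id": subject_id,
                    "core_id": f"{subject_id}_{roi}_{k + 1}",
                    "roi_class": roi,
                    "compartment": _ROI_COMPARTMENT[roi],
                    "score": score,
                }
            )

    n = config.n_tumor
    lvi_all = rng.uniform(size=n) < config.lvi_prevalence
    os_months, event = _survival(rng, n, lvi_all, config)
    reviewed = rng.uniform(size=n) < config.pathology_review_fraction

    for i in range(n):
        sid = f"T{i + 1:04d}"
        add_scores(sid, "tumor_stroma", config.tumor_stroma_mean)
        add_scores(sid, "tumor_epithelium", config.tumor_epi_mean)

        age = float(np.clip(rng.normal(60.0, 11.0), 24.0, 83.0))
        stage = rng.choice(["I", "II", "III", "IV"], p=[0.08, 0.07, 0.60, 0.25])
        grade = "high" if rng.uniform() < 0.95 else "low"
        cr = rng.uniform() < 0.77
        measurable = rng.uniform() < 0.6
        dx = date(2000, 1, 1) + timedelta(days=int(rng.uniform(0, 12 * 365.25)))
        last = dx + timedelta(days=int(round(os_months[i] * 30.4375)))
        clin_rows.append(
            {
                "subject_id": sid,
                "cohort": 2,
                "group": "tumor",
                "age_dx": age,
                "histology": "serous",
                "grade": grade,
                "stage": stage,
                "pT": rng.choice(["<=20mm", "20-50mm", ">50mm"], p=[0.10, 0.13, 0.77]),
                "pN": rng.choice(["involved", "not_involved", "NA"], p=[0.13, 0.40, 0.47]),
                "debulking": rng.choice(["optimal", "suboptimal"], p=[0.79, 0.21]),
                "neoadjuvant": False,
                "recurrent_tissue": False,
                "measurable_disease": measurable,
                "lesion_response": (
                    ("complete" if cr else rng.choice(["partial", "stable", "progression"]))
                    if measurable
                    else None
                ),
                "ca125_normalized_4wk": (cr if not measurable else None),
                "ca125_drop_gt50_4wk": ((not cr) if not measurable else None),
                "progressed_during_adjuvant": False,
                "dx_date": dx,
                "last_contact_or_death_date": last,
                "vital_status": "dead" if event[i] else "alive",
                "til_present": bool(rng.uniform() < 0.43) if reviewed[i] else None,
                "cystic": bool(rng.uniform() < 0.69) if reviewed[i] else None,
                "lvi": bool(lvi_all[i]) if reviewed[i] else None,
            }
        )

    for i in range(config.n_benign):
        sid = f"B{i + 1:04d}"
        add_scores(sid, "benign_stroma", config.benign_stroma_mean)
        add_scores(sid, "benign_epithelium", config.benign_epi_mean)
        clin_rows.append(
            {
                "subject_id": sid,
                "cohort": 2,
                "group": "benign",
                "age_dx": float(np.clip(rng.normal(52.0, 10.0), 24.0, 83.0)),
                "histology": "benign",
                "grade": None,
                "stage": None,
                "pT": None,
                "pN": None,
                "debulking": None,
                "neoadjuvant": False,
                "recurrent_tissue": False,
                "measurable_disease": None,
                "lesion_response": None,
                "ca125_normalized_4wk": None,
                "ca125_drop_gt50_4wk": None,
                "progressed_during_adjuvant": False,
                "dx_date": None,
                "last_contact_or_death_date": None,
                "vital_status": None,
                "til_present": None,
                "cystic": None,
                "lvi": None,
            }
        )

    expression = pd.DataFrame(expr_rows, columns=EXPRESSION_COLUMNS)
    clinical = pd.DataFrame(clin_rows)
    return expression, clinical


@dataclass
class IhcCohortSimConfig:
    """Conditions for the immunohistochemistry-scored cohort.

    Pathologist scoring is categorical: staining intensity 0-3 times a
    percent-positive category 0-3.  The per-compartment category
    probabilities default to values whose implied mean H-scores echo the
    observed compartment means (tumor stroma ~0.3, tumor epithelium ~2.6,
    benign stroma ~0.9, benign epithelium ~3.1).
    """

    n_tumor: int = 73
    n_benign: int = 33
    # P(intensity = 0..3) per compartment
    tumor_stroma_intensity_p: tuple = (0.80, 0.15, 0.04, 0.01)
    tumor_epi_intensity_p: tuple = (0.22, 0.40, 0.25, 0.13)
    benign_stroma_intensity_p: tuple = (0.60, 0.28, 0.08, 0.04)
    benign_epi_intensity_p: tuple = (0.15, 0.35, 0.30, 0.20)
    # percent-positive range (uniform) given any staining, per tissue type
    stroma_percent_range: tuple = (1.0, 45.0)
    epi_percent_range: tuple = (10.0, 90.0)
    censoring_rate: float = 0.11
    baseline_median_os: float = 40.6  # months
    max_followup: float = 393.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_benign < 0:
            raise InvalidConfigError("cohort sizes must be >= 0")
        for p in (
            self.tumor_stroma_intensity_p,
            self.tumor_epi_intensity_p,
            self.benign_stroma_intensity_p,
            self.benign_epi_intensity_p,
        ):
            if len(p) != 4 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise InvalidConfigError("intensity probabilities must be a 4-simplex")


IHC_COLUMNS = ["subject_id", "roi_class", "intensity_cat", "percent_positive"]


def generate_ihc_cohort(config: IhcCohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the IHC cohort: categorical observations + clinical table."""
    rng = np.random.default_rng(config.seed)
    obs_rows: list[dict] = []
    clin_rows: list[dict] = []

    def draw(sid, roi, intensity_p, pct_range):
        i_cat = int(rng.choice(4, p=np.asarray(intensity_p, dtype=float)))
        pct = float(rng.uniform(*pct_range)) if i_cat > 0 else 0.0
        obs_rows.append(
            {"subject_id": sid, "roi_class": roi, "intensity_cat": i_cat, "percent_positive": pct}
        )

    n = config.n_tumor
    cfg_surv = CohortSimConfig(
        censoring_rate=config.censoring_rate,
        baseline_median_os=config.baseline_median_os,
        max_followup=config.max_followup,
        hazard_log_hr_lvi=0.0,
    )
    os_months, event = _survival(rng, n, np.zeros(n, dtype=bool), cfg_surv)

    for i in range(n):
        sid = f"C1T{i + 1:04d}"
        draw(sid, "tumor_stroma", config.tumor_stroma_intensity_p, config.stroma_percent_range)
        draw(sid, "tumor_epithelium", config.tumor_epi_intensity_p, config.epi_percent_range)
        cr = rng.uniform() < 0.51
        measurable = rng.uniform() < 0.6
        dx = date(1987, 1, 1) + timedelta(days=int(rng.uniform(0, 23 * 365.25)))
        clin_rows.append(
            {
                "subject_id": sid,
                "cohort": 1,
                "group": "tumor",
                "age_dx": float(np.clip(rng.normal(62.0, 10.0), 33.0, 83.0)),
                "histology": "serous",
                "grade": "high" if rng.uniform() < 0.96 else "low",
                "stage": rng.choice(["I", "II", "III", "IV"], p=[0.01, 0.01, 0.63, 0.35]),
                "pT": None,
                "pN": rng.choice(["involved", "not_involved", "NA"], p=[0.14, 0.48, 0.38]),
                "debulking": None,
                "neoadjuvant": False,
                "recurrent_tissue": False,
                "measurable_disease": measurable,
                "lesion_response": (
                    ("complete" if cr else rng.choice(["partial", "stable", "progression"]))
                    if measurable
                    else None
                ),
                "ca125_normalized_4wk": (cr if not measurable else None),
                "ca125_drop_gt50_4wk": ((not cr) if not measurable else None),
                "progressed_during_adjuvant": False,
                "dx_date": dx,
                "last_contact_or_death_date": dx
                + timedelta(days=int(round(os_months[i] * 30.4375))),
                "vital_status": "dead" if event[i] else "alive",
                "til_present": None,
                "cystic": None,
                "lvi": None,
            }
        )

    for i in range(config.n_benign):
        sid = f"C1B{i + 1:04d}"
        draw(sid, "benign_stroma", config.benign_stroma_intensity_p, config.stroma_percent_range)
        draw(sid, "benign_epithelium", config.benign_epi_intensity_p, config.epi_percent_range)
        clin_rows.append(
            {
                "subject_id": sid,
                "cohort": 1,
                "group": "benign",
                "age_dx": float(np.clip(rng.normal(50.0, 10.0), 24.0, 83.0)),
                "histology": "benign",
                "grade": None,
                "stage": None,
                "pT": None,
                "pN": None,
                "debulking": None,
                "neoadjuvant": False,
                "recurrent_tissue": False,
                "measurable_disease": None,
                "lesion_response": None,
                "ca125_normalized_4wk": None,
                "ca125_drop_gt50_4wk": None,
                "progressed_during_adjuvant": False,
                "dx_date": None,
                "last_contact_or_death_date": None,
                "vital_status": None,
                "til_present": None,
                "cystic": None,
                "lvi": None,
            }
        )

    return pd.DataFrame(obs_rows, columns=IHC_COLUMNS), pd.DataFrame(clin_rows)
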