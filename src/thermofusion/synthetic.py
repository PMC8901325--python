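"""Synthetic five-view thermogram cohorts with paired clinical records.

The generator emulates the structure an infrared breast-screening cohort
is assumed to have: each patient contributes five views (front, left 45°,
left 90°, right 90°, right 45°) of a smooth, bilaterally symmetric skin
temperature field around 33 °C, and sick patients additionally carry a
localized hotspot — a lesion's elevated metabolism raises the local skin
temperature — that appears consistently in the front view and the two
views on the affected side. Clinical records mirror a screening
questionnaire: mostly binary symptom/history answers plus age and
menarche age, with class-conditional distributions controlled by a single
effect-size dial.

Controlled defects (blur, missing views, protocol violations, injuries,
anomalous ages, blank questionnaire fields) can be injected after clean
generation so every quality-control rule downstream can be exercised
while ground truth is retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

VIEW_LABELS = ("front", "left45", "left90", "right90", "right45")
#: Fusion-layout order: front first, then 45° views, then 90° views.
VIEW_ORDER = ("front", "right45", "left45", "right90", "left90")

IMAGE_DEFECTS = ("blurry", "missing_view", "protocol_violation", "injury")
CLINICAL_DEFECTS = ("age_zero", "age_over_max", "blank_field")
SUPPORTED_DEFECTS = IMAGE_DEFECTS + CLINICAL_DEFECTS

DIAGNOSES = ("healthy", "sick")

#: Binary questionnaire features whose "yes" rate shifts with disease.
INFORMATIVE_BINARY = (
    "complaints", "symptoms", "signs", "nipple_changes", "wart_signs",
    "family_history", "cancer_family",
)
#: Binary lifestyle/history features drawn identically for both classes.
NEUTRAL_BINARY = (
    "menopause", "mammography", "radiotherapy", "plastic_surgery",
    "prosthesis", "biopsy", "hormone_replacement", "smoking_habit",
    "drinks_coffee", "consumes_alcohol", "physical_exercise",
    "applied_products",
)
MULTI_CATEGORY = {
    "marital_status": ("single", "married", "widowed", "divorced"),
    "race": ("white", "black", "pardo", "asian"),
    "eating_habits": ("balanced", "high_fat", "vegetarian"),
    "body_temperature": ("normal", "elevated"),
}
DISCRETE_FEATURES = INFORMATIVE_BINARY + NEUTRAL_BINARY + tuple(MULTI_CATEGORY)
CONTINUOUS_FEATURES = ("age_at_screening", "menarche_age")

_BASE_SYMPTOM_RATE = 0.15
_HEALTHY_AGE_MEAN, _AGE_SD = 50.0, 12.0
_AGE_SHIFT_PER_EFFECT = 20.0  # years of mean age shift per unit clinical_effect
_MENARCHE_MEAN, _MENARCHE_SD = 13.0, 1.5


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``hotspot_delta_t`` is the lesion's peak temperature elevation in °C;
    ``clinical_effect`` shifts the sick class's symptom rates (additively,
    on the probability scale) and mean age. ``defect_rates`` maps defect
    labels to per-patient injection probabilities.
    """

    n_healthy: int = 100
    n_sick: int = 100
    image_height: int = 480
    image_width: int = 640
    base_temp_mean: float = 33.0
    base_temp_sd: float = 0.5
    hotspot_delta_t: float = 2.0
    hotspot_sigma: float | None = None  # pixels; None -> min(h, w) / 16
    n_lesions: int = 1
    pixel_noise_sd: float = 0.3
    clinical_effect: float = 0.3
    dynamic_backup_rate: float = 0.3
    defect_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_sick"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("image_height", "image_width"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8, got {getattr(self, name)}")
        if self.hotspot_delta_t < 0:
            raise ValueError(f"hotspot_delta_t must be >= 0, got {self.hotspot_delta_t}")
        if self.n_lesions < 0:
            raise ValueError(f"n_lesions must be >= 0, got {self.n_lesions}")
        if not 0.0 <= self.dynamic_backup_rate <= 1.0:
            raise ValueError("dynamic_backup_rate must lie in [0, 1]")
        for defect, rate in self.defect_rates.items():
            if defect not in SUPPORTED_DEFECTS:
                raise ValueError(
                    f"defect_rates contains unknown defect {defect!r}; "
                    f"supported: {SUPPORTED_DEFECTS}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"defect_rates[{defect!r}] must lie in [0, 1], got {rate}")

    @property
    def resolved_hotspot_sigma(self) -> float:
        if self.hotspot_sigma is not None:
            return float(self.hotspot_sigma)
        return min(self.image_height, self.image_width) / 8.0


@dataclass
class ThermalStudy:
    """One patient's view-labelled thermal matrices plus QC metadata."""

    patient_id: str
    views: dict[str, np.ndarray]
    protocol: dict[str, str] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)
    diagnosis: str | None = None
    defect_views: dict[str, str] = field(default_factory=dict)
    dynamic_views: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = set()
        for label, matrix in self.views.items():
            if label not in VIEW_LABELS:
                raise ValueError(f"unknown view label {label!r}; expected one of {VIEW_LABELS}")
            if not np.all(np.isfinite(matrix)):
                raise ValueError(f"non-finite temperatures in view {label!r}")
            shapes.add(matrix.shape)
        if len(shapes) > 1:
            raise ValueError(f"views have inconsistent dimensions: {sorted(shapes)}")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")

    def copy(self) -> "ThermalStudy":
        return ThermalStudy(
            patient_id=self.patient_id,
            views={k: v.copy() for k, v in self.views.items()},
            protocol=dict(self.protocol),
            qc_flags=set(self.qc_flags),
            diagnosis=self.diagnosis,
            defect_views=dict(self.defect_views),
            dynamic_views={k: v.copy() for k, v in self.dynamic_views.items()},
        )


@dataclass
class ClinicalRecord:
    """One patient's raw questionnaire answers plus diagnosis label.

    Continuous values may be ``None`` (explicitly missing); discrete values
    are category strings, with ``""`` marking a blank (uncleaned) answer.
    """

    patient_id: str
    discrete: dict[str, str]
    continuous: dict[str, float | None]
    diagnosis: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")
        for name, value in self.continuous.items():
            if value is not None and not np.isfinite(value):
                raise ValueError(f"continuous feature {name!r} must be finite or None")

    def copy(self) -> "ClinicalRecord":
        return ClinicalRecord(
            patient_id=self.patient_id,
            discrete=dict(self.discrete),
            continuous=dict(self.continuous),
            diagnosis=self.diagnosis,
        )


def _draw_bumps(rng: np.random.Generator) -> list[tuple[float, ...]]:
    """Per-patient baseline shape: 2-4 broad bumps in fractional coords,
    shared by all five views of that patient."""
    n_bumps = int(rng.integers(2, 5))
    return [
        (
            rng.uniform(0.4, 1.2),     # amplitude, °C
            rng.uniform(0.2, 0.8),     # centre y fraction
            rng.uniform(0.1, 0.45),    # centre x fraction (left half; mirrored)
            rng.uniform(0.25, 0.5),    # sigma y fraction
            rng.uniform(0.2, 0.4),     # sigma x fraction
        )
        for _ in range(n_bumps)
    ]


def _base_field(height: int, width: int, mean_temp: float,
                bumps: list[tuple[float, ...]]) -> np.ndarray:
    """Smooth bilaterally symmetric baseline: broad Gaussian bumps mirrored
    about the vertical midline."""
    yy, xx = np.mgrid[0:height, 0:width]
    f = np.full((height, width), mean_temp, dtype=float)
    for amp, fy, fx, fsy, fsx in bumps:
        cy, cx = fy * height, fx * width
        sy, sx = fsy * height, fsx * width
        bump = amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2) / 2.0)
        mirror = amp * np.exp(
            -(((yy - cy) / sy) ** 2 + ((xx - (width - 1 - cx)) / sx) ** 2) / 2.0
        )
        f += bump + mirror
    return f


def _add_hotspot(matrix: np.ndarray, cy: int, cx: int, delta_t: float,
                 sigma: float) -> None:
    yy, xx = np.mgrid[0:matrix.shape[0], 0:matrix.shape[1]]
    matrix += delta_t * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))


def _hotspot_center(base: np.ndarray, col_slice: slice, jitter: int,
                    rng: np.random.Generator) -> tuple[int, int]:
    """Lesion site: the warmest point of the (sub-)field, with small jitter.

    Anchoring at the local temperature maximum reflects that lesions tend
    to sit in well-vascularised regions, and makes the cohort's max-
    temperature contrast track ``hotspot_delta_t`` directly.
    """
    h, w = base.shape
    region = base[:, col_slice]
    flat = int(np.argmax(region))
    cy, cx = np.unravel_index(flat, region.shape)
    cx += col_slice.indices(w)[0]
    cy = int(np.clip(cy + rng.integers(-jitter, jitter + 1), 0, h - 1))
    cx = int(np.clip(cx + rng.integers(-jitter, jitter + 1), 0, w - 1))
    return cy, cx


def _generate_study(config: SyntheticConfig, patient_id: str, diagnosis: str,
                    rng: np.random.Generator) -> ThermalStudy:
    h, w = config.image_height, config.image_width
    sigma = config.resolved_hotspot_sigma
    jitter = max(1, int(round(sigma / 4)))
    person_offset = rng.normal(0.0, config.base_temp_sd)
    side = rng.choice(["left", "right"]) if diagnosis == "sick" else None
    half = {"left": slice(0, w // 2), "right": slice(w // 2, w)}
    affected_views = (
        {"front", f"{side}45", f"{side}90"} if side is not None else set()
    )

    bumps = _draw_bumps(rng)
    views: dict[str, np.ndarray] = {}
    for label in VIEW_LABELS:
        base = _base_field(h, w, config.base_temp_mean + person_offset, bumps)
        if diagnosis == "sick" and label in affected_views:
            col = half[side] if label == "front" else slice(0, w)
            for _ in range(config.n_lesions):
                cy, cx = _hotspot_center(base, col, jitter, rng)
                # Amplitude referenced to the field maximum so the study's
                # peak temperature rises by hotspot_delta_t regardless of
                # where within the warm region the lesion lands.
                amp = config.hotspot_delta_t + (float(base.max()) - float(base[cy, cx]))
                if config.hotspot_delta_t > 0:
                    _add_hotspot(base, cy, cx, amp, sigma)
        if config.pixel_noise_sd > 0:
            base = base + rng.normal(0.0, config.pixel_noise_sd, size=(h, w))
        views[label] = base

    return ThermalStudy(
        patient_id=patient_id,
        views=views,
        protocol={label: "static" for label in VIEW_LABELS},
        diagnosis=diagnosis,
    )


def generate_clinical(config: SyntheticConfig, diagnosis: str,
                      rng: np.random.Generator | None = None,
                      patient_id: str = "P0000") -> ClinicalRecord:
    """Draw one questionnaire record conditional on the diagnosis.

    With ``clinical_effect == 0`` both classes are drawn from identical
    distributions; a positive effect raises the sick class's informative
    symptom rates and mean age.
    """
    if diagnosis not in DIAGNOSES:
        raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {diagnosis!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effect = config.clinical_effect if diagnosis == "sick" else 0.0

    discrete: dict[str, str] = {}
    p_info = float(np.clip(_BASE_SYMPTOM_RATE + effect, 0.0, 0.95))
    for name in INFORMATIVE_BINARY:
        discrete[name] = "yes" if rng.random() < p_info else "no"
    for name in NEUTRAL_BINARY:
        discrete[name] = "yes" if rng.random() < 0.3 else "no"
    for name, cats in MULTI_CATEGORY.items():
        if name == "body_temperature":
            p_elev = float(np.clip(0.05 + 0.4 * effect, 0.0, 0.95))
            discrete[name] = "elevated" if rng.random() < p_elev else "normal"
        else:
            discrete[name] = str(rng.choice(cats))

    age = float(rng.normal(_HEALTHY_AGE_MEAN + _AGE_SHIFT_PER_EFFECT * effect, _AGE_SD))
    age = float(np.clip(age, 18.0, 95.0))
    menarche = float(np.clip(rng.normal(_MENARCHE_MEAN, _MENARCHE_SD), 9.0, 18.0))

    record = ClinicalRecord(
        patient_id=patient_id,
        discrete=discrete,
        continuous={"age_at_screening": age, "menarche_age": menarche},
        diagnosis=diagnosis,
    )

    rates = config.defect_rates
    if rng.random() < rates.get("age_zero", 0.0):
        record.continuous["age_at_screening"] = 0.0
    elif rng.random() < rates.get("age_over_max", 0.0):
        record.continuous["age_at_screening"] = 120.0
    if rng.random() < rates.get("blank_field", 0.0):
        target = str(rng.choice(DISCRETE_FEATURES))
        record.discrete[target] = ""
    return record


def inject_defect(study: ThermalStudy, defect: str, seed: int = 0) -> ThermalStudy:
    """Return a copy of ``study`` carrying the given image defect.

    ``blurry`` smooths one view until its finite-difference gradient energy
    drops below half the original; ``missing_view`` deletes one view;
    ``injury`` adds a small high-contrast artefact; ``protocol_violation``
    marks one view as acquired off-protocol.
    """
    if defect not in IMAGE_DEFECTS:
        raise ValueError(
            f"unsupported defect {defect!r}; image defects are {IMAGE_DEFECTS}"
        )
    rng = np.random.default_rng(seed)
    out = study.copy()
    target = str(rng.choice(sorted(out.views)))

    if defect == "blurry":
        original = out.views[target]
        e0 = gradient_energy(original)
        blurred = original
        for sigma in (3.0, 6.0, 12.0, 24.0):
            blurred = ndimage.gaussian_filter(original, sigma=sigma)
            if gradient_energy(blurred) < 0.5 * e0:
                break
        out.views[target] = blurred
    elif defect == "missing_view":
        del out.views[target]
        out.protocol.pop(target, None)
    elif defect == "injury":
        h, w = out.views[target].shape
        cy = int(rng.integers(h // 4, 3 * h // 4))
        cx = int(rng.integers(w // 4, 3 * w // 4))
        _add_hotspot(out.views[target], cy, cx, 6.0, max(2.0, min(h, w) / 40.0))
    elif defect == "protocol_violation":
        out.protocol[target] = "off_protocol"

    out.qc_flags.add(defect)
    out.defect_views[defect] = target
    return out


def gradient_energy(matrix: np.ndarray) -> float:
    """Sum of squared finite differences along both axes."""
    dy = np.diff(matrix, axis=0)
    dx = np.diff(matrix, axis=1)
    return float((dy ** 2).sum() + (dx ** 2).sum())


def generate_cohort(config: SyntheticConfig) -> tuple[list[ThermalStudy], list[ClinicalRecord]]:
    """Generate ``n_healthy + n_sick`` paired studies and clinical records.

    Identical configs (including the seed) give bit-identical cohorts.
    Defects are injected after clean generation, per ``defect_rates``, and
    recorded in ``qc_flags`` so ground truth is retained.
    """
    studies: list[ThermalStudy] = []
    records: list[ClinicalRecord] = []
    labels = ["healthy"] * config.n_healthy + ["sick"] * config.n_sick
    for index, diagnosis in enumerate(labels):
        pid = f"P{index + 1:04d}"
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, index])
        study = _generate_study(config, pid, diagnosis, rng)
        record = generate_clinical(config, diagnosis, rng=rng, patient_id=pid)

        for defect in IMAGE_DEFECTS:
            rate = config.defect_rates.get(defect, 0.0)
            if rng.random() < rate:
                defect_seed = int(rng.integers(0, 2 ** 31 - 1))
                if defect in ("blurry", "missing_view") and (
                    rng.random() < config.dynamic_backup_rate
                ):
                    # A clean dynamic-protocol capture exists for the view
                    # the defect will hit; QC can substitute instead of
                    # removing the patient.
                    probe = inject_defect(study, defect, seed=defect_seed)
                    view = probe.defect_views[defect]
                    study.dynamic_views[view] = study.views[view].copy()
                study = inject_defect(study, defect, seed=defect_seed)

        studies.append(study)
        records.append(record)
    return studies, records


def cohort_arrays(studies: list[ThermalStudy], views: tuple[str, ...],
                  label_map: dict[str, int] | None = None
                  ) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Stack per-view matrices into arrays for model fitting.

    Returns ``(images, y, patient_ids)`` where ``images[view]`` has shape
    ``(n, h, w)``. Studies missing any requested view are rejected.
    """
    if label_map is None:
        label_map = {"healthy": 0, "sick": 1}
    images: dict[str, list[np.ndarray]] = {v: [] for v in views}
    y, ids = [], []
    for study in studies:
        missing = [v for v in views if v not in study.views]
        if missing:
            raise ValueError(
                f"study {study.patient_id} is missing required views {missing}; "
                "run QC filtering first"
            )
        for v in views:
            images[v].append(study.views[v])
        if study.diagnosis is None:
            raise ValueError(f"study {study.patient_id} has no diagnosis label")
        y.append(label_map[study.diagnosis])
        ids.append(study.patient_id)
    stacked = {v: np.stack(mats) if mats else np.empty((0, 0, 0)) for v, mats in images.items()}
    return stacked, np.asarray(y), ids


def config_replace(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """Convenience wrapper over dataclasses.replace with validation."""
    return dataclasses.replace(config, **overrides)
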