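"""Synthetic cohort generator.

Emulates the data structure of a multimodal temporal-lobe-epilepsy surgery
study: two-scanner control cohorts for regional gray-matter (GM) volume and
superficial-white-matter (SWM) mean diffusivity, patients with planted
regional structural abnormalities, intracranial-EEG implantations whose
colocalization with the abnormalities differs by outcome profile, band-power
spectral shifts in the implanted functional focus, resection sets, and ILAE
outcome labels drawn from a logistic link on the resected fractions of the
structural abnormality and of the spectral focus.

Everything is driven by a single integer seed; identical configuration and
seed give bit-identical output.  Ground truth (true abnormal / implanted /
resected sets, planted effect sizes, outcome) is returned alongside the
observable tables so parameter-recovery tests can score the pipeline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

GM = "GM_volume"
SWM = "SWM_MD"
IEEG = "iEEG_bandpower"

BANDS = ("delta", "theta", "alpha", "beta", "gamma")
BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
              "beta": (13.0, 30.0), "gamma": (30.0, 80.0)}

OUTCOME_GOOD = "ILAE12"
OUTCOME_POOR = "ILAE3plus"


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its contract."""


@dataclass(frozen=True)
class ModalityModel:
    """Control-population model for one imaging modality.

    value = roi_baseline + age_slope*(age - 40) + sex_effect*[male]
            + batch_offset + batch_scale * N(0, noise_sd)
    """

    name: str
    baseline_mean: float
    baseline_spread: float        # between-ROI spread of baselines
    noise_sd: float               # between-subject residual SD (feature units)
    age_slope: float = 0.0        # feature units per year
    sex_effect: float = 0.0       # male minus female contrast
    batch_offsets: Mapping[str, float] = field(default_factory=dict)
    batch_scales: Mapping[str, float] = field(default_factory=dict)


# Realistic desk-scale defaults: GM ROI volumes of a few cm^3 with ~10%
# between-subject spread; SWM mean diffusivity ~8e-4 mm^2/s with a subtle
# scanner offset, as seen in multi-protocol MRI studies.
DEFAULT_GM = ModalityModel(
    name=GM, baseline_mean=3000.0, baseline_spread=500.0, noise_sd=250.0,
    age_slope=-6.0, sex_effect=120.0,
    batch_offsets={"scannerA": 0.0, "scannerB": 80.0},
    batch_scales={"scannerA": 1.0, "scannerB": 1.2},
)
DEFAULT_SWM = ModalityModel(
    name=SWM, baseline_mean=8.0e-4, baseline_spread=0.6e-4, noise_sd=0.3e-4,
    age_slope=1.5e-6, sex_effect=-0.5e-5,
    batch_offsets={"scannerA": 0.0, "scannerB": 2.0e-5},
    batch_scales={"scannerA": 1.0, "scannerB": 1.1},
)

DEEP_NAMES = ("hippocampus", "amygdala", "thalamus", "putamen", "caudate",
              "pallidum", "accumbens")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level configuration (sizes follow the emulated study design:
    97 MRI controls and 40 surgical patients; 60 regions stand in for the
    full 460-region parcellation)."""

    n_controls: int = 97
    n_patients: int = 40
    n_rois: int = 60
    n_deep_rois: int = 4
    batches: tuple[str, ...] = ("scannerA", "scannerB")
    batch_fractions: tuple[float, ...] = (0.3, 0.7)
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 0.5        # probability of male
    modalities: tuple[ModalityModel, ...] = (DEFAULT_GM, DEFAULT_SWM)
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls <= 0 or self.n_patients < 0:
            raise ConfigurationError("cohort sizes must be positive")
        if self.n_rois < 2:
            raise ConfigurationError("need at least 2 ROIs")
        if self.n_rois % 2:
            raise ConfigurationError("n_rois must be even (two hemispheres)")
        if self.n_deep_rois % 2 or self.n_deep_rois >= self.n_rois:
            raise ConfigurationError("n_deep_rois must be even and < n_rois")
        if len(self.batches) != len(self.batch_fractions):
            raise ConfigurationError("batches and batch_fractions mismatch")
        if not np.isclose(sum(self.batch_fractions), 1.0):
            raise ConfigurationError("batch fractions must sum to 1")
        for m in self.modalities:
            for b in self.batches:
                if m.batch_scales.get(b, 1.0) <= 0:
                    raise ConfigurationError("batch scales must be > 0")


@dataclass(frozen=True)
class PatientSpec:
    """Planted-effect specification for one synthetic patient.

    Structural effects are in z-units of the control residual SD; the GM
    effect must be <= 0 (volume loss) and the SWM effect >= 0 (increased
    diffusivity).  ``spectral_effect`` (z-units, >= 0) is applied to
    ``spectral_band`` power in implanted true-abnormal regions only.
    """

    side: str = "left"
    n_abnormal_rois: int = 8
    gm_effect: float = -2.0
    swm_effect: float = 2.0
    spectral_effect: float = 3.0
    spectral_band: str = "beta"
    implant_fidelity: float = 0.9
    n_implanted: int = 14
    resect_fraction: float = 0.75  # targeting efficiency over implanted abnormal ROIs
    resect_fraction_sd: float = 0.2    # between-patient spread of the above
    incidental_resect: float = 0.15   # unimplanted abnormal ROI swept up anyway
    spectral_misalignment: float = 0.1  # spectral focus displaced off the
                                        # structural abnormality (onto another
                                        # implanted region)
    spectral_misalignment_sd: float = 0.08  # between-patient spread
    n_resected_extra: int = 4     # non-abnormal ipsilateral ROIs also resected
    # Outcome model: seizure freedom requires removing both the structural
    # abnormality and the electrophysiologically active (spectral) focus:
    # logit P(ILAE 1,2) = intercept + slope * prop_structural_resected
    #                     + spectral_slope * prop_spectral_resected
    outcome_slope: float = 3.0
    outcome_spectral_slope: float = 10.0
    outcome_intercept: float = -5.5
    true_abnormal_rois: tuple[str, ...] | None = None   # explicit override

    def validate(self, config: CohortConfig) -> None:
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"unknown side {self.side!r}")
        if self.gm_effect > 0:
            raise ConfigurationError("gm_effect must be <= 0 (volume loss)")
        if self.swm_effect < 0:
            raise ConfigurationError("swm_effect must be >= 0 (increased MD)")
        if self.spectral_effect < 0:
            raise ConfigurationError("spectral_effect must be >= 0")
        if self.spectral_band not in BANDS:
            raise ConfigurationError(f"unknown band {self.spectral_band!r}")
        for p in (self.implant_fidelity, self.resect_fraction,
                  self.incidental_resect, self.spectral_misalignment):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        if config.n_rois < 2 * self.n_abnormal_rois:
            raise ConfigurationError("n_rois must be >= 2 * n_abnormal_rois")


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    side: str
    true_abnormal_rois: frozenset[str]
    implanted_rois: frozenset[str]
    spectral_rois: frozenset[str]     # implanted ROIs carrying the planted
                                      # band-power shift
    resected_rois: frozenset[str]
    outcome: str
    proportion_true_resected: float
    effects: dict


def default_patient_specs(n_patients: int = 40, n_favorable: int = 19,
                          unfavorable_overrides: Mapping | None = None,
                          **overrides) -> list[PatientSpec]:
    """Two-profile cohort emulating the study's outcome contrast: favorable
    profiles implant and resect the truly abnormal regions with high
    fidelity and their functional (spectral) focus coincides with the
    structural abnormality; unfavorable profiles implant at chance level,
    resect little of the abnormality, and their spectral focus is largely
    displaced onto other implanted tissue."""
    fav_kw = {"implant_fidelity": 0.9, "spectral_misalignment": 0.05, **overrides}
    favorable = PatientSpec(**fav_kw)
    unfav_kw = {"implant_fidelity": 0.4, "spectral_misalignment": 0.95,
                **(dict(unfavorable_overrides or {}))}
    unfavorable = replace(favorable, **unfav_kw)
    sides = ["left", "right"]
    specs = []
    for i in range(n_patients):
        base = favorable if i < n_favorable else unfavorable
        specs.append(replace(base, side=sides[i % 2]))
    return specs


def make_parcellation(config: CohortConfig) -> pd.DataFrame:
    """Two-hemisphere toy parcellation with deep structures and well
    separated centroids (mm), columns: roi_id, name, hemisphere, deep_flag,
    x_mm, y_mm, z_mm."""
    per_hemi = config.n_rois // 2
    deep_per_hemi = config.n_deep_rois // 2
    rows = []
    for hemi, sign in (("left", -1.0), ("right", 1.0)):
        h = hemi[0].upper()
        for i in range(per_hemi):
            deep = i < deep_per_hemi
            if deep:
                name = DEEP_NAMES[i % len(DEEP_NAMES)]
                x, y, z = sign * 25.0, -20.0 - 14.0 * i, -10.0
            else:
                name = f"cortex{i - deep_per_hemi + 1:02d}"
                j = i - deep_per_hemi
                x = sign * (45.0 + 12.0 * (j % 3))
                y, z = -60.0 + 16.0 * (j // 3 % 8), -30.0 + 18.0 * (j // 24)
            rows.append({"roi_id": f"{h}_{name}", "name": name, "hemisphere": hemi,
                         "deep_flag": deep, "x_mm": x, "y_mm": y, "z_mm": z})
    df = pd.DataFrame(rows)
    if df["roi_id"].duplicated().any():
        raise ConfigurationError("parcellation produced duplicate roi ids")
    return df


def roi_points(parcellation: pd.DataFrame) -> dict[str, np.ndarray]:
    """ROI representative point clouds (here: the centroid) for contact
    assignment, keyed by roi_id."""
    return {r.roi_id: np.array([[r.x_mm, r.y_mm, r.z_mm]])
            for r in parcellation.itertuples()}


def _demographics(n: int, prefix: str, config: CohortConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    ages = rng.uniform(*config.age_range, size=n).round(1)
    sexes = np.where(rng.random(n) < config.sex_ratio, "M", "F")
    batch = rng.choice(config.batches, size=n, p=config.batch_fractions)
    return pd.DataFrame({
        "subject_id": [f"{prefix}{i:03d}" for i in range(n)],
        "age": ages, "sex": sexes, "batch": batch,
    })


def _roi_baselines(config: CohortConfig, model: ModalityModel,
                   parcellation: pd.DataFrame) -> pd.Series:
    # Baselines depend only on (seed, modality) so controls and patients
    # share the same underlying population model.
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 101, zlib.crc32(model.name.encode())]))
    vals = model.baseline_mean + model.baseline_spread * rng.standard_normal(len(parcellation))
    return pd.Series(vals, index=parcellation["roi_id"].to_numpy())


def _feature_table(demo: pd.DataFrame, model: ModalityModel, baselines: pd.Series,
                   rng: np.random.Generator) -> pd.DataFrame:
    n, r = len(demo), len(baselines)
    age_term = model.age_slope * (demo["age"].to_numpy() - 40.0)
    sex_term = model.sex_effect * (demo["sex"].to_numpy() == "M")
    offs = np.array([model.batch_offsets.get(b, 0.0) for b in demo["batch"]])
    scales = np.array([model.batch_scales.get(b, 1.0) for b in demo["batch"]])
    noise = rng.standard_normal((n, r)) * model.noise_sd
    values = (baselines.to_numpy()[None, :]
              + (age_term + sex_term + offs)[:, None]
              + scales[:, None] * noise)
    out = pd.DataFrame({
        "subject_id": np.repeat(demo["subject_id"].to_numpy(), r),
        "roi_id": np.tile(baselines.index.to_numpy(), n),
        "modality": model.name,
        "value": values.ravel(),
        "age": np.repeat(demo["age"].to_numpy(), r),
        "sex": np.repeat(demo["sex"].to_numpy(), r),
        "batch": np.repeat(demo["batch"].to_numpy(), r),
    })
    return out


def generate_control_features(config: CohortConfig,
                              parcellation: pd.DataFrame | None = None
                              ) -> dict[str, pd.DataFrame]:
    """Per-modality control feature tables (long format)."""
    config.validate()
    if parcellation is None:
        parcellation = make_parcellation(config)
    root = np.random.SeedSequence([config.seed, 1])
    demo_rng, *mod_rngs = [np.random.default_rng(s)
                           for s in root.spawn(1 + len(config.modalities))]
    demo = _demographics(config.n_controls, "control", config, demo_rng)
    tables = {}
    for model, rng in zip(config.modalities, mod_rngs):
        baselines = _roi_baselines(config, model, parcellation)
        tables[model.name] = _feature_table(demo, model, baselines, rng)
    return tables


def generate_patient_features(config: CohortConfig, specs: Sequence[PatientSpec],
                              parcellation: pd.DataFrame | None = None
                              ) -> tuple[dict[str, pd.DataFrame], list[GroundTruth]]:
    """Patient feature tables with planted structural deviations, plus the
    ground truth (abnormal / implanted / resected sets and outcome labels).

    Patients are drawn from the control model, then the planted z-unit
    shifts are applied in the true abnormal ROIs: GM volume reduced by
    |gm_effect| * noise_sd, SWM MD increased by swm_effect * noise_sd.
    """
    config.validate()
    if parcellation is None:
        parcellation = make_parcellation(config)
    roi_ids = parcellation["roi_id"].to_numpy()
    for spec in specs:
        spec.validate(config)
        if spec.true_abnormal_rois is not None:
            unknown = set(spec.true_abnormal_rois) - set(roi_ids)
            if unknown:
                raise ConfigurationError(f"unknown ROIs in spec: {sorted(unknown)}")

    root = np.random.SeedSequence([config.seed, 2])
    demo_rng, truth_rng, *mod_rngs = [np.random.default_rng(s)
                                      for s in root.spawn(2 + len(config.modalities))]
    demo = _demographics(len(specs), "patient", config, demo_rng)

    truths = _plant_ground_truth(specs, parcellation, demo, truth_rng)
    effect_by_mod = {GM: [t.effects["gm_effect"] for t in truths],
                     SWM: [t.effects["swm_effect"] for t in truths]}
    tables = {}
    for model, rng in zip(config.modalities, mod_rngs):
        baselines = _roi_baselines(config, model, parcellation)
        table = _feature_table(demo, model, baselines, rng)
        shift = np.zeros(len(table))
        abnormal_mask = np.zeros(len(table), dtype=bool)
        for i, t in enumerate(truths):
            rows = (table["subject_id"] == t.patient_id).to_numpy()
            in_set = table["roi_id"].isin(t.true_abnormal_rois).to_numpy()
            abnormal_mask |= rows & in_set
            eff = effect_by_mod.get(model.name, [0.0] * len(truths))[i]
            shift[rows & in_set] = eff * model.noise_sd
        table["value"] = table["value"] + shift
        tables[model.name] = table
    return tables, truths


def _plant_ground_truth(specs, parcellation, demo, rng) -> list[GroundTruth]:
    truths = []
    for spec, pid in zip(specs, demo["subject_id"]):
        hemi = parcellation[parcellation["hemisphere"] == spec.side]
        ipsi = hemi["roi_id"].to_numpy()
        if spec.true_abnormal_rois is not None:
            abnormal = list(spec.true_abnormal_rois)
        else:
            # the deep "hippocampus" analogue is involved more often than
            # chance, emulating the mesial-temporal concentration of
            # abnormalities, but not in every patient
            hippo = [r for r in ipsi if "hippocampus" in r
                     and rng.random() < 0.6]
            pool = [r for r in ipsi if r not in hippo and "hippocampus" not in r]
            extra = rng.choice(pool, size=spec.n_abnormal_rois - len(hippo),
                               replace=False)
            abnormal = hippo + list(extra)
        # implantation: abnormal ROIs with probability implant_fidelity,
        # remaining slots uniform over other ipsilateral ROIs
        implanted = [r for r in abnormal if rng.random() < spec.implant_fidelity]
        others = [r for r in ipsi if r not in abnormal]
        n_fill = max(0, spec.n_implanted - len(implanted))
        if n_fill and others:
            implanted += list(rng.choice(others, size=min(n_fill, len(others)),
                                         replace=False))
        # per-patient heterogeneity around the profile values: surgical
        # targeting efficiency and functional-focus misalignment vary
        # between individuals, independently of each other
        rf = float(np.clip(rng.normal(spec.resect_fraction,
                                      spec.resect_fraction_sd), 0.05, 1.0))
        mis = float(np.clip(rng.normal(spec.spectral_misalignment,
                                       spec.spectral_misalignment_sd), 0.0, 1.0))
        # spectral (functional) focus: the implanted abnormal ROIs, each
        # displaced onto another implanted region with probability
        # spectral_misalignment (mislocalized functional abnormality)
        impl_abn = [r for r in implanted if r in abnormal]
        impl_other = [r for r in implanted if r not in abnormal]
        spectral = []
        for r in impl_abn:
            if rng.random() < mis and impl_other:
                j = int(rng.integers(len(impl_other)))
                spectral.append(impl_other.pop(j))
            else:
                spectral.append(r)
        # resection: surgery can only target what the evaluation implicated —
        # implanted abnormal ROIs are removed with probability
        # resect_fraction, unimplanted abnormal ones only incidentally, plus
        # a few non-abnormal ipsilateral neighbours
        resected = [r for r in abnormal
                    if rng.random() < (rf if r in implanted
                                       else spec.incidental_resect)]
        resected += list(rng.choice(others, size=min(spec.n_resected_extra,
                                                     len(others)), replace=False))
        prop = len(set(resected) & set(abnormal)) / len(abnormal) if abnormal else 0.0
        prop_spec = (len(set(resected) & set(spectral)) / len(spectral)
                     if spectral else 0.0)
        p_good = 1.0 / (1.0 + np.exp(-(spec.outcome_intercept
                                       + spec.outcome_slope * prop
                                       + spec.outcome_spectral_slope * prop_spec)))
        outcome = OUTCOME_GOOD if rng.random() < p_good else OUTCOME_POOR
        truths.append(GroundTruth(
            patient_id=pid, side=spec.side,
            true_abnormal_rois=frozenset(abnormal),
            implanted_rois=frozenset(implanted),
            spectral_rois=frozenset(spectral),
            resected_rois=frozenset(resected),
            outcome=outcome, proportion_true_resected=prop,
            effects={"gm_effect": spec.gm_effect, "swm_effect": spec.swm_effect,
                     "spectral_effect": spec.spectral_effect,
                     "spectral_band": spec.spectral_band},
        ))
    return truths


def surgery_table(truths: Sequence[GroundTruth], parcellation: pd.DataFrame,
                  seed: int = 0) -> pd.DataFrame:
    """Per-(patient, ROI) surgery table with resection-overlap fractions that
    reconstruct the resected set under the strict >0.10 rule, plus
    implanted flags and outcome labels."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for t in truths:
        for roi in parcellation["roi_id"]:
            if roi in t.resected_rois:
                frac = rng.uniform(0.3, 0.95)
            else:
                frac = rng.uniform(0.0, 0.08)
            rows.append({"patient_id": t.patient_id, "roi_id": roi,
                         "overlap_fraction": frac,
                         "implanted": roi in t.implanted_rois,
                         "outcome": t.outcome, "side": t.side})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# iEEG synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IEEGConfig:
    """Band-limited-noise recording model.

    Each channel is a sum of five band-limited noise components with a
    1/f-like base power profile; per-channel per-band log10 power jitter
    (SD ``jitter_log10``) creates the between-subject spread the normative
    map measures, so a planted z-unit spectral effect converts to a power
    scaling of 10**(effect * jitter_log10).
    """

    fs: float = 256.0
    duration_s: float = 72.0
    band_power_base: Mapping[str, float] = field(default_factory=lambda: {
        "delta": 1.0, "theta": 0.5, "alpha": 0.35, "beta": 0.15, "gamma": 0.05})
    jitter_log10: float = 0.1
    contacts_per_roi: int = 2
    n_normative_subjects: int = 30
    contact_scatter_mm: float = 2.0

    def validate(self) -> None:
        if self.fs < 160.0:
            raise ConfigurationError("sampling rate must be >= 160 Hz")
        if self.duration_s < 70.0:
            raise ConfigurationError("duration must be >= 70 s")
        if self.contacts_per_roi < 1 or self.n_normative_subjects < 2:
            raise ConfigurationError("invalid iEEG cohort sizes")


@dataclass
class ElectrodeStudy:
    """One subject's implantation: contact table, multichannel interictal
    time series, and the ROI each contact was placed in (generator truth —
    the pipeline re-derives assignment from coordinates)."""

    subject_id: str
    contacts: pd.DataFrame          # contact_id, x_mm, y_mm, z_mm, tissue, roi_truth
    data: np.ndarray                # channels x samples
    fs: float
    normative: bool = False


def _band_sos(fs: float) -> dict[str, np.ndarray]:
    nyq = fs / 2.0
    return {b: butter(4, [lo / nyq, min(hi, nyq * 0.99) / nyq], btype="band",
                      output="sos") for b, (lo, hi) in BAND_EDGES.items()}


def _synth_signals(n_channels: int, cfg: IEEGConfig, band_log10_power: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sum of unit-variance band-limited noise components scaled to the
    requested per-channel per-band powers (log10)."""
    n = int(round(cfg.fs * cfg.duration_s))
    sos = _band_sos(cfg.fs)
    out = np.zeros((n_channels, n))
    for j, band in enumerate(BANDS):
        white = rng.standard_normal((n_channels, n))
        comp = sosfiltfilt(sos[band], white, axis=-1)
        comp /= comp.std(axis=-1, keepdims=True)
        amp = np.sqrt(10.0 ** band_log10_power[:, j])
        out += amp[:, None] * comp
    return out


def _place_contacts(rois: Sequence[str], parcellation: pd.DataFrame,
                    cfg: IEEGConfig, rng: np.random.Generator,
                    prefix: str) -> pd.DataFrame:
    cent = parcellation.set_index("roi_id")[["x_mm", "y_mm", "z_mm"]]
    rows = []
    k = 0
    for roi in rois:
        for _ in range(cfg.contacts_per_roi):
            offset = rng.uniform(-1, 1, size=3)
            offset *= cfg.contact_scatter_mm / max(np.linalg.norm(offset), 1e-9) \
                * rng.random() ** (1 / 3)
            x, y, z = cent.loc[roi].to_numpy() + offset
            rows.append({"contact_id": f"{prefix}c{k:03d}", "x_mm": x, "y_mm": y,
                         "z_mm": z, "tissue": "GM", "roi_truth": roi})
            k += 1
    return pd.DataFrame(rows)


def _power_scale_for_effect(effect: float, band: str, cfg: IEEGConfig) -> float:
    """Raw power scaling that shifts the *relative* band power by ``effect``
    z-units (i.e. effect * jitter_log10 in log10 relative power).

    Relative powers are renormalized to sum to 1 downstream, so scaling a
    band's raw power by s moves its relative power from f to
    s*f / (1 + (s-1)*f); this inverts that mapping.  Effects that would
    push the relative power to or past 1 are infeasible.
    """
    w = np.array([cfg.band_power_base[b] for b in BANDS], dtype=float)
    f = w[BANDS.index(band)] / w.sum()
    g = 10.0 ** (effect * cfg.jitter_log10)
    if g * f >= 0.999:
        raise ConfigurationError(
            f"spectral effect {effect} infeasible for band {band!r}: "
            f"relative power would reach {g * f:.3f}")
    return g * (1.0 - f) / (1.0 - g * f)


def generate_ieeg_study(patient_id: str, spec: PatientSpec, truth: GroundTruth,
                        parcellation: pd.DataFrame, cfg: IEEGConfig,
                        seed: int = 0) -> ElectrodeStudy:
    """Synthesize one patient's implantation and interictal recording.

    Contacts are placed near the centroids of the implanted ROIs; the
    designated band's power is scaled by 10**(spectral_effect*jitter_log10)
    in the patient's spectral-focus ROIs (implanted abnormal regions, or
    their displaced counterparts under spectral misalignment).
    """
    cfg.validate()
    spec.validate(CohortConfig(n_rois=len(parcellation),
                               n_deep_rois=int(parcellation["deep_flag"].sum())))
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 4, zlib.crc32(patient_id.encode())]))
    rois = sorted(truth.implanted_rois)
    contacts = _place_contacts(rois, parcellation, cfg, rng, f"{patient_id}_")
    base = np.log10([cfg.band_power_base[b] for b in BANDS])
    logp = base[None, :] + cfg.jitter_log10 * rng.standard_normal((len(contacts), 5))
    band_idx = BANDS.index(spec.spectral_band)
    hot = contacts["roi_truth"].isin(truth.spectral_rois).to_numpy()
    logp[hot, band_idx] += np.log10(_power_scale_for_effect(
        spec.spectral_effect, spec.spectral_band, cfg))
    data = _synth_signals(len(contacts), cfg, logp, rng)
    return ElectrodeStudy(subject_id=patient_id, contacts=contacts, data=data,
                          fs=cfg.fs, normative=False)


def generate_ieeg_normative(parcellation: pd.DataFrame, cfg: IEEGConfig,
                            seed: int = 0) -> list[ElectrodeStudy]:
    """Normative channel cohort: every subject contributes one contact per
    ROI with no planted effects, emulating a non-epileptogenic reference."""
    cfg.validate()
    rois = list(parcellation["roi_id"])
    base = np.log10([cfg.band_power_base[b] for b in BANDS])
    studies = []
    for i in range(cfg.n_normative_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 5, i]))
        one = replace(cfg, contacts_per_roi=1)
        contacts = _place_contacts(rois, parcellation, one, rng, f"norm{i:03d}_")
        logp = base[None, :] + cfg.jitter_log10 * rng.standard_normal((len(contacts), 5))
        data = _synth_signals(len(contacts), one, logp, rng)
        studies.append(ElectrodeStudy(subject_id=f"norm{i:03d}", contacts=contacts,
                                      data=data, fs=cfg.fs, normative=True))
    return studies
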