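"""End-to-end orchestration: simulate (or ingest) → harmonize → normative
maps → iEEG band power → abnormal sets → resection overlap → outcome
statistics.

Defaults reproduce the analysis settings of the emulated study design:
200 Hz resampling, 70-s epochs, 2-s/1-s Hamming Welch windows, five bands,
5-mm / 2-mm contact-assignment rules, and the strict >10% resection-overlap
rule.  Every random draw derives from the single config seed; rerunning
with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abnormality as abn
from . import bandpower as bp
from . import stats as st
from . import synthetic as syn
from .harmonize import harmonize_batches
from .normative import build_normative_map, zscore_patients

log = logging.getLogger("epimap")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

MRI_TAG = "MRI"
MULTI_TAG = "MRI+iEEG"


@dataclass
class PipelineConfig:
    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    ieeg: syn.IEEGConfig = field(default_factory=syn.IEEGConfig)
    abnormality: abn.AbnormalityConfig = field(default_factory=abn.AbnormalityConfig)
    n_favorable: int = 19                 # favorable-profile patients (of n_patients)
    patient_overrides: dict = field(default_factory=dict)
    unfavorable_overrides: dict = field(default_factory=dict)
    target_rate_hz: float = 200.0
    epoch_s: float = 70.0
    overlap_threshold: float = st.RESECTED_OVERLAP_THRESHOLD
    max_region_dist_mm: float = 5.0
    max_wm_gm_dist_mm: float = 2.0
    sd_floor: float = 1e-6
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.seed != self.cohort.seed:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "modalities" in c:
                c["modalities"] = tuple(
                    syn.ModalityModel(**m) if isinstance(m, dict) else m
                    for m in c["modalities"])
            for key in ("batches", "batch_fractions", "age_range"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = syn.CohortConfig(**c)
        if "ieeg" in d:
            d["ieeg"] = syn.IEEGConfig(**d["ieeg"])
        if "abnormality" in d:
            a = dict(d["abnormality"])
            if "changepoint" in a and isinstance(a["changepoint"], dict):
                from .changepoint import ChangePointConfig
                a["changepoint"] = ChangePointConfig(**a["changepoint"])
            d["abnormality"] = abn.AbnormalityConfig(**a)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    parcellation: pd.DataFrame
    ground_truth: list
    zscores: dict            # modality -> DataFrame
    abnormal_sets: dict      # patient -> {modality/tag -> AbnormalSet}
    overlap_scores: pd.DataFrame
    results: dict
    prevalence: dict         # tag -> DataFrame


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("ieeg_features")
def _ieeg_feature_table(studies, parcellation, demo_by_subject, cfg: PipelineConfig
                        ) -> pd.DataFrame:
    """Run the band-power chain on each study and pool a long feature table
    (sampled ROIs only)."""
    geometry = syn.roi_points(parcellation)
    rows = []
    for study in studies:
        rec = bp.Recording(data=study.data, fs=study.fs,
                           channel_ids=tuple(study.contacts["contact_id"]))
        rec = bp.preprocess(rec, target_rate=cfg.target_rate_hz)
        rec = bp.extract_epoch(rec, length_s=cfg.epoch_s)
        freqs, psd = bp.welch_psd(rec)
        powers = bp.band_powers(freqs, psd, rec.channel_ids)
        assign = bp.assign_contacts(study.contacts, geometry,
                                    max_region_dist_mm=cfg.max_region_dist_mm,
                                    max_wm_gm_dist_mm=cfg.max_wm_gm_dist_mm)
        regional = bp.regional_band_power(powers, assign)
        demo = demo_by_subject[study.subject_id]
        for r in regional.itertuples():
            rows.append({"subject_id": study.subject_id, "roi_id": r.roi_id,
                         "band": r.band, "modality": syn.IEEG, "value": r.value,
                         "age": demo["age"], "sex": demo["sex"],
                         "batch": "ieeg", "normative": study.normative})
    return pd.DataFrame(rows)


def _colocalization(sets_by_patient, truths, parcellation, response: str) -> dict:
    """Logistic colocalization per outcome group: response (implanted or
    iEEG-abnormal) ~ MRI-abnormal, over ipsilateral ROIs (implantations are
    ipsilateral by design, so contralateral regions carry no information)."""
    out = {}
    for outcome in (syn.OUTCOME_GOOD, syn.OUTCOME_POOR):
        xs, ys = [], []
        for t in truths:
            if t.outcome != outcome:
                continue
            sets = sets_by_patient[t.patient_id]
            mri = sets[MRI_TAG].rois
            ipsi = parcellation.loc[parcellation["hemisphere"] == t.side, "roi_id"]
            for roi in ipsi:
                if response == "implanted":
                    xs.append(int(roi in mri))
                    ys.append(int(roi in t.implanted_rois))
                else:                      # iEEG abnormality, sampled ROIs only
                    if roi not in t.implanted_rois:
                        continue
                    xs.append(int(roi in mri))
                    ys.append(int(roi in sets[syn.IEEG].rois))
        try:
            out[outcome] = st.colocalization_logistic(xs, ys)
        except (st.SeparationError, ValueError) as e:
            out[outcome] = {"error": str(e)}
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a simulated cohort and return scores,
    abnormal sets, and outcome statistics."""
    cfg = config
    parcellation = syn.make_parcellation(cfg.cohort)

    # --- simulate -----------------------------------------------------------
    specs = syn.default_patient_specs(cfg.cohort.n_patients, cfg.n_favorable,
                                      unfavorable_overrides=cfg.unfavorable_overrides,
                                      **cfg.patient_overrides)
    controls = syn.generate_control_features(cfg.cohort, parcellation)
    patients, truths = syn.generate_patient_features(cfg.cohort, specs, parcellation)
    surgery = syn.surgery_table(truths, parcellation, seed=cfg.seed)

    # --- structural modalities: harmonize, map, z-score ---------------------
    zscores = {}
    for modality in (syn.GM, syn.SWM):
        combined = pd.concat([controls[modality], patients[modality]],
                             ignore_index=True)
        harmonized = harmonize_batches(
            combined,
            reference_subjects=set(controls[modality]["subject_id"]))
        is_control = harmonized["subject_id"].str.startswith("control")
        nmap = build_normative_map(harmonized[is_control], sd_floor=cfg.sd_floor)
        zscores[modality] = zscore_patients(harmonized[~is_control], nmap)

    # --- iEEG ---------------------------------------------------------------
    norm_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 6]))
    norm_studies = syn.generate_ieeg_normative(parcellation, cfg.ieeg, seed=cfg.seed)
    demo = {s.subject_id: {"age": float(norm_rng.uniform(*cfg.cohort.age_range)),
                           "sex": "M" if norm_rng.random() < cfg.cohort.sex_ratio else "F"}
            for s in norm_studies}
    pdemo = patients[syn.GM].drop_duplicates("subject_id").set_index("subject_id")
    pat_studies = []
    for spec, t in zip(specs, truths):
        pat_studies.append(syn.generate_ieeg_study(t.patient_id, spec, t,
                                                   parcellation, cfg.ieeg,
                                                   seed=cfg.seed))
        demo[t.patient_id] = {"age": float(pdemo.loc[t.patient_id, "age"]),
                              "sex": str(pdemo.loc[t.patient_id, "sex"])}
    ieeg_table = _ieeg_feature_table(norm_studies + pat_studies, parcellation,
                                     demo, cfg)
    ieeg_table = ieeg_table.dropna(subset=["value"])
    ieeg_map = build_normative_map(ieeg_table[ieeg_table["normative"]],
                                   sd_floor=cfg.sd_floor)
    ieeg_z = zscore_patients(ieeg_table[~ieeg_table["normative"]], ieeg_map)
    ieeg_scores = bp.ieeg_abnormality(ieeg_z)
    zscores[syn.IEEG] = ieeg_z

    # --- abnormal sets ------------------------------------------------------
    sets_by_patient: dict[str, dict] = {}
    for t in truths:
        pid = t.patient_id
        per = {}
        for modality in (syn.GM, syn.SWM):
            zp = zscores[modality][zscores[modality]["patient_id"] == pid]
            per[modality] = abn.abnormal_set(zp, modality, pid, cfg.abnormality)
        zi = ieeg_scores[ieeg_scores["patient_id"] == pid]
        per[syn.IEEG] = abn.abnormal_set(zi, syn.IEEG, pid, cfg.abnormality)
        per[MRI_TAG] = abn.union_abnormalities([per[syn.GM], per[syn.SWM]],
                                               tag=MRI_TAG)
        per[MULTI_TAG] = abn.union_abnormalities(
            [per[syn.GM], per[syn.SWM], per[syn.IEEG]], tag=MULTI_TAG)
        sets_by_patient[pid] = per

    # --- resection overlap --------------------------------------------------
    rows = []
    records = {}
    for t in truths:
        g = surgery[surgery["patient_id"] == t.patient_id]
        rec = st.SurgeryRecord(patient_id=t.patient_id,
                               resected_rois=st.resected_set(g, cfg.overlap_threshold),
                               implanted_rois=t.implanted_rois,
                               outcome=t.outcome, side=t.side)
        records[t.patient_id] = rec
        for tag in (MRI_TAG, MULTI_TAG):
            sc = st.proportion_abnormal_resected(sets_by_patient[t.patient_id][tag],
                                                 rec)
            rows.append({"patient_id": t.patient_id, "modality": tag,
                         "proportion_resected": sc.proportion_resected,
                         "n_abnormal": sc.n_abnormal, "outcome": t.outcome})
    overlap_scores = pd.DataFrame(rows)

    # --- statistics ---------------------------------------------------------
    results: dict = {"n_patients": len(truths),
                     "outcome_counts": {o: sum(t.outcome == o for t in truths)
                                        for o in (syn.OUTCOME_GOOD, syn.OUTCOME_POOR)}}
    scores_by_tag = {}
    for tag in (MRI_TAG, MULTI_TAG):
        sub = overlap_scores[overlap_scores["modality"] == tag]
        good = sub[sub["outcome"] == syn.OUTCOME_GOOD]["proportion_resected"]
        poor = sub[sub["outcome"] == syn.OUTCOME_POOR]["proportion_resected"]
        n_missing = int(sub["proportion_resected"].isna().sum())
        g, p = good.dropna().to_numpy(), poor.dropna().to_numpy()
        valid = sub.dropna(subset=["proportion_resected"])
        if len(g) == 0 or len(p) == 0:
            results[tag] = {"error": "an outcome group is empty",
                            "n_excluded_empty_abnormal": n_missing}
        else:
            w, pval = st.ranksum_one_tailed(g, p)
            results[tag] = {
                "auc": st.auc(g, p),
                "auprc": st.auprc(valid["proportion_resected"],
                                  (valid["outcome"] == syn.OUTCOME_GOOD).astype(int)),
                "ranksum_W": w, "ranksum_p": pval,
                "n_excluded_empty_abnormal": n_missing,
            }
        scores_by_tag[tag] = sub.set_index("patient_id")["proportion_resected"]
    order = [t.patient_id for t in truths]
    labels = [int(t.outcome == syn.OUTCOME_GOOD) for t in truths]
    try:
        results["delong"] = st.delong_paired(
            scores_by_tag[MULTI_TAG].reindex(order).to_numpy(),
            scores_by_tag[MRI_TAG].reindex(order).to_numpy(), labels)
    except ValueError as e:
        results["delong"] = {"error": str(e)}
    results["colocalization_implanted"] = _colocalization(
        sets_by_patient, truths, parcellation, "implanted")
    results["colocalization_ieeg_abnormal"] = _colocalization(
        sets_by_patient, truths, parcellation, "ieeg_abnormal")
    loo = {}
    for tag in (MRI_TAG, MULTI_TAG):
        sub = overlap_scores[overlap_scores["modality"] == tag].dropna(
            subset=["proportion_resected"])
        try:
            cv = st.loo_outcome_cv(sub["proportion_resected"],
                                   (sub["outcome"] == syn.OUTCOME_GOOD).astype(int))
            loo[tag] = {"accuracy": cv["accuracy"], "auc": cv["auc"]}
        except ValueError as e:
            loo[tag] = {"error": str(e)}
    results["loo_cv"] = loo

    # --- lateralized prevalence ---------------------------------------------
    prevalence = {}
    for tag in (MRI_TAG, MULTI_TAG):
        lat_sets = []
        for t in truths:
            lat = st.lateralize(parcellation, t.side).set_index("roi_id")
            renamed = frozenset(
                f"{lat.loc[r, 'laterality']}_{lat.loc[r, 'name']}"
                for r in sets_by_patient[t.patient_id][tag].rois)
            lat_sets.append(dataclasses.replace(
                sets_by_patient[t.patient_id][tag], rois=renamed,
                provenance={}))
        universe = sorted({f"{side}_{name}" for side in ("ipsilateral", "contralateral")
                           for name in parcellation["name"].unique()})
        prevalence[tag] = abn.cohort_prevalence(lat_sets, universe)

    result = PipelineResult(config=cfg, parcellation=parcellation,
                            ground_truth=truths, zscores=zscores,
                            abnormal_sets=sets_by_patient,
                            overlap_scores=overlap_scores, results=results,
                            prevalence=prevalence)
    if cfg.out_dir:
        _write_outputs(result)
    return result


@_stage("write_outputs")
def _write_outputs(res: PipelineResult) -> None:
    out = Path(res.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.parcellation.to_csv(out / "parcellation.csv", index=False)
    res.overlap_scores.to_csv(out / "overlap_scores.csv", index=False)
    for modality, df in res.zscores.items():
        df.to_csv(out / f"zscores_{modality}.csv", index=False)
    sets_payload = {
        pid: {tag: {"rois": sorted(s.rois), "k": s.k, "log_bf": s.log_bf}
              for tag, s in per.items()}
        for pid, per in res.abnormal_sets.items()}
    (out / "abnormal_sets.json").write_text(json.dumps(sets_payload, indent=1))
    (out / "results.json").write_text(json.dumps(res.results, indent=1, default=float))
    for tag, df in res.prevalence.items():
        df.to_csv(out / f"prevalence_{tag.replace('+', '_')}.csv", index=False)
    manifest = {"config": res.config.to_dict(), "seed": res.config.seed,
                "config_sha256": res.config.digest(), "version": 1}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
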