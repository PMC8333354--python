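"""End-to-end pipeline: simulate/load -> QC -> HbO -> features -> stats -> ROC.

A :class:`PipelineConfig` holds every tunable with the study defaults; the
runner is deterministic given the seed and writes a manifest with config
hash, per-stage counts and QC exclusions for auditability.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .features import extract_features
from .paradigm import make_paradigm
from .preprocess import DEFAULT_DPF, PreprocessError, preprocess_recording
from .screening import auc_ci, roc_curve, severity_screen, youden_cutoff
from .simulate import (
    Cohort,
    NoiseSpec,
    control_defaults,
    fibromyalgia_defaults,
    generate_cohort,
)
from .stats import (
    StatsError,
    characterize_cohort,
    gee_wald,
    glm_severity,
    spearman_table,
)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "features_wide"]

OUTCOMES = ("peak_latency_s", "delta_hbo_mM", "delta_hbo_star_mM")
ROIS = ("left_PFC", "right_PFC", "left_MC", "right_MC")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults encode the study protocol."""

    seed: int = 0
    n_fibromyalgia: int = 22
    n_control: int = 19
    sampling_rate: float = 3.91
    cv_threshold: float = 7.5
    band_low: float = 0.01
    band_high: float = 0.2
    filter_order: int = 3
    separation: float = 3.0
    dpf: tuple[float, float] = DEFAULT_DPF
    post_window: float = 15.0
    peak_search: str = "stimulus_end"
    rest_duration: float = 60.0
    baseline_window: float = 30.0
    inter_stimulus_rest: float = 120.0
    artifact_rate: float = 0.0
    screen_temperature: str = "5C"
    group_orientation: str = "low_positive"
    severity_orientation: str = "high_positive"
    severity_quantile: float = 0.5
    ci_method: str = "hanley-mcneil"
    fixed_cutoff_left: float = -0.175
    fixed_cutoff_right: float = -0.205
    bonferroni_family: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(
                "config", f"unknown key(s) {sorted(unknown)}; known: {sorted(known)}"
            )
        if "dpf" in raw:
            raw["dpf"] = tuple(raw["dpf"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    features: pd.DataFrame
    qc: pd.DataFrame
    stats: dict
    screening: dict
    manifest: dict
    cohort: Cohort = field(repr=False, default=None)


def features_wide(
    features: pd.DataFrame, temperature: str = "5C", value: str = "delta_hbo_star_mM"
) -> pd.DataFrame:
    """Pivot one feature at one temperature to subject x ROI columns."""
    sub = features[features["temperature"] == temperature]
    wide = sub.pivot_table(
        index=["subject_id", "group"], columns="roi", values=value,
        aggfunc="first",
    ).reset_index()
    wide.columns = [
        c if c in ("subject_id", "group") else f"dhbostar_{c}" for c in wide.columns
    ]
    return wide


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Run simulate -> preprocess -> features -> stats -> screening.

    ``cohort`` may be supplied (e.g. loaded from disk); otherwise one is
    generated from the config.  Raises :class:`PipelineError` with a stage
    tag on any failure.
    """
    t0 = time.time()
    if cohort is None:
        try:
            groups = [
                fibromyalgia_defaults(config.n_fibromyalgia),
                control_defaults(config.n_control),
            ]
            base = make_paradigm(
                rest_duration=config.rest_duration,
                baseline_window=config.baseline_window,
                inter_stimulus_rest=config.inter_stimulus_rest,
                post_window=config.post_window,
            )
            cohort = generate_cohort(
                groups, paradigm=base,
                noise=NoiseSpec(artifact_rate=config.artifact_rate),
                seed=config.seed, sampling_rate=config.sampling_rate,
                analysis_band=(config.band_low, config.band_high),
                filter_order=config.filter_order,
            )
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc

    feature_frames, qc_frames = [], []
    group_of = dict(zip(cohort.metadata.subject_id, cohort.metadata.group))
    for s in cohort.subjects:
        try:
            hb, qc = preprocess_recording(
                s.recording,
                cv_threshold=config.cv_threshold,
                band=(config.band_low, config.band_high),
                separation=config.separation,
                dpf=config.dpf,
                filter_order=config.filter_order,
            )
        except PreprocessError as exc:
            raise PipelineError("preprocess", f"{s.subject_id}: {exc}") from exc
        q = qc.frame.copy()
        q.insert(0, "subject_id", s.subject_id)
        qc_frames.append(q)
        try:
            feats = extract_features(
                hb, cohort.montage, s.paradigm,
                group=group_of[s.subject_id],
                post_window=config.post_window,
                peak_search=config.peak_search,
            )
        except Exception as exc:
            raise PipelineError("features", f"{s.subject_id}: {exc}") from exc
        feature_frames.append(feats)
    features = pd.concat(feature_frames, ignore_index=True)
    qc_all = pd.concat(qc_frames, ignore_index=True)

    # --- statistics ------------------------------------------------------
    stats_out: dict = {"gee": {}, "spearman": None, "glm": {},
                       "characterization": None}
    try:
        continuous = [
            c for c in ("age", "bmi", "years_study", "csi_total", "pcp_total")
            if c in cohort.metadata.columns
        ]
        categorical = [
            c for c in ("analgesic_use",) if c in cohort.metadata.columns
        ]
        stats_out["characterization"] = characterize_cohort(
            cohort.metadata, continuous=continuous, categorical=categorical
        )
        for roi in ROIS:
            for outcome in OUTCOMES:
                sub = features.dropna(subset=[outcome])
                sub = sub[sub["roi"] == roi]
                complete = sub.groupby("subject_id")["temperature"].nunique()
                keep = complete.index[complete == 2]
                sub = features[features["subject_id"].isin(keep)]
                results = gee_wald(
                    sub.dropna(subset=[outcome]), outcome, roi,
                    bonferroni_family=config.bonferroni_family,
                )
                stats_out["gee"][(roi, outcome)] = results
    except StatsError as exc:
        raise PipelineError("stats", str(exc)) from exc

    wide = features_wide(features, temperature=config.screen_temperature)
    merged = wide.merge(cohort.metadata, on=["subject_id", "group"])
    fm = merged[merged["group"] == "fibromyalgia"]
    if len(fm) >= 4:
        stats_out["spearman"] = spearman_table(
            fm,
            ["pcp_total", "csi_total", "dhbostar_left_PFC", "dhbostar_right_PFC",
             "dhbostar_left_MC", "dhbostar_right_MC"],
        )
        for score in ("pcp_total", "csi_total"):
            try:
                stats_out["glm"][score] = glm_severity(fm, score)
            except StatsError:
                stats_out["glm"][score] = None

    # --- screening -------------------------------------------------------
    screening: dict = {"group": {}, "severity": {}}
    labels = (merged["group"] == "fibromyalgia").astype(int).to_numpy()
    for side, cutoff in (
        ("left_PFC", config.fixed_cutoff_left),
        ("right_PFC", config.fixed_cutoff_right),
    ):
        col = f"dhbostar_{side}"
        ok = merged[col].notna().to_numpy()
        roc = roc_curve(
            merged.loc[ok, col].to_numpy(), labels[ok],
            orientation=config.group_orientation,
        )
        auc_ci(roc, method=config.ci_method)
        screening["group"][side] = {
            "roc": roc,
            "youden_cutoff": youden_cutoff(roc),
            "fixed_cutoff": cutoff,
        }
        fm_ok = fm[fm[col].notna()]
        if len(fm_ok) >= 4:
            screening["severity"][side] = {
                score: severity_screen(
                    fm_ok[col].to_numpy(), fm_ok[score].to_numpy(),
                    fixed_cutoffs=(cutoff,),
                    quantile=config.severity_quantile,
                    orientation=config.severity_orientation,
                    ci_method=config.ci_method,
                )
                for score in ("pcp_total", "csi_total")
            }

    manifest = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "version": __version__,
        "seed": config.seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "subjects_in": len(cohort),
        "subjects_analyzed": int(features["subject_id"].nunique()),
        "channels_rejected": int(qc_all["rejected"].sum()),
        "rois_missing": int((features["n_channels"] == 0).sum() // 2),
        "elapsed_s": round(time.time() - t0, 2),
    }
    if manifest["subjects_in"] != manifest["subjects_analyzed"]:
        raise PipelineError(
            "manifest",
            "subject accounting mismatch: "
            f"{manifest['subjects_in']} in vs {manifest['subjects_analyzed']} analyzed",
        )
    return PipelineResult(
        features=features, qc=qc_all, stats=stats_out,
        screening=screening, manifest=manifest, cohort=cohort,
    )
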