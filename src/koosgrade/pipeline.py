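"""End-to-end orchestration: preprocessing, training, prediction, CV.

The inference chain per case mirrors the grading pipeline's second
stage: reorient to RAS → resample to the canonical isotropic grid →
detect the tumor side from sagittal projections → relabel hemispheres
ipsilateral/contralateral → extract the 9 geometric predictors → grade
with the Random Forest (one per input pseudo-modality), the
volume-threshold baseline, and — when external network votes are
supplied — the six-vote casting-vote ensemble.

Per-case failures during batch feature extraction are quarantined and
logged rather than aborting the batch; callers receive the quarantined
ids and a nonzero exit status at the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .classify import (
    GradeModel,
    RFConfig,
    Thresholds,
    VotePanel,
    ensemble_vote,
    fit_rf,
    fit_volume_baseline,
    predict_baseline,
)
from .errors import DegenerateInputError, GeometryError, KoosGradeError
from .features import (
    FEATURE_COLUMNS,
    SENTINEL_DISTANCE_MM,
    FeatureTable,
    extract_features,
    feature_name,
)
from .laterality import Side, detect_side, to_ipsi_contra
from .phantom import MODALITIES, PhantomCase
from .schemes import VS, LabelScheme
from .stats import (
    MetricsReport,
    PairedDiffs,
    confusion,
    corrected_ttest,
    cv_test_train_ratio,
    metrics_report,
    stratified_kfold,
)
from .volumes import (
    TARGET_SPACING_MM,
    ImageVolume,
    LabelVolume,
    reorient_ras,
    resample_iso,
)

log = logging.getLogger(__name__)

VOLUME_COLUMN = feature_name("volume", VS)


@dataclass
class PipelineConfig:
    target_spacing: float = TARGET_SPACING_MM
    side_mode: str = "auto"  # "auto", "left" or "right"
    rf: RFConfig = field(default_factory=RFConfig)
    baseline: bool = True
    cv_k: int = 5
    cv_seed: int = 0
    sentinel_distance: float = SENTINEL_DISTANCE_MM
    paper_ratio: bool = False  # corrected-t ratio convention, see stats


def scheme_hash(scheme: LabelScheme) -> str:
    payload = json.dumps([scheme.sidedness, sorted(scheme.entries.items())])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-case preprocessing + feature extraction


def preprocess_case(
    labels: LabelVolume,
    image: ImageVolume | None = None,
    target_spacing: float = TARGET_SPACING_MM,
    side: str | Side = "auto",
) -> tuple[LabelVolume, Side]:
    """Canonicalize one case: RAS, isotropic grid, ipsi/contra labels.

    ``side='auto'`` detects the tumor side from the sagittal projection
    means of the tumor mask and the MR image (which must then be given);
    a forced side skips detection (restricted-FOV fallback).
    """
    labels = resample_iso(reorient_ras(labels), target_spacing)
    if isinstance(side, Side):
        detected = side
    elif side in ("left", "right"):
        detected = Side(side)
    else:
        if image is None:
            raise DegenerateInputError("side detection requires the MR image")
        image = resample_iso(reorient_ras(image), target_spacing)
        if not image.same_grid(labels):
            raise GeometryError("image and labels disagree after resampling")
        vs_only = LabelVolume(
            (labels.voxels == labels.scheme.label_of(VS)).astype(np.int32)
            * labels.scheme.label_of(VS),
            labels.affine,
            scheme=labels.scheme,
        )
        detected = detect_side(image, vs_only)
    return to_ipsi_contra(labels, detected), detected


def features_for_case(
    labels: LabelVolume,
    case_id: str,
    image: ImageVolume | None = None,
    side: str | Side = "auto",
    cfg: PipelineConfig | None = None,
):
    cfg = cfg or PipelineConfig()
    canonical, detected = preprocess_case(
        labels, image, cfg.target_spacing, side if cfg.side_mode == "auto" else cfg.side_mode
    )
    fv = extract_features(canonical, case_id, cfg.sentinel_distance)
    return fv, detected


def cohort_feature_tables(
    cases: list[PhantomCase],
    cfg: PipelineConfig | None = None,
) -> tuple[dict[str, FeatureTable], list[str]]:
    """Extract per-pseudo-modality feature tables from a phantom cohort.

    Returns (tables keyed by modality tag, quarantined case ids).
    Failed cases are skipped with a logged warning, and the run
    continues.
    """
    cfg = cfg or PipelineConfig()
    rows: dict[str, list[pd.Series]] = {m: [] for m in MODALITIES}
    grades: dict[str, int] = {}
    quarantined: list[str] = []
    for case in cases:
        try:
            series = {}
            memo: dict[int, pd.Series] = {}  # identical volumes share features
            for modality, vol in case.volumes.items():
                if id(vol) not in memo:
                    fv, _ = features_for_case(
                        vol, case.case_id, image=case.image, cfg=cfg
                    )
                    memo[id(vol)] = fv.to_series()
                series[modality] = memo[id(vol)]
        except KoosGradeError as exc:
            log.warning("case %s quarantined: %s", case.case_id, exc)
            quarantined.append(case.case_id)
            continue
        for modality, s in series.items():
            rows[modality].append(s)
        grades[case.case_id] = case.grade
    tables = {}
    for modality in MODALITIES:
        df = pd.DataFrame(rows[modality])
        df.index.name = "case_id"
        tables[modality] = FeatureTable(df, pd.Series(grades, name="koos_grade"))
    return tables, quarantined


# ---------------------------------------------------------------------------
# Train / predict


@dataclass
class TrainedArtifacts:
    models: dict[str, GradeModel]  # one Random Forest per modality tag
    thresholds: Thresholds | None
    scheme_hash: str
    config: PipelineConfig

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        joblib.dump({"models": self.models, "thresholds": self.thresholds}, out / "model.joblib")
        meta = {
            "format_version": 1,
            "scheme_hash": self.scheme_hash,
            "rf_config": vars(self.config.rf),
            "target_spacing": self.config.target_spacing,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedArtifacts":
        out = Path(out_dir)
        blob = joblib.load(out / "model.joblib")
        meta = json.loads((out / "meta.json").read_text())
        cfg = PipelineConfig(
            target_spacing=meta["target_spacing"], rf=RFConfig(**meta["rf_config"])
        )
        return cls(blob["models"], blob["thresholds"], meta["scheme_hash"], cfg)


def run_train(
    tables: dict[str, FeatureTable],
    scheme: LabelScheme,
    cfg: PipelineConfig | None = None,
) -> TrainedArtifacts:
    """Fit one Random Forest per modality table plus the volume baseline."""
    cfg = cfg or PipelineConfig()
    models = {m: fit_rf(t, cfg.rf) for m, t in tables.items()}
    thresholds = None
    if cfg.baseline:
        ref = tables.get("ceT1+hrT2") or next(iter(tables.values()))
        thresholds = fit_volume_baseline(
            ref.features[VOLUME_COLUMN].to_numpy(), ref.grades.to_numpy()
        )
    return TrainedArtifacts(models, thresholds, scheme_hash(scheme), cfg)


def read_vote_file(path: str | Path) -> pd.DataFrame:
    """External vote CSV: case_id,grade,source,is_caster."""
    df = pd.read_csv(path)
    required = {"case_id", "grade"}
    if not required <= set(df.columns):
        raise KoosGradeError(f"vote file {path} must have columns {sorted(required)}")
    if "is_caster" not in df.columns:
        df["is_caster"] = False
    if "source" not in df.columns:
        df["source"] = Path(path).stem
    return df


def run_predict(
    artifacts: TrainedArtifacts,
    tables: dict[str, FeatureTable],
    scheme: LabelScheme,
    external_votes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case grade predictions for every branch.

    The Random-Forest grade per modality is always reported; the
    baseline grade requires fitted thresholds; the ensemble grade is
    computed over the Random-Forest votes (casters) plus any external
    votes for the case.  Missing modalities downgrade the ensemble to
    the available votes with a warning.
    """
    if artifacts.scheme_hash != scheme_hash(scheme):
        raise KoosGradeError("label scheme does not match the trained artifacts")
    case_ids = next(iter(tables.values())).features.index
    records = []
    for case_id in case_ids:
        rec: dict[str, object] = {"case_id": case_id}
        panel = VotePanel()
        for modality, model in artifacts.models.items():
            table = tables.get(modality)
            if table is None or case_id not in table.features.index:
                log.warning("case %s: modality %s missing", case_id, modality)
                continue
            g = int(model.predict(table.features.loc[case_id])[0])
            rec[f"rf_{modality}"] = g
            panel.add(g, is_caster=True, source=f"rf:{modality}")
        if artifacts.thresholds is not None:
            ref = tables.get("ceT1+hrT2") or next(iter(tables.values()))
            vol = float(ref.features.loc[case_id, VOLUME_COLUMN])
            rec["baseline"] = predict_baseline(vol, artifacts.thresholds)
        if external_votes is not None:
            for _, row in external_votes[external_votes["case_id"] == case_id].iterrows():
                panel.add(int(row["grade"]), bool(row["is_caster"]), str(row["source"]))
        if panel.votes:
            rec["ensemble"] = ensemble_vote(panel)
        records.append(rec)
    return pd.DataFrame(records).set_index("case_id")


# ---------------------------------------------------------------------------
# Cross-validation


def run_cv(
    tables: dict[str, FeatureTable],
    cfg: PipelineConfig | None = None,
    external_votes: pd.DataFrame | None = None,
    methods: tuple[str, ...] = ("rf", "baseline", "ensemble"),
) -> dict:
    """Stratified k-fold cross-validation of the requested methods.

    Per fold, the Random Forests and baseline are refit on the training
    cases and evaluated on the held-out fold; pooled and per-fold
    metrics are reported, plus corrected resampled paired t-tests on
    the per-fold weighted-F1 differences for each method pair.  The
    reported "rf" method is the combined-modality forest; "ensemble"
    pools the three modality forests' votes (casters) with any external
    votes.
    """
    cfg = cfg or PipelineConfig()
    ref_mod = "ceT1+hrT2" if "ceT1+hrT2" in tables else next(iter(tables))
    ref = tables[ref_mod]
    grades = ref.grades.to_numpy(dtype=int)
    case_ids = ref.features.index.to_numpy()
    folds = stratified_kfold(grades, cfg.cv_k, cfg.cv_seed)
    # the ensemble needs one forest per modality; rf/baseline only the
    # reference modality
    needed = tables if "ensemble" in methods else {ref_mod: ref}
    per_fold: dict[str, list[MetricsReport]] = {m: [] for m in methods}
    pooled: dict[str, tuple[list, list]] = {m: ([], []) for m in methods}
    for f in range(cfg.cv_k):
        test = folds == f
        train_tables = {
            m: FeatureTable(t.features.loc[~test], t.grades.loc[~test])
            for m, t in needed.items()
        }
        artifacts = run_train(train_tables, canonical_ipsi_scheme(), cfg)
        test_tables = {
            m: FeatureTable(t.features.loc[test], t.grades.loc[test])
            for m, t in needed.items()
        }
        preds = run_predict(artifacts, test_tables, canonical_ipsi_scheme(), external_votes)
        y_true = grades[test]
        for method in methods:
            col = {"rf": f"rf_{ref_mod}", "baseline": "baseline", "ensemble": "ensemble"}[method]
            y_pred = preds[col].to_numpy(dtype=int)
            per_fold[method].append(metrics_report(y_true, y_pred))
            pooled[method][0].extend(y_true.tolist())
            pooled[method][1].extend(y_pred.tolist())
    ratio = cv_test_train_ratio(cfg.cv_k, cfg.paper_ratio)
    result: dict = {"k": cfg.cv_k, "seed": cfg.cv_seed, "test_train_ratio": ratio, "methods": {}}
    for method in methods:
        reports = per_fold[method]
        pooled_report = metrics_report(*pooled[method])
        pooled_report.per_fold = {
            "accuracy": [r.accuracy for r in reports],
            "weighted_f1": [r.weighted_f1 for r in reports],
            "ma_mae": [r.ma_mae for r in reports],
        }
        result["methods"][method] = pooled_report
    result["ttests"] = {}
    method_list = list(methods)
    for i, a in enumerate(method_list):
        for b in method_list[i + 1 :]:
            fa = result["methods"][a].per_fold["weighted_f1"]
            fb = result["methods"][b].per_fold["weighted_f1"]
            diffs = np.asarray(fa) - np.asarray(fb)
            t, p = corrected_ttest(PairedDiffs(diffs, ratio))
            result["ttests"][f"{a} vs {b}"] = {"t": t, "p": p, "mean_diff": float(diffs.mean())}
    return result


def canonical_ipsi_scheme() -> LabelScheme:
    from .schemes import IPSI_CONTRA, canonical_scheme

    return canonical_scheme(IPSI_CONTRA)


def cv_summary_table(result: dict) -> pd.DataFrame:
    """Mean ± sd per-fold metrics, one row per method."""
    rows = {}
    for method, report in result["methods"].items():
        pf = report.per_fold
        rows[method] = {
            f"{name} (mean ± sd)": f"{np.mean(vals):.3f} ± {np.std(vals, ddof=1):.3f}"
            for name, vals in pf.items()
        }
    return pd.DataFrame(rows).T
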