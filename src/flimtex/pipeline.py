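"""End-to-end orchestration: simulate -> features -> classify -> compare.

The pipeline reproduces the shape of the study's analysis on a synthetic
cohort: generate cells, extract the 8 per-cell features (4 lifetime
histogram statistics + 4 LBP statistics, optionally the full 26-bin LBP
descriptor), run the stepwise discriminant with leave-one-out and repeated
hold-out validation at cell and patient level, build a Table-1/2-shaped
group comparison, and count foci.  Every intermediate is written as
tab-separated text; a plain-text log records the seed, config hash and
per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminant import (
    aggregate_per_patient,
    holdout_validate,
    loo_validate,
    stepwise_select,
)
from .features import histogram_stats
from .foci import detect_foci
from .groupstats import mann_whitney_u, wilcoxon_signed_rank
from .io import extract_roi, read_lifetime_matrix, read_manifest
from .lbp import LBPParams, lbp_histogram, lbp_stats, lbp_transform
from .synthetic import GeneratorParams, default_params, generate_cohort

__all__ = [
    "PipelineConfig",
    "compute_features",
    "feature_table",
    "classify",
    "compare_groups",
    "run_pipeline",
]

#: feature sets selectable for classification
FEATURE_SETS = {
    "summary4": ["lbp_mean", "lbp_sd", "lbp_skewness", "lbp_entropy"],
    "raw6": ["mean_ps", "sd_ps", "skewness", "entropy", "p5_ps", "p95_ps"],
}


@dataclass
class PipelineConfig:
    """Flat, text-serialisable configuration of one pipeline run."""

    # cohort
    n_control_patients: int = 27
    n_scd_patients: int = 45
    cells_per_patient_control: int = 10
    cells_per_patient_nonsickled: int = 10
    cells_per_patient_sickled: int = 5
    # LBP / entropy
    lbp_p: int = 24
    lbp_r: float = 3.0
    entropy_bins: int = 32
    entropy_base: str = "e"
    include_lbp26: bool = False
    # classification
    feature_set: str = "summary4"
    stepwise: bool = True
    f_enter: float = 3.84
    f_remove: float = 2.71
    holdout_repeats: int = 10
    loo_group: str = "cell"  # "cell" leaves out cells; "patient" guards leakage
    # foci
    foci_threshold_sd: float = 3.5
    foci_min_area_px: int = 6
    # run
    seed: int = 0
    matrix_format: str = "tsv"
    generator: GeneratorParams = field(default_factory=default_params)

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "generator":
                for gf in dataclasses.fields(GeneratorParams):
                    gv = getattr(v, gf.name)
                    lines.append(f"generator.{gf.name} = {json.dumps(_jsonable(gv))}")
            else:
                lines.append(f"{f.name} = {json.dumps(_jsonable(v))}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        cfg = cls()
        gen_kwargs = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            value = json.loads(raw.strip())
            if key.startswith("generator."):
                gen_kwargs[key[len("generator.") :]] = _unjsonable(value)
            else:
                if not hasattr(cfg, key):
                    raise ValueError(f"config line {lineno}: unknown key {key!r}")
                setattr(cfg, key, _unjsonable(value))
        if gen_kwargs:
            cfg.generator = GeneratorParams(**gen_kwargs)
        cfg.generator.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return dict(v)
    return v


def _unjsonable(v):
    if isinstance(v, list):
        return tuple(v)
    return v


# ---------------------------------------------------------------------------
# features


def compute_features(
    roi: np.ndarray,
    lbp_params: LBPParams = LBPParams(),
    entropy_bins: int = 32,
    entropy_base="e",
    include_lbp26: bool = False,
) -> dict:
    """The 8 per-cell features (+ optional 26-bin LBP descriptor)."""
    hist = histogram_stats(roi, entropy_bins=entropy_bins, entropy_base=entropy_base)
    codes = lbp_transform(roi, lbp_params)
    lbp = lbp_stats(codes, entropy_base=entropy_base)
    out = {**hist.as_dict(), **lbp.as_dict()}
    if include_lbp26:
        h = lbp_histogram(codes)
        for i, p in enumerate(h.normalized):
            out[f"lbp_bin{i:02d}"] = float(p)
    return out


def feature_table(
    cells,
    lbp_params: LBPParams = LBPParams(),
    entropy_bins: int = 32,
    entropy_base="e",
    include_lbp26: bool = False,
) -> pd.DataFrame:
    """Per-cell feature table from (CellRecord, matrix) pairs."""
    rows = []
    for rec, matrix in cells:
        roi = extract_roi(matrix, rec.roi)
        feats = compute_features(
            roi,
            lbp_params=lbp_params,
            entropy_bins=entropy_bins,
            entropy_base=entropy_base,
            include_lbp26=include_lbp26,
        )
        rows.append(
            {
                "cell_id": rec.cell_id,
                "patient_id": rec.patient_id,
                "group": rec.group,
                "subtype": rec.subtype,
                "shape_class": rec.shape_class,
                **feats,
            }
        )
    return pd.DataFrame(rows)


def load_cells(run_dir) -> list:
    """Reload (CellRecord, matrix) pairs from a written run directory."""
    run_dir = Path(run_dir)
    records = read_manifest(run_dir / "manifest.tsv")
    return [(rec, read_lifetime_matrix(run_dir / rec.path)) for rec in records]


# ---------------------------------------------------------------------------
# classification


def classify(
    features: pd.DataFrame,
    config: PipelineConfig,
    level: str = "cell",
    subtypes=("control", "nonsickled"),
) -> dict:
    """Stepwise LDA of control vs SCD with LOO and repeated hold-out.

    ``level="cell"`` classifies single cells; ``level="patient"`` averages
    each patient's cells first (only the listed subtypes contribute).
    """
    df = features[features["subtype"].isin(subtypes)].copy()
    cols = FEATURE_SETS.get(config.feature_set)
    if cols is None:
        if config.feature_set == "lbp26":
            cols = sorted(c for c in df.columns if c.startswith("lbp_bin"))
        elif config.feature_set == "all":
            cols = FEATURE_SETS["raw6"] + FEATURE_SETS["summary4"]
        else:
            raise ValueError(f"unknown feature_set {config.feature_set!r}")
    if not cols or any(c not in df.columns for c in cols):
        raise ValueError(f"feature table lacks columns for feature_set {config.feature_set!r}")

    if level == "patient":
        df = aggregate_per_patient(df[["patient_id", "group"] + cols])
        unit_ids = None
    elif level == "cell":
        unit_ids = df["patient_id"].to_numpy() if config.loo_group == "patient" else None
    else:
        raise ValueError(f"unknown level {level!r}")

    X = df[cols].to_numpy(dtype=float)
    y = df["group"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("need both groups present for classification")

    loo = loo_validate(
        X,
        y,
        unit_ids=unit_ids,
        stepwise=config.stepwise,
        f_enter=config.f_enter,
        f_remove=config.f_remove,
        feature_names=cols,
        level=level,
    )
    hold = holdout_validate(
        X,
        y,
        train_fraction=0.5,
        repeats=config.holdout_repeats,
        seed=config.seed,
        stepwise=config.stepwise,
        f_enter=config.f_enter,
        f_remove=config.f_remove,
        feature_names=cols,
        level=level,
    )
    return {
        "level": level,
        "n_units": int(X.shape[0]),
        "feature_set": config.feature_set,
        "selected_features": loo.selected_features,
        "accuracy": loo.accuracy,
        "accuracy_loo": loo.accuracy_loo,
        "confusion_loo": loo.confusion.tolist(),
        "holdout_accuracy_mean": hold.accuracy,
        "holdout_per_repeat": hold.per_repeat_accuracy,
        "f_score_mean": hold.f_score_mean,
        "f_score_sd": hold.f_score_sd,
    }


# ---------------------------------------------------------------------------
# group comparison (Tables 1/2 shape)


_FEATURES_8 = FEATURE_SETS["raw6"] + FEATURE_SETS["summary4"]


def compare_groups(features: pd.DataFrame, level: str = "cell") -> pd.DataFrame:
    """Feature-by-feature group comparison shaped like the study tables.

    Columns: control mean, p (control x non-sickled, Mann-Whitney),
    non-sickled mean, sickled mean, p (non-sickled x sickled; Wilcoxon on
    patient means at patient level — a dependent comparison — else
    Mann-Whitney).  Comparisons lacking a group are reported as NaN.
    """
    df = features.copy()
    if level == "patient":
        keep = ["patient_id", "subtype"] + [c for c in _FEATURES_8 if c in df.columns]
        df = (
            df[keep]
            .groupby(["patient_id", "subtype"], sort=True)
            .mean()
            .reset_index()
        )
    rows = []
    for feat in [c for c in _FEATURES_8 if c in df.columns]:
        ctrl = df.loc[df["subtype"] == "control", feat].to_numpy()
        nons = df.loc[df["subtype"] == "nonsickled", feat].to_numpy()
        sick = df.loc[df["subtype"] == "sickled", feat].to_numpy()
        p_cn = np.nan
        if ctrl.size and nons.size:
            p_cn = mann_whitney_u(ctrl, nons).p_value
        p_ns = np.nan
        if nons.size and sick.size:
            if level == "patient":
                sub = df[df["subtype"].isin(["nonsickled", "sickled"])]
                wide = sub.pivot(index="patient_id", columns="subtype", values=feat).dropna()
                diffs = (wide["sickled"] - wide["nonsickled"]).to_numpy()
                diffs = diffs[diffs != 0]
                if diffs.size:
                    p_ns = wilcoxon_signed_rank(diffs).p_value
            else:
                p_ns = mann_whitney_u(nons, sick).p_value
        rows.append(
            {
                "feature": feat,
                "control_mean": ctrl.mean() if ctrl.size else np.nan,
                "p_control_vs_nonsickled": p_cn,
                "nonsickled_mean": nons.mean() if nons.size else np.nan,
                "sickled_mean": sick.mean() if sick.size else np.nan,
                "p_nonsickled_vs_sickled": p_ns,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# foci


def foci_table(cells, threshold_sd: float = 3.0, min_area_px: int = 2) -> pd.DataFrame:
    rows = []
    for rec, matrix in cells:
        roi = extract_roi(matrix, rec.roi)
        rep = detect_foci(roi, threshold_sd=threshold_sd, min_area_px=min_area_px, label=rec.subtype)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "patient_id": rec.patient_id,
                "subtype": rec.subtype,
                "n_foci": rep.count,
                "planted_dots": rec.extra.get("n_dots", ""),
                "largest_focus_px": rep.foci[0].area_px if rep.foci else 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run simulate -> features -> classify -> compare -> foci into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    cfg_hash = config.config_hash()
    t_start = time.time()

    def log(stage: str, message: str) -> None:
        with open(log_path, "a") as fh:
            fh.write(f"[{time.time() - t_start:8.2f}s] {stage}: {message}\n")

    with open(log_path, "w") as fh:
        fh.write(f"flimtex {__version__} | seed={config.seed} | config={cfg_hash}\n")
    (out_dir / "config.txt").write_text(f"# config hash {cfg_hash}\n" + config.to_text())

    stage = "simulate"
    try:
        cohort = generate_cohort(
            n_per_group={"control": config.n_control_patients, "scd": config.n_scd_patients},
            cells_per_patient={
                "control": config.cells_per_patient_control,
                "nonsickled": config.cells_per_patient_nonsickled,
                "sickled": config.cells_per_patient_sickled,
            },
            params=config.generator,
            seed=config.seed,
            out_dir=out_dir,
            matrix_format=config.matrix_format,
        )
        log(stage, f"{len(cohort.cells)} cells written")

        stage = "features"
        feats = feature_table(
            cohort.cells,
            lbp_params=LBPParams(P=config.lbp_p, R=config.lbp_r),
            entropy_bins=config.entropy_bins,
            entropy_base=config.entropy_base,
            include_lbp26=config.include_lbp26,
        )
        feats.to_csv(out_dir / "features.tsv", sep="\t", index=False)
        log(stage, f"{len(feats)} rows")

        stage = "classify"
        reports = {}
        for level in ("cell", "patient"):
            reports[level] = classify(feats, config, level=level)
        (out_dir / "classification.json").write_text(json.dumps(reports, indent=2))
        log(stage, f"cell LOO={reports['cell']['accuracy_loo']:.3f} "
                   f"patient LOO={reports['patient']['accuracy_loo']:.3f}")

        stage = "compare"
        n_sickled = int((feats["subtype"] == "sickled").sum())
        for level in ("cell", "patient"):
            table = compare_groups(feats, level=level)
            table.to_csv(out_dir / f"compare_{level}.tsv", sep="\t", index=False)
        if n_sickled == 0:
            log(stage, "no sickled cells: sickled comparisons skipped (NaN)")
        else:
            log(stage, "tables written")

        stage = "foci"
        ft = foci_table(
            cohort.cells,
            threshold_sd=config.foci_threshold_sd,
            min_area_px=config.foci_min_area_px,
        )
        ft.to_csv(out_dir / "foci.tsv", sep="\t", index=False)
        means = ft.groupby("subtype")["n_foci"].mean().to_dict()
        log(stage, f"mean foci/cell {means}")
    except Exception as exc:
        log(stage, f"FAILED: {exc}")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log("done", "ok")
    return out_dir
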