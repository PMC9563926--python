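"""End-to-end orchestration: preprocess -> match -> test -> classify.

``run_pipeline`` executes the stages in order from one configuration,
writing each stage's output before the next begins (matrix.csv,
matches.csv, results.csv, report.json, run.log) so that every
intermediate is individually re-loadable and a rerun with the same
config and seed reproduces the report bit for bit. The log records
per-subject breath-scan counts and stratification exclusions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CVConfig, balanced_subsample, crossvalidate
from .errors import ConfigError
from .panel import MarkerPanel, match_markers, reference_panel, load_panel
from .preprocess import (
    DEFAULT_GATE_FRACTION,
    DEFAULT_HEIGHT_FILTER,
    DEFAULT_TOLERANCE,
    FeatureGrid,
    IntensityMatrix,
    apply_recalibration,
    average_breath_scans,
    build_feature_matrix,
    fit_recalibration,
    normalize_cascade,
    select_breath_scans,
)
from .spectra import BreathSession, read_mzxml
from .stats import (
    StratificationRule,
    SubjectRecord,
    apply_stratification,
    compare_groups,
)

_VERSION = "0.1.0"

logger = logging.getLogger("breathflow")


@dataclass
class RunConfig:
    """One full analysis run."""

    input_dir: Path
    metadata_path: Path
    output_dir: Path
    panel_path: Optional[Path] = None  # None -> bundled 78-feature panel
    stratification: str = "strat1"
    tolerance: float = DEFAULT_TOLERANCE
    height_filter: float = DEFAULT_HEIGHT_FILTER
    gate_fraction: float = DEFAULT_GATE_FRACTION
    grid_step: float = 0.001
    mass_range: tuple[float, float] = (50.0, 500.0)
    alpha: float = 0.05
    cv_folds: int = 10
    balance: bool = False
    seed: int = 0
    recalibrate: bool = True

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items()
            if k != "output_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read the subject table (CSV with the SubjectRecord columns)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SubjectRecord(
                subject_id=str(d["subject_id"]),
                group=d["group"],
                ahi_visit=_opt(d.get("ahi_visit")),
                ahi_diagnosis=_opt(d.get("ahi_diagnosis")),
                odi=_opt(d.get("odi")),
                ess=_opt(d.get("ess")),
                cpap_hours=_opt(d.get("cpap_hours")),
            )
        )
    return records


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def preprocess_sessions(
    sessions: Sequence[BreathSession],
    grid: Optional[FeatureGrid] = None,
    height_filter: float = DEFAULT_HEIGHT_FILTER,
    gate_fraction: float = DEFAULT_GATE_FRACTION,
    tolerance: float = DEFAULT_TOLERANCE,
    recalibrate: bool = True,
) -> IntensityMatrix:
    """Run the spectral chain on in-memory sessions to an auto-scaled matrix.

    The reference spectrum for recalibration is the first session's most
    intense breath scan.
    """
    if len(sessions) < 2:
        raise ConfigError("need at least two sessions")
    grid = grid or FeatureGrid()
    reference = max(sessions[0].scans, key=lambda s: s.tic)
    profiles = []
    for session in sessions:
        if recalibrate:
            model = fit_recalibration(session, reference, min_height=height_filter)
            session = apply_recalibration(session, model)
        indices = select_breath_scans(session, gate_fraction=gate_fraction)
        logger.info(
            "subject %s: %d breath scans of %d",
            session.subject_id, len(indices), len(session.scans),
        )
        profiles.append(
            average_breath_scans(session, indices, grid, min_height=height_filter)
        )
    raw = build_feature_matrix(profiles, align_tolerance=tolerance)
    return normalize_cascade(raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict.

    Stages: read + preprocess -> panel matching -> stratified group
    statistics -> balanced (optional) cross-validated classification.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    input_dir = Path(config.input_dir)
    files = sorted(input_dir.glob("*.mzXML")) + sorted(input_dir.glob("*.mzxml"))
    if not files:
        raise ConfigError(f"no mzXML files in {input_dir}")
    records = load_metadata(config.metadata_path)
    by_id = {r.subject_id: r for r in records}
    sessions = []
    for f in files:
        session = read_mzxml(f)
        session.metadata = by_id.get(session.subject_id)
        if session.metadata is None:
            logger.warning("subject %s has no metadata row; skipped", session.subject_id)
            continue
        sessions.append(session)
    grid = FeatureGrid(config.mass_range[0], config.mass_range[1], config.grid_step)
    matrix = preprocess_sessions(
        sessions,
        grid=grid,
        height_filter=config.height_filter,
        gate_fraction=config.gate_fraction,
        tolerance=config.tolerance,
        recalibrate=config.recalibrate,
    )
    matrix_df = pd.DataFrame(
        matrix.values,
        index=matrix.subject_ids,
        columns=[f"{m:.4f}" for m in matrix.feature_mz],
    )
    matrix_df.to_csv(out / "matrix.csv", index_label="subject_id")
    (out / "matrix.json").write_text(json.dumps({
        "state": matrix.state,
        "config_hash": config.config_hash(),
        "version": _VERSION,
    }, indent=1))

    panel = (
        load_panel(config.panel_path) if config.panel_path else reference_panel()
    )
    matches = match_markers(matrix, panel, tolerance=config.tolerance)
    pd.DataFrame({
        "panel_mz": [m.mz for m in panel.markers],
        "matched_mz": [
            None if c is None else matrix.feature_mz[c] for c in matches.column
        ],
        "delta_mz": matches.delta_mz,
    }).to_csv(out / "matches.csv", index=False)
    logger.info("detected %d of %d panel features", matches.n_detected, len(panel))

    rule = StratificationRule(config.stratification)
    included, excluded = apply_stratification(
        [s.metadata for s in sessions], rule
    )
    for sid, reason in excluded.items():
        logger.info("excluded %s: %s", sid, reason)
    group_a = [s for s in included["osa_untreated"] if s in matrix.subject_ids]
    group_b = [s for s in included["osa_treated"] if s in matrix.subject_ids]
    results, significant = compare_groups(
        matrix, matches, group_a, group_b, alpha=config.alpha
    )
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        out / "results.csv", index=False
    )

    detected_cols = matches.detected_columns()
    fc_scale = matrix.tic_values if matrix.tic_values is not None else matrix.values
    ids = group_a + group_b
    idx = matrix.column_for(ids)
    X = fc_scale[np.ix_(idx, detected_cols)]
    y = np.array([1] * len(group_a) + [0] * len(group_b))
    if config.balance:
        keep = balanced_subsample(y, seed=config.seed)
        X, y = X[keep], y[keep]
    cv = CVConfig(k=config.cv_folds, seed=config.seed)
    report = crossvalidate(X, y, cv)
    payload = {
        "schema_version": 1,
        "package_version": _VERSION,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(sessions),
        "n_detected_markers": matches.n_detected,
        "n_significant_markers": len(significant),
        "significant_mz": [r.mz for r in significant],
        "classification": report.as_dict(),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1))
    return payload
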