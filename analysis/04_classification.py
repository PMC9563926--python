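#!/usr/bin/env python
"""Cross-validated OSA prediction from the detected marker signature.

Two experiments:

1. the simulated scan-level cohort (from 01/02): balanced untreated vs
   treated classification with stratification-2 inclusion, 10-fold CV —
   mirrors the design of a balanced 15/15 comparison at small n;
2. the fast matrix tier at the published balanced size (15 vs 15, nine
   markers at 2 pooled-SD shifts, 42 detected features), averaged over
   25 seeds, reporting mean AUC/accuracy/sensitivity/specificity.

Writes results/classification.json.
"""

import json
from pathlib import Path

import numpy as np

import breathflow as bf
from breathflow.pipeline import load_metadata

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "marker_tests", Path(__file__).parent / "03_marker_tests.py"
)
_mt = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mt)


def scan_level_experiment(seed: int = 7) -> dict:
    matrix = _mt.load_matrix()
    records = load_metadata(ROOT / "scratch" / "cohort" / "subjects.csv")
    included, _ = bf.apply_stratification(records, bf.STRAT2)
    ids_a = [s for s in included["osa_untreated"] if s in matrix.subject_ids]
    ids_b = [s for s in included["osa_treated"] if s in matrix.subject_ids]
    matches = bf.match_markers(matrix, bf.reference_panel())
    idx = matrix.column_for(ids_a + ids_b)
    X = matrix.tic_values[np.ix_(idx, matches.detected_columns())]
    y = np.array([1] * len(ids_a) + [0] * len(ids_b))
    keep = bf.balanced_subsample(y, seed=seed)
    X, y = X[keep], y[keep]
    k = min(10, int((y == 1).sum()))
    report = bf.crossvalidate(X, y, bf.CVConfig(k=k, seed=seed))
    print(f"scan-level cohort (strat2, balanced {int((y==1).sum())}/"
          f"{int((y==0).sum())}, {k}-fold): AUC {report.auc:.2f}, "
          f"accuracy {report.accuracy:.0%}, sensitivity {report.sensitivity:.0%}, "
          f"specificity {report.specificity:.0%}")
    return {"experiment": "scan_level_balanced", **report.as_dict()}


def matrix_tier_experiment(n_seeds: int = 25) -> dict:
    effects = {round(m.mz, 4): 2.0 for m in bf.table2_panel().markers}
    panel = bf.MarkerPanel(markers=list(bf.reference_panel().markers[:42]))
    metrics = {"auc": [], "accuracy": [], "sensitivity": [], "specificity": []}
    for seed in range(n_seeds):
        m, _ = bf.simulate_feature_matrix(
            15, 15, effects=effects, panel=panel, n_baseline_peaks=10, seed=seed
        )
        norm = bf.normalize_cascade(m)
        matches = bf.match_markers(norm, panel)
        X = norm.tic_values[:, matches.detected_columns()]
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        r = bf.crossvalidate(X, y, bf.CVConfig(k=10, seed=seed))
        for k in metrics:
            metrics[k].append(getattr(r, k))
    means = {k: float(np.mean(v)) for k, v in metrics.items()}
    print(f"matrix tier (15/15, 42 features, nine 2-SD markers, "
          f"{n_seeds} seeds): mean AUC {means['auc']:.2f}, "
          f"accuracy {means['accuracy']:.0%}, sensitivity "
          f"{means['sensitivity']:.0%}, specificity {means['specificity']:.0%}")
    return {"experiment": "matrix_tier_15v15", "n_seeds": n_seeds, "mean": means}


def main() -> None:
    out = {
        "scan_level": scan_level_experiment(),
        "matrix_tier": matrix_tier_experiment(),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "classification.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
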