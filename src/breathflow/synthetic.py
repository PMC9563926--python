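"""Synthetic breath-measurement cohorts with known ground truth.

Nothing from the clinical study is redistributable, so every pipeline
stage is exercised on generated data that emulates its salient features:

* scan streams of six consecutive exhalations — ambient scans with low
  background alternating with exhalation blocks in which the protonated
  water trimer (m/z 55.039) bursts with a trapezoidal intensity profile;
* Gaussian peak profiles on the m/z axis with TOF-like resolving power
  (m/dm ~ 30,000), additive Gaussian noise, and a per-subject linear
  mass drift;
* marker intensities log-normal across subjects (breath intensities are
  right-skewed, which is what motivates the nonparametric testing), with
  configurable between-group median shifts in pooled-SD units;
* subject metadata (AHI, ODI, ESS, CPAP usage) drawn from log-normal
  approximations of the study cohort's published medians/IQRs, so the
  stratification rules have known pass/fail sets.

Two tiers are provided. ``generate_cohort`` renders full scan streams to
mzXML (slow, exercises spectral preprocessing end to end);
``simulate_feature_matrix`` draws the subjects x features matrix directly
from the same intensity model (fast, for the large statistical
simulations).

Generated spectra are sparse profiles: points are stored on local grids
around each peak (half-sigma spacing out to four sigma) plus a coarse
1 Da baseline lattice; the pipeline's gridding interpolates between
stored points exactly as it would for dense profile data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .panel import MarkerPanel, table2_panel, reference_panel
from .preprocess import (
    IntensityMatrix,
    WATER_DIMER_MZ,
    WATER_TRIMER_MZ,
    WATER_TETRAMER_MZ,
)
from .spectra import BreathSession, MassSpectrum, write_mzxml
from .stats import SubjectRecord

#: Log-normal (mu, sigma) approximations of the cohort metadata
#: distributions, fitted to published group medians and IQRs.
_META_DISTS = {
    "osa_untreated": {
        "ahi_visit": (np.log(28.0), 0.56),
        "ahi_diagnosis": (np.log(30.2), 0.466),
        "odi": (np.log(29.9), 0.80),
        "ess": (np.log(5.0), 0.81),
    },
    "osa_treated": {
        "ahi_visit": (np.log(1.3), 1.115),
        "ahi_diagnosis": (np.log(35.5), 0.457),
        "odi": (np.log(29.0), 0.78),
        "ess": (np.log(6.0), 0.81),
    },
    "control": {
        "ahi_visit": (np.log(3.0), 0.514),
        "ahi_diagnosis": (np.log(3.0), 0.514),
        "odi": (np.log(4.5), 0.91),
        "ess": (np.log(7.5), 0.45),
    },
}
#: CPAP usage (h/night) for treated subjects: normal, clipped at 0.
_CPAP_MEAN, _CPAP_SD = 5.8, 1.5


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the validation-study shape: group sizes 43/43/32,
    six exhalations per session, 0.5 s scans, m/z 50-500, and the nine
    attributed panel markers shifted upward in untreated OSA (2 pooled
    SDs — a clearly detectable signature) against a 78-feature targeted
    panel.
    """

    n_untreated: int = 43
    n_treated: int = 43
    n_control: int = 32
    effect_table: Optional[dict[float, float]] = None  # m/z -> shift, pooled-SD units
    panel: Optional[MarkerPanel] = None  # markers planted in every subject
    n_baseline_peaks: int = 60
    baseline_log_mu: float = np.log(20.0)
    baseline_log_sigma: float = 1.0
    marker_log_mu: float = np.log(30.0)
    marker_log_sigma: float = 0.5
    noise_sd: float = 1.0  # counts/s
    mass_drift_max: float = 0.003  # Da, per-subject offset ~ U(-max, max)
    n_exhalations: int = 6
    exhalation_duration_scans: int = 4
    ambient_scans_between: int = 3
    lead_in_scans: int = 3
    scan_period: float = 0.5  # s
    mass_range: tuple[float, float] = (50.0, 500.0)
    resolution: float = 30000.0  # m / dm (FWHM)
    gate_height: float = 200.0  # water-trimer apex during exhalation, counts/s
    ambient_background: float = 0.02  # ambient scans at this fraction of breath signal
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_untreated, self.n_treated) <= 0 or self.n_control < 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mass_drift_max > 0.01:
            raise ValueError("|mass drift| must be <= 0.01 Da")
        if self.panel is None:
            self.panel = reference_panel()
        if self.effect_table is None:
            self.effect_table = {m.mz: 2.0 for m in table2_panel().markers}

    @property
    def scans_per_session(self) -> int:
        return self.lead_in_scans + self.n_exhalations * (
            self.exhalation_duration_scans + self.ambient_scans_between
        )

    def exhalation_windows(self) -> list[list[int]]:
        """Planted exhalation scan indices, one list per exhalation."""
        windows = []
        pos = self.lead_in_scans
        for _ in range(self.n_exhalations):
            windows.append(list(range(pos, pos + self.exhalation_duration_scans)))
            pos += self.exhalation_duration_scans + self.ambient_scans_between
        return windows


def lognormal_sd(mu: float, sigma: float) -> float:
    """Population SD of a log-normal(mu, sigma) variable."""
    mean = np.exp(mu + sigma**2 / 2)
    return float(mean * np.sqrt(np.exp(sigma**2) - 1.0))


def _trapezoid(n: int) -> np.ndarray:
    """Exhalation intensity profile: half-height shoulders, flat top."""
    prof = np.ones(n)
    if n >= 2:
        prof[0] = prof[-1] = 0.5
    return prof


def _render_scan(
    peak_mz: np.ndarray,
    peak_height: np.ndarray,
    cfg: CohortConfig,
    rng: np.random.Generator,
    drift_offset: float,
) -> MassSpectrum:
    """Render one sparse profile scan from peak positions and apex heights."""
    lo, hi = cfg.mass_range
    grids = [np.arange(lo + 0.5, hi, 1.0)]  # coarse baseline lattice
    for mz0 in peak_mz:
        sigma = mz0 / cfg.resolution / 2.3548
        grids.append(mz0 + sigma * np.arange(-8, 9) / 2.0)
    mz = np.unique(np.concatenate(grids))
    intensity = np.zeros_like(mz)
    for mz0, h in zip(peak_mz, peak_height):
        if h <= 0:
            continue
        sigma = mz0 / cfg.resolution / 2.3548
        sel = slice(
            np.searchsorted(mz, mz0 - 5 * sigma), np.searchsorted(mz, mz0 + 5 * sigma)
        )
        intensity[sel] += h * np.exp(-0.5 * ((mz[sel] - mz0) / sigma) ** 2)
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=mz.size)
    np.clip(intensity, 0.0, None, out=intensity)
    # the instrument records nothing outside its acquisition range
    keep = (mz >= lo) & (mz <= hi)
    return MassSpectrum(mz=mz[keep] + drift_offset, intensity=intensity[keep])


def generate_session(
    subject_id: str,
    marker_heights: dict[float, float],
    baseline_mz: np.ndarray,
    baseline_heights: np.ndarray,
    cfg: CohortConfig,
    seed: int,
    drift_offset: Optional[float] = None,
    metadata: Optional[SubjectRecord] = None,
) -> tuple[BreathSession, dict]:
    """Generate one subject's scan stream plus its ground truth.

    ``marker_heights`` maps true marker m/z to the subject's apex height
    during full exhalation; ``baseline_*`` are the non-marker background
    peaks shared across the cohort. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if drift_offset is None:
        drift_offset = float(rng.uniform(-cfg.mass_drift_max, cfg.mass_drift_max))
    windows = cfg.exhalation_windows()
    in_window = {i: w_scale for w in windows
                 for i, w_scale in zip(w, _trapezoid(len(w)))}
    # full protonated water-cluster series: the trimer gates exhalation,
    # the dimer/tetramer give recalibration a usable calibrant set
    cluster_mz = [WATER_DIMER_MZ, WATER_TRIMER_MZ, WATER_TETRAMER_MZ]
    cluster_height = [0.6 * cfg.gate_height, cfg.gate_height, 0.4 * cfg.gate_height]
    peak_mz = np.concatenate(
        [cluster_mz, list(marker_heights.keys()), baseline_mz]
    )
    full_height = np.concatenate(
        [cluster_height, list(marker_heights.values()), baseline_heights]
    )
    scans = []
    for i in range(cfg.scans_per_session):
        if i in in_window:
            h = full_height * in_window[i]
        else:
            h = full_height * cfg.ambient_background
            h[0:3] = 0.0  # no water-cluster burst while not exhaling
        scan = _render_scan(peak_mz, h, cfg, rng, drift_offset)
        scan.scan_time = i * cfg.scan_period
        scans.append(scan)
    session = BreathSession(subject_id=subject_id, scans=scans, metadata=metadata)
    ground_truth = {
        "subject_id": subject_id,
        "exhalation_windows": windows,
        "breath_scan_indices": sorted(in_window),
        "drift_offset": drift_offset,
        "marker_heights": {f"{k:.4f}": v for k, v in marker_heights.items()},
    }
    return session, ground_truth


def _sample_metadata(
    subject_id: str, group: str, rng: np.random.Generator
) -> SubjectRecord:
    dists = _META_DISTS[group]
    draw = {k: float(np.exp(rng.normal(mu, s))) for k, (mu, s) in dists.items()}
    cpap = None
    if group == "osa_treated":
        cpap = float(max(0.0, rng.normal(_CPAP_MEAN, _CPAP_SD)))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        ahi_visit=round(draw["ahi_visit"], 1),
        ahi_diagnosis=round(draw["ahi_diagnosis"], 1),
        odi=round(draw["odi"], 1),
        ess=float(int(np.clip(draw["ess"], 0, 24))),
        cpap_hours=round(cpap, 1) if cpap is not None else None,
    )


def _subject_plan(cfg: CohortConfig, rng: np.random.Generator):
    """Per-subject group labels, metadata and true marker heights."""
    groups = (
        ["osa_untreated"] * cfg.n_untreated
        + ["osa_treated"] * cfg.n_treated
        + ["control"] * cfg.n_control
    )
    marker_mzs = [m.mz for m in cfg.panel.markers]
    pooled_sd = lognormal_sd(cfg.marker_log_mu, cfg.marker_log_sigma)
    plan = []
    for i, group in enumerate(groups):
        sid = f"S{i:03d}"
        meta = _sample_metadata(sid, group, rng)
        heights = {}
        for mz in marker_mzs:
            base = float(
                np.exp(rng.normal(cfg.marker_log_mu, cfg.marker_log_sigma))
            )
            effect = cfg.effect_table.get(round(mz, 4), 0.0)
            if group == "osa_untreated" and effect:
                base += effect * pooled_sd
            heights[mz] = base
        plan.append((sid, group, meta, heights))
    return plan


def _baseline_peaks(cfg: CohortConfig, rng: np.random.Generator):
    """Cohort-wide background peak positions, clear of markers and gate."""
    lo, hi = cfg.mass_range
    avoid = np.concatenate([[WATER_TRIMER_MZ], [m.mz for m in cfg.panel.markers]])
    mzs: list[float] = []
    while len(mzs) < cfg.n_baseline_peaks:
        m = float(rng.uniform(lo + 5, hi - 5))
        if np.all(np.abs(avoid - m) > 0.05) and all(abs(m - x) > 0.05 for x in mzs):
            mzs.append(m)
    return np.sort(np.array(mzs))


def simulate_cohort_sessions(
    cfg: CohortConfig,
) -> tuple[list[BreathSession], list[SubjectRecord], dict]:
    """In-memory cohort of full scan-stream sessions (slow tier)."""
    rng = np.random.default_rng(cfg.seed)
    baseline_mz = _baseline_peaks(cfg, rng)
    sessions, records, per_subject = [], [], {}
    seed_stream = np.random.SeedSequence(cfg.seed).spawn(
        cfg.n_untreated + cfg.n_treated + cfg.n_control
    )
    for (sid, group, meta, heights), ss in zip(_subject_plan(cfg, rng), seed_stream):
        baseline_heights = np.exp(
            rng.normal(cfg.baseline_log_mu, cfg.baseline_log_sigma, baseline_mz.size)
        )
        session, gt = generate_session(
            sid,
            heights,
            baseline_mz,
            baseline_heights,
            cfg,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            metadata=meta,
        )
        gt["group"] = group
        sessions.append(session)
        records.append(meta)
        per_subject[sid] = gt
    ground_truth = {
        "effect_table": {f"{k:.4f}": v for k, v in cfg.effect_table.items()},
        "subjects": per_subject,
    }
    return sessions, records, ground_truth


def generate_cohort(cfg: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a cohort to disk: one mzXML per subject, subjects.csv and
    ground_truth.json. Fully reproducible from ``cfg.seed``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions, records, ground_truth = simulate_cohort_sessions(cfg)
    for session in sessions:
        write_mzxml(session, outdir / f"{session.subject_id}.mzXML")
    meta_df = pd.DataFrame([asdict(r) for r in records])
    meta_path = outdir / "subjects.csv"
    meta_df.to_csv(meta_path, index=False)
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(ground_truth, indent=1))
    return {"dir": outdir, "metadata": meta_path, "ground_truth": gt_path}


# ---------------------------------------------------------------------------
# fast statistical tier


def simulate_feature_matrix(
    n_a: int,
    n_b: int,
    effects: Optional[dict[float, float]] = None,
    panel: Optional[MarkerPanel] = None,
    n_baseline_peaks: int = 60,
    marker_log_mu: float = np.log(30.0),
    marker_log_sigma: float = 0.5,
    baseline_log_mu: float = np.log(20.0),
    baseline_log_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[IntensityMatrix, np.ndarray]:
    """Draw a raw subjects x features matrix directly (fast tier).

    Rows 0..n_a-1 are untreated (label 1), the rest treated (label 0).
    Feature columns are the panel m/z plus background columns; marker
    intensities are log-normal with the same between-group shift model
    as the scan-level generator, in pooled-SD units.

    Returns ``(matrix, labels)``; ``matrix.tics`` holds per-subject TICs.
    """
    panel = panel or reference_panel()
    effects = effects if effects is not None else {}
    rng = np.random.default_rng(seed)
    marker_mz = np.array([m.mz for m in panel.markers])
    lo_free = np.setdiff1d(
        np.round(np.linspace(60.0, 480.0, n_baseline_peaks * 3), 2), np.round(marker_mz, 2)
    )
    baseline_mz = np.sort(rng.choice(lo_free, size=n_baseline_peaks, replace=False))
    feature_mz = np.concatenate([marker_mz, baseline_mz])
    order = np.argsort(feature_mz)
    n = n_a + n_b
    pooled_sd = lognormal_sd(marker_log_mu, marker_log_sigma)
    markers = np.exp(rng.normal(marker_log_mu, marker_log_sigma, (n, marker_mz.size)))
    for j, mz in enumerate(marker_mz):
        eff = effects.get(round(float(mz), 4), 0.0)
        if eff:
            markers[:n_a, j] += eff * pooled_sd
    baseline = np.exp(
        rng.normal(baseline_log_mu, baseline_log_sigma, (n, baseline_mz.size))
    )
    values = np.concatenate([markers, baseline], axis=1)[:, order]
    subject_ids = [f"S{i:03d}" for i in range(n)]
    labels = np.array([1] * n_a + [0] * n_b)
    matrix = IntensityMatrix(
        subject_ids=subject_ids,
        feature_mz=feature_mz[order],
        values=values,
        state="raw",
        tics=values.sum(axis=1),
    )
    return matrix, labels
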