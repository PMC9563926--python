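"""Spectral preprocessing: recalibration, alignment, gating, peak picking,
averaging and the normalization cascade.

The chain mirrors standard real-time breath-analysis practice:

1. every subject's spectra are recalibrated onto one reference breath
   spectrum via a two-parameter linear m/z correction fitted on
   always-present calibrant ions (the protonated water-cluster series);
2. intensities are linearly interpolated onto a common uniform m/z grid;
3. exhalation scans are selected by the protonated water trimer at
   m/z 55.039 (gate = fraction of the session-wide maximum in a ±0.005 Da
   window);
4. the selected scans are averaged and peaks are picked on the averaged
   trace with a 5 counts/s height filter;
5. subject profiles are aligned across the cohort into an intensity
   matrix, which is TIC-normalized, scaled to the cohort median TIC and
   auto-scaled (per-feature z-score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import CalibrationError, NoBreathDetectedError, NormalizationError
from .spectra import BreathSession, MassSpectrum

#: Protonated water cluster series [(H2O)n+H]+, n = 2..4 — always present in
#: exhaled breath, used both for gating and as default calibrants.
WATER_DIMER_MZ = 37.0284
WATER_TRIMER_MZ = 55.0390
WATER_TETRAMER_MZ = 73.0495
DEFAULT_CALIBRANTS = (WATER_DIMER_MZ, WATER_TRIMER_MZ, WATER_TETRAMER_MZ)

DEFAULT_HEIGHT_FILTER = 5.0  # counts/s
DEFAULT_TOLERANCE = 0.005  # Da
DEFAULT_GATE_FRACTION = 0.1
DEFAULT_GRID_STEP = 0.001  # Da

_MATRIX_STATES = ("raw", "tic_normalized", "median_scaled", "autoscaled")


# ---------------------------------------------------------------------------
# recalibration


@dataclass
class CalibrationModel:
    """Linear m/z correction  m/z_corrected = slope * m/z + offset.

    ``residuals`` holds per-calibrant deviations (Da) after the fit.
    Accepted fits satisfy slope in [0.999, 1.001] and |offset| <= 0.05 Da
    (sanity bounds for a high-resolution TOF).
    """

    slope: float
    offset: float
    reference_id: str = ""
    residuals: dict[float, float] = field(default_factory=dict)

    def apply(self, mz: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(mz, dtype=float) + self.offset

    def inverse(self) -> "CalibrationModel":
        return CalibrationModel(
            slope=1.0 / self.slope,
            offset=-self.offset / self.slope,
            reference_id=self.reference_id,
        )

    @property
    def max_residual(self) -> float:
        return max((abs(r) for r in self.residuals.values()), default=0.0)


def _window_centroid(
    spectrum: MassSpectrum, center: float, tol: float, min_height: float
) -> Optional[float]:
    """Intensity-weighted centroid of the signal in ``center`` ± ``tol``.

    Returns None when the window apex is below ``min_height``.
    """
    lo = np.searchsorted(spectrum.mz, center - tol, side="left")
    hi = np.searchsorted(spectrum.mz, center + tol, side="right")
    if hi <= lo:
        return None
    mz = spectrum.mz[lo:hi]
    inten = spectrum.intensity[lo:hi]
    apex = inten.max()
    if apex < min_height:
        return None
    keep = inten >= apex / 2.0
    return float(np.average(mz[keep], weights=inten[keep]))


def _representative_scan(session: BreathSession) -> MassSpectrum:
    """The session's most intense scan (highest TIC) — used for calibration."""
    return max(session.scans, key=lambda s: s.tic)


def fit_recalibration(
    session: BreathSession,
    reference: MassSpectrum,
    calibrant_mzs: Sequence[float] = DEFAULT_CALIBRANTS,
    window: float = 0.02,
    min_height: float = DEFAULT_HEIGHT_FILTER,
) -> CalibrationModel:
    """Fit a linear m/z correction mapping the session onto ``reference``.

    Each calibrant is located (windowed centroid, ``window`` = coarse
    search half-width in Da) in both the session's most intense scan and
    the reference; a least-squares line through the matched
    (observed, reference) positions gives slope and offset.

    Raises
    ------
    CalibrationError
        If fewer than two calibrants are detectable in both spectra, or the
        fitted model violates the sanity bounds.
    """
    scan = _representative_scan(session)
    observed, target, missing = [], [], []
    for cal in calibrant_mzs:
        obs = _window_centroid(scan, cal, window, min_height)
        ref = _window_centroid(reference, cal, window, min_height)
        if obs is None or ref is None:
            missing.append(cal)
            continue
        observed.append(obs)
        target.append(ref)
    if len(observed) < 2:
        raise CalibrationError(
            f"session {session.subject_id!r}: only {len(observed)} calibrant(s) "
            f"matched; missing {missing}"
        )
    obs_arr = np.array(observed)
    tgt_arr = np.array(target)
    slope, offset = np.polyfit(obs_arr, tgt_arr, 1)
    residuals = {
        cal: float(t - (slope * o + offset))
        for cal, o, t in zip(
            [c for c in calibrant_mzs if c not in missing], obs_arr, tgt_arr
        )
    }
    model = CalibrationModel(
        slope=float(slope), offset=float(offset), reference_id=session.subject_id,
        residuals=residuals,
    )
    if not (0.999 <= model.slope <= 1.001) or abs(model.offset) > 0.05:
        raise CalibrationError(
            f"session {session.subject_id!r}: fitted correction "
            f"(slope {model.slope:.6f}, offset {model.offset:.4f} Da) outside "
            "sanity bounds"
        )
    return model


def apply_recalibration(session: BreathSession, model: CalibrationModel) -> BreathSession:
    """Return a new session with corrected m/z axes; intensities untouched."""
    scans = [
        MassSpectrum(
            mz=model.apply(s.mz),
            intensity=s.intensity.copy(),
            scan_time=s.scan_time,
            ms_level=s.ms_level,
            centroided=s.centroided,
        )
        for s in session.scans
    ]
    return BreathSession(
        subject_id=session.subject_id, scans=scans, metadata=session.metadata
    )


# ---------------------------------------------------------------------------
# gridding


@dataclass
class FeatureGrid:
    """Uniform common m/z axis covering the acquisition range."""

    start: float = 50.0
    stop: float = 500.0
    step: float = DEFAULT_GRID_STEP

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop <= self.start:
            raise ValueError("invalid grid specification")
        n = int(round((self.stop - self.start) / self.step)) + 1
        self.mz_grid = self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return self.mz_grid.size


def interpolate_to_grid(spectrum: MassSpectrum, grid: FeatureGrid) -> np.ndarray:
    """Linearly interpolate a spectrum onto the grid; 0 outside its support."""
    if spectrum.mz.size == 0:
        raise ValueError("cannot interpolate an empty spectrum")
    return np.interp(grid.mz_grid, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# exhalation gating


def select_breath_scans(
    session: BreathSession,
    gate_mz: float = WATER_TRIMER_MZ,
    gate_tolerance: float = DEFAULT_TOLERANCE,
    gate_fraction: float = DEFAULT_GATE_FRACTION,
) -> list[int]:
    """Indices of scans acquired during exhalation.

    A scan is selected iff its maximum intensity in ``gate_mz`` ±
    ``gate_tolerance`` exceeds ``gate_fraction`` times the session-wide
    maximum of that window. The water-cluster gate is robust to
    inter-subject intensity scale because the threshold is relative.

    Raises
    ------
    NoBreathDetectedError
        If no scan passes the gate (failed measurement).
    """
    window_max = np.array(
        [s.max_in_window(gate_mz, gate_tolerance) for s in session.scans]
    )
    peak = window_max.max()
    if peak <= 0:
        raise NoBreathDetectedError(
            f"session {session.subject_id!r}: no water-cluster signal at "
            f"m/z {gate_mz:.4f}"
        )
    selected = np.flatnonzero(window_max > gate_fraction * peak)
    if selected.size == 0:
        raise NoBreathDetectedError(
            f"session {session.subject_id!r}: no scan above the exhalation gate"
        )
    return selected.tolist()


# ---------------------------------------------------------------------------
# peak picking


@dataclass
class PeakList:
    """Picked peaks: ascending centroids (Da) with apex heights (counts/s)."""

    centroids: np.ndarray
    heights: np.ndarray

    def __len__(self) -> int:
        return self.centroids.size


def pick_peaks(
    intensity: np.ndarray,
    grid: FeatureGrid,
    min_height: float = DEFAULT_HEIGHT_FILTER,
) -> PeakList:
    """Pick local maxima on a gridded trace.

    A peak is a local maximum strictly greater than both neighbours
    (plateaus resolve to the plateau midpoint) with apex height >=
    ``min_height``. The centroid is the intensity-weighted mean m/z over
    the contiguous region above half the apex.
    """
    intensity = np.asarray(intensity, dtype=float)
    apex_idx, props = find_peaks(intensity, height=min_height, plateau_size=1)
    centroids = np.empty(apex_idx.size)
    heights = props["peak_heights"]
    mz = grid.mz_grid
    for k, i in enumerate(apex_idx):
        half = intensity[i] / 2.0
        lo = i
        while lo > 0 and intensity[lo - 1] >= half and intensity[lo - 1] <= intensity[lo]:
            lo -= 1
        hi = i
        n = intensity.size
        while hi < n - 1 and intensity[hi + 1] >= half and intensity[hi + 1] <= intensity[hi]:
            hi += 1
        seg = slice(lo, hi + 1)
        centroids[k] = np.average(mz[seg], weights=intensity[seg])
    order = np.argsort(centroids)
    return PeakList(centroids=centroids[order], heights=heights[order])


# ---------------------------------------------------------------------------
# averaging


@dataclass
class SubjectProfile:
    """Per-subject averaged feature list (picked from the mean breath trace)."""

    subject_id: str
    feature_mz: np.ndarray
    feature_intensity: np.ndarray
    tic: float

    def __post_init__(self) -> None:
        if np.any(self.feature_intensity < 0):
            raise ValueError("negative feature intensities")


def average_breath_scans(
    session: BreathSession,
    indices: Sequence[int],
    grid: FeatureGrid,
    min_height: float = DEFAULT_HEIGHT_FILTER,
    pick_per_scan: bool = False,
) -> SubjectProfile:
    """Average the selected (gridded) breath scans and pick peaks.

    By default the gridded traces are averaged first and peaks are picked
    on the mean trace (average-then-pick). ``pick_per_scan=True`` instead
    averages per-scan peak heights on the union of peak positions
    (pick-then-average), offered for comparison.
    """
    if len(indices) == 0:
        raise ValueError("empty breath-scan index set")
    traces = np.stack(
        [interpolate_to_grid(session.scans[i], grid) for i in indices]
    )
    if pick_per_scan:
        # pick-then-average: peaks per scan, clustered along m/z, heights
        # averaged over ALL selected scans (absent peak contributes 0)
        per_scan = [pick_peaks(t, grid, min_height=0.0) for t in traces]
        mzs = np.concatenate([p.centroids for p in per_scan])
        hts = np.concatenate([p.heights for p in per_scan])
        if mzs.size == 0:
            peaks = PeakList(centroids=np.empty(0), heights=np.empty(0))
        else:
            order = np.argsort(mzs)
            mzs, hts = mzs[order], hts[order]
            brk = np.flatnonzero(np.diff(mzs) > DEFAULT_TOLERANCE) + 1
            cid = np.zeros(mzs.size, dtype=int)
            cid[brk] = 1
            cid = np.cumsum(cid)
            n_c = cid[-1] + 1
            cent = np.array(
                [np.average(mzs[cid == c], weights=np.maximum(hts[cid == c], 1e-300))
                 for c in range(n_c)]
            )
            mean_h = np.bincount(cid, weights=hts, minlength=n_c) / len(indices)
            keep = mean_h >= min_height
            peaks = PeakList(centroids=cent[keep], heights=mean_h[keep])
    else:
        mean_trace = traces.mean(axis=0)
        peaks = pick_peaks(mean_trace, grid, min_height)
    return SubjectProfile(
        subject_id=session.subject_id,
        feature_mz=peaks.centroids,
        feature_intensity=peaks.heights,
        tic=float(peaks.heights.sum()),
    )


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class IntensityMatrix:
    """Subjects x aligned features with a normalization-state flag.

    ``state`` advances only in the order raw -> tic_normalized ->
    median_scaled -> autoscaled. ``tic_values`` snapshots the
    TIC-normalized matrix (fold changes are ratios, so they are computed
    on that scale, not on z-scores).
    """

    subject_ids: list[str]
    feature_mz: np.ndarray
    values: np.ndarray
    state: str = "raw"
    tics: Optional[np.ndarray] = None
    tic_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.state not in _MATRIX_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), self.feature_mz.size):
            raise ValueError("values shape does not match subjects x features")

    def column_for(self, subject_ids: Sequence[str]) -> np.ndarray:
        idx = [self.subject_ids.index(s) for s in subject_ids]
        return np.asarray(idx, dtype=int)


def build_feature_matrix(
    profiles: Sequence[SubjectProfile],
    align_tolerance: float = DEFAULT_TOLERANCE,
) -> IntensityMatrix:
    """Align subject profiles into a raw intensity matrix.

    Features from all subjects are clustered along m/z by 1-D single
    linkage: sorted features are split wherever the gap between
    consecutive m/z values exceeds ``align_tolerance``. Each cluster
    becomes one column; its representative m/z is the intensity-weighted
    mean. Subjects lacking a feature get 0 (absent signal, not missing).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to build a matrix")
    all_mz = np.concatenate([p.feature_mz for p in profiles])
    all_int = np.concatenate([p.feature_intensity for p in profiles])
    all_subj = np.concatenate(
        [np.full(p.feature_mz.size, i) for i, p in enumerate(profiles)]
    )
    order = np.argsort(all_mz)
    all_mz, all_int, all_subj = all_mz[order], all_int[order], all_subj[order]
    if all_mz.size == 0:
        return IntensityMatrix(
            subject_ids=[p.subject_id for p in profiles],
            feature_mz=np.empty(0),
            values=np.zeros((len(profiles), 0)),
            tics=np.array([p.tic for p in profiles]),
        )
    breaks = np.flatnonzero(np.diff(all_mz) > align_tolerance) + 1
    cluster_of = np.zeros(all_mz.size, dtype=int)
    cluster_of[breaks] = 1
    cluster_of = np.cumsum(cluster_of)
    n_clusters = cluster_of[-1] + 1
    rep_mz = np.array(
        [
            np.average(all_mz[cluster_of == c], weights=np.maximum(all_int[cluster_of == c], 1e-300))
            for c in range(n_clusters)
        ]
    )
    values = np.zeros((len(profiles), n_clusters))
    # a subject contributing several features to one cluster sums them
    np.add.at(values, (all_subj, cluster_of), all_int)
    return IntensityMatrix(
        subject_ids=[p.subject_id for p in profiles],
        feature_mz=rep_mz,
        values=values,
        tics=np.array([p.tic for p in profiles]),
    )


def normalize_cascade(
    matrix: IntensityMatrix,
    tics: Optional[np.ndarray] = None,
    ddof: int = 0,
) -> IntensityMatrix:
    """Run the full raw -> TIC -> median-TIC -> auto-scaled cascade.

    Step 1 divides each subject row by its TIC; step 2 multiplies all rows
    by the median TIC across subjects (restores a common intensity scale);
    step 3 z-scores each feature column (population SD by default,
    ``ddof=1`` for sample SD). Zero-variance columns are dropped with a
    warning. The TIC-normalized matrix is retained in ``tic_values``.
    """
    if matrix.state != "raw":
        raise NormalizationError(f"cascade starts from 'raw', got {matrix.state!r}")
    tics = np.asarray(tics if tics is not None else matrix.tics, dtype=float)
    if tics is None or tics.shape != (len(matrix.subject_ids),):
        raise NormalizationError("per-subject TICs required")
    zero = np.flatnonzero(tics == 0)
    if zero.size:
        raise NormalizationError(
            f"zero TIC for subject(s) {[matrix.subject_ids[i] for i in zero]}"
        )
    tic_norm = matrix.values / tics[:, None]
    median_scaled = tic_norm * np.median(tics)
    sd = median_scaled.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature column(s)",
            stacklevel=2,
        )
    scaled = median_scaled[:, keep]
    autoscaled = (scaled - scaled.mean(axis=0)) / sd[keep]
    return IntensityMatrix(
        subject_ids=list(matrix.subject_ids),
        feature_mz=matrix.feature_mz[keep],
        values=autoscaled,
        state="autoscaled",
        tics=tics,
        tic_values=tic_norm[:, keep],
    )
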