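"""In-memory spectral model and mzXML input/output.

A breath measurement is a time series of full MS1 scans (positive mode,
m/z 50-500, 0.5 s accumulation), six consecutive exhalations per subject.
Scans are stored exactly as read: the reader never reorders scans or m/z
points, and intensities are preserved to floating-point read precision.

mzXML is the canonical on-disk format. Reading goes through
:mod:`pyteomics.mzxml`; writing uses a minimal mzXML 3.2 emitter
(base64-encoded network-order float64 m/z-intensity pairs) whose output
round-trips through the reader bit-identically within 1e-9 relative.
"""

from __future__ import annotations

import base64
import warnings
import xml.sax
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pyteomics import mzxml as _pymzxml

from .errors import EmptySessionError, MzxmlParseError

#: Default acquisition range of the instrument, Da.
DEFAULT_MASS_RANGE = (50.0, 500.0)


@dataclass
class MassSpectrum:
    """One full scan: ascending m/z (Da) with intensities in counts/s.

    Parameters
    ----------
    mz : ndarray
        Strictly ascending m/z values, Da.
    intensity : ndarray
        Non-negative intensities, counts per second; same length as ``mz``.
    scan_time : float
        Seconds from session start.
    ms_level : int
        MS level; always 1 for breath data.
    centroided : bool
        Whether the scan is centroided (peak list) rather than profile.
    """

    mz: np.ndarray
    intensity: np.ndarray
    scan_time: float = 0.0
    ms_level: int = 1
    centroided: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D and equally long")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    @property
    def tic(self) -> float:
        """Total ion current: sum of all intensities."""
        return float(self.intensity.sum())

    def out_of_range(self, mass_range: tuple[float, float] = DEFAULT_MASS_RANGE) -> int:
        """Number of m/z points outside the acquisition range."""
        lo, hi = mass_range
        return int(np.count_nonzero((self.mz < lo) | (self.mz > hi)))

    def max_in_window(self, center: float, tol: float) -> float:
        """Maximum intensity within ``center`` ± ``tol`` Da (0 if no points)."""
        lo = np.searchsorted(self.mz, center - tol, side="left")
        hi = np.searchsorted(self.mz, center + tol, side="right")
        if hi <= lo:
            return 0.0
        return float(self.intensity[lo:hi].max())


@dataclass
class BreathSession:
    """A subject's ordered scan stream plus metadata.

    ``metadata`` is a :class:`breathflow.stats.SubjectRecord` (or None when
    the session has not yet been joined to the subject table).
    """

    subject_id: str
    scans: list[MassSpectrum] = field(default_factory=list)
    metadata: Optional[object] = None

    def __post_init__(self) -> None:
        if not self.scans:
            raise EmptySessionError(f"session {self.subject_id!r} has no scans")
        times = [s.scan_time for s in self.scans]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("scan_time must be non-decreasing across scans")

    def __len__(self) -> int:
        return len(self.scans)


def read_mzxml(path: str | Path, subject_id: Optional[str] = None) -> BreathSession:
    """Read an mzXML file into a :class:`BreathSession`.

    Scans are returned in acquisition order; only MS1 scans are kept.
    Scan times are converted to seconds (pyteomics reports minutes).
    A warning is issued if any m/z point lies outside the default
    acquisition range 50-500 Da; such points are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: list[MassSpectrum] = []
    try:
        with _pymzxml.read(str(path)) as reader:
            for entry in reader:
                if int(entry.get("msLevel", 1)) != 1:
                    continue
                rt = entry.get("retentionTime", 0.0)
                # pyteomics unitfloat in minutes
                scan_time = float(rt) * 60.0
                centroided = bool(int(entry.get("centroided", 0)))
                scans.append(
                    MassSpectrum(
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        scan_time=scan_time,
                        ms_level=1,
                        centroided=centroided,
                    )
                )
    except (xml.sax.SAXException, SyntaxError, KeyError, ValueError) as exc:
        raise MzxmlParseError(
            f"malformed mzXML {path.name} near scan {len(scans) + 1}: {exc}"
        ) from exc
    if not scans:
        raise EmptySessionError(f"{path.name}: no MS1 scans")
    n_out = sum(s.out_of_range() for s in scans)
    if n_out:
        warnings.warn(
            f"{path.name}: {n_out} m/z points outside the "
            f"{DEFAULT_MASS_RANGE[0]:g}-{DEFAULT_MASS_RANGE[1]:g} Da acquisition "
            "range were retained",
            stacklevel=2,
        )
    return BreathSession(subject_id=subject_id or path.stem, scans=scans)


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray) -> str:
    interleaved = np.empty(2 * mz.size, dtype=">f8")
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    return base64.b64encode(interleaved.tobytes()).decode("ascii")


def write_mzxml(session: BreathSession, path: str | Path) -> Path:
    """Write a session to mzXML (profile or centroid flags preserved).

    The emitted file parses with :func:`read_mzxml` to an equivalent
    session (identity on mz/intensity/scan_time to float64 precision).
    """
    path = Path(path)
    parts = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
        f'<msRun scanCount="{len(session.scans)}">\n'
    ]
    for i, scan in enumerate(session.scans, start=1):
        lo = float(scan.mz.min()) if scan.mz.size else 0.0
        hi = float(scan.mz.max()) if scan.mz.size else 0.0
        parts.append(
            f'<scan num="{i}" msLevel="{scan.ms_level}" '
            f'peaksCount="{scan.mz.size}" '
            f'retentionTime="PT{scan.scan_time!r}S" '
            f'centroided="{int(scan.centroided)}" '
            f'lowMz="{lo!r}" highMz="{hi!r}" '
            f'totIonCurrent="{scan.tic!r}">\n'
            '<peaks precision="64" byteOrder="network" contentType="m/z-int" '
            'compressionType="none" compressedLen="0">'
            f"{_encode_peaks(scan.mz, scan.intensity)}</peaks>\n</scan>\n"
        )
    parts.append("</msRun>\n</mzXML>\n")
    path.write_text("".join(parts))
    return path


def session_summary(session: BreathSession) -> dict:
    """Scan count, m/z range and per-scan TIC (used by ``breathflow inspect``)."""
    mz_lo = min(float(s.mz.min()) for s in session.scans if s.mz.size)
    mz_hi = max(float(s.mz.max()) for s in session.scans if s.mz.size)
    return {
        "subject_id": session.subject_id,
        "n_scans": len(session.scans),
        "mz_range": (mz_lo, mz_hi),
        "tic_per_scan": [s.tic for s in session.scans],
    }
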