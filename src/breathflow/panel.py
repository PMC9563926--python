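"""Targeted marker panel: monoisotopic masses, panel loading, matching, audit.

The OSA breath signature is a fixed panel of positive-mode m/z features
previously reported in two independent cohorts. Features of a cohort's
intensity matrix are matched against the panel at a fixed mass tolerance
(0.005 Da, nearest column wins). Panel entries carrying an elemental
composition are interpreted as cation formulas (protonated species,
charge +1): the printed m/z values are consistent with that reading to
well under 0.001 Da. ``audit_panel_masses`` checks this consistency from
first-principles monoisotopic masses.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence
import warnings

import numpy as np

from .preprocess import DEFAULT_TOLERANCE, IntensityMatrix

# Monoisotopic masses of the most abundant isotopes (IUPAC 2021), Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.000548579909  # Da

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition such as ``C8H13O`` to atom counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        if not m.group(0):
            break
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula.strip()) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str, charge: int = 1) -> float:
    """Monoisotopic m/z of an ion: most-abundant-isotope masses minus
    ``charge`` electron masses, divided by ``|charge|``.

    ``charge=0`` returns the neutral monoisotopic mass with a warning
    (m/z is undefined for a neutral).
    """
    counts = parse_formula(formula)
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())
    if charge == 0:
        warnings.warn("charge 0: returning neutral mass, not m/z", stacklevel=2)
        return mass
    return (mass - charge * ELECTRON_MASS) / abs(charge)


@dataclass
class MarkerDefinition:
    """One targeted feature: m/z plus optional annotation."""

    mz: float
    formula: Optional[str] = None
    name: Optional[str] = None
    prior_direction: Optional[str] = None  # "increased" | "decreased"
    prior_significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (50.0 <= self.mz <= 500.0):
            raise ValueError(f"marker m/z {self.mz} outside 50-500 Da")
        if self.formula:
            parse_formula(self.formula)


@dataclass
class MarkerPanel:
    """Ordered targeted feature list with a provenance label."""

    markers: list[MarkerDefinition]
    provenance: str = ""

    def __post_init__(self) -> None:
        rounded = [round(m.mz, 4) for m in self.markers]
        if len(set(rounded)) != len(rounded):
            raise ValueError("panel m/z values not unique at 4 decimals")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m.mz for m in self.markers])


def load_panel(path: str | Path, provenance: str = "") -> MarkerPanel:
    """Load a panel CSV with columns mz, formula, name, prior_direction,
    prior_significant (empty cells allowed for the optional columns)."""
    markers = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sig = row.get("prior_significant", "").strip().lower()
            markers.append(
                MarkerDefinition(
                    mz=float(row["mz"]),
                    formula=row.get("formula") or None,
                    name=row.get("name") or None,
                    prior_direction=row.get("prior_direction") or None,
                    prior_significant={"true": True, "false": False}.get(sig),
                )
            )
    return MarkerPanel(markers=markers, provenance=provenance or str(path))


def _asset(name: str) -> Path:
    return Path(resources.files("breathflow").joinpath("assets", name))


def table2_panel() -> MarkerPanel:
    """The nine fully attributed significant OSA markers (bundled asset)."""
    return load_panel(_asset("table2_markers.csv"), provenance="table2")


def reference_panel() -> MarkerPanel:
    """The bundled 78-feature targeted panel.

    Only the nine significant markers are attributed (m/z, composition,
    name); the remaining 69 rows are synthetic placeholder m/z values
    standing in for the unpublished remainder of the reference panel, as
    documented in the asset file.
    """
    return load_panel(_asset("panel78_synthetic.csv"), provenance="panel78_synthetic")


@dataclass
class MatchTable:
    """Per-marker nearest matrix column within tolerance (or none)."""

    panel: MarkerPanel
    column: list[Optional[int]]
    delta_mz: list[Optional[float]]
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def n_detected(self) -> int:
        return sum(c is not None for c in self.column)

    def detected_columns(self) -> list[int]:
        return [c for c in self.column if c is not None]

    def detected_markers(self) -> list[MarkerDefinition]:
        return [m for m, c in zip(self.panel.markers, self.column) if c is not None]


def match_markers(
    matrix: IntensityMatrix,
    panel: MarkerPanel,
    tolerance: float = DEFAULT_TOLERANCE,
) -> MatchTable:
    """Match each panel marker to the nearest matrix column within tolerance."""
    if matrix.feature_mz.size == 0:
        raise ValueError("matrix has no feature columns")
    cols: list[Optional[int]] = []
    deltas: list[Optional[float]] = []
    feat = matrix.feature_mz
    for marker in panel.markers:
        i = int(np.argmin(np.abs(feat - marker.mz)))
        d = float(feat[i] - marker.mz)
        if abs(d) <= tolerance:
            cols.append(i)
            deltas.append(d)
        else:
            cols.append(None)
            deltas.append(None)
    return MatchTable(panel=panel, column=cols, delta_mz=deltas, tolerance=tolerance)


@dataclass
class PanelAudit:
    """Mass-consistency audit of formula-bearing panel entries."""

    n_checked: int
    n_pass: int
    deltas: dict[float, float] = field(default_factory=dict)  # printed mz -> Da deviation


def audit_panel_masses(
    panel: MarkerPanel, tolerance: float = DEFAULT_TOLERANCE, charge: int = 1
) -> PanelAudit:
    """Check each formula-bearing marker's printed m/z against the computed
    cation monoisotopic mass; pass iff |computed - printed| <= tolerance."""
    deltas: dict[float, float] = {}
    n_pass = 0
    for marker in panel.markers:
        if not marker.formula:
            continue
        delta = monoisotopic_mass(marker.formula, charge=charge) - marker.mz
        deltas[marker.mz] = delta
        if abs(delta) <= tolerance:
            n_pass += 1
    return PanelAudit(n_checked=len(deltas), n_pass=n_pass, deltas=deltas)
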