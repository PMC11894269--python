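"""The 26 cusp-tip reference points and their CSV serialization.

The landmark scheme covers the canine-to-second-molar span of one dental
arch: per side, one canine tip, four premolar cusps (two buccal, two
lingual) and eight molar cusps (four in the buccal row, four in the
lingual row), for 13 points per side and 26 in total.  Labels are the
opaque codes ``Pt1`` .. ``Pt26``; coordinates are millimetres in an
arbitrary right-handed Cartesian frame (everything downstream is
invariant to rigid motion of that frame).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LandmarkLabel",
    "LandmarkSet",
    "ValidationReport",
    "LABELS",
    "LABEL_TABLE",
    "read_landmarks",
    "write_landmarks",
    "validate_for_fitting",
    "LandmarkError",
    "LandmarkParseError",
    "LandmarkValidationError",
]

CSV_HEADER = ["label", "x_mm", "y_mm", "z_mm"]

#: Minimum point count that determines a sphere.
MIN_FIT_POINTS = 4

#: Thickness ratio below which a configuration is treated as coplanar.
COPLANARITY_TOL = 1e-6


class LandmarkError(Exception):
    """Base class for landmark I/O and validation failures."""


class LandmarkParseError(LandmarkError):
    """A landmark CSV row could not be parsed."""


class LandmarkValidationError(LandmarkError):
    """A landmark set violates the 26-point scheme."""


@dataclass(frozen=True)
class LandmarkLabel:
    """One entry of the 26-point scheme.

    Attributes
    ----------
    code : str
        ``Pt1`` .. ``Pt26``.
    tooth : str
        ``canine``, ``premolar`` or ``molar``.
    cusp : str
        Cusp role: ``cusp tip`` for the canine, ``buccal`` / ``lingual``
        for premolars, and the four molar corner roles
        (``mesio-buccal``, ``disto-buccal``, ``mesio-lingual``,
        ``disto-lingual``).
    side : str
        ``right`` or ``left`` arch side.
    """

    code: str
    tooth: str
    cusp: str
    side: str


def _side_labels(side: str, start: int) -> list[LandmarkLabel]:
    # Anterior-to-posterior order: canine, PM1, PM2, M1, M2.
    roles = [
        ("canine", "cusp tip"),
        ("premolar", "buccal"),
        ("premolar", "lingual"),
        ("premolar", "buccal"),
        ("premolar", "lingual"),
        ("molar", "mesio-buccal"),
        ("molar", "mesio-lingual"),
        ("molar", "disto-buccal"),
        ("molar", "disto-lingual"),
        ("molar", "mesio-buccal"),
        ("molar", "mesio-lingual"),
        ("molar", "disto-buccal"),
        ("molar", "disto-lingual"),
    ]
    return [
        LandmarkLabel(code=f"Pt{start + i}", tooth=t, cusp=c, side=side)
        for i, (t, c) in enumerate(roles)
    ]


#: The closed label table: Pt1..Pt13 right side, Pt14..Pt26 left side.
LABELS: tuple[LandmarkLabel, ...] = tuple(
    _side_labels("right", 1) + _side_labels("left", 14)
)
LABEL_TABLE: dict[str, LandmarkLabel] = {lab.code: lab for lab in LABELS}
LABEL_CODES: tuple[str, ...] = tuple(lab.code for lab in LABELS)


@dataclass
class LandmarkSet:
    """Labeled cusp-tip coordinates for one dentition, in millimetres."""

    subject_id: str
    points: dict[str, tuple[float, float, float]]
    units: str = "mm"
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for code, xyz in self.points.items():
            if code not in LABEL_TABLE:
                raise LandmarkValidationError(f"unknown landmark code {code!r}")
            if not all(math.isfinite(v) for v in xyz):
                raise LandmarkValidationError(
                    f"non-finite coordinate for {code}: {xyz}"
                )

    @property
    def is_complete(self) -> bool:
        return len(self.points) == len(LABELS)

    def coordinates(self) -> np.ndarray:
        """Points as an (n, 3) array in Pt1..Pt26 order."""
        return np.array(
            [self.points[c] for c in LABEL_CODES if c in self.points], float
        )

    def labels_present(self) -> list[str]:
        return [c for c in LABEL_CODES if c in self.points]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_for_fitting`."""

    missing_labels: tuple[str, ...]
    duplicate_labels: tuple[str, ...]
    n_points: int
    coplanar: bool
    thickness_ratio: float
    fit_ready: bool
    reasons: tuple[str, ...] = ()


def read_landmarks(path: str | Path, strict: bool = True) -> LandmarkSet:
    """Read a landmark CSV (header ``label,x_mm,y_mm,z_mm``).

    Lines starting with ``#`` are ignored.  With ``strict`` on, missing
    or duplicated labels raise :class:`LandmarkValidationError`; with it
    off, missing labels are recorded on the returned set and the first
    occurrence of a duplicate wins.
    """
    path = Path(path)
    points: dict[str, tuple[float, float, float]] = {}
    duplicates: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        header_seen = False
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if not header_seen:
                if [c.strip() for c in row] != CSV_HEADER:
                    raise LandmarkParseError(
                        f"{path}:{lineno}: expected header "
                        f"{','.join(CSV_HEADER)!r}, got {','.join(row)!r}"
                    )
                header_seen = True
                continue
            if len(row) != 4:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}"
                )
            code = row[0].strip()
            if code not in LABEL_TABLE:
                raise LandmarkParseError(
                    f"{path}:{lineno}: unknown landmark code {code!r}"
                )
            try:
                xyz = tuple(float(v) for v in row[1:4])
            except ValueError as exc:
                raise LandmarkParseError(
                    f"{path}:{lineno}: non-numeric coordinate ({exc})"
                ) from None
            if not all(math.isfinite(v) for v in xyz):
                raise LandmarkParseError(
                    f"{path}:{lineno}: non-finite coordinate for {code}"
                )
            if code in points:
                duplicates.append(code)
                continue
            points[code] = xyz  # type: ignore[assignment]
    missing = tuple(c for c in LABEL_CODES if c not in points)
    if strict:
        problems = []
        if duplicates:
            problems.append(f"duplicate labels: {', '.join(sorted(set(duplicates)))}")
        if missing:
            problems.append(f"missing labels: {', '.join(missing)}")
        if problems:
            raise LandmarkValidationError(f"{path}: " + "; ".join(problems))
    return LandmarkSet(subject_id=path.stem, points=points, missing=missing)


def write_landmarks(lms: LandmarkSet, path: str | Path) -> Path:
    """Write a landmark set as CSV, labels in Pt1..Pt26 order."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for code in LABEL_CODES:
            if code in lms.points:
                x, y, z = lms.points[code]
                writer.writerow([code, repr(x), repr(y), repr(z)])
    return path


def _thickness_ratio(pts: np.ndarray) -> float:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0.0:
        return 0.0
    return float(s[-1] / s[0])


def validate_for_fitting(lms: LandmarkSet) -> ValidationReport:
    """Check whether a landmark set determines a sphere.

    Fit-ready means at least four points that are not all coplanar
    (thickness ratio above ``COPLANARITY_TOL``).
    """
    present = set(lms.labels_present())
    missing = tuple(c for c in LABEL_CODES if c not in present)
    n = len(lms.points)
    reasons: list[str] = []
    coplanar = False
    thickness = 0.0
    if n < MIN_FIT_POINTS:
        reasons.append("insufficient points")
    else:
        thickness = _thickness_ratio(lms.coordinates())
        coplanar = thickness < COPLANARITY_TOL
        if coplanar:
            reasons.append("coplanar")
    return ValidationReport(
        missing_labels=missing,
        duplicate_labels=(),
        n_points=n,
        coplanar=coplanar,
        thickness_ratio=thickness,
        fit_ready=not reasons,
        reasons=tuple(reasons),
    )


def from_array(
    coords: Iterable[Iterable[float]],
    subject_id: str = "anon",
    codes: Iterable[str] | None = None,
) -> LandmarkSet:
    """Build a LandmarkSet from an (n, 3) array, defaulting to Pt1..Ptn."""
    arr = np.asarray(list(coords), float)
    if codes is None:
        codes = LABEL_CODES[: len(arr)]
    points = {c: tuple(map(float, p)) for c, p in zip(codes, arr, strict=True)}
    missing = tuple(c for c in LABEL_CODES if c not in points)
    return LandmarkSet(subject_id=subject_id, points=points, missing=missing)
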