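"""Data model and I/O for assigned 2D 1H-15N peak lists and titration series.

A :class:`Peak` is one assigned amide cross-peak (backbone or Gln/Asn
side-chain amide) under one sample condition.  Slow-exchange conformers
(e.g. the native-like and alternate states of S65-phosphorylated
ubiquitin) give separate peaks for the same residue and are distinguished
by a :class:`Conformer` label, encoded in assignment strings by a trailing
``*`` (alternate) or ``+`` ("additional" dimer signals) on the residue
part, e.g. ``K63*N-H``.

A :class:`PeakList` collects the peaks of one spectrum; a
:class:`TitrationSeries` orders peak lists along one varying condition
(pH, temperature or ligand concentration) and supports peak tracking and
the residue-exclusion rules used before population/pKa analysis.
"""

from __future__ import annotations

import csv as _csv
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "Site",
    "Conformer",
    "Condition",
    "Peak",
    "PeakList",
    "TitrationSeries",
    "Trajectory",
    "TrajectoryPoint",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
    "track_peaks",
    "filter_residues",
    "combined_shift_distance",
]

AMIDE_H_RANGE = (5.0, 12.0)   # ppm, plausible amide 1H window
AMIDE_N_RANGE = (100.0, 135.0)  # ppm, plausible amide 15N window

#: default overlap radii (typical amide linewidths at 600 MHz)
OVERLAP_RADIUS_H = 0.03   # ppm 1H
OVERLAP_RADIUS_N = 0.15   # ppm 15N


class PeakListError(ValueError):
    """Malformed peak-list input or inconsistent peak data."""


class Site(str, Enum):
    """Which N-H pair of the residue the cross-peak belongs to."""

    BACKBONE = "backbone-amide"
    SIDECHAIN_E21 = "sidechain-amide-e21"
    SIDECHAIN_E22 = "sidechain-amide-e22"
    OTHER = "other"


class Conformer(str, Enum):
    """Slow-exchange conformer label of a signal."""

    NAT = "nat"
    ALT = "alt"
    ADDITIONAL = "additional"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class Condition:
    """Sample condition of one spectrum.

    Temperature in kelvin, concentrations in molar.  Unset fields mean
    "not applicable / not recorded".
    """

    pH: float | None = None
    temperature: float | None = None
    ligand_total: float | None = None
    protein_total: float | None = None
    buffer: str = ""

    def __post_init__(self) -> None:
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        for name in ("ligand_total", "protein_total"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def value_of(self, varying: str) -> float:
        v = {"pH": self.pH, "temperature": self.temperature, "ligand": self.ligand_total}[varying]
        if v is None:
            raise ValueError(f"condition lacks the varying field {varying!r}")
        return v


@dataclass(frozen=True)
class Peak:
    """One assigned amide cross-peak."""

    residue_index: int
    residue_name: str = ""
    site: Site = Site.BACKBONE
    conformer: Conformer = Conformer.UNSPECIFIED
    shift_H: float = 0.0  # ppm
    shift_N: float = 0.0  # ppm
    intensity: float = 0.0  # arbitrary units, >= 0

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.site is not Site.OTHER:
            if not (AMIDE_H_RANGE[0] <= self.shift_H <= AMIDE_H_RANGE[1]) or not (
                AMIDE_N_RANGE[0] <= self.shift_N <= AMIDE_N_RANGE[1]
            ):
                warnings.warn(
                    f"peak {self.key} at ({self.shift_H:.3f}, {self.shift_N:.3f}) ppm "
                    "is outside the typical amide region",
                    stacklevel=2,
                )

    @property
    def key(self) -> tuple[int, Site, Conformer]:
        return (self.residue_index, self.site, self.conformer)

    @property
    def assignment(self) -> str:
        """Sparky-style assignment string, e.g. ``K63*N-H``."""
        suffix = {Conformer.ALT: "*", Conformer.ADDITIONAL: "+"}.get(self.conformer, "")
        atoms = {
            Site.BACKBONE: "N-H",
            Site.SIDECHAIN_E21: "NE2-HE21",
            Site.SIDECHAIN_E22: "NE2-HE22",
            Site.OTHER: "N-H",
        }[self.site]
        return f"{self.residue_name}{self.residue_index}{suffix}{atoms}"


# residue name (letters), index, conformer suffix, 15N atom, 1H atom
_ASSIGNMENT_RE = re.compile(
    r"^(?P<name>[A-Za-z]{0,3})(?P<index>\d+)(?P<suffix>[*+]?)"
    r"(?P<natom>N(?:E2|D2)?)-(?P<hatom>H(?:E21|E22|D21|D22)?)$"
)


def parse_assignment(text: str) -> tuple[int, str, Site, Conformer]:
    """Parse an assignment string like ``Q62N-H`` or ``K63*N-H``.

    Returns (residue_index, residue_name, site, conformer).
    """
    m = _ASSIGNMENT_RE.match(text.strip())
    if m is None:
        raise PeakListError(f"cannot parse assignment string {text!r}")
    index = int(m.group("index"))
    name = m.group("name")
    conformer = {"*": Conformer.ALT, "+": Conformer.ADDITIONAL, "": Conformer.NAT}[m.group("suffix")]
    natom, hatom = m.group("natom"), m.group("hatom")
    if natom == "N" and hatom == "H":
        site = Site.BACKBONE
    elif hatom in ("HE21", "HD21"):
        site = Site.SIDECHAIN_E21
    elif hatom in ("HE22", "HD22"):
        site = Site.SIDECHAIN_E22
    else:
        site = Site.OTHER
    return index, name, site, conformer


@dataclass
class PeakList:
    """The peaks of one spectrum, all sharing one :class:`Condition`."""

    peaks: list[Peak]
    condition: Condition = field(default_factory=Condition)
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[int, Site, Conformer]] = set()
        for p in self.peaks:
            if p.key in seen:
                raise PeakListError(
                    f"duplicate peak key {p.key} in peak list {self.label!r}"
                )
            seen.add(p.key)
        if not self.peaks:
            warnings.warn(f"peak list {self.label!r} is empty", stacklevel=2)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def get(self, residue_index: int, site: Site = Site.BACKBONE,
            conformer: Conformer = Conformer.NAT) -> Peak | None:
        for p in self.peaks:
            if p.key == (residue_index, site, conformer):
                return p
        return None

    @property
    def residues(self) -> set[int]:
        return {p.residue_index for p in self.peaks}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_index": [p.residue_index for p in self.peaks],
                "residue_name": [p.residue_name for p in self.peaks],
                "site": [p.site.value for p in self.peaks],
                "conformer": [p.conformer.value for p in self.peaks],
                "shift_H_ppm": [p.shift_H for p in self.peaks],
                "shift_N_ppm": [p.shift_N for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
            }
        )


@dataclass
class TitrationSeries:
    """Ordered peak lists along one varying condition.

    ``varying`` is one of ``"pH"``, ``"temperature"``, ``"ligand"``; the
    varying field must change strictly monotonically across points while
    the other condition fields stay constant (within tolerance).
    ``reference_index`` marks the point used as the reference state
    (default: the first).
    """

    points: list[PeakList]
    varying: str
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.varying not in ("pH", "temperature", "ligand"):
            raise ValueError(f"unknown varying condition {self.varying!r}")
        if not self.points:
            raise ValueError("series needs at least one point")
        vals = self.values
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError(
                f"varying condition {self.varying!r} is not strictly monotone: {vals}"
            )
        if not (0 <= self.reference_index < len(self.points)):
            raise ValueError("reference_index out of range")

    @property
    def values(self) -> list[float]:
        return [pl.condition.value_of(self.varying) for pl in self.points]

    @property
    def reference(self) -> PeakList:
        return self.points[self.reference_index]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[PeakList]:
        return iter(self.points)


def combined_shift_distance(dH: float, dN: float, scale_N: float = 5.0) -> float:
    """Combined 1H/15N shift distance sqrt(dH^2 + (dN/scale_N)^2) in ppm."""
    return math.hypot(dH, dN / scale_N)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peaklist(path: str | Path, format: str = "sparky",
                  condition: Condition | None = None, label: str = "") -> PeakList:
    """Read an assigned peak list.

    Formats:

    ``sparky``
        Whitespace-separated ``Assignment  w1(15N ppm)  w2(1H ppm)  Data Height``,
        with an optional header line.
    ``csv``
        Columns ``residue_index,residue_name,site,conformer,shift_H_ppm,
        shift_N_ppm,intensity``; ``#``-prefixed header lines may carry the
        condition (``# pH = 6.8`` etc.) and override ``condition`` fields.
    """
    path = Path(path)
    if format == "sparky":
        return _read_sparky(path, condition or Condition(), label or path.stem)
    if format == "csv":
        return _read_csv(path, condition, label or path.stem)
    raise ValueError(f"unknown peak-list format {format!r}")


def _read_sparky(path: Path, condition: Condition, label: str) -> PeakList:
    peaks: list[Peak] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise PeakListError(f"{path}:{lineno}: malformed row {raw!r}")
        try:
            index, name, site, conformer = parse_assignment(parts[0])
            w1 = float(parts[1])  # 15N
            w2 = float(parts[2])  # 1H
            height = float(parts[3]) if len(parts) > 3 else 0.0
        except (ValueError, PeakListError) as exc:
            raise PeakListError(f"{path}:{lineno}: malformed row {raw!r}: {exc}") from None
        peaks.append(Peak(index, name, site, conformer, shift_H=w2, shift_N=w1,
                          intensity=height))
    return PeakList(peaks, condition, label)


_CONDITION_KEYS = {
    "ph": "pH",
    "temperature": "temperature",
    "temperature_k": "temperature",
    "ligand_total": "ligand_total",
    "ligand_total_m": "ligand_total",
    "protein_total": "protein_total",
    "protein_total_m": "protein_total",
    "buffer": "buffer",
}


def _read_csv(path: Path, condition: Condition | None, label: str) -> PeakList:
    cond_fields: dict[str, object] = {}
    rows: list[str] = []
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            m = re.match(r"#\s*([\w]+)\s*[=:]\s*(.+)", raw)
            if m and m.group(1).lower() in _CONDITION_KEYS:
                key = _CONDITION_KEYS[m.group(1).lower()]
                val = m.group(2).strip()
                cond_fields[key] = val if key == "buffer" else float(val)
        elif raw.strip():
            rows.append(raw)
    if condition is None:
        condition = Condition(**cond_fields)  # type: ignore[arg-type]
    elif cond_fields:
        condition = replace(condition, **cond_fields)  # type: ignore[arg-type]
    peaks: list[Peak] = []
    reader = _csv.DictReader(rows)
    for lineno, row in enumerate(reader, start=2):
        try:
            peaks.append(
                Peak(
                    residue_index=int(row["residue_index"]),
                    residue_name=row.get("residue_name", "") or "",
                    site=Site(row.get("site", Site.BACKBONE.value)),
                    conformer=Conformer(row.get("conformer", Conformer.UNSPECIFIED.value)),
                    shift_H=float(row["shift_H_ppm"]),
                    shift_N=float(row["shift_N_ppm"]),
                    intensity=float(row["intensity"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise PeakListError(f"{path}: data row {lineno}: {exc}") from None
    return PeakList(peaks, condition, label)


def write_peaklist(peaklist: PeakList, path: str | Path, format: str = "csv") -> None:
    """Write a peak list; the CSV dialect round-trips all fields."""
    path = Path(path)
    if format == "sparky":
        lines = ["      Assignment         w1         w2   Data Height"]
        for p in peaklist:
            lines.append(f"{p.assignment:>16s} {p.shift_N:10.3f} {p.shift_H:10.3f} {p.intensity:13.6g}")
        path.write_text("\n".join(lines) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown peak-list format {format!r}")
    cond = peaklist.condition
    header = []
    if cond.pH is not None:
        header.append(f"# pH = {float(cond.pH)!r}")
    if cond.temperature is not None:
        header.append(f"# temperature_K = {float(cond.temperature)!r}")
    if cond.ligand_total is not None:
        header.append(f"# ligand_total_M = {float(cond.ligand_total)!r}")
    if cond.protein_total is not None:
        header.append(f"# protein_total_M = {float(cond.protein_total)!r}")
    if cond.buffer:
        header.append(f"# buffer = {cond.buffer}")
    lines = header + ["residue_index,residue_name,site,conformer,shift_H_ppm,shift_N_ppm,intensity"]
    for p in peaklist:
        lines.append(
            f"{p.residue_index},{p.residue_name},{p.site.value},{p.conformer.value},"
            f"{float(p.shift_H)!r},{float(p.shift_N)!r},{float(p.intensity)!r}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Peak tracking across a titration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryPoint:
    condition_value: float
    shift_H: float
    shift_N: float
    intensity: float


@dataclass
class Trajectory:
    """Ordered path of one signal along the varying condition.

    ``complete`` is False when the signal was lost or its link was
    ambiguous somewhere along the series; ``ambiguous_at`` lists the
    condition values where two candidate peaks were too close to call.
    """

    key: tuple[int, Site, Conformer]
    points: list[TrajectoryPoint]
    complete: bool = True
    ambiguous_at: list[float] = field(default_factory=list)

    @property
    def residue_index(self) -> int:
        return self.key[0]

    def point_at(self, value: float, atol: float = 1e-9) -> TrajectoryPoint:
        best = min(self.points, key=lambda p: abs(p.condition_value - value))
        return best


def track_peaks(series: TitrationSeries, max_jump: float = 0.05,
                scale_N: float = 5.0,
                ambiguity_ratio: float = 0.10,
                by_assignment: bool = True) -> dict[tuple[int, Site, Conformer], Trajectory]:
    """Link peaks across adjacent titration points into trajectories.

    Starting from each peak of the first point, the nearest peak of the
    next point in the combined-shift metric is linked, refusing links
    farther than ``max_jump`` (ppm).  A link is flagged ambiguous — not
    guessed — when the two nearest candidates are within
    ``ambiguity_ratio`` of each other's distance.

    With ``by_assignment`` (the default for assigned peak lists) the
    candidate set at each step is restricted to peaks carrying the same
    (residue, site, conformer) assignment, and the distance metric only
    validates the link; set it to False for pure nearest-neighbour
    tracking of effectively unassigned data, which cannot distinguish
    crossing peaks.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    values = series.values
    trajectories: dict[tuple[int, Site, Conformer], Trajectory] = {}
    for peak in series.points[0]:
        tp = TrajectoryPoint(values[0], peak.shift_H, peak.shift_N, peak.intensity)
        trajectories[peak.key] = Trajectory(peak.key, [tp])

    current: dict[tuple[int, Site, Conformer], Peak] = {p.key: p for p in series.points[0]}
    for i, peaklist in enumerate(series.points[1:], start=1):
        nxt: dict[tuple[int, Site, Conformer], Peak] = {}
        all_candidates = list(peaklist)
        by_key = {p.key: p for p in peaklist}
        for key, prev in current.items():
            traj = trajectories[key]
            if by_assignment:
                candidates = [by_key[key]] if key in by_key else []
            else:
                candidates = all_candidates
            if not candidates:
                traj.complete = False
                continue
            dists = sorted(
                ((combined_shift_distance(c.shift_H - prev.shift_H,
                                          c.shift_N - prev.shift_N, scale_N), c)
                 for c in candidates),
                key=lambda t: t[0],
            )
            d1, best = dists[0]
            if d1 > max_jump:
                traj.complete = False
                continue
            if len(dists) > 1:
                d2 = dists[1][0]
                if d2 <= d1 * (1.0 + ambiguity_ratio):
                    traj.complete = False
                    traj.ambiguous_at.append(values[i])
                    continue
            traj.points.append(
                TrajectoryPoint(values[i], best.shift_H, best.shift_N, best.intensity)
            )
            nxt[key] = best
        current = nxt
    return trajectories


# ---------------------------------------------------------------------------
# Residue-selection rules
# ---------------------------------------------------------------------------

def filter_residues(
    series: TitrationSeries,
    require_alt: bool = False,
    overlap_radius_H: float = OVERLAP_RADIUS_H,
    overlap_radius_N: float = OVERLAP_RADIUS_N,
    max_jump: float = 0.05,
    scale_N: float = 5.0,
) -> tuple[set[int], dict[int, str]]:
    """Apply the residue-exclusion rules used before population analysis.

    Residues are excluded when (1) any of their peaks overlaps another
    peak within the elliptical overlap radius at any titration point,
    (2) their trajectory is broken — the signal was lost by attenuation
    or its migration was ambiguous, or (3) with ``require_alt``, they
    show no alternate-conformer signal.

    Returns (retained residue indices, {excluded residue: reason}).
    """
    excluded: dict[int, str] = {}

    # rule 1: pairwise overlap at any point
    for peaklist in series:
        peaks = peaklist.peaks
        for i, a in enumerate(peaks):
            for b in peaks[i + 1:]:
                if a.key == b.key:
                    continue
                e = math.hypot((a.shift_H - b.shift_H) / overlap_radius_H,
                               (a.shift_N - b.shift_N) / overlap_radius_N)
                if e < 1.0:
                    for r in (a.residue_index, b.residue_index):
                        excluded.setdefault(r, "overlap")

    # rule 2: broken or ambiguous trajectories
    trajectories = track_peaks(series, max_jump=max_jump, scale_N=scale_N)
    n_points = len(series)
    for traj in trajectories.values():
        if not traj.complete or len(traj.points) < n_points:
            reason = "ambiguous-migration" if traj.ambiguous_at else "lost-signal"
            excluded.setdefault(traj.residue_index, reason)

    # rule 3: alternate-conformer signal required
    all_residues = set().union(*(pl.residues for pl in series))
    if require_alt:
        with_alt = {
            p.residue_index for pl in series for p in pl if p.conformer is Conformer.ALT
        }
        for r in sorted(all_residues - with_alt):
            excluded.setdefault(r, "no-alt-signal")

    retained = all_residues - excluded.keys()
    if not retained:
        warnings.warn("all residues excluded by the selection rules", stacklevel=2)
    return retained, excluded
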