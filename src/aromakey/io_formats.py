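"""Data model and tabular I/O for the aroma analysis pipeline.

Five kinds of plain-text tables flow through the pipeline, all UTF-8 CSV
with a header row:

* peak tables — one chromatographic peak per row (sample, replicate,
  retention time, detector area);
* a compound library — names, chemical classes, reference retention
  indices, odor thresholds in water (µg/kg) and odor descriptors;
* an n-alkane ladder — (carbon number, retention time) calibration points;
* GC-O event logs — panelist odor detections with 1–5 intensities;
* sensory score sheets — trained-panel QDA scores (1–5) on six attributes.

Compound names are matched case-insensitively after whitespace
normalization; the library may carry an ``aliases`` column (``;``-separated
synonyms) so that spelling variants such as "tetramethylpyrazine" and
"2,3,5,6-tetramethylpyrazine" resolve to one entry.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

log = logging.getLogger("aromakey")

CHEM_CLASSES = frozenset({
    "pyrazine", "ketone", "acid", "alcohol", "aldehyde", "phenol",
    "ester", "furan", "oxazole", "sulfide", "other",
})

SENSORY_ATTRIBUTES = (
    "soy_sauce_like", "roasted", "smoky", "sweet", "buttery", "grain",
)


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


def normalize_name(name: str) -> str:
    """Canonical form used for all compound-name comparisons."""
    return re.sub(r"\s+", " ", str(name).strip()).lower()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundLibraryEntry:
    name: str
    chem_class: str
    ref_ri: Optional[float] = None
    odor_threshold: Optional[float] = None  # µg/kg in water
    odor_descriptor: str = ""
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"unknown chemical class {self.chem_class!r} for {self.name!r}")
        if self.odor_threshold is not None and not self.odor_threshold > 0:
            raise ValidationError(
                f"odor threshold must be > 0 for {self.name!r}, "
                f"got {self.odor_threshold}")


@dataclass(frozen=True)
class PeakRecord:
    sample_id: str
    replicate: int
    peak_id: str
    retention_time: float  # minutes
    area: float            # arbitrary detector counts
    assigned_compound: Optional[str] = None

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.retention_time < 0:
            raise ValidationError(
                f"retention time must be >= 0, got {self.retention_time}")
        if self.area < 0:
            raise ValidationError(f"area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class AlkaneLadder:
    """Ordered (carbon number, retention time) pairs, e.g. C7–C30."""
    entries: tuple[tuple[int, float], ...]

    def __post_init__(self):
        if len(self.entries) < 2:
            raise ValidationError("alkane ladder needs at least 2 entries")
        carbons = [c for c, _ in self.entries]
        rts = [t for _, t in self.entries]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValidationError("ladder carbon numbers must strictly increase")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError("ladder retention times must strictly increase")

    @property
    def carbons(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def retention_times(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.entries)


@dataclass(frozen=True)
class InternalStandardSpec:
    """The known spike against which analyte areas are ratioed.

    Defaults are the sec-octanol spike used throughout: 5 µL of a
    180 µg/mL solution into a 3 g sample.
    """
    compound_name: str = "sec-octanol"
    Cs: float = 180.0   # µg/mL
    Vs: float = 0.005   # mL
    mx: float = 3.0     # g

    def __post_init__(self):
        for f in ("Cs", "Vs", "mx"):
            if not getattr(self, f) > 0:
                raise ValidationError(f"{f} must be > 0")


@dataclass(frozen=True)
class GCOEvent:
    sample_id: str
    replicate: int
    panelist: str
    compound_or_rt: str  # library name, or a retention time as text
    intensity: int       # 1..5
    descriptor: str = ""

    def __post_init__(self):
        if self.intensity not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"GC-O intensity must be in 1..5, got {self.intensity}")


@dataclass(frozen=True)
class SensoryScore:
    sample_id: str
    panelist: str
    session: int
    attribute: str
    score: int  # 1..5

    def __post_init__(self):
        if self.attribute not in SENSORY_ATTRIBUTES:
            raise ValidationError(f"unknown sensory attribute {self.attribute!r}")
        if self.score not in (1, 2, 3, 4, 5):
            raise ValidationError(f"score must be in 1..5, got {self.score}")
        if self.session < 1:
            raise ValidationError("session must be >= 1")


@dataclass
class AnalysisConfig:
    """Tunable thresholds for the whole pipeline.

    The screening thresholds mirror the study conventions: rOAV >= 1
    (inclusive) marks a perceptible contributor, a GC-O compound counts
    once at least two of three panelists log it, RI matches are accepted
    within 15 index units, and supervised models are validated with
    7-fold cross-validation and 200 permutations at alpha 0.05.
    """
    roav_threshold: float = 1.0
    gco_min_panelists: int = 2
    ri_match_tolerance: float = 15.0
    cv_folds: int = 7
    n_permutations: int = 200
    n_orth_components: int | str = "auto"
    scaling: str = "unit_variance"
    alpha: float = 0.05
    random_seed: int = 0

    def __post_init__(self):
        if self.roav_threshold <= 0 or self.ri_match_tolerance <= 0:
            raise ValidationError("thresholds must be positive")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.scaling not in ("unit_variance", "pareto", "center_only"):
            raise ValidationError(f"unknown scaling {self.scaling!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _optional(value: str) -> Optional[str]:
    return value if value not in ("", "NA", "nan") else None


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Parse a peak table CSV; every bad row raises with its line number."""
    df = _read_csv(path)
    _require_columns(
        df, ["sample_id", "replicate", "peak_id", "retention_time", "area"],
        "peak table")
    records: list[PeakRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = PeakRecord(
                sample_id=row.sample_id,
                replicate=int(row.replicate),
                peak_id=row.peak_id,
                retention_time=float(row.retention_time),
                area=float(row.area),
                assigned_compound=_optional(getattr(row, "assigned_compound", "")),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"peak table line {i}: {exc}") from exc
        key = (rec.sample_id, rec.replicate, rec.peak_id)
        if key in seen:
            raise ValidationError(
                f"peak table line {i}: duplicate (sample, replicate, peak) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=[
        "sample_id", "replicate", "peak_id", "retention_time", "area",
        "assigned_compound"])
    df["assigned_compound"] = df["assigned_compound"].fillna("")
    df.to_csv(path, index=False)


def read_library(path: str | Path) -> list[CompoundLibraryEntry]:
    df = _read_csv(path)
    _require_columns(df, ["name", "chem_class"], "compound library")
    entries: list[CompoundLibraryEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ref_ri = _optional(getattr(row, "ref_ri", ""))
            ot = _optional(getattr(row, "odor_threshold", ""))
            aliases_raw = _optional(getattr(row, "aliases", "")) or ""
            entry = CompoundLibraryEntry(
                name=row.name,
                chem_class=row.chem_class,
                ref_ri=float(ref_ri) if ref_ri is not None else None,
                odor_threshold=float(ot) if ot is not None else None,
                odor_descriptor=getattr(row, "odor_descriptor", ""),
                aliases=tuple(a.strip() for a in aliases_raw.split(";") if a.strip()),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"library line {i}: {exc}") from exc
        key = normalize_name(entry.name)
        if key in seen:
            raise ValidationError(f"library line {i}: duplicate name {entry.name!r}")
        seen.add(key)
        entries.append(entry)
    return entries


def write_library(entries: Iterable[CompoundLibraryEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        d = dataclasses.asdict(e)
        d["aliases"] = ";".join(e.aliases)
        rows.append(d)
    df = pd.DataFrame(rows, columns=[
        "name", "chem_class", "ref_ri", "odor_threshold", "odor_descriptor",
        "aliases"])
    df.to_csv(path, index=False)


def library_index(entries: Sequence[CompoundLibraryEntry]) -> dict[str, CompoundLibraryEntry]:
    """Normalized name (and alias) -> entry lookup."""
    idx: dict[str, CompoundLibraryEntry] = {}
    for e in entries:
        for key in (e.name, *e.aliases):
            idx[normalize_name(key)] = e
    return idx


def read_ladder(path: str | Path) -> AlkaneLadder:
    df = _read_csv(path)
    _require_columns(df, ["carbon_number", "retention_time"], "alkane ladder")
    try:
        entries = tuple(
            (int(r.carbon_number), float(r.retention_time))
            for r in df.itertuples(index=False))
    except ValueError as exc:
        raise ValidationError(f"alkane ladder: {exc}") from exc
    return AlkaneLadder(entries=entries)


def write_ladder(ladder: AlkaneLadder, path: str | Path) -> None:
    pd.DataFrame(ladder.entries,
                 columns=["carbon_number", "retention_time"]).to_csv(path, index=False)


def read_gco(path: str | Path) -> list[GCOEvent]:
    df = _read_csv(path)
    _require_columns(
        df, ["sample_id", "replicate", "panelist", "compound_or_rt", "intensity"],
        "GC-O log")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            events.append(GCOEvent(
                sample_id=row.sample_id,
                replicate=int(row.replicate),
                panelist=row.panelist,
                compound_or_rt=row.compound_or_rt,
                intensity=int(row.intensity),
                descriptor=getattr(row, "descriptor", ""),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"GC-O log line {i}: {exc}") from exc
    return events


def write_gco(events: Iterable[GCOEvent], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in events], columns=[
        "sample_id", "replicate", "panelist", "compound_or_rt", "intensity",
        "descriptor"]).to_csv(path, index=False)


def read_sensory(path: str | Path) -> list[SensoryScore]:
    df = _read_csv(path)
    _require_columns(
        df, ["sample_id", "panelist", "session", "attribute", "score"],
        "sensory sheet")
    scores = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            scores.append(SensoryScore(
                sample_id=row.sample_id,
                panelist=row.panelist,
                session=int(row.session),
                attribute=row.attribute,
                score=int(row.score),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"sensory sheet line {i}: {exc}") from exc
    return scores


def write_sensory(scores: Iterable[SensoryScore], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in scores], columns=[
        "sample_id", "panelist", "session", "attribute", "score"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# cross-table validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only cross-reference check; an empty report means consistent."""
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "bundle consistent"


def validate_bundle(
    peaks: Sequence[PeakRecord],
    library: Sequence[CompoundLibraryEntry],
    ladder: AlkaneLadder,
    is_spec: InternalStandardSpec,
    gco: Sequence[GCOEvent] = (),
    sensory: Sequence[SensoryScore] = (),
) -> ValidationReport:
    """Cross-reference all tables without mutating any of them."""
    report = ValidationReport()
    idx = library_index(library)

    for p in peaks:
        if p.assigned_compound is not None:
            key = normalize_name(p.assigned_compound)
            if key not in idx and key != normalize_name(is_spec.compound_name):
                report.errors.append(
                    f"peak {p.peak_id} ({p.sample_id} rep {p.replicate}) assigned "
                    f"to {p.assigned_compound!r}, absent from library")

    for e in gco:
        name = e.compound_or_rt
        try:
            float(name)  # retention-time events resolve later via the ladder
        except ValueError:
            if normalize_name(name) not in idx:
                report.errors.append(
                    f"GC-O event by {e.panelist} names {name!r}, absent from library")

    peak_samples = {p.sample_id for p in peaks}
    sensory_samples = {s.sample_id for s in sensory}
    if sensory:
        for s in sorted(peak_samples - sensory_samples):
            report.warnings.append(f"sample {s} has peaks but no sensory scores")
        for s in sorted(sensory_samples - peak_samples):
            report.warnings.append(f"sample {s} has sensory scores but no peaks")

    lo, hi = ladder.retention_times[0], ladder.retention_times[-1]
    n_outside = sum(1 for p in peaks if not lo <= p.retention_time <= hi)
    if n_outside:
        report.warnings.append(
            f"{n_outside} peak(s) elute outside the alkane ladder span "
            f"[{lo}, {hi}] min; their retention indices will be extrapolated")
    return report
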