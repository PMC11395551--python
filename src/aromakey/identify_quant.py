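"""Retention-index identification, internal-standard quantitation and rOAV.

The chain implemented here turns raw peak tables into compound
concentrations and odor-activity values:

1. Retention indices are computed against an n-alkane ladder with the
   van den Dool–Kratz (temperature-programmed, piecewise-linear) formula
   ``RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))``.
2. Peaks are assigned to library compounds by nearest reference RI within
   a tolerance (deterministic tie-break by name).
3. Concentrations follow the internal-standard ratio
   ``Cx = Ax * Cs * Vs / (As * mx)`` in µg/g, where ``Ax``/``As`` are the
   analyte and internal-standard peak areas, ``Cs`` and ``Vs`` the spike
   concentration (µg/mL) and volume (mL), and ``mx`` the sample mass (g).
4. rOAV = Ci / OTi with Ci the replicate-mean concentration converted to
   µg/kg and OTi the odor threshold in water (µg/kg). Compounds without a
   threshold get an *undefined* (not zero) rOAV and are excluded from the
   rOAV screen, though GC-O can still rescue them downstream.

Concentrations are stored in µg/g and converted (×1000) to µg/kg where
class totals and thresholds are involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlkaneLadder,
    CompoundLibraryEntry,
    InternalStandardSpec,
    PeakRecord,
    ValidationError,
    library_index,
    log,
    normalize_name,
)

UG_PER_G_TO_UG_PER_KG = 1000.0


class QuantitationError(ValueError):
    """Internal-standard area missing or non-positive for a sample-replicate."""


@dataclass(frozen=True)
class RetentionIndexValue:
    value: float
    extrapolated: bool = False


@dataclass(frozen=True)
class QuantifiedCompound:
    sample_id: str
    replicate: int
    compound_name: str
    concentration: float  # µg/g
    Ax: float
    As: float
    peak_id: str = ""


def compute_retention_index(rt: float, ladder: AlkaneLadder) -> RetentionIndexValue:
    """Van den Dool–Kratz retention index of a retention time.

    Inside the ladder span the index is piecewise-linear between
    bracketing alkanes and equals 100×carbon number at each alkane's own
    retention time. Outside the span the nearest segment's slope is
    extended and the value is flagged ``extrapolated``.
    """
    carbons = np.asarray(ladder.carbons, dtype=float)
    rts = np.asarray(ladder.retention_times, dtype=float)

    extrapolated = not (rts[0] <= rt <= rts[-1])
    if extrapolated:
        log.warning("retention time %.3f min outside ladder span [%.3f, %.3f]; "
                    "extrapolating", rt, rts[0], rts[-1])
        seg = 0 if rt < rts[0] else len(rts) - 2
    else:
        seg = int(np.searchsorted(rts, rt, side="right")) - 1
        seg = min(max(seg, 0), len(rts) - 2)

    n0, n1 = carbons[seg], carbons[seg + 1]
    t0, t1 = rts[seg], rts[seg + 1]
    value = 100.0 * (n0 + (n1 - n0) * (rt - t0) / (t1 - t0))
    return RetentionIndexValue(value=float(value), extrapolated=extrapolated)


def invert_retention_index(ri: float, ladder: AlkaneLadder) -> float:
    """Retention time whose index equals ``ri`` (inverse of the linear form)."""
    carbons = np.asarray(ladder.carbons, dtype=float)
    rts = np.asarray(ladder.retention_times, dtype=float)
    ris = 100.0 * carbons
    if ri < ris[0]:
        seg = 0
    elif ri > ris[-1]:
        seg = len(ris) - 2
    else:
        seg = min(max(int(np.searchsorted(ris, ri, side="right")) - 1, 0),
                  len(ris) - 2)
    frac = (ri - ris[seg]) / (ris[seg + 1] - ris[seg])
    return float(rts[seg] + frac * (rts[seg + 1] - rts[seg]))


def match_library(
    ri: RetentionIndexValue | float,
    library: Sequence[CompoundLibraryEntry],
    tolerance: float = 15.0,
) -> list[tuple[CompoundLibraryEntry, float]]:
    """Library entries within ``tolerance`` RI units, closest first.

    Ties on |ΔRI| break lexicographically on the compound name so the
    ranking is deterministic regardless of library order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    value = ri.value if isinstance(ri, RetentionIndexValue) else float(ri)
    hits = [
        (e, abs(e.ref_ri - value))
        for e in library
        if e.ref_ri is not None and abs(e.ref_ri - value) <= tolerance
    ]
    hits.sort(key=lambda h: (h[1], normalize_name(h[0].name)))
    return hits


def quantify_peak(
    peak: PeakRecord,
    is_area: float,
    is_spec: InternalStandardSpec,
    compound_name: Optional[str] = None,
) -> QuantifiedCompound:
    """Apply the internal-standard ratio to one peak."""
    if is_area <= 0:
        raise QuantitationError(
            f"internal standard area must be > 0 for {peak.sample_id} "
            f"rep {peak.replicate}, got {is_area}")
    conc = peak.area * is_spec.Cs * is_spec.Vs / (is_area * is_spec.mx)
    return QuantifiedCompound(
        sample_id=peak.sample_id,
        replicate=peak.replicate,
        compound_name=compound_name or peak.assigned_compound or peak.peak_id,
        concentration=conc,
        Ax=peak.area,
        As=is_area,
        peak_id=peak.peak_id,
    )


def quantify_table(
    peaks: Sequence[PeakRecord],
    library: Sequence[CompoundLibraryEntry],
    ladder: AlkaneLadder,
    is_spec: InternalStandardSpec,
    ri_tolerance: float = 15.0,
) -> pd.DataFrame:
    """Identify and quantify every peak of a study.

    Peaks carrying an explicit ``assigned_compound`` keep it (validated
    against the library); the rest are assigned to the nearest library RI
    within tolerance. Internal-standard peaks provide the per
    sample-replicate ``As`` and are excluded from the compound table.
    Unmatched peaks are dropped with a log entry.

    Returns a tidy frame with columns sample_id, replicate, compound_name,
    chem_class, concentration (µg/g), Ax, As, ri, extrapolated.
    """
    idx = library_index(library)
    is_key = normalize_name(is_spec.compound_name)

    # pass 1: locate the internal standard in every sample-replicate
    is_areas: dict[tuple[str, int], float] = {}
    for p in peaks:
        if p.assigned_compound and normalize_name(p.assigned_compound) == is_key:
            is_areas[(p.sample_id, p.replicate)] = p.area

    rows = []
    n_unmatched = 0
    for p in peaks:
        if p.assigned_compound and normalize_name(p.assigned_compound) == is_key:
            continue
        ri = compute_retention_index(p.retention_time, ladder)
        if p.assigned_compound:
            entry = idx.get(normalize_name(p.assigned_compound))
            if entry is None:
                raise ValidationError(
                    f"peak {p.peak_id} assigned to unknown compound "
                    f"{p.assigned_compound!r}")
        else:
            hits = match_library(ri, library, ri_tolerance)
            if not hits:
                n_unmatched += 1
                continue
            entry = hits[0][0]
        if normalize_name(entry.name) == is_key:
            continue  # the spike itself is never a reported compound
        key = (p.sample_id, p.replicate)
        if key not in is_areas:
            raise QuantitationError(
                f"no internal-standard peak for sample {p.sample_id} "
                f"rep {p.replicate}")
        q = quantify_peak(p, is_areas[key], is_spec, compound_name=entry.name)
        rows.append({
            "sample_id": q.sample_id,
            "replicate": q.replicate,
            "compound_name": q.compound_name,
            "chem_class": entry.chem_class,
            "concentration": q.concentration,
            "Ax": q.Ax,
            "As": q.As,
            "ri": ri.value,
            "extrapolated": ri.extrapolated,
        })
    if n_unmatched:
        log.info("%d peak(s) had no library match within ±%.0f RI units",
                 n_unmatched, ri_tolerance)
    df = pd.DataFrame(rows, columns=[
        "sample_id", "replicate", "compound_name", "chem_class",
        "concentration", "Ax", "As", "ri", "extrapolated"])
    # co-assigned duplicates within a sample-replicate: sum their areas
    if not df.empty and df.duplicated(
            ["sample_id", "replicate", "compound_name"]).any():
        df = (df.groupby(["sample_id", "replicate", "compound_name",
                          "chem_class"], as_index=False)
                .agg({"concentration": "sum", "Ax": "sum", "As": "first",
                      "ri": "first", "extrapolated": "max"}))
    return df


def roav(Ci_ug_per_g: float, OTi_ug_per_kg: Optional[float]) -> Optional[float]:
    """rOAV = Ci / OTi after converting Ci to µg/kg; None when no threshold."""
    if Ci_ug_per_g < 0:
        raise ValueError("concentration must be >= 0")
    if OTi_ug_per_kg is None:
        return None
    if OTi_ug_per_kg <= 0:
        raise ValidationError("odor threshold must be > 0")
    return Ci_ug_per_g * UG_PER_G_TO_UG_PER_KG / OTi_ug_per_kg


def roav_table(
    quant: pd.DataFrame,
    library: Sequence[CompoundLibraryEntry],
) -> pd.DataFrame:
    """Per-sample rOAV with Ci the replicate-mean concentration.

    Columns: sample_id, compound_name, Ci (µg/g), OTi (µg/kg), roav
    (NaN when the library lacks a threshold).
    """
    idx = library_index(library)
    mean = (quant.groupby(["sample_id", "compound_name"], as_index=False)
                 ["concentration"].mean()
                 .rename(columns={"concentration": "Ci"}))
    ots, roavs = [], []
    n_undefined = 0
    for _, row in mean.iterrows():
        entry = idx.get(normalize_name(row["compound_name"]))
        ot = entry.odor_threshold if entry is not None else None
        val = roav(row["Ci"], ot)
        ots.append(np.nan if ot is None else ot)
        if val is None:
            n_undefined += 1
            roavs.append(np.nan)
        else:
            roavs.append(val)
    mean["OTi"] = ots
    mean["roav"] = roavs
    if n_undefined:
        log.info("%d sample-compound pairs have no odor threshold; "
                 "their rOAV is undefined and excluded from screening",
                 n_undefined)
    return mean


def aggregate_classes(
    quant: pd.DataFrame,
    library: Sequence[CompoundLibraryEntry],
    reference_sample: str,
) -> pd.DataFrame:
    """Per-sample chemical-class totals (µg/kg) and % change vs a reference.

    Replicates are averaged per compound before summing within a class;
    a ``grand_total`` row per sample is appended so that class totals can
    be checked to conserve the sample total.
    """
    if reference_sample not in set(quant["sample_id"]):
        raise ValueError(f"reference sample {reference_sample!r} absent")
    idx = library_index(library)

    mean = (quant.groupby(["sample_id", "compound_name"], as_index=False)
                 ["concentration"].mean())
    classes = []
    for name in mean["compound_name"]:
        entry = idx.get(normalize_name(name))
        if entry is None:
            raise ValidationError(f"compound {name!r} has no library class")
        classes.append(entry.chem_class)
    mean["chem_class"] = classes
    mean["ug_per_kg"] = mean["concentration"] * UG_PER_G_TO_UG_PER_KG

    totals = (mean.pivot_table(index="sample_id", columns="chem_class",
                               values="ug_per_kg", aggfunc="sum", fill_value=0.0)
                  .stack().rename("total").reset_index())
    grand = (mean.groupby("sample_id", as_index=False)["ug_per_kg"].sum()
                 .rename(columns={"ug_per_kg": "total"}))
    grand["chem_class"] = "grand_total"
    totals = pd.concat([totals, grand[totals.columns]], ignore_index=True)

    ref = totals[totals["sample_id"] == reference_sample].set_index("chem_class")[
        "total"]
    pct = []
    for _, row in totals.iterrows():
        ref_total = ref.get(row["chem_class"], 0.0)
        if ref_total == 0:
            pct.append(np.nan if row["total"] == 0 else np.inf)
        else:
            pct.append(100.0 * (row["total"] - ref_total) / ref_total)
    totals["pct_change_vs_reference"] = pct
    return totals.sort_values(["sample_id", "chem_class"]).reset_index(drop=True)
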