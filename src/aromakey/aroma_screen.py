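"""Key aroma compound screening: rOAV threshold ∩ GC-O consensus.

A compound is a *key* aroma contributor when it clears the rOAV threshold
in every sample group **and** is consensus-detected at the sniffing port.
The two screens overlap but do not coincide — some potent compounds lack
an odor threshold (GC-O only), others pass rOAV without reliable sniffer
detection — so the result is reported as Venn regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_formats import (
    AlkaneLadder,
    CompoundLibraryEntry,
    GCOEvent,
    library_index,
    log,
    normalize_name,
)
from .identify_quant import compute_retention_index, match_library


@dataclass(frozen=True)
class GCOConsensusRecord:
    sample_id: str
    compound_name: str
    n_panelists_detecting: int
    mean_intensity: Optional[float]  # over all reports by detecting panelists
    consensus: bool
    descriptor: str = ""


@dataclass
class KeyCompoundSet:
    members: set[str]
    per_sample_roav_pass: dict[str, set[str]]
    gco_set: set[str]
    roav_only: set[str] = field(default_factory=set)
    gco_only: set[str] = field(default_factory=set)

    @property
    def roav_intersection(self) -> set[str]:
        sets = list(self.per_sample_roav_pass.values())
        return set.intersection(*sets) if sets else set()

    def venn_counts(self) -> dict[str, int]:
        return {
            "roav_intersection": len(self.roav_intersection),
            "gco_consensus": len(self.gco_set),
            "key_compounds": len(self.members),
            "roav_only": len(self.roav_only),
            "gco_only": len(self.gco_only),
        }


@dataclass(frozen=True)
class OdorGroupAssignment:
    compound_name: str
    group: int | str  # 1..4 or "unassigned"
    rationale: str


def resolve_gco_compounds(
    events: Sequence[GCOEvent],
    library: Sequence[CompoundLibraryEntry],
    ladder: Optional[AlkaneLadder] = None,
    ri_tolerance: float = 15.0,
) -> list[GCOEvent]:
    """Resolve retention-time GC-O events to library compound names.

    Events already naming a library compound pass through; numeric events
    need a ladder and are assigned to the nearest reference RI. Events
    that resolve to nothing are dropped with a log entry.
    """
    idx = library_index(library)
    resolved: list[GCOEvent] = []
    n_dropped = 0
    for e in events:
        key = normalize_name(e.compound_or_rt)
        if key in idx:
            resolved.append(GCOEvent(
                e.sample_id, e.replicate, e.panelist, idx[key].name,
                e.intensity, e.descriptor))
            continue
        try:
            rt = float(e.compound_or_rt)
        except ValueError:
            n_dropped += 1
            continue
        if ladder is None:
            n_dropped += 1
            continue
        ri = compute_retention_index(rt, ladder)
        hits = match_library(ri, library, ri_tolerance)
        if hits:
            resolved.append(GCOEvent(
                e.sample_id, e.replicate, e.panelist, hits[0][0].name,
                e.intensity, e.descriptor))
        else:
            n_dropped += 1
    if n_dropped:
        log.info("%d GC-O event(s) could not be resolved to a library compound",
                 n_dropped)
    return resolved


def gco_consensus(
    events: Sequence[GCOEvent],
    panel_size: int,
    min_panelists: int = 2,
) -> list[GCOConsensusRecord]:
    """Per-sample consensus detection from resolved GC-O events.

    A compound is consensus-detected in a sample when at least
    ``min_panelists`` distinct panelists report it in any replicate
    session; the mean intensity averages *all* reports from detecting
    panelists across replicates. Descriptors from detecting panelists are
    pooled (deduplicated, sorted).
    """
    if min_panelists > panel_size:
        raise ValueError("min_panelists cannot exceed panel_size")
    by_key: dict[tuple[str, str], list[GCOEvent]] = {}
    names: dict[str, str] = {}
    for e in events:
        key = normalize_name(e.compound_or_rt)
        names.setdefault(key, e.compound_or_rt)
        by_key.setdefault((e.sample_id, key), []).append(e)

    records = []
    for (sample_id, key), evs in sorted(by_key.items()):
        panelists = {e.panelist for e in evs}
        n = len(panelists)
        intensities = [e.intensity for e in evs]
        descriptors = sorted({e.descriptor for e in evs if e.descriptor})
        records.append(GCOConsensusRecord(
            sample_id=sample_id,
            compound_name=names[key],
            n_panelists_detecting=n,
            mean_intensity=sum(intensities) / len(intensities) if n else None,
            consensus=n >= min_panelists,
            descriptor="; ".join(descriptors),
        ))
    return records


def screen_roav(
    roav_df: pd.DataFrame,
    threshold: float = 1.0,
) -> dict[str, set[str]]:
    """Per-sample sets of compounds with a defined rOAV ≥ threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    passes: dict[str, set[str]] = {s: set() for s in sorted(set(roav_df["sample_id"]))}
    for _, row in roav_df.iterrows():
        val = row["roav"]
        if pd.notna(val) and val >= threshold:
            passes[row["sample_id"]].add(row["compound_name"])
    return passes


def intersect_key_compounds(
    roav_pass: Mapping[str, set[str]],
    gco_records: Sequence[GCOConsensusRecord],
) -> KeyCompoundSet:
    """Venn combination of the rOAV screen with GC-O consensus.

    ``members`` requires an rOAV pass in **all** samples plus GC-O
    consensus in at least one sample; ``roav_only`` and ``gco_only`` are
    the unshared Venn regions.
    """
    sets = [set(v) for v in roav_pass.values()]
    roav_all = set.intersection(*sets) if sets else set()
    gco_set = {r.compound_name for r in gco_records if r.consensus}
    members = roav_all & gco_set
    return KeyCompoundSet(
        members=members,
        per_sample_roav_pass={k: set(v) for k, v in roav_pass.items()},
        gco_set=gco_set,
        roav_only=roav_all - gco_set,
        gco_only=gco_set - roav_all,
    )


# keyword rules for the four descriptor-based odor groups:
# 1 roasted/nutty, 2 buttery/caramel, 3 smoky/earthy, 4 pungent/mushroom
_GROUP_KEYWORDS: dict[int, tuple[str, ...]] = {
    1: ("roasted", "roast", "nutty", "nut", "cocoa", "chocolate", "coffee",
        "baked", "potato", "peanut"),
    2: ("buttery", "butter", "creamy", "cream", "caramel", "yoghurt",
        "yogurt", "popcorn", "burnt sugar", "sweet"),
    3: ("smoky", "smoke", "woody", "wood", "earthy", "grassy", "grass",
        "cucumber", "medicinal", "medical", "herb"),
    4: ("pungent", "mushroom", "sweat", "sweaty", "cheese", "stinky",
        "pea", "fatty"),
}


def assign_odor_groups(
    key_set: Sequence[str] | set[str],
    descriptor_map: Mapping[str, str],
) -> list[OdorGroupAssignment]:
    """Deterministic keyword mapping of descriptors to odor groups 1–4.

    The group with the most keyword hits wins; ties break toward the
    lower group number. Descriptors matching nothing yield group
    ``"unassigned"`` with a warning.
    """
    assignments = []
    for name in sorted(key_set, key=normalize_name):
        descriptor = (descriptor_map.get(name)
                      or descriptor_map.get(normalize_name(name)) or "")
        text = descriptor.lower()
        hits = {g: sum(1 for kw in kws if kw in text)
                for g, kws in _GROUP_KEYWORDS.items()}
        best = max(hits, key=lambda g: (hits[g], -g))
        if hits[best] == 0:
            log.warning("descriptor %r for %s matches no odor group",
                        descriptor, name)
            assignments.append(OdorGroupAssignment(name, "unassigned", descriptor))
        else:
            assignments.append(OdorGroupAssignment(name, best, descriptor))
    return assignments


def consensus_table(records: Sequence[GCOConsensusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "sample_id": r.sample_id,
            "compound_name": r.compound_name,
            "n_panelists_detecting": r.n_panelists_detecting,
            "mean_intensity": r.mean_intensity,
            "consensus": r.consensus,
            "descriptor": r.descriptor,
        } for r in records],
        columns=["sample_id", "compound_name", "n_panelists_detecting",
                 "mean_intensity", "consensus", "descriptor"])
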