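"""Seeded synthetic GC-O-MS studies with planted ground truth.

The generator emulates a four-group fermentation study (wild-type S1 and
three knockout ferments S2–S4, three replicates each) profiled by
HS-SPME-GC-MS with a sec-octanol internal standard, a three-person GC-O
panel and a ten-person QDA sensory panel:

* a 99-compound library over the study's chemical classes (13 pyrazines,
  19 ketones, 6 acids, 22 alcohols, 16 aldehydes, 3 phenols plus furans,
  oxazoles, sulfides, esters and others); the aroma-active compounds
  carry their real names and descriptors, the bulk of the volatilome is
  synthetic filler (``<class>_NN`` names). Reference retention indices
  are synthetic placements on a C7–C30 ladder, not literature values.
* true per-group mean concentrations with planted effects: marker
  pyrazines and guaiacol elevated in the mutant groups (strongest in
  S4), 1-octen-3-ol and 3-hydroxy-2-butanone depressed in S4;
* peak areas back-computed from true concentrations through the
  internal-standard formula with multiplicative log-normal replicate
  noise, and retention times placed at the library RI (plus jitter) on a
  simulated alkane ladder — with zero noise the quantitation path
  inverts generation exactly;
* GC-O detections drawn per panelist with probability logistic in
  log10(rOAV × sniffability), where the per-compound sniffability factor
  models how recognizable an odorant is at the port — this keeps the
  rOAV and GC-O screens correlated but not identical, so the Venn
  regions are non-trivial;
* sensory scores linearly driven by odor-group abundances plus panelist
  noise, rounded half-up and clamped to 1..5.

``paper_fixture`` is the deterministic study used throughout the test
suite: its screening arithmetic is planted so that the per-group rOAV
pass counts are 15, 15, 16, 18 with a 15-compound cross-group
intersection, a 17-compound GC-O consensus set, and a 12-member key set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io_formats import (
    AlkaneLadder,
    AnalysisConfig,
    CompoundLibraryEntry,
    GCOEvent,
    InternalStandardSpec,
    PeakRecord,
    SensoryScore,
    SENSORY_ATTRIBUTES,
)
from .identify_quant import UG_PER_G_TO_UG_PER_KG, invert_retention_index

SAMPLE_IDS = ("S1", "S2", "S3", "S4")

# one planted aroma-active compound: name, class, descriptor, odor group,
# base concentration in S1 (µg/g), per-group multipliers, target rOAV in S1
# (None = no odor threshold in the library), and a sniffability factor for
# the GC-O detection model.
@dataclass(frozen=True)
class _Active:
    name: str
    chem_class: str
    descriptor: str
    odor_group: int
    base: float
    multipliers: tuple[float, float, float, float]
    target_roav: Optional[float]
    sniff: float
    role: str  # key | roav_only | partial | gco_only


# The 12 planted key compounds span the four descriptor odor groups; the
# five "marker" compounds get the strongest S1-vs-mutant contrast and are
# the planted VIP>1 set.
_ACTIVES: tuple[_Active, ...] = (
    # --- key compounds (rOAV >= 1 everywhere AND GC-O consensus) ---
    _Active("2,3,5-trimethylpyrazine", "pyrazine", "roasted peanut, cocoa", 1,
            0.60, (1.0, 1.45, 1.40, 2.30), 124.0, 60.0, "key"),
    _Active("2,5-dimethylpyrazine", "pyrazine", "woody grass medical", 1,
            0.45, (1.0, 0.97, 0.90, 0.90), 42.0, 60.0, "key"),
    _Active("2,3,5,6-tetramethylpyrazine", "pyrazine", "chocolate, nutty", 1,
            0.80, (1.0, 1.50, 1.45, 2.50), 6.0, 150.0, "key"),
    _Active("2,3-dimethylpyrazine", "pyrazine", "nutty, coffee", 1,
            0.12, (1.0, 1.40, 1.50, 2.40), 4.5, 200.0, "key"),
    _Active("3-ethyl-2,5-dimethylpyrazine", "pyrazine", "roasted potato", 1,
            0.08, (1.0, 1.12, 1.05, 1.15), 1.8, 400.0, "key"),
    _Active("2,3-butanedione", "ketone", "strong butter, yoghurt", 2,
            0.50, (1.0, 1.15, 1.05, 0.80), 364.0, 30.0, "key"),
    _Active("3-hydroxy-2-butanone", "ketone", "buttery, creamy", 2,
            0.40, (1.0, 1.10, 1.05, 0.55), 5.2, 180.0, "key"),
    _Active("malic acid", "acid", "caramel, popcorn", 2,
            0.30, (1.0, 1.08, 1.12, 1.26), 1.6, 450.0, "key"),
    _Active("guaiacol", "phenol", "smoky, woody", 3,
            0.35, (1.0, 1.50, 1.55, 2.20), 320.0, 30.0, "key"),
    _Active("2,4,5-trimethyloxazole", "oxazole", "earthy, cucumbers", 3,
            0.15, (1.0, 1.60, 1.55, 2.00), 11.0, 90.0, "key"),
    _Active("2-methylbutanoic acid", "acid", "stinky feet, cheese", 4,
            0.25, (1.0, 1.06, 1.10, 1.30), 1.6, 450.0, "key"),
    _Active("1-octen-3-ol", "alcohol", "mushroom", 4,
            0.20, (1.0, 0.98, 1.00, 0.60), 30.0, 60.0, "key"),
    # --- rOAV everywhere but never consensus-sniffed ---
    _Active("dimethyl disulfide", "sulfide", "sulfurous, cabbage", 3,
            0.05, (1.0, 1.05, 1.00, 1.10), 25.0, 0.001, "roav_only"),
    _Active("2-methylbutyraldehyde", "aldehyde", "malty, cocoa", 1,
            0.15, (1.0, 1.00, 1.05, 1.10), 9.4, 0.002, "roav_only"),
    _Active("2-ethylfuran", "furan", "beany, earthy", 3,
            0.08, (1.0, 1.00, 1.00, 1.05), 6.6, 0.003, "roav_only"),
    # --- rOAV >= 1 only in some groups ---
    _Active("2-n-pentylfuran", "furan", "green bean, metallic", 3,
            0.10, (1.0, 1.00, 2.80, 1.00), 0.55, 0.01, "partial"),
    _Active("3-methylbutyric acid", "acid", "sweaty, rancid", 4,
            0.20, (1.0, 1.00, 1.00, 2.50), 0.55, 0.01, "partial"),
    # --- GC-O consensus without a full rOAV pass ---
    _Active("phenethyl alcohol", "alcohol", "rose, honey", 2,
            0.30, (1.0, 1.00, 1.00, 2.60), 0.50, 300.0, "gco_only"),
    _Active("2,6-dimethylpyrazine", "pyrazine", "roasted nut, cocoa", 1,
            0.18, (1.0, 1.10, 1.10, 2.60), 0.50, 300.0, "gco_only"),
    _Active("2-methylpyrazine", "pyrazine", "nutty, popcorn", 1,
            0.25, (1.0, 1.20, 1.20, 1.60), None, 150.0, "gco_only"),
    _Active("2-ethyl-3-methylpyrazine", "pyrazine", "roasted, nutty", 1,
            0.10, (1.0, 1.15, 1.15, 1.50), 0.30, 500.0, "gco_only"),
    _Active("acetic acid", "acid", "vinegar, sour", 4,
            0.40, (1.0, 1.05, 1.05, 1.20), 0.40, 380.0, "gco_only"),
)

# filler class composition bringing the library to 99 compounds while
# matching the study's class tally (13 pyrazines, 19 ketones, 6 acids,
# 22 alcohols, 16 aldehydes, 3 phenols, ...)
_FILLER_CLASS_COUNTS = {
    "pyrazine": 5, "ketone": 17, "acid": 2, "alcohol": 20, "aldehyde": 15,
    "phenol": 2, "furan": 3, "oxazole": 1, "sulfide": 2, "ester": 6,
    "other": 4,
}
_FILLER_CLASS_MULTIPLIERS = {
    "pyrazine": (1.0, 1.30, 1.30, 1.80),
    "ketone": (1.0, 1.19, 1.13, 1.00),
    "acid": (1.0, 1.05, 1.10, 1.26),
    "alcohol": (1.0, 1.00, 1.00, 0.90),
    "aldehyde": (1.0, 1.00, 1.00, 1.05),
}


@dataclass
class SimulationDesign:
    """Everything that defines a synthetic study except the seed's draws."""
    n_groups: int = 4
    n_replicates: int = 3
    noise_cv: float = 0.12              # replicate CV of concentrations
    ri_jitter_sd: float = 1.5           # RI units
    is_spec: InternalStandardSpec = field(default_factory=InternalStandardSpec)
    is_area: float = 1.0e6              # detector counts for the spike
    is_ref_ri: float = 1125.0
    gco_panel_size: int = 3
    gco_midpoint: float = 1.5           # log10 effective OAV at 50% detection
    gco_slope: float = 3.0
    gco_deterministic: bool = False     # detect iff p >= 0.5 (fixture mode)
    sensory_panel_size: int = 10
    sensory_noise_sd: float = 0.35
    # per-compound overrides of the planted group-effect multipliers
    multiplier_overrides: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_groups != 4:
            raise ValueError("design requires 4 groups and >= 1 replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class PlantedTruth:
    true_means: pd.DataFrame            # compounds × samples, µg/g
    key_set: set[str]
    vip_markers: set[str]
    cluster_partition: tuple[frozenset, frozenset]
    correlation_signs: dict[tuple[str, str], int]
    odor_groups: dict[str, int]
    roav_pass_by_sample: dict[str, set[str]]
    gco_compounds: set[str]


@dataclass
class DatasetBundle:
    peaks: list[PeakRecord]
    ladder: AlkaneLadder
    library: list[CompoundLibraryEntry]
    is_spec: InternalStandardSpec
    gco: list[GCOEvent]
    sensory: list[SensoryScore]
    config: AnalysisConfig


VIP_MARKERS = {
    "2,3,5,6-tetramethylpyrazine", "2,3,5-trimethylpyrazine", "guaiacol",
    "2,3-dimethylpyrazine", "2,4,5-trimethyloxazole",
}


# ---------------------------------------------------------------------------
# deterministic roster construction (identical across seeds)
# ---------------------------------------------------------------------------

def _simulated_ladder() -> AlkaneLadder:
    """C7–C30 ladder under a mildly curved temperature program."""
    entries = tuple(
        (n, round(2.0 + 2.1 * (n - 7) + 0.012 * (n - 7) ** 2, 4))
        for n in range(7, 31))
    return AlkaneLadder(entries=entries)


def _build_roster() -> pd.DataFrame:
    """The full 99-compound roster with all planted per-compound constants.

    Construction is deterministic (fixed internal generator) so every
    seeded dataset shares one library and one set of true means.
    """
    rng = np.random.default_rng(7)
    rows = []
    for a in _ACTIVES:
        rows.append({
            "name": a.name, "chem_class": a.chem_class,
            "descriptor": a.descriptor, "odor_group": a.odor_group,
            "base": a.base, "multipliers": a.multipliers,
            "target_roav": a.target_roav, "sniff": a.sniff, "role": a.role,
        })
    for chem_class, count in _FILLER_CLASS_COUNTS.items():
        mult = _FILLER_CLASS_MULTIPLIERS.get(chem_class, (1.0, 1.0, 1.0, 1.0))
        for i in range(count):
            base = float(np.exp(rng.normal(math.log(0.04), 1.0)))
            # fillers never clear the rOAV threshold: target well below 1
            target = float(np.exp(rng.uniform(math.log(1e-3), math.log(0.4))))
            missing = rng.random() < 0.07
            rows.append({
                "name": f"{chem_class}_{i + 1:02d}", "chem_class": chem_class,
                "descriptor": "", "odor_group": 0,
                "base": base, "multipliers": mult,
                "target_roav": None if missing else target,
                "sniff": 1.0, "role": "filler",
            })
    roster = pd.DataFrame(rows)
    assert len(roster) == 99
    # synthetic RI placements: a shuffled grid with > 2x the match
    # tolerance between neighbours so assignments are unambiguous
    grid = 720.0 + 17.0 * np.arange(len(roster))
    roster["ref_ri"] = rng.permutation(grid)
    return roster


def _truth_from_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """True mean concentration (µg/g) per compound per sample group."""
    data = {
        s: roster["base"].to_numpy()
        * np.array([m[g] for m in roster["multipliers"]])
        for g, s in enumerate(SAMPLE_IDS)
    }
    return pd.DataFrame(data, index=roster["name"])


def _thresholds(roster: pd.DataFrame) -> dict[str, Optional[float]]:
    """Odor thresholds (µg/kg) back-derived from the S1 rOAV targets."""
    out = {}
    for _, r in roster.iterrows():
        if pd.isna(r["target_roav"]):
            out[r["name"]] = None
        else:
            out[r["name"]] = (r["base"] * UG_PER_G_TO_UG_PER_KG
                              / float(r["target_roav"]))
    return out


def _library_from_roster(roster: pd.DataFrame) -> list[CompoundLibraryEntry]:
    thresholds = _thresholds(roster)
    entries = []
    for _, r in roster.iterrows():
        aliases = ()
        if r["name"] == "2,3,5,6-tetramethylpyrazine":
            aliases = ("tetramethylpyrazine",)
        entries.append(CompoundLibraryEntry(
            name=r["name"], chem_class=r["chem_class"],
            ref_ri=float(r["ref_ri"]),
            odor_threshold=thresholds[r["name"]],
            odor_descriptor=r["descriptor"], aliases=aliases))
    return entries


def _expected_screens(roster: pd.DataFrame) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Planted rOAV pass sets, GC-O set and key set, from the constants."""
    truth = _truth_from_roster(roster)
    thresholds = _thresholds(roster)
    roav_pass: dict[str, set[str]] = {s: set() for s in SAMPLE_IDS}
    for name in truth.index:
        ot = thresholds[name]
        if ot is None:
            continue
        for s in SAMPLE_IDS:
            if truth.loc[name, s] * UG_PER_G_TO_UG_PER_KG / ot >= 1.0:
                roav_pass[s].add(name)
    gco = set(roster.loc[roster["role"].isin(["key", "gco_only"]), "name"])
    key = set.intersection(*roav_pass.values()) & gco
    return roav_pass, gco, key


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _detection_probability(
    roav_value: Optional[float],
    sniff: float,
    midpoint: float,
    slope: float,
) -> float:
    """Logistic-in-log10 detection model with a sniffability factor.

    Compounds without an odor threshold still smell; their detectability
    is carried entirely by the sniffability factor (nominal OAV 1).
    """
    effective = (roav_value if roav_value is not None else 1.0) * sniff
    if effective <= 0:
        return 0.0
    x = slope * (math.log10(effective) - midpoint)
    return 1.0 / (1.0 + math.exp(-x))


def generate_dataset(design: SimulationDesign) -> tuple[DatasetBundle, PlantedTruth]:
    """Draw one complete seeded study and its planted truth."""
    rng = np.random.default_rng(design.seed)
    roster = _build_roster()
    if design.multiplier_overrides:
        unknown = set(design.multiplier_overrides) - set(roster["name"])
        if unknown:
            raise ValueError(f"multiplier overrides for unknown compounds: "
                             f"{sorted(unknown)}")
        roster = roster.copy()
        roster["multipliers"] = [
            tuple(design.multiplier_overrides.get(n, m))
            for n, m in zip(roster["name"], roster["multipliers"])]
    truth = _truth_from_roster(roster)
    thresholds = _thresholds(roster)
    library = _library_from_roster(roster)
    ladder = _simulated_ladder()
    spec = design.is_spec
    sigma = math.sqrt(math.log(1 + design.noise_cv ** 2))

    roav_pass, gco_set, key_set = _expected_screens(roster)

    # ---- peak tables: invert the quantitation formula ----
    peaks: list[PeakRecord] = []
    for s in SAMPLE_IDS:
        for rep in range(1, design.n_replicates + 1):
            As = design.is_area * float(np.exp(rng.normal(0, sigma / 4)))
            peaks.append(PeakRecord(
                sample_id=s, replicate=rep, peak_id=f"{s}_r{rep}_IS",
                retention_time=round(
                    invert_retention_index(design.is_ref_ri, ladder), 4),
                area=As,
                assigned_compound=spec.compound_name,
            ))
            for j, (_, r) in enumerate(roster.iterrows()):
                conc = truth.loc[r["name"], s] * float(
                    np.exp(rng.normal(0, sigma)))
                area = conc * As * spec.mx / (spec.Cs * spec.Vs)
                ri = r["ref_ri"] + rng.normal(0, design.ri_jitter_sd)
                peaks.append(PeakRecord(
                    sample_id=s, replicate=rep, peak_id=f"{s}_r{rep}_p{j:03d}",
                    retention_time=round(invert_retention_index(ri, ladder), 4),
                    area=area,
                ))

    # ---- GC-O events ----
    gco_events: list[GCOEvent] = []
    panelists = [f"P{i + 1}" for i in range(design.gco_panel_size)]
    for g, s in enumerate(SAMPLE_IDS):
        for _, r in roster.iterrows():
            ot = thresholds[r["name"]]
            conc_kg = truth.loc[r["name"], s] * UG_PER_G_TO_UG_PER_KG
            roav_value = conc_kg / ot if ot is not None else None
            p = _detection_probability(
                roav_value, r["sniff"], design.gco_midpoint, design.gco_slope)
            for rep in range(1, design.n_replicates + 1):
                for panelist in panelists:
                    detected = (p >= 0.5 if design.gco_deterministic
                                else rng.random() < p)
                    if not detected:
                        continue
                    base = 1.0 + 1.1 * max(math.log10(roav_value), 0.0) \
                        if roav_value is not None and roav_value > 0 else 3.0
                    noise = 0.0 if design.gco_deterministic else rng.normal(0, 0.5)
                    intensity = int(min(5, max(1, math.floor(base + noise + 0.5))))
                    gco_events.append(GCOEvent(
                        sample_id=s, replicate=rep, panelist=panelist,
                        compound_or_rt=r["name"], intensity=intensity,
                        descriptor=r["descriptor"]))

    # ---- sensory scores from odor-group abundances ----
    odor_groups = {r["name"]: int(r["odor_group"])
                   for _, r in roster.iterrows() if r["odor_group"] > 0}
    group_index = {}
    for og in (1, 2, 3, 4):
        names = [n for n, g in odor_groups.items() if g == og]
        block = truth.loc[names]
        geomean = np.exp(np.log(block).mean(axis=1))
        group_index[og] = np.log2(block.div(geomean, axis=0)).mean(axis=0)
    weights = {
        "soy_sauce_like": {1: 0.9, 3: 0.7},
        "roasted": {1: 1.4},
        "smoky": {3: 1.4},
        "buttery": {2: 1.2},
        "sweet": {2: 0.9},
        "grain": {4: 1.2},
    }
    sensory: list[SensoryScore] = []
    for s in SAMPLE_IDS:
        for panelist in [f"Q{i + 1}" for i in range(design.sensory_panel_size)]:
            for session in range(1, design.n_replicates + 1):
                for attr in SENSORY_ATTRIBUTES:
                    base = 3.0 + sum(w * group_index[og][s]
                                     for og, w in weights[attr].items())
                    score = base + rng.normal(0, design.sensory_noise_sd)
                    score = int(min(5, max(1, math.floor(score + 0.5))))
                    sensory.append(SensoryScore(
                        sample_id=s, panelist=panelist, session=session,
                        attribute=attr, score=score))

    config = AnalysisConfig(random_seed=design.seed)
    bundle = DatasetBundle(
        peaks=peaks, ladder=ladder, library=library, is_spec=spec,
        gco=gco_events, sensory=sensory, config=config)

    # planted attribute drivers: only group-1 compounds elevated in
    # *every* mutant group are planted as "roasted" drivers — a mild or
    # decreasing pyrazine (e.g. 2,5-dimethylpyrazine) is not
    mult_by_name = dict(zip(roster["name"], roster["multipliers"]))
    signs: dict[tuple[str, str], int] = {}
    for name, og in odor_groups.items():
        if og == 1 and min(mult_by_name[name][1:]) > 1.3:
            signs[(name, "roasted")] = 1
    signs[("guaiacol", "smoky")] = 1
    signs[("malic acid", "sweet")] = 1
    signs[("3-hydroxy-2-butanone", "buttery")] = 1
    signs[("2,3-butanedione", "buttery")] = 1
    truth_obj = PlantedTruth(
        true_means=truth,
        key_set=key_set,
        vip_markers=set(VIP_MARKERS),
        cluster_partition=(frozenset({"S1", "S2", "S3"}), frozenset({"S4"})),
        correlation_signs=signs,
        odor_groups=odor_groups,
        roav_pass_by_sample=roav_pass,
        gco_compounds=gco_set,
    )
    return bundle, truth_obj


_FIXTURE_SEED = 20240828


def paper_fixture() -> tuple[DatasetBundle, PlantedTruth]:
    """The deterministic study-shaped dataset.

    GC-O detections are expectation-thresholded (a panelist logs a
    compound exactly when the detection model gives p >= 0.5) so the
    screening counts are fixed by construction: per-group rOAV passes
    15, 15, 16, 18; cross-group intersection 15; GC-O consensus set 17;
    key set 12.
    """
    design = SimulationDesign(seed=_FIXTURE_SEED, gco_deterministic=True)
    return generate_dataset(design)


# ---------------------------------------------------------------------------
# bundle directory round-trip
# ---------------------------------------------------------------------------

def write_bundle(
    bundle: DatasetBundle,
    outdir,
    truth: Optional[PlantedTruth] = None,
) -> None:
    """Write a study as a directory of CSVs (+ config, + truth sidecar)."""
    from pathlib import Path
    import json
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_peak_table(bundle.peaks, outdir / "peaks.csv")
    io.write_ladder(bundle.ladder, outdir / "ladder.csv")
    io.write_library(bundle.library, outdir / "library.csv")
    io.write_gco(bundle.gco, outdir / "gco.csv")
    io.write_sensory(bundle.sensory, outdir / "sensory.csv")
    (outdir / "internal_standard.yaml").write_text(
        "compound_name: {0}\nCs: {1}\nVs: {2}\nmx: {3}\n".format(
            bundle.is_spec.compound_name, bundle.is_spec.Cs,
            bundle.is_spec.Vs, bundle.is_spec.mx))
    bundle.config.to_yaml(outdir / "config.yaml")
    if truth is not None:
        sidecar = {
            "key_set": sorted(truth.key_set),
            "vip_markers": sorted(truth.vip_markers),
            "cluster_partition": [sorted(p) for p in truth.cluster_partition],
            "roav_pass_by_sample": {s: sorted(v) for s, v in
                                    truth.roav_pass_by_sample.items()},
            "gco_compounds": sorted(truth.gco_compounds),
            "odor_groups": truth.odor_groups,
            "true_means": truth.true_means.round(8).to_dict(orient="index"),
        }
        (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2,
                                                      sort_keys=True))


def read_bundle(indir) -> DatasetBundle:
    """Read a study directory written by :func:`write_bundle`."""
    from pathlib import Path
    import yaml
    from . import io_formats as io

    indir = Path(indir)
    is_raw = yaml.safe_load((indir / "internal_standard.yaml").read_text())
    config_path = indir / "config.yaml"
    config = (AnalysisConfig.from_yaml(config_path) if config_path.exists()
              else AnalysisConfig())
    gco_path = indir / "gco.csv"
    if not gco_path.exists():
        raise FileNotFoundError(f"bundle is missing required input {gco_path}")
    return DatasetBundle(
        peaks=io.read_peak_table(indir / "peaks.csv"),
        ladder=io.read_ladder(indir / "ladder.csv"),
        library=io.read_library(indir / "library.csv"),
        is_spec=InternalStandardSpec(**is_raw),
        gco=io.read_gco(gco_path),
        sensory=io.read_sensory(indir / "sensory.csv"),
        config=config,
    )


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def _set_metrics(truth: set[str], recovered: set[str]) -> dict[str, float]:
    tp = len(truth & recovered)
    precision = tp / len(recovered) if recovered else 0.0
    recall = tp / len(truth) if truth else 1.0
    return {"precision": precision, "recall": recall,
            "true_positives": tp, "recovered_size": len(recovered),
            "truth_size": len(truth)}


def rand_index(partition_a: Mapping[str, int], partition_b: Mapping[str, int]) -> float:
    """Plain Rand index over the shared items of two flat partitions."""
    items = sorted(set(partition_a) & set(partition_b))
    if len(items) < 2:
        raise ValueError("need at least 2 shared items")
    agree = total = 0
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            same_a = partition_a[a] == partition_a[b]
            same_b = partition_b[a] == partition_b[b]
            agree += same_a == same_b
            total += 1
    return agree / total


def truth_report(
    truth: PlantedTruth,
    recovered_key_set: set[str],
    recovered_vip: Optional[set[str]] = None,
    recovered_partition: Optional[Mapping[str, int]] = None,
    correlation_signs: Optional[Mapping[tuple[str, str], int]] = None,
) -> dict:
    """Score recovered results against the planted truth."""
    report: dict = {"key_set": _set_metrics(truth.key_set, recovered_key_set)}
    if recovered_vip is not None:
        report["vip_markers"] = _set_metrics(truth.vip_markers, recovered_vip)
    if recovered_partition is not None:
        planted = {s: i for i, part in enumerate(truth.cluster_partition)
                   for s in part}
        report["cluster_rand_index"] = rand_index(planted, dict(recovered_partition))
    if correlation_signs is not None:
        pairs = set(truth.correlation_signs) & set(correlation_signs)
        if pairs:
            agree = sum(
                1 for p in pairs
                if np.sign(correlation_signs[p]) == truth.correlation_signs[p])
            report["correlation_sign_agreement"] = agree / len(pairs)
    return report
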