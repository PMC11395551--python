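"""End-to-end orchestration: quantify → screen → chemometrics → stats.

``run_pipeline`` executes the stages in the order the bench workflow
follows: internal-standard quantitation, rOAV screening, GC-O consensus,
key-compound intersection, class aggregation + HCA, PCA, OPLS-DA
(VIP, permutation test, CV-ANOVA), PLSR against sensory attributes
(correlation loadings, jack-knife) and per-compound ANOVA-LSD. Each
stage's tables can be written as CSV with a JSON run manifest; outputs
are pure functions of (bundle, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import univariate_stats as uni
from .aroma_screen import (
    KeyCompoundSet,
    assign_odor_groups,
    consensus_table,
    gco_consensus,
    intersect_key_compounds,
    resolve_gco_compounds,
    screen_roav,
)
from .identify_quant import aggregate_classes, quantify_table, roav_table
from .io_formats import AnalysisConfig, ValidationError, log, validate_bundle
from .synthetic_data import DatasetBundle

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    quantified: pd.DataFrame
    roav: pd.DataFrame
    class_totals: pd.DataFrame
    gco_consensus: pd.DataFrame
    key_set: KeyCompoundSet
    odor_groups: list
    sample_clusters: dict[str, int]
    sample_dendrogram: str
    pca: chem.LatentModel
    opls: chem.LatentModel
    opls_q2: float
    vip: pd.Series
    permutation: chem.PermutationResult
    cv_anova: chem.CVANOVAResult
    plsr: chem.LatentModel
    correlation_loadings: chem.CorrelationLoadings
    jackknife: chem.JackknifeResult
    anova_letters: pd.DataFrame
    contrast: tuple[str, tuple[str, ...]]
    key_matrix: pd.DataFrame            # sample-replicate × key compounds


@dataclass
class RunManifest:
    config: dict
    seed: int
    software_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _wide_matrix(quant: pd.DataFrame, compounds: list[str]) -> pd.DataFrame:
    """Sample-replicate × compound concentration matrix (µg/g)."""
    wide = quant[quant["compound_name"].isin(compounds)].pivot_table(
        index=["sample_id", "replicate"], columns="compound_name",
        values="concentration", aggfunc="mean")
    return wide.reindex(columns=sorted(compounds)).fillna(0.0)


def run_pipeline(
    bundle: DatasetBundle,
    config: Optional[AnalysisConfig] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    config = config or bundle.config or AnalysisConfig()
    log.info("pipeline config: %s", dataclasses.asdict(config))

    report = validate_bundle(bundle.peaks, bundle.library, bundle.ladder,
                             bundle.is_spec, bundle.gco, bundle.sensory)
    if report.errors:
        raise ValidationError("bundle validation failed:\n"
                              + "\n".join(report.errors))

    quant = _stage("quantify")(quantify_table)(
        bundle.peaks, bundle.library, bundle.ladder, bundle.is_spec,
        ri_tolerance=config.ri_match_tolerance)
    samples = sorted(set(quant["sample_id"]))
    reference = samples[0]

    roav_df = _stage("roav")(roav_table)(quant, bundle.library)
    class_totals = _stage("aggregate")(aggregate_classes)(
        quant, bundle.library, reference)

    # --- screening ---
    roav_pass = _stage("screen")(screen_roav)(roav_df, config.roav_threshold)
    resolved = resolve_gco_compounds(bundle.gco, bundle.library, bundle.ladder,
                                     config.ri_match_tolerance)
    panel = len({e.panelist for e in bundle.gco}) or 1
    consensus = _stage("gco")(gco_consensus)(
        resolved, panel, config.gco_min_panelists)
    key_set = intersect_key_compounds(roav_pass, consensus)
    descriptor_map = {e.name: e.odor_descriptor for e in bundle.library}
    odor_groups = assign_odor_groups(key_set.members, descriptor_map)

    # --- HCA on samples (group means, per-compound row scaling) ---
    mean_wide = quant.pivot_table(index="compound_name", columns="sample_id",
                                  values="concentration", aggfunc="mean")
    scaled = uni.scale_rows(mean_wide.to_numpy())
    hca = _stage("hca")(uni.hca_cluster)(scaled.T, list(mean_wide.columns), k=2)

    # --- chemometrics on the key-compound matrix ---
    key_compounds = sorted(key_set.members)
    if len(key_compounds) < 2:
        raise PipelineError("stage 'chemometrics' failed: fewer than 2 key "
                            "compounds recovered")
    key_matrix = _wide_matrix(quant, key_compounds)
    X = key_matrix.to_numpy()
    sx = chem.autoscale(X, config.scaling)
    pca = _stage("pca")(chem.pca_fit)(sx.values, k=min(2, *sx.values.shape))

    labels = np.array([reference if s == reference else "mutant"
                       for s, _ in key_matrix.index])
    folds = min(config.cv_folds, X.shape[0])
    if config.n_orth_components == "auto":
        n_orth = chem.auto_orth_components(sx.values, labels, folds=folds)
    else:
        n_orth = int(config.n_orth_components)
    opls = _stage("opls_da")(chem.opls_da_fit)(sx.values, labels, n_orth=n_orth)
    opls_q2 = chem.opls_da_cv(sx.values, labels, n_orth=n_orth, folds=folds)
    vip_scores = pd.Series(chem.vip(opls), index=key_matrix.columns,
                           name="VIP").sort_values(ascending=False)
    perm = _stage("permutation")(chem.permutation_test)(
        sx.values, labels, n_permutations=config.n_permutations,
        n_orth=n_orth, folds=folds, rng=config.random_seed)
    cvan = _stage("cv_anova")(chem.cv_anova_opls)(
        sx.values, labels, n_orth=n_orth, folds=folds)

    # --- PLSR against sensory attribute means (sample × session rows) ---
    sens = pd.DataFrame([dataclasses.asdict(s) for s in bundle.sensory])
    sens_mean = sens.pivot_table(index=["sample_id", "session"],
                                 columns="attribute", values="score",
                                 aggfunc="mean")
    sens_mean = sens_mean.reindex(key_matrix.index.set_names(
        ["sample_id", "session"]))
    aligned = sens_mean.dropna()
    Xp = key_matrix.loc[aligned.index.set_names(key_matrix.index.names)]
    plsr, loadings = _stage("plsr")(chem.plsr_sensory)(
        Xp.to_numpy(), aligned.to_numpy(),
        list(key_matrix.columns), list(aligned.columns), config.scaling)
    jk = _stage("jackknife")(chem.jackknife_significance)(
        Xp.to_numpy(), aligned.to_numpy(), n_components=2, alpha=config.alpha,
        scaling=config.scaling)

    # --- per-compound ANOVA with Fisher-LSD letters ---
    letter_rows = []
    for compound in key_compounds:
        sub = quant[quant["compound_name"] == compound]
        groups = {s: sub.loc[sub["sample_id"] == s, "concentration"].to_numpy()
                  for s in samples}
        groups = {s: v for s, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        try:
            res = uni.anova_lsd(groups, alpha=config.alpha)
        except ValueError:
            continue
        for s in groups:
            letter_rows.append({
                "compound_name": compound, "sample_id": s,
                "mean": res.group_means[s], "letters": res.letters[s],
                "anova_p": res.f_p_value})
    letters = pd.DataFrame(letter_rows, columns=[
        "compound_name", "sample_id", "mean", "letters", "anova_p"])

    result = PipelineResult(
        quantified=quant, roav=roav_df, class_totals=class_totals,
        gco_consensus=consensus_table(consensus), key_set=key_set,
        odor_groups=odor_groups,
        sample_clusters=hca.flat_clusters, sample_dendrogram=hca.newick,
        pca=pca, opls=opls, opls_q2=opls_q2, vip=vip_scores,
        permutation=perm, cv_anova=cvan,
        plsr=plsr, correlation_loadings=loadings, jackknife=jk,
        anova_letters=letters,
        contrast=(reference, tuple(s for s in samples if s != reference)),
        key_matrix=key_matrix,
    )
    if outdir is not None:
        write_results(result, config, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_CSV_FLOAT = "%.10g"


def write_results(result: PipelineResult, config: AnalysisConfig,
                  outdir: Path) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config),
                           seed=config.random_seed)

    def save(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False, float_format=_CSV_FLOAT)
        manifest.outputs.append(name)

    save(result.quantified, "quantified.csv")
    save(result.roav, "roav.csv")
    save(result.class_totals, "class_totals.csv")
    save(result.gco_consensus, "gco_consensus.csv")

    venn = result.key_set.venn_counts()
    save(pd.DataFrame([venn]), "venn_counts.csv")
    save(pd.DataFrame(
        sorted((m, "key") for m in result.key_set.members)
        + sorted((m, "roav_only") for m in result.key_set.roav_only)
        + sorted((m, "gco_only") for m in result.key_set.gco_only),
        columns=["compound_name", "region"]), "venn_membership.csv")
    save(pd.DataFrame(
        [{"compound_name": a.compound_name, "odor_group": a.group,
          "rationale": a.rationale} for a in result.odor_groups]),
        "odor_groups.csv")
    save(pd.DataFrame(
        [{"sample_id": s, "cluster": c}
         for s, c in sorted(result.sample_clusters.items())]),
        "sample_clusters.csv")
    (outdir / "sample_dendrogram.nwk").write_text(result.sample_dendrogram + "\n")
    manifest.outputs.append("sample_dendrogram.nwk")

    save(result.vip.rename_axis("compound_name").reset_index(), "vip.csv")
    save(pd.DataFrame({
        "correlation": result.permutation.correlations,
        "R2Y": result.permutation.permuted_r2y,
        "Q2": result.permutation.permuted_q2,
    }), "permutation_scatter.csv")
    save(result.anova_letters, "anova_letters.csv")

    cl = result.correlation_loadings
    save(pd.DataFrame({
        "name": list(cl.x_names) + list(cl.y_names),
        "block": ["X"] * len(cl.x_names) + ["Y"] * len(cl.y_names),
        "factor1": np.concatenate([cl.x_correlations[:, 0],
                                   cl.y_correlations[:, 0]]),
        "factor2": np.concatenate([cl.x_correlations[:, 1],
                                   cl.y_correlations[:, 1]]),
    }), "correlation_loadings.csv")

    summary = summarize(result)
    (outdir / "summary.txt").write_text(summary)
    manifest.outputs.append("summary.txt")
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True))
    return manifest


def summarize(result: PipelineResult) -> str:
    venn = result.key_set.venn_counts()
    perm = result.permutation
    lines = [
        "aroma pipeline summary",
        "======================",
        f"samples: {sorted(set(result.quantified['sample_id']))} "
        f"[quantified.csv]",
        f"compounds quantified: "
        f"{result.quantified['compound_name'].nunique()} [quantified.csv]",
        f"rOAV pass counts: "
        + ", ".join(f"{s}={len(v)}" for s, v in
                    sorted(result.key_set.per_sample_roav_pass.items()))
        + " [roav.csv]",
        f"rOAV cross-sample intersection: {venn['roav_intersection']} "
        f"[venn_counts.csv]",
        f"GC-O consensus compounds: {venn['gco_consensus']} [gco_consensus.csv]",
        f"key aroma compounds (rOAV ∩ GC-O): {venn['key_compounds']} "
        f"[venn_membership.csv]",
        f"sample clusters (k=2): {result.sample_clusters} "
        f"[sample_clusters.csv]",
        f"PCA R2X (2 comps): {result.pca.R2X:.3f}",
        f"OPLS-DA contrast {result.contrast[0]} vs rest: "
        f"R2Y={result.opls.R2Y:.3f}, Q2={result.opls_q2:.3f} "
        f"({result.opls.meta['n_orth']} orth comps)",
        f"VIP > 1: {sorted(result.vip[result.vip > 1].index.tolist())} "
        f"[vip.csv]",
        f"permutation test (n={perm.n_permutations}): p={perm.p_value:.4g} "
        f"[permutation_scatter.csv]",
        f"CV-ANOVA: F={result.cv_anova.F:.2f} "
        f"(df {result.cv_anova.df1},{result.cv_anova.df2}), "
        f"p={result.cv_anova.p_value:.4g}",
        f"PLSR (2 factors): R2X={result.plsr.meta['r2x_cum']:.3f}, "
        f"R2Y={result.plsr.meta['r2y_cum']:.3f} [correlation_loadings.csv]",
        f"ANOVA-LSD letters per key compound [anova_letters.csv]",
    ]
    return "\n".join(lines) + "\n"


def file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
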