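"""End-to-end orchestration: normalize -> profile -> embed -> tracks ->
cluster -> heritage -> dosage, from a single config, with a run manifest.

Every stage consumes and produces plain CSV files in the output
directory; a ``manifest.json`` records the seed, the full config and a
hash of it, package and library versions, and per-stage row accounting
(clones in / excluded / out) so filtering effects are auditable.  A fixed
config and seed reproduce every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clone_io import CloneTable, read_clone_table, write_clone_table
from .cluster_order import cut_k, hcluster, optimal_leaf_order, similarity_from_points, to_newick
from .dosage_correlation import correlate_compositions, significance_matrix
from .embedding import (classical_mds, conditional_affinities, embed_tsne,
                        joint_affinities, lineage_ancestry_distance, pca_scores)
from .errors import ConfigError
from .heritage import classify_inheritance, heritage_summary, pooled_inheritance_rate, switch_direction_matrix
from .lineages import LINEAGES
from .normalization import apply_donor_factors, donor_size_factors, lineage_size_factors, log10_transform
from .potency_metrics import (PositivityThresholds, bias_yield_association,
                              potency_composition, profile_table)
from .synthetic_data import (SimulationParams, simulate_clone_table,
                             simulate_dosage_tables, simulate_granddaughter_families)
from .tracks import assign_tracks, assignment_frame, build_backbones, distance_to_tracks

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Run configuration; defaults are the analysis defaults throughout
    (perplexity 20, backbone threshold 0.7, positivity 7 with 2 for CDP,
    four-cluster cut, pseudocount 1)."""

    input_path: str | None = None
    synthetic: bool = False
    n_clones_scale: float = 1.0
    seed: int = 0
    threshold_default: int = 7
    threshold_cdp: int = 2
    perplexity: float = 20.0
    tsne_iterations: int = 1000
    backbone_threshold: float = 0.7
    pseudocount: float = 1.0
    k_clusters: int = 4
    donor_normalize: bool = True
    lineage_normalize: bool = True
    n_families: int = 0
    dosage_noise_sd: float = 3.0
    output_dir: str = "clonepotency_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def paper_defaults() -> PipelineConfig:
    """The frozen default analysis profile."""
    return PipelineConfig()


def _thresholds(config: PipelineConfig) -> PositivityThresholds:
    return PositivityThresholds(default=config.threshold_default,
                                per_subset={"CDP": config.threshold_cdp})


def _load_table(config: PipelineConfig) -> CloneTable:
    if config.input_path:
        return read_clone_table(config.input_path)
    if not config.synthetic:
        raise ConfigError("config names no input_path and synthetic is false")
    params = SimulationParams(seed=config.seed)
    if config.n_clones_scale != 1.0:
        params.n_clones = {s: max(1, int(round(n * config.n_clones_scale)))
                           for s, n in params.n_clones.items()}
    return simulate_clone_table(params)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write artifacts; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    accounting: dict = {}
    try:
        table = _load_table(config)
        write_clone_table(table, out / "clones.csv")
        accounting["input"] = {"clones_in": len(table)}

        # profiles and bias statistics
        thresholds = _thresholds(config)
        prof = profile_table(table, thresholds)
        prof.to_csv(out / "profiles.csv", index=False)
        potency_composition(table, thresholds).to_csv(out / "composition.csv", index=False)
        productive = prof["productive"].to_numpy()
        accounting["profile"] = {"clones_in": len(prof),
                                 "excluded_unproductive": int((~productive).sum()),
                                 "clones_out": int(productive.sum())}
        from .potency_metrics import bias_profile  # per-clone objects for association
        profiles = [bias_profile(rec, thresholds) for rec, ok in zip(table, productive) if ok]
        assoc = bias_yield_association(profiles)
        assoc.equipotency_hist.to_csv(out / "equipotency_hist.csv", index=False)
        assoc.bias_hist.to_csv(out / "bias_hist.csv", index=False)
        pd.DataFrame([{
            "equipotency_pct_below_half": assoc.equipotency_pct_below_half,
            "bias_pct_below_half": assoc.bias_pct_below_half,
            "spearman_equipotency_vs_log_yield": assoc.spearman_equipotency_vs_log_yield,
            "spearman_bias_vs_log_yield": assoc.spearman_bias_vs_log_yield,
            "n_non_unipotent": assoc.n_non_unipotent,
        }]).to_csv(out / "bias_stats.csv", index=False)

        # normalization
        donor_f = donor_size_factors(table)
        donor_f.to_frame().to_csv(out / "donor_factors.csv", index=False)
        Y = apply_donor_factors(table, donor_f) if config.donor_normalize \
            else table.yields().astype(float)
        sub = Y[productive]
        if config.lineage_normalize:
            lineage_f, sub = lineage_size_factors(sub)
            lineage_f.to_frame().to_csv(out / "lineage_factors.csv", index=False)
        X = log10_transform(sub, pseudocount=config.pseudocount)

        # embedding
        cond, _sigma = conditional_affinities(X, perplexity=config.perplexity)
        aff = joint_affinities(cond, perplexity=config.perplexity)
        emb = embed_tsne(aff, seed=config.seed, n_iter=config.tsne_iterations)
        ids = table.clone_ids()[productive]
        pd.DataFrame({"clone_id": ids, "dim1": emb.coords[:, 0], "dim2": emb.coords[:, 1]}
                     ).to_csv(out / "embedding.csv", index=False)
        pca = pca_scores(X)
        pd.DataFrame(pca.scores[:, :2], columns=["PC1", "PC2"]).assign(clone_id=ids) \
            .to_csv(out / "pca.csv", index=False)
        D = lineage_ancestry_distance(table)
        pd.DataFrame(D, index=list(LINEAGES), columns=list(LINEAGES)) \
            .to_csv(out / "lineage_distance.csv")
        mds_coords, mds_eig = classical_mds(D, k=2)
        pd.DataFrame({"lineage": list(LINEAGES), "dim1": mds_coords[:, 0],
                      "dim2": mds_coords[:, 1]}).to_csv(out / "lineage_mds.csv", index=False)
        accounting["embedding"] = {"clones_in": int(productive.sum()),
                                   "kl_final": emb.kl_final}

        # tracks
        commit = prof.loc[productive, [f"commit_{l}" for l in LINEAGES]].to_numpy()
        bb = build_backbones(commit, emb.coords, threshold=config.backbone_threshold)
        dist = distance_to_tracks(emb.coords, bb)
        assign = assign_tracks(dist)
        assignment_frame(ids, assign).to_csv(out / "tracks.csv", index=False)
        accounting["tracks"] = {"clones_in": len(ids),
                                "empty_backbones": bb.empty_lineages}

        # clustering
        tree = hcluster(X, labels=list(ids))
        perm, objective = optimal_leaf_order(tree, similarity_from_points(X))
        labels = cut_k(tree, config.k_clusters)
        pd.DataFrame({"clone_id": ids, "cluster": labels,
                      "leaf_position": np.argsort(perm)}).to_csv(out / "clusters.csv", index=False)
        (out / "dendrogram.nwk").write_text(to_newick(tree) + "\n")
        accounting["cluster"] = {"clones_in": len(ids), "k": config.k_clusters,
                                 "leaf_order_objective": objective}

        # heritage (synthetic tracing arm)
        if config.n_families > 0:
            params = SimulationParams(seed=config.seed)
            fams = simulate_granddaughter_families(params, config.n_families)
            calls = [classify_inheritance(f) for f in fams]
            heritage_summary(calls).to_csv(out / "heritage.csv", index=False)
            switch_direction_matrix(calls).to_csv(out / "switch_matrix.csv")
            rate, se, n = pooled_inheritance_rate(calls)
            accounting["heritage"] = {"families": len(fams), "granddaughters": n,
                                      "inherited_rate": rate, "rate_se": se}

        # dosage correlation (synthetic gate tables)
        if config.synthetic:
            params = SimulationParams(seed=config.seed)
            tables = simulate_dosage_tables(params, noise_sd=config.dosage_noise_sd)
            r = correlate_compositions(tables)
            r.to_csv(out / "dosage_r.csv")
            significance_matrix(r, n=tables.n_subsets).to_csv(out / "dosage_p.csv")
            accounting["dosage"] = {"n_subsets": tables.n_subsets}
    except Exception as exc:
        stage = list(accounting)[-1] if accounting else "input"
        logger.error("pipeline aborted after stage %r: %s", stage, exc)
        raise

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "accounting": accounting,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def summarize_division_potency(table: CloneTable,
                               thresholds: PositivityThresholds | None = None) -> pd.DataFrame:
    """Per-CFSE-division mean +/- s.e.m. of clone totals and potency classes.

    Only division-tracked clones contribute; an empty frame (with a
    logged notice) results when none are tracked.
    """
    prof = profile_table(table, thresholds)
    div = table.frame["division"]
    tracked = div.notna().to_numpy()
    if not tracked.any():
        logger.info("no division-tracked clones; empty division summary")
        return pd.DataFrame(columns=["division", "n", "mean_total", "sem_total",
                                     "clonal_efficiency", "mean_n_lineages"])
    rows = []
    sub = prof[tracked].assign(division=div[tracked].astype(int).to_numpy())
    for d, grp in sub.groupby("division"):
        totals = grp["total_yield"].to_numpy(dtype=float)
        rows.append(dict(
            division=int(d), n=len(grp),
            mean_total=float(totals.mean()),
            sem_total=float(totals.std(ddof=1) / np.sqrt(len(grp))) if len(grp) > 1 else np.nan,
            clonal_efficiency=float(grp["productive"].mean()),
            mean_n_lineages=float(grp["n_lineages"].mean()),
        ))
    return pd.DataFrame(rows).sort_values("division").reset_index(drop=True)
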