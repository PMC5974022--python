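"""End-to-end orchestration: config, staged run directory, manifest.

A run takes either a synthetic cohort spec or paths to the three input tables
(taxon counts, NMR buckets, clinical), then executes, per cohort group:
depth normalization -> relative abundances -> mean-abundance filter ->
alpha/beta diversity + PCoA -> NMR normalization (total integral + PQN) ->
merged FMN construction, community detection and summary -> clinical
cross-correlation -> consensus HE risk ranking. Every output lands in the
run directory together with a manifest recording seeds, settings and a
config hash, so a rerun with the same manifest reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import fmnet
from fmnet import abundance as ab
from fmnet import clinical_crosscorr as cc
from fmnet import fmn_network as net
from fmnet import he_risk as hr
from fmnet import nmr_preprocessing as nmr
from fmnet import synthetic_data as syn
from fmnet._utils import read_table, write_table

log = logging.getLogger("fmnet")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults mirror the reference settings
    (0.5% abundance filter, |r| > 0.7, Louvain resolution 1, alpha = 0.05,
    total integral 1000)."""

    out_dir: str = "fmnet_run"
    seed: int = 0
    # inputs: either paths ...
    taxa_path: str | None = None
    nmr_path: str | None = None
    clinical_path: str | None = None
    # ... or a synthetic cohort
    synthetic: dict | None = None
    # analysis settings
    filter_threshold: float = 0.005
    corr_threshold: float = 0.7
    resolution: float = 1.0
    n_restarts: int = 20
    keystone_k: int = 5
    alpha: float = 0.05
    rarefy_depth: int | None = None  # None -> least-rich sample
    nmr_total: float = 1000.0
    group_column: str = "group"
    he_column: str = "HE"
    he_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.synthetic is None:
            missing = [
                p
                for p in (self.taxa_path, self.clinical_path)
                if p is None or not Path(p).exists()
            ]
            if missing or self.taxa_path is None:
                raise ValueError(
                    "config must give an existing taxa_path + clinical_path, "
                    "or a synthetic spec"
                )
            if self.nmr_path is not None and not Path(self.nmr_path).exists():
                raise ValueError(f"nmr_path does not exist: {self.nmr_path}")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must lie in (0, 1)")
        if not 0 <= self.filter_threshold < 1:
            raise ValueError("filter_threshold must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        spec = syn.SyntheticCohortSpec(**{**config.synthetic, "seed": config.seed})
        taxa, buckets, clinical, planted = syn.generate_cohort(spec)
        return taxa, buckets, clinical, planted
    taxa = ab.read_abundance_table(config.taxa_path)
    clinical = read_table(config.clinical_path)
    buckets = None
    if config.nmr_path:
        df = read_table(config.nmr_path)
        edges = [(i, i + 1) for i in range(df.shape[1])]  # opaque bucket ids
        buckets = nmr.NmrBucketMatrix(df, edges, "raw", provenance=["loaded"])
    return taxa, buckets, clinical, None


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    stage = "load-inputs"
    try:
        taxa, buckets, clinical, planted = _load_inputs(config)

        stage = "abundance-normalization"
        if taxa.kind == "counts":
            taxa_r = ab.rarefy(taxa, depth=config.rarefy_depth, seed=config.seed)
            taxa_rel = ab.to_relative(taxa_r)
        else:
            taxa_rel = taxa
        filtered = ab.filter_by_mean_abundance(taxa_rel, config.filter_threshold)
        filtered.write(out / "taxa_relative_filtered.tsv")

        stage = "diversity"
        write_table(ab.alpha_diversity(taxa_rel), out / "alpha_diversity.tsv")
        groups = clinical[config.group_column].astype(str).to_dict()
        for metric in ("bray_curtis", "yue_clayton"):
            dist = ab.beta_dissimilarity(taxa_rel, metric)
            dist.write(out / f"distance_{metric}.tsv")
            write_table(
                ab.within_group_mean_distance(dist, groups),
                out / f"within_group_{metric}.tsv",
            )
            coords, evals = ab.pcoa(dist, k=2)
            write_table(coords, out / f"pcoa_{metric}.tsv",
                        [f"eigenvalues={','.join(f'{e:.6g}' for e in evals)}"])

        stage = "nmr-normalization"
        met_matrix = None
        if buckets is not None:
            total = nmr.total_integral_normalize(buckets, config.nmr_total)
            met_matrix, quot = nmr.pqn_normalize(total)
            met_matrix.write(out / "nmr_normalized.tsv")
            write_table(quot.to_frame(), out / "pqn_quotients.tsv")

        stage = "fmn-network"
        summaries = {}
        for gname, gsamples in pd.Series(groups).groupby(pd.Series(groups)):
            ids = list(gsamples.index)
            if len(ids) < 4:
                log.warning("skipping network for tiny group %s", gname)
                continue
            sub_taxa = ab.AbundanceTable(filtered.df.loc[ids], kind="relative")
            if met_matrix is not None:
                merged = net.merge_features(sub_taxa, met_matrix.df.loc[ids])
            else:
                meta = pd.DataFrame(
                    {"kind": "taxon", "mean_rel_abund": sub_taxa.df.mean(axis=0)},
                    index=sub_taxa.df.columns,
                )
                merged = net.MergedFeatureMatrix(sub_taxa.df, meta)
            R, P = net.pearson_matrix(merged)
            network = net.build_network(R, merged, threshold=config.corr_threshold)
            net.node_metrics(network)
            partition = None
            if network.n_edges > 0:
                partition = net.detect_fmcs(
                    network,
                    resolution=config.resolution,
                    seed=config.seed,
                    n_restarts=config.n_restarts,
                )
            summary = net.network_summary(network, partition, config.keystone_k)
            summary.to_json(out / f"network_summary_{gname}.json")
            write_table(summary.to_table(), out / f"network_summary_{gname}.tsv")
            net.export_network(network, partition, out / f"network_{gname}.graphml")
            summaries[gname] = summary

        stage = "clinical-crosscorr"
        numeric = clinical.select_dtypes(include=[np.number]).drop(
            columns=[config.he_column], errors="ignore"
        )
        if numeric.shape[1] > 0:
            feats = filtered.df
            if met_matrix is not None:
                feats = pd.concat([feats, met_matrix.df], axis=1)
            xcorr = cc.crosscorrelate(feats, numeric, alpha=config.alpha)
            xcorr.write(out / "crosscorrelation.tsv")

        stage = "he-risk"
        if config.he_column in clinical.columns:
            y = clinical[config.he_column].astype(int)
            feats = filtered.df
            if met_matrix is not None:
                feats = pd.concat([feats, met_matrix.df], axis=1)
            feats = feats.loc[y.index.intersection(feats.index)]
            if y.loc[feats.index].nunique() == 2:
                std = hr.standardize(feats)
                report = hr.fit_consensus(
                    std,
                    y.loc[feats.index],
                    seed=config.seed,
                    config=hr.ConsensusConfig(**config.he_config),
                )
                report.write(out / "he_risk_report.tsv")
                write_table(hr.select_he_features(report), out / "he_risk_selected.tsv")
            else:
                log.warning("single-class HE labels; skipping risk model")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "fmnet",
        "version": fmnet.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages_completed": True,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
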