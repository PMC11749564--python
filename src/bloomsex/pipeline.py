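"""End-to-end pipeline driver: configuration, artifacts, logging.

``run_all`` executes taxonomy -> expression conditioning -> differential
expression -> profile clustering -> GO enrichment -> cross-study
comparison -> event detection -> constrained ordination, writing one
TSV/JSON artifact per stage. Every artifact embeds the configuration
hash so mixed-config artifact directories can be rejected; a single
seed drives all stage-local random substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, crossref, enrichment, events, expression, ordination, taxonomy
from .containers import CountMatrix, HomologyPanel
from .de import NBDifferentialExpression
from .simulate import SimulationConfig, simulate_all

log = logging.getLogger("bloomsex")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and a hint."""


@dataclass
class PipelineConfig:
    """Thresholds, paths and the seed for one pipeline run."""

    outdir: str = "bloomsex_out"
    seed: int = 0
    simulate: bool = True
    inputs: dict = field(default_factory=dict)  # paths when simulate=False
    sim_overrides: dict = field(default_factory=dict)

    rank: str = "class"
    evalue_max: float = taxonomy.EVALUE_MAX_18S_CLASS
    focal_taxon: str = "Pseudo-nitzschia_australis"
    min_focal_fraction: float = 0.05

    min_mean_per_day: float = 5.0
    de_alpha: float = 0.05
    n_clusters: int = 8
    k_grid: tuple | None = None
    merge_r: float = 0.9
    n_starts: int = 5
    min_de_in_go: int = 5
    overlap_threshold: float = 0.8
    transience_delta: float = 1.0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # a location, not an analysis parameter
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError(f"config: unknown keys {sorted(unknown)}")
        if "k_grid" in raw and raw["k_grid"] is not None:
            raw["k_grid"] = tuple(raw["k_grid"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# artifact IO with embedded config hash


def write_table(df: pd.DataFrame, path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bloomsex config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def artifact_hash(path) -> str | None:
    p = Path(path)
    if p.suffix == ".json":
        with open(p) as fh:
            data = json.load(fh)
        meta = data.get("_meta", {}) if isinstance(data, dict) else {}
        return meta.get("config_hash")
    with open(p) as fh:
        first = fh.readline()
    if first.startswith("# bloomsex config_hash="):
        return first.strip().split("=", 1)[1]
    return None


def check_artifact_dir(outdir) -> str:
    """Verify all artifacts in a directory share one config hash."""
    hashes = set()
    for p in sorted(Path(outdir).iterdir()):
        if p.suffix in (".tsv", ".json") and p.name != "pipeline.log":
            h = artifact_hash(p)
            if h:
                hashes.add(h)
    if len(hashes) > 1:
        raise StageError(f"artifacts: mixed config hashes in {outdir}: {sorted(hashes)}")
    return hashes.pop() if hashes else ""


def write_json(obj: dict, path, cfg_hash: str) -> None:
    obj = dict(obj)
    obj["_meta"] = {"config_hash": cfg_hash}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# input loading


def write_simulation(bundle: dict, outdir, cfg_hash: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm: CountMatrix = bundle["counts"]
    write_table(cm.counts, outdir / "counts.tsv", cfg_hash)
    write_table(cm.samples, outdir / "samples.tsv", cfg_hash)
    write_table(bundle["hits"], outdir / "hits.tsv", cfg_hash, index=False)
    write_table(bundle["taxmap"], outdir / "taxmap.tsv", cfg_hash, index=False)
    write_table(bundle["annotations"], outdir / "go.tsv", cfg_hash, index=False)
    panel: HomologyPanel = bundle["panel"]
    write_table(panel.homology, outdir / "homology.tsv", cfg_hash, index=False)
    write_table(panel.labels, outdir / "invitro_de.tsv", cfg_hash, index=False)
    write_table(bundle["environment"], outdir / "env.tsv", cfg_hash)
    with open(outdir / "truth.json", "w") as fh:
        fh.write(bundle["truth"].to_json())


def load_inputs(paths: dict) -> dict:
    """Load pipeline inputs from files (the non-simulated route)."""
    need = ("counts", "samples")
    for key in need:
        if key not in paths:
            raise StageError(f"inputs: missing required path {key!r}")
        if not Path(paths[key]).exists():
            raise StageError(f"inputs: file not found: {paths[key]} (key {key!r})")
    counts = read_table(paths["counts"], index_col=0)
    samples = read_table(paths["samples"], index_col=0)
    bundle: dict = {"counts": CountMatrix(counts, samples), "truth": None}
    if "hits" in paths:
        bundle["hits"] = taxonomy.read_hits(paths["hits"])
        bundle["taxmap_raw"] = read_table(paths["taxmap"])
    if "go" in paths:
        bundle["annotations"] = read_table(paths["go"])
    if "homology" in paths:
        bundle["panel"] = HomologyPanel(
            read_table(paths["homology"]), read_table(paths["invitro_de"])
        )
    if "env" in paths:
        bundle["environment"] = read_table(paths["env"], index_col=0)
    if "markers" in paths:
        bundle["markers"] = read_table(paths["markers"])
    return bundle


# ---------------------------------------------------------------------------
# the driver


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory artifacts dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {"config_hash": cfg_hash}

    current_stage = {"name": "inputs"}

    def stage(name):
        current_stage["name"] = name
        log.info("stage %s: start (config %s, seed %d)", name, cfg_hash, config.seed)

    try:
        # -- inputs --------------------------------------------------------
        stage("inputs")
        if config.simulate:
            sim_cfg = SimulationConfig(seed=config.seed, **config.sim_overrides)
            bundle = simulate_all(sim_cfg)
            write_simulation(bundle, outdir, cfg_hash)
        else:
            bundle = load_inputs(config.inputs)
        cm: CountMatrix = bundle["counts"]
        results["truth"] = bundle.get("truth")

        # -- taxonomy ------------------------------------------------------
        excluded: list = []
        if "hits" in bundle:
            stage("taxonomy")
            taxmap = (
                taxonomy.TaxonomyMap(bundle["taxmap_raw"])
                if "taxmap_raw" in bundle
                else taxonomy.TaxonomyMap(bundle["taxmap"])
            )
            assignments = taxonomy.assign_reads(
                bundle["hits"], taxmap, config.rank, config.evalue_max
            )
            read_samples = taxonomy.sample_of_read(assignments.index)
            abundance = taxonomy.relative_abundance(assignments, read_samples)
            write_table(abundance.fractions, outdir / "abundance.tsv", cfg_hash)
            excluded = taxonomy.exclude_low_focal_samples(
                abundance, config.focal_taxon, config.min_focal_fraction
            )
            excluded = [s for s in excluded if s in set(cm.sample_ids)]
            log.info("taxonomy: excluding %d low-focal samples: %s", len(excluded), excluded)
            results["abundance"] = abundance
            if excluded:
                cm = cm.subset_samples([s for s in cm.sample_ids if s not in set(excluded)])
        results["excluded_samples"] = excluded

        # -- expression conditioning ----------------------------------------
        stage("expression")
        cm = expression.filter_low_coverage(cm, config.min_mean_per_day)
        if cm.counts.shape[0] == 0:
            raise StageError("expression: no gene passes the coverage filter")
        s = expression.size_factors(cm.counts)
        transformed = expression.transform(cm.counts, s)
        pcs, var_frac, groups = expression.pca_group(
            transformed, k=3, samplesheet=cm.samples, seed=config.seed
        )
        write_table(pcs.assign(group=groups), outdir / "pca.tsv", cfg_hash)
        results.update(counts=cm, size_factors=s, transformed=transformed, pca=pcs,
                       pca_variance=var_frac, groups=groups)

        # -- differential expression ----------------------------------------
        stage("differential_expression")
        de_model = NBDifferentialExpression(cm, groups=groups, size_factors=s)
        de_res = de_model.fit()
        write_table(de_res.table, outdir / "de_results.tsv", cfg_hash, index=False)
        de_genes = sorted(de_res.de_union(config.de_alpha))
        results["de"] = de_res
        results["de_genes"] = de_genes
        log.info("de: %d genes in the DE union", len(de_genes))

        # -- pooling + log2FC ------------------------------------------------
        stage("pooling")
        pooled = expression.pool_replicates(cm)
        s_pooled = expression.size_factors(pooled.counts)
        lfc = expression.log2fc_over_median(pooled.counts, s_pooled)
        results.update(pooled=pooled, pooled_size_factors=s_pooled, log2fc=lfc)

        # -- clustering ------------------------------------------------------
        if not de_genes:
            log.warning("clustering: no DE genes; skipping clustering and detection")
            results["clusters"] = None
            report = events.assemble_report(
                events.TransientDetection(None, None, float("nan")), None, None, None
            )
            write_json(report, outdir / "event_report.json", cfg_hash)
            results["event_report"] = report
            return results
        stage("clustering")
        de_pooled = pooled.counts.loc[de_genes]
        k = config.n_clusters
        if config.k_grid:
            k, bic_curve = clustering.choose_k(
                de_pooled, s_pooled, config.k_grid, seed=config.seed, n_starts=config.n_starts
            )
            write_table(bic_curve.to_frame(), outdir / "bic.tsv", cfg_hash)
        fit = clustering.em_cluster(
            de_pooled, s_pooled, min(k, len(de_genes)), seed=config.seed, n_starts=config.n_starts
        )
        merged = fit.merge_similar(config.merge_r)
        write_table(merged.profiles, outdir / "profiles.tsv", cfg_hash)
        assign = merged.assignments
        write_table(
            pd.DataFrame(
                {
                    "cluster": assign,
                    "max_responsibility": merged.responsibilities.max(axis=1),
                }
            ),
            outdir / "clusters.tsv",
            cfg_hash,
        )
        results["clusters"] = merged

        # -- GO enrichment ----------------------------------------------------
        go_records = pd.DataFrame()
        if "annotations" in bundle:
            stage("enrichment")
            parts = []
            for klabel in merged.profiles.index:
                genes_k = assign.index[assign == klabel]
                rec = enrichment.go_enrichment(
                    genes_k,
                    bundle["annotations"],
                    min_de_in_go=config.min_de_in_go,
                    cluster_label=klabel,
                )
                parts.append(rec)
            go_records = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
            write_table(go_records, outdir / "enrichment.tsv", cfg_hash, index=False)
            sig = go_records[go_records["qvalue"] <= 0.05] if len(go_records) else go_records
            if len(sig):
                go_clusters = enrichment.collapse_redundant(
                    sig, bundle["annotations"], config.overlap_threshold
                )
                write_table(
                    pd.DataFrame(
                        {
                            "representative": [g.representative for g in go_clusters],
                            "members": [";".join(g.members) for g in go_clusters],
                        }
                    ),
                    outdir / "go_clusters.tsv",
                    cfg_hash,
                    index=False,
                )
                results["go_clusters"] = go_clusters
        results["enrichment"] = go_records

        # -- cross-study comparison --------------------------------------------
        cross = pd.DataFrame()
        if "panel" in bundle and not bundle["panel"].is_empty():
            stage("cross_study")
            cluster_sets = {
                str(klabel): set(assign.index[assign == klabel])
                for klabel in merged.profiles.index
            }
            cross = crossref.cross_enrich_all(cluster_sets, bundle["panel"])
            write_table(cross, outdir / "crossref.tsv", cfg_hash, index=False)
        results["cross"] = cross

        # -- markers ------------------------------------------------------------
        marker_table = None
        marker_map = {}
        if bundle.get("truth") is not None:
            marker_map = bundle["truth"].marker_genes
        elif "markers" in bundle:
            marker_map = dict(zip(bundle["markers"]["marker"], bundle["markers"]["gene"]))
        if marker_map:
            stage("markers")
            marker_table = crossref.marker_report(lfc, marker_map)
            write_table(marker_table, outdir / "markers.tsv", cfg_hash, index=False)
        results["markers"] = marker_table

        # -- event detection -----------------------------------------------------
        stage("event_detection")
        detection = events.detect_transient_cluster(merged.profiles, config.transience_delta)
        report = events.assemble_report(
            detection, assign, marker_table, cross, go_records, alpha=config.de_alpha
        )
        write_json(report, outdir / "event_report.json", cfg_hash)
        results["detection"] = detection
        results["event_report"] = report

        # -- ordination -------------------------------------------------------------
        if "environment" in bundle:
            stage("ordination")
            env = bundle["environment"]
            cols = [c for c in ordination.DEFAULT_COVARIATES if c in env.columns]
            env = env.loc[transformed.columns, cols]
            response = ordination.prepare_response(transformed.T)
            cca_res = ordination.cca(response, env)
            write_table(cca_res.sample_scores, outdir / "ordination.tsv", cfg_hash)
            write_json(
                {
                    "eigenvalues": list(map(float, cca_res.eigenvalues)),
                    "total_inertia": cca_res.total_inertia,
                    "proportion_constrained": cca_res.proportion_constrained,
                    "aliased": cca_res.aliased,
                    "response_shift": cca_res.metadata.get("response_shift"),
                },
                outdir / "ordination.json",
                cfg_hash,
            )
            results["cca"] = cca_res

        check_artifact_dir(outdir)
        log.info("pipeline complete; verdict=%s", report["sexual_reproduction_signal"])
        return results
    except StageError:
        raise
    except Exception as exc:  # name the failing stage for remediation
        raise StageError(
            f"stage {current_stage['name']!r} failed: {exc} "
            f"(check its inputs in {outdir} and the thresholds in the config)"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
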