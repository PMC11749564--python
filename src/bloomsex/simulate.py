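"""Synthetic diatom-bloom metatranscriptome generator with known truth.

Emulates the data shapes of a coastal bloom survey: duplicate samples
per day over ~10 sampling days, negative-binomial read counts for the
focal species with library-size variation, six temporal expression
archetypes including a one-day sexualization spike carrying designated
marker genes (MRP1/MRP2, Rad51, cathepsin D, gene 7488 homologs),
BLAST-like taxonomic hit tables, GO annotations with nested redundancy,
and an in vitro crossing-experiment label panel whose association with
the spike cluster has a controlled odds ratio. Every generator is
deterministic under a fixed seed, and ground truth is recorded so each
downstream stage can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TIMEPOINTS, CountMatrix, HomologyPanel

PHASES = ("early", "middle", "late")

#: Default marker names: two MRP1 homologs (the strongest spike genes),
#: two Rad51 and two cathepsin D homologs, the uncharacterized 7488
#: homolog, and MRP2 -- the sexualization marker panel of pennate diatoms.
DEFAULT_MARKER_NAMES = (
    "MRP1_h1",
    "MRP1_h2",
    "Rad51_h1",
    "Rad51_h2",
    "cathepsinD_h1",
    "cathepsinD_h2",
    "gene7488_h1",
    "MRP2_h1",
)

OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic bloom.

    Defaults mirror a two-replicate, ten-day survey with ~1200
    differentially expressed genes split over six temporal archetypes,
    the smallest of which is a 75-gene one-day spike with log2FC 8.
    """

    n_genes: int = 3000
    days: tuple = tuple(f"d{i + 1:02d}" for i in range(10))
    replicates_per_day: int = 2
    n_clusters: int = 6
    cluster_sizes: tuple = (300, 350, 180, 160, 135, 75)
    spike_day_index: int = 3
    spike_log2fc: float = 8.0
    phase_boundaries: tuple = (3, 7)
    dispersion: float = 0.2
    lib_size_log_sd: float = 0.3
    baseline_log2_mean: float = 6.5
    baseline_log2_sd: float = 1.5
    marker_gene_count: int = 8
    extra_rep_log2_sd: float = 0.0  # optional between-replicate extra noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_day <= 0:
            raise ConfigurationError("n_genes and replicates_per_day must be positive")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ConfigurationError("cluster_sizes length must equal n_clusters")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ConfigurationError("cluster sizes must be positive")
        if sum(self.cluster_sizes) > self.n_genes:
            raise ConfigurationError(
                f"cluster sizes sum to {sum(self.cluster_sizes)} > n_genes={self.n_genes}"
            )
        if not 0 <= self.spike_day_index < len(self.days):
            raise ConfigurationError("spike_day_index out of range")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be positive")
        lo, hi = self.phase_boundaries
        if not 0 < lo < hi < len(self.days):
            raise ConfigurationError("phase_boundaries must split days into three non-empty phases")
        if self.marker_gene_count > self.cluster_sizes[-1]:
            raise ConfigurationError("marker_gene_count exceeds spike cluster size")
        if self.lib_size_log_sd < 0:
            raise ConfigurationError("lib_size_log_sd must be non-negative")

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def spike_cluster(self) -> int:
        """Cluster label (1-based) of the one-day spike archetype."""
        return self.n_clusters

    def phase_of_day(self, day_index: int) -> str:
        lo, hi = self.phase_boundaries
        if day_index < lo:
            return "early"
        if day_index < hi:
            return "middle"
        return "late"


@dataclass
class BloomTruth:
    """Ground truth of one simulated bloom.

    ``assignments`` maps every gene to its planted cluster (0 for the
    non-DE background), ``profiles`` holds the per-cluster log2FC-vs-
    baseline value for every day (the background row is all zero), and
    ``size_factors`` are the planted per-sample library-size factors.
    """

    assignments: pd.Series
    marker_genes: dict
    spike_day: str
    profiles: pd.DataFrame  # clusters (0..K) x days
    size_factors: pd.Series
    config: SimulationConfig
    invitro_targets: dict = field(default_factory=dict)
    go_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        spike = self.config.spike_cluster
        for name, gene in self.marker_genes.items():
            if self.assignments.get(gene) != spike:
                raise ValueError(f"marker {name} ({gene}) not in spike cluster")
        if not (self.profiles.loc[0] == 0).all():
            raise ValueError("background profile must be all zero")

    def cluster_members(self, cluster: int) -> list:
        return list(self.assignments.index[self.assignments == cluster])

    def to_json(self) -> str:
        payload = {
            "assignments": self.assignments.to_dict(),
            "marker_genes": self.marker_genes,
            "spike_day": self.spike_day,
            "profiles": {str(k): row.to_dict() for k, row in self.profiles.iterrows()},
            "size_factors": self.size_factors.to_dict(),
            "config": dataclasses.asdict(self.config),
            "invitro_targets": {"|".join(map(str, k)): v for k, v in self.invitro_targets.items()},
            "go_truth": self.go_truth,
        }
        return json.dumps(payload, indent=1)


def cluster_profiles(config: SimulationConfig) -> pd.DataFrame:
    """Per-cluster log2FC-vs-baseline profiles over days (row 0 = background).

    The six default archetypes: (1) up during the middle phase, (2) a
    gradual monotone increase over the bloom, (3) high early / low
    afterwards, (4) high early, low middle, strong late recovery,
    (5) down during the late phase only, (6) a single-day transient
    spike of amplitude ``spike_log2fc``.
    """
    d = config.n_days
    lo, hi = config.phase_boundaries
    phase_vec = lambda e, m, l: np.array([e] * lo + [m] * (hi - lo) + [l] * (d - hi), float)  # noqa: E731
    archetypes = [
        phase_vec(-1.5, 1.5, -1.0),
        np.linspace(-1.2, 1.2, d),
        phase_vec(1.5, -1.5, -0.5),
        phase_vec(1.5, -1.5, 1.2),
        phase_vec(0.8, 0.8, -1.8),
    ]
    spike = np.zeros(d)
    spike[config.spike_day_index] = config.spike_log2fc
    archetypes.append(spike)
    if config.n_clusters > len(archetypes):
        raise ConfigurationError("at most 6 cluster archetypes are defined")
    # keep the spike archetype as the last cluster regardless of K
    rows = archetypes[: config.n_clusters - 1] + [spike]
    profiles = np.vstack([np.zeros(d)] + rows)
    return pd.DataFrame(profiles, index=range(config.n_clusters + 1), columns=list(config.days))


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for di, day in enumerate(config.days):
        for rep in range(1, config.replicates_per_day + 1):
            rows.append(
                {
                    "sample_id": f"{day}_r{rep}",
                    "day": day,
                    "replicate": rep,
                    "group": config.phase_of_day(di),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, BloomTruth]:
    """Draw the gene x sample NB count matrix and record ground truth.

    Counts for gene g in sample j are NB with mean
    ``s_j * 2**(b_g + p[k(g), day(j)])`` and shape ``1/dispersion``,
    where b_g is the gene's log2 baseline, p the planted cluster profile
    and s_j a lognormal library-size factor (geometric mean 1). Sampling
    uses the gamma-Poisson construction, which degrades gracefully to
    Poisson as dispersion -> 0.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene")
    samples = _sample_sheet(config)
    profiles = cluster_profiles(config)

    # scatter cluster members over the gene index
    assignment = np.zeros(config.n_genes, dtype=int)
    perm = rng.permutation(config.n_genes)
    pos = 0
    for k, size in enumerate(config.cluster_sizes, start=1):
        assignment[perm[pos : pos + size]] = k
        pos += size
    assignments = pd.Series(assignment, index=genes, name="cluster")

    spike_members = genes[assignment == config.spike_cluster]
    marker_ids = list(spike_members[: config.marker_gene_count])
    marker_genes = dict(zip(DEFAULT_MARKER_NAMES[: config.marker_gene_count], marker_ids))

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    log_s = rng.normal(0.0, config.lib_size_log_sd, len(samples))
    log_s -= log_s.mean()  # geometric mean 1
    size_factors = pd.Series(np.exp(log_s), index=samples.index, name="size_factor")

    day_index = np.array([list(config.days).index(d) for d in samples["day"]])
    effect = profiles.values[assignment][:, day_index]  # genes x samples
    log2_mean = baselines[:, None] + effect
    if config.extra_rep_log2_sd > 0:
        log2_mean = log2_mean + rng.normal(0.0, config.extra_rep_log2_sd, log2_mean.shape)
    mu = size_factors.values[None, :] * np.exp2(log2_mean)

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples.index), samples)
    truth = BloomTruth(
        assignments=assignments,
        marker_genes=marker_genes,
        spike_day=config.days[config.spike_day_index],
        profiles=profiles,
        size_factors=size_factors,
        config=config,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# taxonomic hit tables


def simulate_hits(
    config: SimulationConfig,
    taxa_profile: dict,
    n_reads: int,
    ambiguous_fraction: float,
    seed: int,
    sample_id: str = "s1",
    above_threshold_fraction: float = 0.1,
    evalue_threshold: float = 1e-70,
    ranks: tuple = ("class", "genus", "species"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a BLAST-outfmt6-like hit table plus a taxonomy map.

    Each read gets 1-5 hit records. A planted ``ambiguous_fraction`` of
    reads carry two minimum-e-value hits pointing at different taxa (so
    the consensus rule rejects them); ``above_threshold_fraction`` of
    reads have their best e-value above ``evalue_threshold`` (so the
    e-value filter is exercised). Remaining reads are drawn from
    ``taxa_profile`` and are cleanly assignable.
    """
    if not taxa_profile:
        raise ConfigurationError("taxa_profile must not be empty")
    fracs = np.array(list(taxa_profile.values()), float)
    if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("taxa_profile fractions must be non-negative and sum to 1")
    if not 0 <= ambiguous_fraction <= 1:
        raise ConfigurationError("ambiguous_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = list(taxa_profile.keys())

    subjects, lineages = [], []
    for t in taxa:
        for i in range(3):
            subjects.append(f"ref_{t}_{i}")
            lineages.append(";".join(f"{t}" if r == ranks[0] else f"{t}|{r}" for r in ranks))
    taxmap = pd.DataFrame({"subject_id": subjects, "lineage": lineages})

    true_taxon = rng.choice(len(taxa), size=n_reads, p=fracs)
    is_ambig = rng.random(n_reads) < ambiguous_fraction
    is_high_e = (~is_ambig) & (rng.random(n_reads) < above_threshold_fraction)

    log10_thr = np.log10(evalue_threshold)
    rows = []
    for i in range(n_reads):
        rid = f"{sample_id}.{i:06d}"
        t = true_taxon[i]
        if is_high_e[i]:
            best_e = 10.0 ** rng.uniform(log10_thr + 3, log10_thr + 15)
        else:
            best_e = 10.0 ** rng.uniform(log10_thr - 50, log10_thr - 2)
        best_subj = f"ref_{taxa[t]}_{rng.integers(3)}"
        rows.append((rid, best_subj, best_e))
        if is_ambig[i]:
            other = (t + 1 + rng.integers(len(taxa) - 1)) % len(taxa) if len(taxa) > 1 else t
            if len(taxa) == 1:
                # single-taxon profile cannot produce cross-taxon ties
                pass
            else:
                rows.append((rid, f"ref_{taxa[other]}_{rng.integers(3)}", best_e))
        for _ in range(rng.integers(0, 4)):
            t2 = rng.integers(len(taxa))
            rows.append((rid, f"ref_{taxa[t2]}_{rng.integers(3)}", best_e * 10.0 ** rng.uniform(1, 30)))

    hits = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])
    n = len(hits)
    hits["pident"] = np.round(rng.uniform(80, 100, n), 2)
    hits["length"] = rng.integers(80, 150, n)
    hits["mismatch"] = rng.integers(0, 10, n)
    hits["gapopen"] = rng.integers(0, 3, n)
    hits["qstart"] = 1
    hits["qend"] = hits["length"]
    hits["sstart"] = 1
    hits["send"] = hits["length"]
    hits["bitscore"] = np.round(-10.0 * np.log10(hits["evalue"] + 1e-300), 1)
    hits = hits[list(OUTFMT6_COLUMNS)]
    return hits, taxmap


def simulate_hit_series(
    config: SimulationConfig,
    focal_taxon: str = "Pseudo-nitzschia_australis",
    other_taxa: tuple = ("Chaetoceros_sp", "Thalassiosira_sp", "Guinardia_sp"),
    focal_trajectory: tuple | None = None,
    n_reads_per_sample: int = 2000,
    ambiguous_fraction: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample hit tables for the whole survey, concatenated.

    The focal species' relative abundance follows a bloom trajectory
    that collapses on the final sampling day (default minimum 0.02), so
    the downstream low-focal-abundance sample exclusion is exercised.
    """
    if focal_trajectory is None:
        d = config.n_days
        ramp = 0.2 + 0.45 * np.sin(np.linspace(0, np.pi, d)) ** 2
        ramp[-1] = 0.02
        focal_trajectory = tuple(ramp)
    if len(focal_trajectory) != config.n_days:
        raise ConfigurationError("focal_trajectory length must equal number of days")
    seed = config.seed if seed is None else seed
    samples = _sample_sheet(config)
    all_hits, taxmap = [], None
    for j, (sid, row) in enumerate(samples.iterrows()):
        di = list(config.days).index(row["day"])
        f = float(focal_trajectory[di])
        rest = (1.0 - f) / len(other_taxa)
        profile = {focal_taxon: f, **{t: rest for t in other_taxa}}
        hits, taxmap = simulate_hits(
            config,
            profile,
            n_reads=n_reads_per_sample,
            ambiguous_fraction=ambiguous_fraction,
            seed=seed + 1000 + j,
            sample_id=sid,
        )
        all_hits.append(hits)
    return pd.concat(all_hits, ignore_index=True), taxmap


# ---------------------------------------------------------------------------
# GO annotations


def simulate_annotations(
    config: SimulationConfig,
    truth: BloomTruth,
    n_go: int = 40,
    nesting: float = 0.5,
    seed: int | None = None,
    baseline_membership: float = 0.05,
    planted_or: float = 10.0,
    enriched_cluster: int | None = None,
) -> pd.DataFrame:
    """Gene -> GO annotation table with planted enrichment and redundancy.

    One designated GO term ("GO:1000000") is enriched in
    ``enriched_cluster`` (default: the spike cluster) at odds ratio
    ``planted_or`` against a ``baseline_membership`` background rate.
    With probability ``nesting`` each ordinary GO term spawns a strict
    subset term (overlap coefficient 1), exercising redundancy collapse.
    """
    if n_go < 2:
        raise ConfigurationError("n_go must be >= 2")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genes = truth.assignments.index.to_numpy()
    enriched_cluster = config.spike_cluster if enriched_cluster is None else enriched_cluster
    in_cluster = (truth.assignments == enriched_cluster).to_numpy()

    pairs = []
    nested_pairs = []

    odds0 = baseline_membership / (1 - baseline_membership)
    p1 = planted_or * odds0 / (1 + planted_or * odds0)
    p_mem = np.where(in_cluster, p1, baseline_membership)
    enriched_go = "GO:1000000"
    members = genes[rng.random(len(genes)) < p_mem]
    pairs.extend((g, enriched_go) for g in members)

    for i in range(n_go - 1):
        go = f"GO:{i + 1:07d}"
        size = int(rng.integers(20, 200))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        pairs.extend((g, go) for g in members)
        if rng.random() < nesting and len(members) >= 5:
            sub = f"GO:{i + 1:07d}s"
            k = max(3, int(0.6 * len(members)))
            sub_members = rng.choice(members, size=k, replace=False)
            pairs.extend((g, sub) for g in sub_members)
            nested_pairs.append((sub, go))

    annotations = pd.DataFrame(pairs, columns=["gene", "go_id"]).drop_duplicates(ignore_index=True)
    truth.go_truth = {
        "enriched_go": enriched_go,
        "enriched_cluster": int(enriched_cluster),
        "planted_or": float(planted_or),
        "nested_pairs": nested_pairs,
    }
    return annotations


# ---------------------------------------------------------------------------
# in vitro crossing-experiment labels


def default_invitro_targets(config: SimulationConfig) -> dict:
    """Planted (cluster, timepoint, direction) -> odds-ratio map.

    Mirrors the observed regime: a very strong T1-up association for
    the spike cluster (OR 24), strong down-regulation matches for the
    early-high clusters, and moderate up-regulation matches for the
    middle-up cluster.
    """
    spike = config.spike_cluster
    targets = {(spike, "T1", "up"): 24.0}
    if config.n_clusters >= 4:
        targets[(3, "T1", "down")] = 7.0
        targets[(4, "T1", "down")] = 8.0
    if config.n_clusters >= 1:
        targets[(1, "T2", "up")] = 2.5
        targets[(1, "T3", "up")] = 2.5
    return targets


def simulate_invitro_labels(
    config: SimulationConfig,
    truth: BloomTruth,
    target_or: dict | None = None,
    homolog_coverage: float = 0.7,
    seed: int | None = None,
    baseline_up: float = 0.08,
    baseline_down: float = 0.08,
) -> HomologyPanel:
    """Homology panel with planted cluster-by-label odds ratios.

    Each in situ gene maps to at most one in vitro gene with probability
    ``homolog_coverage``. Per timepoint, a gene's probability of an
    up/down label follows the baseline rates, boosted on the odds scale
    for (cluster, timepoint, direction) cells listed in ``target_or`` so
    the expected 2x2 odds ratio equals the target. Signed log2FCs are
    drawn consistently with the label; the vs-MT+ and vs-MT- columns are
    identical by default.
    """
    if not 0 <= homolog_coverage <= 1:
        raise ConfigurationError("homolog_coverage must be in (0, 1]")
    target_or = default_invitro_targets(config) if target_or is None else dict(target_or)
    for cell, orr in target_or.items():
        if not np.isfinite(orr) or orr <= 0:
            raise ConfigurationError(f"unattainable odds ratio {orr!r} for cell {cell}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    genes = truth.assignments.index.to_numpy()
    mapped_mask = rng.random(len(genes)) < homolog_coverage
    mapped = genes[mapped_mask]
    homology = pd.DataFrame(
        {"insitu_gene": mapped, "invitro_gene": [f"ivt_{g}" for g in mapped]}
    )

    clusters = truth.assignments.loc[mapped].to_numpy()
    rows = []
    for tp in TIMEPOINTS:
        p_up = np.full(len(mapped), baseline_up)
        p_down = np.full(len(mapped), baseline_down)
        for (cl, cell_tp, direction), orr in target_or.items():
            if cell_tp != tp:
                continue
            base = baseline_up if direction == "up" else baseline_down
            odds = orr * base / (1 - base)
            p_new = odds / (1 + odds)
            if direction == "up":
                p_up = np.where(clusters == cl, p_new, p_up)
            else:
                p_down = np.where(clusters == cl, p_new, p_down)
        overflow = p_up + p_down >= 1.0
        if overflow.any():
            bad = [
                cell
                for cell in target_or
                if (clusters == cell[0]).any() and cell[1] == tp
            ]
            raise ConfigurationError(
                f"unattainable odds ratios at {tp}: cells {bad} drive p_up+p_down >= 1"
            )
        u = rng.random(len(mapped))
        direction = np.where(u < p_up, "up", np.where(u < p_up + p_down, "down", "ns"))
        lfc = np.where(
            direction == "up",
            0.5 + np.abs(rng.normal(2.0, 0.7, len(mapped))),
            np.where(
                direction == "down",
                -(0.5 + np.abs(rng.normal(2.0, 0.7, len(mapped)))),
                rng.normal(0.0, 0.3, len(mapped)),
            ),
        )
        for g, d, f in zip(homology["invitro_gene"], direction, lfc):
            rows.append((g, tp, round(float(f), 4), round(float(f), 4), d))

    labels = pd.DataFrame(
        rows,
        columns=["invitro_gene", "timepoint", "vs_plus_log2fc", "vs_minus_log2fc", "direction"],
    )
    truth.invitro_targets = target_or
    return HomologyPanel(homology, labels)


# ---------------------------------------------------------------------------
# environmental covariates


def simulate_environment(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Sample x covariate table of bloom-period environmental conditions.

    Smooth day-level trends plus replicate-level noise for PAR,
    salinity, temperature, chlorophyll fluorescence, turbidity and tidal
    amplitude — the covariate set used for the constrained ordination
    (rainfall and nutrients are not generated).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 7919)
    samples = _sample_sheet(config)
    d = config.n_days
    t = np.linspace(0, 1, d)
    day_vals = {
        "par": 293 + 80 * np.sin(2 * np.pi * t) + rng.normal(0, 15, d),
        "salinity": 34.2 + 0.4 * t + rng.normal(0, 0.05, d),
        "temperature": 11.5 + 1.0 * t + rng.normal(0, 0.1, d),
        "fluorescence": 2.0 + 3.0 * np.sin(np.pi * t) ** 2 + rng.normal(0, 0.2, d),
        "turbidity": 1.5 + 0.8 * t + rng.normal(0, 0.1, d),
        "tidal_amplitude": 3.5 + 1.5 * np.cos(2 * np.pi * t) + rng.normal(0, 0.1, d),
    }
    day_index = {day: i for i, day in enumerate(config.days)}
    rows = {}
    for var, vals in day_vals.items():
        per_sample = np.array([vals[day_index[d_]] for d_ in samples["day"]])
        rows[var] = per_sample + rng.normal(0, 0.02 * (np.std(vals) + 1e-9), len(samples))
    return pd.DataFrame(rows, index=samples.index)


# ---------------------------------------------------------------------------
# one-call bundle for the CLI / pipeline


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input from one config (single seed)."""
    cm, truth = simulate_counts(config)
    hits, taxmap = simulate_hit_series(config)
    annotations = simulate_annotations(config, truth)
    panel = simulate_invitro_labels(config, truth)
    env = simulate_environment(config)
    return {
        "counts": cm,
        "truth": truth,
        "hits": hits,
        "taxmap": taxmap,
        "annotations": annotations,
        "panel": panel,
        "environment": env,
    }
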