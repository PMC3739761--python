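"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generator emulates a three-stage injury time course (uninjured control
plus two post-injury stages) with 2 control and 3 injured replicates,
log-normal baseline expression, planted fold changes, a detection limit
controlling confidence-interval lower bounds, a scale-free interaction
network with planted hub genes, per-gene isoform structure with planted
major-isoform switch events, and Ct tables consistent with the planted fold
changes.  Every planted quantity is recorded in a :class:`GroundTruth` so
downstream stages can be validated without any external download.

Noise model: multiplicative log-normal on FPKM (additive Gaussian on log2),
the standard bulk-expression assumption.  Confidence bounds are symmetric
on the log scale with half-width a + b/√(FPKM+ε) (wider near the detection
limit) and a linear-scale subtraction proportional to the detection limit,
so estimates near or below the limit have a zero lower bound with high
probability; the constants are calibrated so that pooled reliability at
0.1 FPKM is ≈ 0.99 under the default configuration.

A single global seed drives everything; each sub-generator derives its own
stream from (seed, fixed offset), so a fixed seed fixes every emitted table
bitwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd

from .containers import (
    EdgeList,
    ExpressionStudy,
    GeneSetCollection,
    ValidationError,
)

# fixed stream offsets for the sub-generators
_STREAM_STUDY, _STREAM_NETWORK, _STREAM_ISOFORM, _STREAM_QPCR = 0, 1, 2, 3
_STREAM_ANNOT, _STREAM_SETS = 4, 5


def _default_isoform_probs() -> dict[int, float]:
    # 99% of genes carry 1-5 isoforms; a thin tail reaches 12
    probs = {1: 0.44, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05}
    tail = 0.01 / 7
    probs.update({k: tail for k in range(6, 13)})
    return probs


@dataclass
class IsoformConfig:
    count_probs: dict[int, float] = field(default_factory=_default_isoform_probs)
    switch_fraction: float = 0.05
    proportion_noise_sd: float = 0.2  # log2 jitter on per-sample proportions

    def __post_init__(self) -> None:
        if any(k < 1 or k > 12 for k in self.count_probs):
            raise ValidationError("isoform counts must lie in 1..12")
        total = sum(self.count_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError("isoform count probabilities must sum to 1")
        if not 0 <= self.switch_fraction <= 1:
            raise ValidationError("switch_fraction must be in [0, 1]")


@dataclass
class NetworkConfig:
    n_nodes: int = 300
    attachment: int = 2        # preferential-attachment edges per new node
    n_hubs: int = 5
    hub_min_degree: int = 25

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError("network needs at least 2 nodes")
        if self.n_hubs < 0 or self.n_hubs > self.n_nodes:
            raise ValidationError("n_hubs must be in [0, n_nodes]")


@dataclass
class QpcrConfig:
    housekeeping_gene: str = "Hprt"
    housekeeping_ct: float = 20.0
    ct_noise_sd: float = 0.1   # per-reaction cycle noise
    n_technical: int = 3


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults emulate the study design."""

    n_genes: int = 2000
    stages: tuple[str, ...] = ("CTR", "D2", "D7")
    replicates: tuple[int, ...] = (2, 3, 3)
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    fraction_silent: float = 0.05
    detection_limit: float = 0.1
    fraction_up: float = 0.05
    fraction_down: float = 0.05
    effect_log2_mean: float = 2.0   # |log2 FC| ~ Normal(2, 0.5) truncated ≥ 1
    effect_log2_sd: float = 0.5
    effect_log2_min: float = 1.0
    noise_sd: float = 0.25          # replicate noise, log2 scale
    ci_halfwidth_a: float = 0.08    # log2 half-width far from the limit
    ci_halfwidth_b: float = 0.05    # growth term toward the limit
    background_log2_mean: float = -1.5  # silent-gene background, log2 units
    background_log2_sd: float = 1.0     # relative to the detection limit
    isoforms: IsoformConfig = field(default_factory=IsoformConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_silent", "fraction_up", "fraction_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.fraction_up + self.fraction_down > 1:
            raise ValidationError("fraction_up + fraction_down must not exceed 1")
        if self.detection_limit <= 0:
            raise ValidationError("detection_limit must be positive")
        if len(self.stages) != len(self.replicates):
            raise ValidationError("stages and replicates lengths differ")
        if any(r < 2 for r in self.replicates):
            raise ValidationError("at least 2 replicates per stage")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for stage, n_rep in zip(self.stages, self.replicates):
            for r in range(1, n_rep + 1):
                rows.append({"sample_id": f"{stage}_r{r}", "stage": stage,
                             "replicate": r})
        return pd.DataFrame(rows).set_index("sample_id")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream validation."""

    stage_means: pd.DataFrame              # genes × stages, true FPKM
    de: dict[str, pd.DataFrame]            # contrast name -> gene truth table
    silent: set[str]
    detection_limit: float
    hubs: list[str] = field(default_factory=list)
    prime_candidate: str | None = None     # hub carrying top degree + top FC
    switches: pd.DataFrame | None = None   # per-gene isoform switch truth
    isoform_proportions: dict | None = None
    qpcr_folds: pd.DataFrame | None = None

    def de_genes(self, contrast: str, direction: str | None = None) -> set[str]:
        t = self.de[contrast]
        if direction is None:
            return set(t.index[t["label"] != "none"])
        return set(t.index[t["label"] == direction])


def _contrast_name(treated: str, control: str) -> str:
    return f"{treated}_vs_{control}"


def simulate_study(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Gene-level expression study with confidence bounds, plus ground truth."""
    rng = config.rng(_STREAM_STUDY)
    genes = config.gene_ids()
    n = config.n_genes
    control, *injured = config.stages

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean,
                                 config.baseline_log2_sd, size=n)
    silent_mask = rng.random(n) < config.fraction_silent
    baseline[silent_mask] = 0.0

    stage_means = pd.DataFrame(
        {s: baseline.copy() for s in config.stages},
        index=pd.Index(genes, name="gene"),
    )
    de: dict[str, pd.DataFrame] = {}
    for stage in injured:
        u = rng.random(n)
        up = (~silent_mask) & (u < config.fraction_up)
        down = (~silent_mask) & (u >= config.fraction_up) & (
            u < config.fraction_up + config.fraction_down
        )
        mag = np.maximum(
            rng.normal(config.effect_log2_mean, config.effect_log2_sd, size=n),
            config.effect_log2_min,
        )
        delta = np.where(up, mag, np.where(down, -mag, 0.0))
        stage_means[stage] = baseline * 2.0**delta
        de[_contrast_name(stage, control)] = pd.DataFrame(
            {
                "true_log2_fc": delta,
                "label": np.select([up, down], ["up", "down"], default="none"),
            },
            index=stage_means.index,
        )

    samples = config.sample_table()
    truth_per_sample = stage_means[samples["stage"]].to_numpy()
    noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=truth_per_sample.shape)
    observed = truth_per_sample * noise

    d = config.detection_limit
    # truly silent transcripts still register a small spurious background
    # signal (misassigned fragments), proportional to the detection limit
    n_silent = int(silent_mask.sum())
    if n_silent:
        observed[silent_mask, :] = d * 2.0 ** rng.normal(
            config.background_log2_mean,
            config.background_log2_sd,
            size=(n_silent, observed.shape[1]),
        )
    halfwidth = config.ci_halfwidth_a + config.ci_halfwidth_b / np.sqrt(
        observed + 1e-6
    )
    u_lo = rng.uniform(0.75, 1.75, size=observed.shape)
    u_hi = rng.uniform(0.75, 1.75, size=observed.shape)
    ci_lo = np.maximum(0.0, observed * 2.0**-halfwidth - d * u_lo)
    ci_hi = observed * 2.0**halfwidth + d * u_hi

    cols = list(samples.index)
    idx = stage_means.index
    study = ExpressionStudy(
        values=pd.DataFrame(observed, index=idx, columns=cols),
        samples=samples,
        ci_lo=pd.DataFrame(ci_lo, index=idx, columns=cols),
        ci_hi=pd.DataFrame(ci_hi, index=idx, columns=cols),
        stage_order=list(config.stages),
    )
    truth = GroundTruth(
        stage_means=stage_means,
        de=de,
        silent=set(np.asarray(genes)[silent_mask]),
        detection_limit=d,
    )
    return study, truth


def simulate_network(
    config: NetworkConfig,
    gene_ids: list[str],
    seed_rng: np.random.Generator,
    hub_genes: list[str] | None = None,
) -> tuple[EdgeList, list[str]]:
    """Scale-free-like interaction network over ``gene_ids`` with planted hubs.

    A preferential-attachment graph is grown over the first ``n_nodes`` gene
    ids; the earliest nodes (naturally the highest-degree ones) are the
    planted hubs, topped up with extra edges until each reaches the
    configured minimum degree.  The first hub is additionally wired to hold
    the strictly largest degree in the emitted graph.  When ``hub_genes``
    is given, those ids occupy the hub positions.
    """
    n = config.n_nodes
    if n > len(gene_ids):
        raise ValidationError("n_nodes exceeds the number of available genes")
    m = max(1, min(config.attachment, n - 1))
    g = nx.barabasi_albert_graph(n, m, seed=int(seed_rng.integers(2**31)))
    nodes = list(gene_ids[:n])
    if hub_genes is not None:
        if len(hub_genes) != config.n_hubs:
            raise ValidationError("hub_genes length must equal n_hubs")
        others = [gid for gid in nodes if gid not in set(hub_genes)]
        nodes = list(hub_genes) + others[: n - len(hub_genes)]
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    hubs = nodes[: config.n_hubs]
    for hub in hubs:
        candidates = [v for v in nodes if v != hub and not g.has_edge(hub, v)]
        need = config.hub_min_degree - g.degree(hub)
        if need > 0:
            extra = seed_rng.choice(len(candidates), size=min(need, len(candidates)),
                                    replace=False)
            g.add_edges_from((hub, candidates[i]) for i in extra)
    if hubs:
        prime = hubs[0]
        top_other = max((d for v, d in g.degree() if v != prime), default=0)
        need = top_other + 3 - g.degree(prime)
        if need > 0:
            candidates = [v for v in nodes if v != prime and not g.has_edge(prime, v)]
            extra = seed_rng.choice(len(candidates), size=min(need, len(candidates)),
                                    replace=False)
            g.add_edges_from((prime, candidates[i]) for i in extra)
    return EdgeList.from_pairs(g.edges()), hubs


def simulate_isoforms(
    config: SimulationConfig,
    truth: GroundTruth,
    study: ExpressionStudy,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Isoform-level study consistent with the gene-level study.

    Per-sample isoform values are the gene's observed value split by jittered
    stage proportions, so isoform values sum exactly to the gene value in
    every sample.  Switch genes reverse the dominance of two isoforms across
    the time course (one declines while the other rises); all other genes
    keep their proportions constant, so the true major isoform is stable.
    """
    iso_cfg = config.isoforms
    rng = config.rng(_STREAM_ISOFORM)
    genes = list(study.features)
    counts_support = np.array(sorted(iso_cfg.count_probs))
    counts_probs = np.array([iso_cfg.count_probs[k] for k in counts_support])
    n_iso = rng.choice(counts_support, size=len(genes), p=counts_probs)

    # switch events are only meaningful where a major isoform is defined:
    # restrict planting to multi-isoform genes expressed in every stage
    expressed = truth.stage_means.min(axis=1) >= 2.0 * truth.detection_limit
    multi = [g for g, k in zip(genes, n_iso) if k >= 2 and expressed.get(g, False)]
    n_switch = int(round(iso_cfg.switch_fraction * len(genes)))
    switch_set = set(
        rng.choice(multi, size=min(n_switch, len(multi)), replace=False)
    )

    stages = study.stages
    sample_stage = study.samples["stage"].to_numpy()
    iso_rows, iso_ids, gene_of = [], [], []
    truth_rows = []
    proportions: dict[str, pd.DataFrame] = {}
    gene_values = study.values.to_numpy()
    for gi, (gene, k) in enumerate(zip(genes, n_iso)):
        ids = [f"{gene}.{j}" for j in range(1, k + 1)]
        base = np.sort(rng.dirichlet(np.ones(k)))[::-1]
        per_stage = np.tile(base, (len(stages), 1))  # stages × isoforms
        if gene in switch_set:
            hi, lo = 0, 1  # dominant and runner-up isoform positions
            ramp = np.linspace(0.0, 1.0, len(stages))
            for si, t in enumerate(ramp):
                p = base.copy()
                p[hi] = (1 - t) * 0.70 + t * 0.20
                p[lo] = (1 - t) * 0.20 + t * 0.70
                rest = base[2:].sum()
                if rest > 0:
                    p[2:] = base[2:] * (1 - p[hi] - p[lo]) / rest
                else:
                    scale = p[hi] + p[lo]
                    p[hi], p[lo] = p[hi] / scale, p[lo] / scale
                per_stage[si] = p
        prop_df = pd.DataFrame(per_stage, index=stages, columns=ids)
        proportions[gene] = prop_df

        jitter = 2.0 ** rng.normal(
            0.0, iso_cfg.proportion_noise_sd, size=(len(sample_stage), k)
        )
        stage_idx = [stages.index(s) for s in sample_stage]
        p_samples = per_stage[stage_idx] * jitter
        p_samples /= p_samples.sum(axis=1, keepdims=True)
        iso_rows.append((gene_values[gi][:, None] * p_samples).T)  # k × samples
        iso_ids.extend(ids)
        gene_of.extend([gene] * k)

        majors = {s: ids[int(np.argmax(per_stage[si]))]
                  for si, s in enumerate(stages)}
        truth_rows.append(
            {
                "gene": gene,
                "n_isoforms": int(k),
                "is_switch": gene in switch_set,
                **{f"major_{s}": majors[s] for s in stages},
            }
        )

    iso_values = np.vstack(iso_rows)
    iso_study = ExpressionStudy(
        values=pd.DataFrame(
            iso_values,
            index=pd.Index(iso_ids, name="isoform"),
            columns=study.values.columns,
        ),
        samples=study.samples.copy(),
        feature_kind="isoform",
        isoform_to_gene=pd.Series(gene_of, index=pd.Index(iso_ids, name="isoform")),
        stage_order=stages,
    )
    switch_truth = pd.DataFrame(truth_rows).set_index("gene")
    truth.switches = switch_truth
    truth.isoform_proportions = proportions
    return iso_study, switch_truth


def simulate_qpcr(
    truth: GroundTruth,
    genes: list[str],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Ct table (technical triplicates) consistent with planted fold changes.

    Each gene's Ct tracks −log2 of its expression relative to the control
    stage (one cycle per 2-fold), offset from the housekeeping baseline,
    with Gaussian per-reaction cycle noise.
    """
    q = config.qpcr
    rng = config.rng(_STREAM_QPCR)
    control = config.stages[0]
    missing = [g for g in genes if g not in truth.stage_means.index]
    if missing:
        raise ValidationError(f"genes not in ground truth: {missing[:5]}")
    d = truth.detection_limit
    means = truth.stage_means.clip(lower=d)
    rows = []
    fold_rows = []
    offsets = {g: rng.uniform(2.0, 8.0) for g in genes}
    for stage, n_rep in zip(config.stages, config.replicates):
        for rep in range(1, n_rep + 1):
            sid = f"{stage}_r{rep}"
            for _ in range(q.n_technical):
                rows.append(
                    {
                        "gene": q.housekeeping_gene,
                        "sample_id": sid,
                        "stage": stage,
                        "ct": q.housekeeping_ct
                        + rng.normal(0.0, q.ct_noise_sd),
                    }
                )
            for g in genes:
                rel = means.loc[g, stage] / means.loc[g, control]
                base_ct = q.housekeeping_ct + offsets[g] - math.log2(rel)
                for _ in range(q.n_technical):
                    rows.append(
                        {
                            "gene": g,
                            "sample_id": sid,
                            "stage": stage,
                            "ct": base_ct + rng.normal(0.0, q.ct_noise_sd),
                        }
                    )
    for g in genes:
        for stage in config.stages[1:]:
            fold_rows.append(
                {
                    "gene": g,
                    "contrast": _contrast_name(stage, control),
                    "fold_change": float(means.loc[g, stage] / means.loc[g, control]),
                }
            )
    truth.qpcr_folds = pd.DataFrame(fold_rows)
    return pd.DataFrame(rows)


def simulate_annotations(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Cellular-location / drug-availability annotation for every gene.

    Planted hubs are annotated plasma-membrane (the framework's premise is
    that key candidates are surface-accessible or druggable); other genes
    draw a location from a fixed mixture and carry drug information with
    probability 0.1.
    """
    rng = config.rng(_STREAM_ANNOT)
    genes = list(truth.stage_means.index)
    locs = rng.choice(
        ["extracellular_space", "plasma_membrane", "cytoplasm", "nucleus", "other"],
        size=len(genes),
        p=[0.10, 0.20, 0.35, 0.25, 0.10],
    )
    ann = pd.DataFrame(
        {"location": locs, "has_drug": rng.random(len(genes)) < 0.1},
        index=pd.Index(genes, name="gene"),
    )
    for hub in truth.hubs:
        ann.loc[hub, "location"] = "plasma_membrane"
    return ann


def simulate_gene_sets(
    truth: GroundTruth,
    config: SimulationConfig,
    set_size: int = 40,
    n_random: int = 5,
) -> GeneSetCollection:
    """Marker-style gene sets: one planted signature per injury contrast
    (genes up-regulated specifically in that stage) plus random sets."""
    rng = config.rng(_STREAM_SETS)
    control = config.stages[0]
    all_genes = np.asarray(truth.stage_means.index)
    sets: dict[str, set[str]] = {}
    up_by_stage = {
        stage: truth.de_genes(_contrast_name(stage, control), "up")
        for stage in config.stages[1:]
    }
    for stage in config.stages[1:]:
        others = set().union(
            *(up_by_stage[s] for s in config.stages[1:] if s != stage)
        )
        specific = sorted(up_by_stage[stage] - others)
        if specific:
            take = min(set_size, len(specific))
            sets[f"{stage}_up_signature"] = set(
                rng.choice(specific, size=take, replace=False)
            )
    for i in range(n_random):
        sets[f"random_{i+1}"] = set(
            rng.choice(all_genes, size=set_size, replace=False)
        )
    return GeneSetCollection(sets=sets)


@dataclass
class SimulatedBundle:
    """Complete synthetic input bundle for an end-to-end run."""

    config: SimulationConfig
    study: ExpressionStudy
    isoform_study: ExpressionStudy
    truth: GroundTruth
    edges: EdgeList
    annotations: pd.DataFrame
    ct_table: pd.DataFrame
    gene_sets: GeneSetCollection


def simulate_all(config: SimulationConfig) -> SimulatedBundle:
    """Generate every input the pipeline consumes, with shared ground truth.

    Planted hubs are the up-regulated genes (first injury stage) with the
    largest planted effects; the first hub carries both the globally largest
    planted |log2 FC| and the largest degree, so a "prime candidate" exists
    whose recovery validates the prioritization framework.
    """
    study, truth = simulate_study(config)
    net_cfg = config.network
    if net_cfg.n_nodes > config.n_genes:  # clamp the default for small studies
        net_cfg = dataclasses.replace(net_cfg, n_nodes=config.n_genes)
    net_rng = config.rng(_STREAM_NETWORK)
    control, first_injured = config.stages[0], config.stages[1]
    contrast = _contrast_name(first_injured, control)
    de_truth = truth.de[contrast]
    up = de_truth[de_truth["label"] == "up"].sort_values(
        "true_log2_fc", ascending=False
    )
    n_hubs = config.network.n_hubs
    hub_genes = list(up.index[:n_hubs]) if len(up) >= n_hubs else None
    if hub_genes:
        # make the first hub the unambiguous top-fold-change gene
        boost = float(de_truth["true_log2_fc"].abs().max()) + 0.25
        prime = hub_genes[0]
        truth.de[contrast].loc[prime, "true_log2_fc"] = boost
        truth.stage_means.loc[prime, first_injured] = (
            truth.stage_means.loc[prime, control] * 2.0**boost
        )
        de_all = set(de_truth.index[de_truth["label"] != "none"])
        for c, t in truth.de.items():
            de_all |= set(t.index[t["label"] != "none"])
        others = [g for g in truth.stage_means.index
                  if g not in set(hub_genes)]
        de_first = [g for g in others if g in de_all]
        rest = [g for g in others if g not in de_all]
        node_pool = hub_genes + de_first + rest
    else:
        node_pool = list(truth.stage_means.index)
    edges, hubs = simulate_network(
        net_cfg, node_pool, net_rng,
        hub_genes=hub_genes,
    )
    truth.hubs = hubs
    truth.prime_candidate = hubs[0] if hubs else None

    # patch observed values of the boosted prime candidate so the observed
    # study matches the updated truth
    if hub_genes:
        prime = hubs[0]
        cols = study.samples_of_stage(first_injured)
        base = truth.stage_means.loc[prime, first_injured]
        patch_rng = np.random.default_rng([int(config.seed), 7])
        newvals = base * 2.0 ** patch_rng.normal(0.0, config.noise_sd, len(cols))
        study.values.loc[prime, cols] = newvals
        hw = config.ci_halfwidth_a + config.ci_halfwidth_b / np.sqrt(newvals + 1e-6)
        study.ci_lo.loc[prime, cols] = np.maximum(
            0.0, newvals * 2.0**-hw - truth.detection_limit
        )
        study.ci_hi.loc[prime, cols] = newvals * 2.0**hw + truth.detection_limit

    isoform_study, _ = simulate_isoforms(config, truth, study)
    annotations = simulate_annotations(truth, config)
    qpcr_genes = hubs if hubs else list(truth.stage_means.index[:5])
    ct_table = simulate_qpcr(truth, qpcr_genes, config)
    gene_sets = simulate_gene_sets(truth, config)
    return SimulatedBundle(
        config=config,
        study=study,
        isoform_study=isoform_study,
        truth=truth,
        edges=edges,
        annotations=annotations,
        ct_table=ct_table,
        gene_sets=gene_sets,
    )


def simulate_trajectory_archetypes(
    n_per_archetype: int = 100,
    k: int = 9,
    noise_sd: float = 0.2,
    n_stages: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted trajectory archetypes for clustering validation.

    Standardized ``n_stages``-point profiles lie on a circle in the plane
    orthogonal to the constant vector; the k archetypes are k evenly spaced
    directions on that circle (up-up, up-flat, down-down, ... shapes), each
    contributing ``n_per_archetype`` genes with Gaussian within-archetype
    noise.  Returns raw profiles and the true archetype labels.
    """
    if n_stages != 3:
        raise ValidationError("archetype construction is defined for 3 stages")
    rng = np.random.default_rng(seed)
    e1 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0)
    e2 = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)
    rows, labels = [], []
    r = np.sqrt(3.0 / 2.0)  # unit-variance radius for 3-point z-profiles
    for a in range(k):
        theta = 2.0 * np.pi * a / k
        center = r * (np.cos(theta) * e1 + np.sin(theta) * e2)
        for _ in range(n_per_archetype):
            rows.append(center + rng.normal(0.0, noise_sd, size=3))
            labels.append(a)
    idx = pd.Index([f"T{i:04d}" for i in range(len(rows))], name="gene")
    profiles = pd.DataFrame(rows, index=idx, columns=["S1", "S2", "S3"])
    return profiles, pd.Series(labels, index=idx, name="archetype")
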