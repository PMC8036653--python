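"""Synthetic data generators with planted, machine-readable ground truth.

Every pipeline input can be simulated here: an 8-plex peptide quant table
with planted per-channel fold changes, a modular protein-interaction graph
(stochastic block model), co-citation profiles for chemicals and diseases
enriched on planted target blocks, and Bernoulli term annotations.  All
generators are deterministic given their seed, and every planted effect is
returned as an explicit truth table so downstream recovery can be scored.

Proteins share a single accession namespace ``P000001...`` across all
generators, so quant truth, graph nodes, annotations and profiles join on
protein id.

Count-valued draws ("at least one peptide per protein", "at least one
co-citation") use a shifted Poisson ``1 + Poisson(mean - 1)``, which has
exactly the configured mean and support >= 1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .quant import CHANNELS, REFERENCE_CHANNEL, intensity_col

NOISE_MODELS = ("lognormal", "cauchy_logratio")

#: Cauchy log10-ratio noise is clipped to this many decades; the clip sits
#: far beyond any decision boundary but keeps intensities finite.
_LOG_RATIO_CLIP = 8.0


def protein_ids(n: int) -> list[str]:
    """Accessions ``P000001 ... P{n:06d}`` of the shared namespace."""
    return [f"P{i + 1:06d}" for i in range(n)]


def _shifted_poisson(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    return 1 + rng.poisson(mean - 1.0, size)


# ---------------------------------------------------------------------------
# quant table


@dataclasses.dataclass(frozen=True)
class SynthQuantConfig:
    """Parameters of the simulated 8-plex quant experiment.

    Defaults mirror the scale of the real experiment this emulates:
    834 proteins quantified from ~2,710 peptides (3.25 peptides/protein),
    roughly a fifth of the proteome responding per treatment with 2-fold
    effects, and heavy-tailed ratio noise matching the Cauchy null the
    significance model assumes.
    """

    n_proteins: int = 834
    peptides_per_protein: float = 3.25
    channel_labels: tuple[int, ...] = CHANNELS
    planted_fraction: float = 0.2
    fold_change: float = 2.0
    noise_model: str = "cauchy_logratio"
    noise_scale: float = 0.05
    channel_bias: tuple[float, float] = (0.5, 2.0)
    base_meanlog: float = math.log(1e5)
    base_sdlog: float = 0.5
    planted_candidates: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise_model {self.noise_model!r}; choose from {NOISE_MODELS}"
            )
        if not self.noise_scale >= 0:
            raise ValueError("noise_scale must be non-negative")
        lo, hi = self.channel_bias
        if not (0 < lo <= hi):
            raise ValueError("channel_bias range must satisfy 0 < low <= high")


def gen_quant_table(cfg: SynthQuantConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide quant table and its regulation truth.

    Returns ``(table, truth)``:

    * ``table`` -- columns ``peptide``, ``protein``, ``i113`` ... ``i121``,
      strictly positive intensities.
    * ``truth`` -- one row per (protein, non-reference channel):
      ``protein``, ``channel``, ``direction`` in {up, down, null} and
      ``true_fold`` (the multiplicative effect actually applied).

    The reference channel carries no planted effect and no ratio noise;
    the configured noise distribution therefore *is* the distribution of
    peptide log10-ratios.  A per-channel multiplicative bias (drawn once
    per channel from the ``channel_bias`` range) multiplies every row of
    that channel, emulating loading/labelling bias.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = protein_ids(cfg.n_proteins)
    npep = _shifted_poisson(rng, cfg.peptides_per_protein, cfg.n_proteins)
    total = int(npep.sum())
    prot_idx = np.repeat(np.arange(cfg.n_proteins), npep)
    pep_rank = np.concatenate([np.arange(k) for k in npep])

    base = rng.lognormal(cfg.base_meanlog, cfg.base_sdlog, total)
    bias = rng.uniform(cfg.channel_bias[0], cfg.channel_bias[1], len(cfg.channel_labels))

    if cfg.planted_candidates is None:
        candidate_mask = np.ones(cfg.n_proteins, dtype=bool)
    else:
        pool = set(cfg.planted_candidates)
        unknown = pool.difference(proteins)
        if unknown:
            raise ValueError(f"planted_candidates outside the protein set: {sorted(unknown)[:5]}")
        candidate_mask = np.array([p in pool for p in proteins])

    log_fc = math.log10(cfg.fold_change)
    cols: dict[str, np.ndarray] = {}
    truth_rows: list[pd.DataFrame] = []
    for ci, c in enumerate(cfg.channel_labels):
        if c == REFERENCE_CHANNEL:
            cols[intensity_col(c)] = base * bias[ci]
            continue
        regulated = (rng.random(cfg.n_proteins) < cfg.planted_fraction) & candidate_mask
        up = rng.random(cfg.n_proteins) < 0.5
        direction = np.where(regulated, np.where(up, 1.0, -1.0), 0.0)
        if cfg.noise_model == "cauchy_logratio":
            eps = rng.standard_cauchy(total) * cfg.noise_scale
            eps = np.clip(eps, -_LOG_RATIO_CLIP, _LOG_RATIO_CLIP)
        else:  # lognormal
            eps = rng.normal(0.0, cfg.noise_scale, total)
        log_ratio = direction[prot_idx] * log_fc + eps
        cols[intensity_col(c)] = base * bias[ci] * 10.0 ** log_ratio
        truth_rows.append(
            pd.DataFrame(
                {
                    "protein": proteins,
                    "channel": c,
                    "direction": np.where(
                        direction > 0, "up", np.where(direction < 0, "down", "null")
                    ),
                    "true_fold": cfg.fold_change ** direction,
                }
            )
        )

    table = pd.DataFrame(
        {
            "peptide": [f"{proteins[i]}_pep{j + 1}" for i, j in zip(prot_idx, pep_rank)],
            "protein": [proteins[i] for i in prot_idx],
            **cols,
        }
    )
    truth = pd.concat(truth_rows, ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# interaction graph


@dataclasses.dataclass(frozen=True)
class SynthGraphConfig:
    """Stochastic-block-model stand-in for a protein-interaction network."""

    block_sizes: tuple[int, ...] = (100, 100)
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_sizes) == 0:
            raise ValueError("block_sizes must be non-empty")
        if any(b < 2 for b in self.block_sizes):
            raise ValueError("every block must contain at least 2 nodes")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")


def gen_ppi_network(cfg: SynthGraphConfig) -> tuple[nx.Graph, dict[str, int]]:
    """Sample an undirected SBM graph; returns (graph, node -> block index).

    Nodes are relabelled into the shared accession namespace in block
    order, so block 0 is ``P000001 ... P{block_sizes[0]:06d}``.
    """
    k = len(cfg.block_sizes)
    p = [[cfg.p_in if i == j else cfg.p_out for j in range(k)] for i in range(k)]
    seed = int(cfg.seed) % (2**31)
    g = nx.stochastic_block_model(list(cfg.block_sizes), p, seed=seed)
    n = sum(cfg.block_sizes)
    names = protein_ids(n)
    mapping = dict(zip(range(n), names))
    blocks: dict[str, int] = {}
    start = 0
    for bi, size in enumerate(cfg.block_sizes):
        for node in range(start, start + size):
            blocks[names[node]] = bi
        start += size
    out = nx.Graph()
    out.add_nodes_from(names)
    out.add_edges_from((mapping[u], mapping[v]) for u, v in g.edges())
    return out, blocks


# ---------------------------------------------------------------------------
# co-citation profiles


@dataclasses.dataclass(frozen=True)
class SynthCocitConfig:
    """Planted chemical/disease co-citation profiles over graph blocks.

    Each entity either targets one block (its co-citation hits fall on
    that block with probability ``hit_rate`` and elsewhere with
    ``background_rate``) or targets nothing (background everywhere).
    ``target_blocks`` maps entity id to block index or ``None``; if the
    mapping is omitted entirely, every entity is assigned a uniformly
    random block.
    """

    n_chemicals: int = 20
    n_diseases: int = 1
    target_blocks: Mapping[str, int | None] | None = None
    hit_rate: float = 0.8
    background_rate: float = 0.05
    count_mean: float = 3.0
    metabolite_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 0 or self.n_diseases < 0:
            raise ValueError("entity counts must be non-negative")
        if not (0.0 <= self.background_rate < self.hit_rate <= 1.0):
            raise ValueError("require 0 <= background_rate < hit_rate <= 1")
        if self.count_mean < 1:
            raise ValueError("count_mean must be >= 1")
        if not 0.0 <= self.metabolite_fraction <= 1.0:
            raise ValueError("metabolite_fraction must lie in [0, 1]")


def chemical_ids(n: int) -> list[str]:
    return [f"CHEM{i + 1:04d}" for i in range(n)]


def disease_ids(n: int) -> list[str]:
    return [f"DISEASE{i + 1:04d}" for i in range(n)]


def gen_cocitation_profiles(
    cfg: SynthCocitConfig, graph: nx.Graph, blocks: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the entity co-citation table and its association truth.

    Returns ``(profiles, truth)``:

    * ``profiles`` -- rows (entity, entity_type, protein, count,
      is_metabolite), counts >= 1, only proteins actually co-cited.
    * ``truth`` -- rows (entity, entity_type, target_block) with
      ``target_block`` = -1 for untargeted entities.
    """
    nodes = sorted(graph.nodes)
    missing = [n for n in nodes if n not in blocks]
    if missing:
        raise ValueError(f"blocks do not cover graph nodes, e.g. {missing[:5]}")
    block_ids = set(blocks[n] for n in nodes)
    rng = np.random.default_rng(cfg.seed)

    entities = [(e, "chemical") for e in chemical_ids(cfg.n_chemicals)]
    entities += [(e, "disease") for e in disease_ids(cfg.n_diseases)]

    targets: dict[str, int | None] = {}
    for eid, _ in entities:
        if cfg.target_blocks is not None:
            t = cfg.target_blocks.get(eid, None)
            if t is not None and t not in block_ids:
                raise ValueError(f"target block {t} of {eid} not present in the graph")
        else:
            t = int(rng.choice(sorted(block_ids)))
        targets[eid] = t

    node_blocks = np.array([blocks[n] for n in nodes])
    n_chem = cfg.n_chemicals
    metab = rng.random(n_chem) < cfg.metabolite_fraction if n_chem else np.zeros(0, bool)

    rows = []
    for i, (eid, etype) in enumerate(entities):
        t = targets[eid]
        rate = np.where(node_blocks == t, cfg.hit_rate, cfg.background_rate) \
            if t is not None else np.full(len(nodes), cfg.background_rate)
        hit = rng.random(len(nodes)) < rate
        counts = _shifted_poisson(rng, cfg.count_mean, int(hit.sum()))
        is_met = bool(metab[i]) if etype == "chemical" else False
        for node, cnt in zip(np.array(nodes)[hit], counts):
            rows.append((eid, etype, node, int(cnt), is_met))

    profiles = pd.DataFrame(
        rows, columns=["entity", "entity_type", "protein", "count", "is_metabolite"]
    )
    truth = pd.DataFrame(
        {
            "entity": [e for e, _ in entities],
            "entity_type": [t for _, t in entities],
            "target_block": [-1 if targets[e] is None else targets[e] for e, _ in entities],
        }
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# annotations


@dataclasses.dataclass(frozen=True)
class TermSpec:
    """One annotation term: namespace, free-text description, and the
    independent probability with which each protein carries the term."""

    term: str
    namespace: str
    description: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability of {self.term} outside [0, 1]")
        if self.namespace not in ("GO_BP", "PIR_keyword"):
            raise ValueError(f"unknown namespace {self.namespace!r}")


def gen_annotations(
    proteins: Sequence[str], term_specs: Sequence[TermSpec], seed: int = 0
) -> AnnotationTable:
    """Annotate each protein to each term independently with its probability."""
    rng = np.random.default_rng(seed)
    protein_terms: dict[str, set[str]] = {p: set() for p in proteins}
    term_info = {}
    for spec in term_specs:
        term_info[spec.term] = (spec.namespace, spec.description)
        mask = rng.random(len(proteins)) < spec.probability
        for p, m in zip(proteins, mask):
            if m:
                protein_terms[p].add(spec.term)
    return AnnotationTable(protein_terms, term_info)


# ---------------------------------------------------------------------------
# writers (all plain TSV; annotations use GMT via AnnotationTable)


def write_quant_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_quant_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    expected = {"peptide", "protein", *(intensity_col(c) for c in CHANNELS)}
    missing = expected.difference(table.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    return table


def write_edge_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            w = data.get("weight")
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_blocks_tsv(blocks: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tblock\n")
        for node in sorted(blocks):
            fh.write(f"{node}\t{blocks[node]}\n")


def write_profiles_tsv(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"entity", "entity_type", "protein", "count"}
    missing = required.difference(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    if "is_metabolite" not in df.columns:
        df["is_metabolite"] = False
    return df


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")
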