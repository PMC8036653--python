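"""End-to-end orchestration: simulate -> quantify -> filter -> embed -> rank.

A single :class:`RunConfig` (built in code or loaded from YAML) drives the
whole pipeline.  Every stage input is either a file path or a synthetic
config -- never both.  One master seed deterministically derives per-stage
seeds by stage-name hashing, so a run is reproduced byte-identically from
one number.

This module also houses the small extracellular metabolite-rate utility
(consumption/production normalised to cell number).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from typing import Any, Mapping

import yaml

from . import annotation as anno
from . import embedding as emb_mod
from . import quant
from . import repositioning as repo
from . import synthetic as synth

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed from the master seed (stage-name hashing, < 2^31)."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


#: Default demo annotation scheme: the five metabolic GO processes, two
#: non-metabolic GO processes, and the two PIR keywords whose prevalence
#: among dysregulated proteins (60-70%) the study design emulates.
def default_term_specs() -> list[synth.TermSpec]:
    specs = [
        synth.TermSpec(t, "GO_BP", desc, 0.15) for t, desc in anno.METABOLIC_GO_TERMS.items()
    ]
    specs += [
        synth.TermSpec("GO:0006351", "GO_BP", "transcription, DNA-templated", 0.20),
        synth.TermSpec("GO:0006810", "GO_BP", "transport", 0.25),
        synth.TermSpec("acetylation", "PIR_keyword", "acetylation", 0.65),
        synth.TermSpec("phosphoprotein", "PIR_keyword", "phosphoprotein", 0.60),
    ]
    return specs


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    Each of ``quant``/``graph``/``cocitation``/``annotations`` is either a
    synthetic config (``*_synth``) or an input path (``*_path``) -- never
    both.  Analysis parameters cover every stage; ``seed`` is the master
    seed from which stage seeds derive.
    """

    seed: int = 0
    outdir: str = "drugprox_run"
    # stage inputs
    quant_synth: synth.SynthQuantConfig | None = None
    quant_path: str | None = None
    graph_synth: synth.SynthGraphConfig | None = None
    graph_path: str | None = None
    cocit_synth: synth.SynthCocitConfig | None = None
    cocit_path: str | None = None
    annotation_specs: tuple[synth.TermSpec, ...] | None = None
    annotation_path: str | None = None
    # quantification
    normalize_method: str = "median"
    aggregate: str = "mean"
    noise_fit_method: str = "quartile"
    alpha: float = 0.05
    # annotation filter
    focus_channel: int = 121
    metabolic_terms: tuple[str, ...] = tuple(anno.METABOLIC_GO_TERMS)
    # embedding
    walk: emb_mod.WalkParams = emb_mod.WalkParams()
    train: emb_mod.TrainParams = emb_mod.TrainParams()
    # repositioning
    tau: float = 0.5
    weight_mode: str = "raw"
    disease: str | None = None
    top_n: int = 500
    top_k: int = 70
    exclude_metabolites: bool = True

    def __post_init__(self) -> None:
        pairs = [
            ("quant", self.quant_synth, self.quant_path),
            ("graph", self.graph_synth, self.graph_path),
            ("cocitation", self.cocit_synth, self.cocit_path),
            ("annotations", self.annotation_specs, self.annotation_path),
        ]
        for name, synth_cfg, path in pairs:
            if synth_cfg is None and path is None:
                raise ValueError(f"stage {name!r} needs a synthetic config or a path")
            if synth_cfg is not None and path is not None:
                raise ValueError(f"stage {name!r} has both a synthetic config and a path")

    # -- YAML loading -------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        kw: dict[str, Any] = {}
        for key in (
            "seed", "outdir", "normalize_method", "aggregate", "noise_fit_method",
            "alpha", "focus_channel", "tau", "weight_mode", "disease",
            "top_n", "top_k", "exclude_metabolites",
        ):
            if key in raw:
                kw[key] = raw[key]
        if "metabolic_terms" in raw:
            kw["metabolic_terms"] = tuple(raw["metabolic_terms"])
        for stage, synth_cls, synth_key, path_key in (
            ("quant", synth.SynthQuantConfig, "quant_synth", "quant_path"),
            ("graph", synth.SynthGraphConfig, "graph_synth", "graph_path"),
            ("cocitation", synth.SynthCocitConfig, "cocit_synth", "cocit_path"),
        ):
            section = raw.get(stage)
            if isinstance(section, Mapping):
                if "path" in section:
                    kw[path_key] = section["path"]
                else:
                    sec = dict(section)
                    for tup_key in ("block_sizes", "channel_labels", "planted_candidates"):
                        if tup_key in sec and sec[tup_key] is not None:
                            sec[tup_key] = tuple(sec[tup_key])
                    kw[synth_key] = synth_cls(**sec)
        section = raw.get("annotations")
        if isinstance(section, Mapping):
            if "path" in section:
                kw["annotation_path"] = section["path"]
            else:
                kw["annotation_specs"] = tuple(
                    synth.TermSpec(**spec) for spec in section.get("terms", [])
                )
        if "walk" in raw:
            kw["walk"] = emb_mod.WalkParams(**raw["walk"])
        if "train" in raw:
            kw["train"] = emb_mod.TrainParams(**raw["train"])
        return cls(**kw)

    def to_jsonable(self) -> dict[str, Any]:
        """Parameter echo for the run report (no output paths)."""
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        d.pop("outdir", None)
        return d


def demo_config(seed: int = 0, outdir: str = "drugprox_run", **overrides) -> RunConfig:
    """All-synthetic planted benchmark configuration.

    200 proteins in two interaction blocks of 100; regulation planted
    inside block 0 only; 20 chemicals of which CHEM0001 targets block 0
    (hit rate 0.8 vs background 0.05) while the rest carry background
    co-citations only; one disease profile also anchored on block 0.
    Embedding parameters are scaled to the 200-node graph.
    """
    n_per_block = 100
    block0 = tuple(synth.protein_ids(2 * n_per_block)[:n_per_block])
    targets: dict[str, int | None] = {e: None for e in synth.chemical_ids(20)}
    targets["CHEM0001"] = 0
    targets["DISEASE0001"] = 0
    cfg = dict(
        seed=seed,
        outdir=outdir,
        quant_synth=synth.SynthQuantConfig(
            n_proteins=2 * n_per_block,
            planted_candidates=block0,
            seed=derive_seed(seed, "quant"),
        ),
        graph_synth=synth.SynthGraphConfig(
            block_sizes=(n_per_block, n_per_block), seed=derive_seed(seed, "graph")
        ),
        cocit_synth=synth.SynthCocitConfig(
            n_chemicals=20,
            n_diseases=1,
            target_blocks=targets,
            seed=derive_seed(seed, "cocitation"),
        ),
        annotation_specs=tuple(default_term_specs()),
        walk=emb_mod.WalkParams(
            num_walks_per_node=10, walk_length=40, seed=derive_seed(seed, "walks")
        ),
        train=emb_mod.TrainParams(
            dimension=64, window=5, epochs=3, seed=derive_seed(seed, "train")
        ),
        disease="DISEASE0001",
        top_n=20,
        top_k=10,
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages, write artifacts under ``cfg.outdir``, return the report.

    Stage order: inputs -> quantification -> annotation filter ->
    embedding -> repositioning.  A stage failure aborts with
    :class:`PipelineError` naming the stage; artifacts written so far are
    retained.
    """
    out = pathlib.Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": cfg.to_jsonable(),
        "stage_seeds": {
            s: derive_seed(cfg.seed, s)
            for s in ("quant", "graph", "cocitation", "annotations", "walks", "train")
        },
    }

    # ---- stage: inputs ----------------------------------------------------
    stage = "inputs"
    try:
        if cfg.quant_synth is not None:
            table, reg_truth = synth.gen_quant_table(cfg.quant_synth)
            synth.write_quant_tsv(table, out / "quant_table.tsv")
            synth.write_truth_tsv(reg_truth, out / "regulation_truth.tsv")
        else:
            table = synth.read_quant_tsv(cfg.quant_path)
            reg_truth = None
        if cfg.graph_synth is not None:
            graph, blocks = synth.gen_ppi_network(cfg.graph_synth)
            synth.write_edge_tsv(graph, out / "edges.tsv")
            synth.write_blocks_tsv(blocks, out / "blocks.tsv")
        else:
            graph = emb_mod.build_graph(cfg.graph_path)
            blocks = None
        if cfg.cocit_synth is not None:
            if blocks is None:
                raise ValueError("synthetic co-citation profiles need a synthetic graph")
            profiles_df, assoc_truth = synth.gen_cocitation_profiles(
                cfg.cocit_synth, graph, blocks
            )
            synth.write_profiles_tsv(profiles_df, out / "profiles.tsv")
            synth.write_truth_tsv(assoc_truth, out / "association_truth.tsv")
        else:
            profiles_df = synth.read_profiles_tsv(cfg.cocit_path)
        if cfg.annotation_specs is not None:
            proteins = sorted(set(table["protein"]))
            annotations = synth.gen_annotations(
                proteins, list(cfg.annotation_specs), seed=derive_seed(cfg.seed, "annotations")
            )
            annotations.to_gmt(out / "annotations.gmt")
        else:
            annotations = anno.AnnotationTable.from_gmt(cfg.annotation_path)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    # ---- stage: quantification -------------------------------------------
    stage = "quantification"
    try:
        design = quant.DEFAULT_DESIGN
        normed = quant.normalize_channels(table, method=cfg.normalize_method)
        ratios = quant.protein_log_ratios(normed, design, aggregate=cfg.aggregate)
        model = quant.fit_cauchy_noise(ratios, method=cfg.noise_fit_method)
        calls = quant.call_regulation(ratios, model, alpha=cfg.alpha)
        quant.write_ratio_table(calls, out / "ratio_table.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    dysregulated_per_channel = {
        str(c): int(((calls["channel"] == c) & (calls["call"] != "ns")).sum())
        for c in design.treatment_channels
    }

    # ---- stage: annotation filter ----------------------------------------
    stage = "annotation_filter"
    try:
        query = anno.filter_by_go(
            calls, annotations, terms=cfg.metabolic_terms, channel=cfg.focus_channel
        )
        (out / "filtered_proteins.txt").write_text(
            "".join(f"{p}\n" for p in sorted(query))
        )
        if not query:
            raise ValueError(
                f"no dysregulated protein in channel {cfg.focus_channel} carries a "
                "metabolic annotation"
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: embedding -------------------------------------------------
    stage = "embedding"
    try:
        embeddings = emb_mod.embed_graph(graph, cfg.walk, cfg.train)
        embeddings.to_tsv(out / "embeddings.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: repositioning ---------------------------------------------
    stage = "repositioning"
    try:
        profiles = repo.profiles_from_dataframe(profiles_df)
        chemicals = [p for p in profiles if p.entity_type == "chemical"]
        ranking, unscorable = repo.rank_chemicals(
            query, chemicals, embeddings, tau=cfg.tau, weight_mode=cfg.weight_mode
        )
        disease_profile = None
        if cfg.disease is not None:
            matches = [p for p in profiles if p.entity_id == cfg.disease]
            if not matches:
                raise ValueError(f"disease profile {cfg.disease!r} not found")
            disease_profile = matches[0]
            ranking = repo.disease_link_scores(
                ranking, disease_profile, chemicals, embeddings,
                tau=cfg.tau, weight_mode=cfg.weight_mode,
            )
        repo.write_ranking_tsv(ranking, out / "ranking.tsv")
        candidates = repo.select_candidates(
            ranking,
            top_n=min(cfg.top_n, len(ranking)),
            top_k=min(cfg.top_k, min(cfg.top_n, len(ranking))),
            exclude_metabolites=cfg.exclude_metabolites,
        )
        repo.write_ranking_tsv(candidates, out / "candidates.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    report.update(
        {
            "channels": [str(c) for c in quant.CHANNELS],
            "contrasts": [
                f"{c}:{design.conditions[c]}" for c in design.treatment_channels
            ],
            "n_peptide_rows": int(len(table)),
            "n_proteins_quantified": int(calls["protein"].nunique()),
            "dysregulated_per_channel": dysregulated_per_channel,
            "focus_channel": str(cfg.focus_channel),
            "n_filtered_query": len(query),
            "noise_model_fit": {
                "location": model.location,
                "scale": model.scale,
                "n_fit": model.n_fit,
            },
            "n_chemicals_ranked": int(len(ranking)),
            "n_unscorable": len(unscorable),
            "unscorable": [list(u) for u in unscorable],
            "n_embedded": len(embeddings.nodes),
            "n_embedding_skipped": len(embeddings.skipped),
            "n_candidates": int(len(candidates)),
            "top_candidate": str(candidates["entity"].iloc[0]) if len(candidates) else None,
        }
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# metabolite consumption/production rates


@dataclasses.dataclass(frozen=True)
class RateMeasurement:
    """Start/end concentrations of an extracellular metabolite.

    Concentrations in umol/mL, volume in mL, duration in hours; cell
    counts at the start and end of the incubation.
    """

    metabolite: str
    c_start: float
    c_end: float
    volume: float
    cells_start: float
    cells_end: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.cells_start <= 0 or self.cells_end <= 0:
            raise ValueError("cell counts must be positive")
        if self.c_start < 0 or self.c_end < 0 or self.volume <= 0:
            raise ValueError("concentrations must be >= 0 and volume > 0")


def compute_metabolite_rate(m: RateMeasurement, convention: str = "mean_cells") -> float:
    """Consumption/production rate in umol per 10^6 cells per hour.

    rate = (c_start - c_end) * volume / (cells/10^6 * duration), with
    ``cells`` the mean of start and end counts (``mean_cells``, the
    default normalisation for proliferating cultures) or the final count
    (``final_cells``).  Positive = consumption, negative = production.
    """
    if convention == "mean_cells":
        cells = 0.5 * (m.cells_start + m.cells_end)
    elif convention == "final_cells":
        cells = m.cells_end
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return (m.c_start - m.c_end) * m.volume / ((cells / 1e6) * m.duration)
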