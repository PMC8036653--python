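"""Co-citation-weighted proximity scoring and drug-repositioning ranking.

A chemical or disease is represented as a weighted protein set (its
co-citation profile: proteins co-mentioned with the entity in literature
and bioassays, weighted by mention count).  Its proximity to a query
protein set (here: the KDACi/hypoxia-dysregulated metabolic proteins) is

    S = sum_{a in query} sum_{b in profile} w_b * cos(e_a, e_b) * [cos >= tau]

with ``e`` the node embeddings, ``tau`` the similarity threshold (0.5 by
default) and ``w_b`` the raw co-citation count (or the count normalised to
sum 1).  Query proteins are unweighted.  Chemicals are ranked by
descending score; candidates are then re-ranked within the top of the list
by their proximity to a disease profile, metabolites are excluded, and the
leading entries are reported.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingMatrix

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("raw", "normalized")


@dataclasses.dataclass(frozen=True)
class EntityProfile:
    """A chemical or disease as a co-citation-weighted protein set."""

    entity_id: str
    entity_type: str  # "chemical" | "disease"
    weights: Mapping[str, int]
    is_metabolite: bool = False

    def __post_init__(self) -> None:
        if self.entity_type not in ("chemical", "disease"):
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        if not self.weights:
            raise ValueError(f"profile of {self.entity_id} has no proteins")
        if any(c < 1 for c in self.weights.values()):
            raise ValueError(f"co-citation counts of {self.entity_id} must be >= 1")


def profiles_from_dataframe(df: pd.DataFrame) -> list[EntityProfile]:
    """Build profiles from a (entity, entity_type, protein, count[, is_metabolite]) table."""
    out = []
    for (eid, etype), sub in df.groupby(["entity", "entity_type"], sort=True):
        met = bool(sub["is_metabolite"].any()) if "is_metabolite" in sub else False
        weights = {str(r.protein): int(r.count) for r in sub.itertuples()}
        out.append(EntityProfile(str(eid), str(etype), weights, is_metabolite=met))
    return out


@dataclasses.dataclass(frozen=True)
class ProximityResult:
    entity_id: str
    score: float
    n_contributing_pairs: int
    n_scored_pairs: int

    def __post_init__(self) -> None:
        if self.score < 0 and self.n_contributing_pairs > 0:
            # negative scores only possible with tau < 0
            pass
        if self.n_contributing_pairs > self.n_scored_pairs:
            raise ValueError("contributing pairs cannot exceed scored pairs")


def _unit_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding vector")
    return matrix / norms


def group_similarity_matrix(
    group_a: Iterable[str],
    group_b: Iterable[str],
    emb: EmbeddingMatrix,
) -> tuple[np.ndarray, list[str], list[str]]:
    """All-pairs cosine matrix between two protein groups.

    Proteins without embedding vectors are omitted; returns the matrix and
    the effective (lexicographically ordered) member lists.  Raises if a
    group has no embedded member.
    """
    rows_a, mat_a = emb.vectors_for(group_a)
    rows_b, mat_b = emb.vectors_for(group_b)
    if not rows_a:
        raise ValueError("group A has no embedded proteins")
    if not rows_b:
        raise ValueError("group B has no embedded proteins")
    sim = _unit_rows(mat_a) @ _unit_rows(mat_b).T
    return sim, rows_a, rows_b


def proximity_score(
    query: Iterable[str],
    profile: EntityProfile,
    emb: EmbeddingMatrix,
    tau: float = 0.5,
    weight_mode: str = "raw",
) -> ProximityResult:
    """Thresholded, co-citation-weighted cosine proximity of a profile to a query.

    Only pairs with cosine >= ``tau`` contribute; each contribution is the
    cosine times the profile protein's weight (raw count, or count
    normalised to the profile's total under ``weight_mode="normalized"``).
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [-1, 1]")
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    sim, rows_q, rows_p = group_similarity_matrix(query, profile.weights, emb)
    w = np.array([profile.weights[b] for b in rows_p], dtype=np.float64)
    if weight_mode == "normalized":
        w = w / float(sum(profile.weights.values()))
    mask = sim >= tau
    score = float(((sim * mask) * w[None, :]).sum())
    return ProximityResult(
        entity_id=profile.entity_id,
        score=score,
        n_contributing_pairs=int(mask.sum()),
        n_scored_pairs=int(sim.size),
    )


def proximity_score_bruteforce(
    query: Iterable[str],
    profile: EntityProfile,
    emb: EmbeddingMatrix,
    tau: float = 0.5,
    weight_mode: str = "raw",
) -> float:
    """Reference double-loop recomputation of :func:`proximity_score`."""
    from .embedding import cosine_similarity

    total_w = float(sum(profile.weights.values()))
    s = 0.0
    for a in sorted(set(query)):
        if a not in emb:
            continue
        for b in sorted(profile.weights):
            if b not in emb:
                continue
            c = cosine_similarity(emb[a], emb[b])
            if c >= tau:
                w = profile.weights[b]
                if weight_mode == "normalized":
                    w = w / total_w
                s += w * c
    return s


def rank_chemicals(
    query: Iterable[str],
    profiles: Sequence[EntityProfile],
    emb: EmbeddingMatrix,
    tau: float = 0.5,
    weight_mode: str = "raw",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score every chemical profile against the query and rank descending.

    Returns ``(ranking, unscorable)``.  The ranking has columns ``rank``
    (1-based), ``entity``, ``network_score``, ``disease_score`` (NaN until
    filled), ``n_contributing_pairs``, ``n_scored_pairs``,
    ``is_metabolite``.  Ties break lexicographically by entity id.
    ``unscorable`` lists (entity, reason) for profiles with no embedded
    protein.
    """
    chem = [p for p in profiles if p.entity_type == "chemical"]
    rows, unscorable = [], []
    for prof in sorted(chem, key=lambda p: p.entity_id):
        try:
            res = proximity_score(query, prof, emb, tau=tau, weight_mode=weight_mode)
        except ValueError as exc:
            unscorable.append((prof.entity_id, str(exc)))
            continue
        rows.append(
            (
                prof.entity_id,
                res.score,
                res.n_contributing_pairs,
                res.n_scored_pairs,
                prof.is_metabolite,
            )
        )
    if not rows:
        raise ValueError("no chemical profile is scorable against the query")
    ranking = pd.DataFrame(
        rows,
        columns=[
            "entity",
            "network_score",
            "n_contributing_pairs",
            "n_scored_pairs",
            "is_metabolite",
        ],
    )
    ranking = ranking.sort_values(
        ["network_score", "entity"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    ranking.insert(3, "disease_score", np.nan)
    return ranking, unscorable


def disease_link_scores(
    ranking: pd.DataFrame,
    disease_profile: EntityProfile,
    chemical_profiles: Sequence[EntityProfile],
    emb: EmbeddingMatrix,
    tau: float = 0.5,
    weight_mode: str = "raw",
) -> pd.DataFrame:
    """Fill the disease_score column: each chemical's protein support scored
    against the disease's weighted profile.

    Chemicals whose support has no embedded protein get a disease score of
    0 (no pair can clear the threshold).
    """
    by_id = {p.entity_id: p for p in chemical_profiles}
    scores = []
    for entity in ranking["entity"]:
        prof = by_id.get(entity)
        if prof is None:
            raise KeyError(f"chemical {entity} missing from the profile set")
        try:
            res = proximity_score(
                sorted(prof.weights), disease_profile, emb, tau=tau, weight_mode=weight_mode
            )
            scores.append(res.score)
        except ValueError:
            scores.append(0.0)
    out = ranking.copy()
    out["disease_score"] = scores
    return out


def select_candidates(
    ranking: pd.DataFrame,
    top_n: int = 500,
    top_k: int = 70,
    exclude_metabolites: bool = True,
) -> pd.DataFrame:
    """Final candidate list: top ``top_n`` by network score, re-ranked by
    disease score, metabolites dropped, first ``top_k`` returned.

    If fewer than ``top_k`` remain after exclusion the remainder is
    returned with a logged note.
    """
    if ranking.empty:
        raise ValueError("ranking is empty")
    if top_k > top_n:
        raise ValueError("top_k cannot exceed top_n")
    head = ranking.nsmallest(top_n, "rank")
    head = head.sort_values(
        ["disease_score", "entity"], ascending=[False, True], kind="mergesort"
    )
    if exclude_metabolites:
        head = head[~head["is_metabolite"].astype(bool)]
    out = head.head(top_k).reset_index(drop=True)
    if len(out) < top_k:
        logger.info(
            "only %d candidate(s) remain after metabolite exclusion (asked for %d)",
            len(out),
            top_k,
        )
    out = out.rename(columns={"rank": "network_rank"})
    out.insert(0, "final_rank", np.arange(1, len(out) + 1))
    return out


def write_ranking_tsv(ranking: pd.DataFrame, path) -> None:
    ranking.to_csv(path, sep="\t", index=False, float_format="%.10g")
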