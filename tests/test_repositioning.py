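"""Proximity scoring, ranking, disease re-ranking and candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import drugprox as dp


def unit_embedding(vectors):
    """EmbeddingMatrix from explicit vectors (dict node -> list)."""
    nodes = sorted(vectors)
    return dp.EmbeddingMatrix(nodes, np.array([vectors[n] for n in nodes], dtype=float))


# -- similarity matrix ------------------------------------------------------


def test_similarity_matrix_self_is_one(random_embedding):
    sim, rows, cols = dp.group_similarity_matrix(["P000001"], ["P000001"], random_embedding)
    assert sim.shape == (1, 1)
    assert sim[0, 0] == pytest.approx(1.0, rel=1e-12)


def test_similarity_matrix_matches_double_loop(random_embedding):
    ga = [f"P{i + 1:06d}" for i in range(5)]
    gb = [f"P{i + 11:06d}" for i in range(7)]
    sim, rows, cols = dp.group_similarity_matrix(ga, gb, random_embedding)
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            assert sim[i, j] == pytest.approx(
                dp.cosine_similarity(random_embedding[a], random_embedding[b]), rel=1e-12
            )


def test_similarity_matrix_rejects_unembedded_group(random_embedding):
    with pytest.raises(ValueError, match="group A"):
        dp.group_similarity_matrix(["MISSING"], ["P000001"], random_embedding)


# -- proximity score --------------------------------------------------------


def test_single_pair_above_threshold():
    emb = unit_embedding({"Q": [1.0, 0.0], "B": [0.6, 0.8]})
    prof = dp.EntityProfile("CHEM1", "chemical", {"B": 1})
    res = dp.proximity_score(["Q"], prof, emb, tau=0.5)
    assert res.score == pytest.approx(0.6, rel=1e-12)
    assert res.n_contributing_pairs == 1 and res.n_scored_pairs == 1


def test_single_pair_below_threshold_scores_zero():
    emb = unit_embedding({"Q": [1.0, 0.0], "B": [0.4, np.sqrt(1 - 0.16)]})
    prof = dp.EntityProfile("CHEM1", "chemical", {"B": 1})
    res = dp.proximity_score(["Q"], prof, emb, tau=0.5)
    assert res.score == 0.0
    assert res.n_contributing_pairs == 0


def test_score_matches_bruteforce_on_random_instances(random_embedding):
    rng = np.random.default_rng(1)
    nodes = random_embedding.nodes
    for _ in range(25):
        query = list(rng.choice(nodes, rng.integers(1, 10), replace=False))
        prof_nodes = rng.choice(nodes, rng.integers(1, 12), replace=False)
        weights = {n: int(rng.integers(1, 9)) for n in prof_nodes}
        prof = dp.EntityProfile("CHEMX", "chemical", weights)
        for mode in dp.repositioning.WEIGHT_MODES:
            got = dp.proximity_score(query, prof, random_embedding, tau=0.5, weight_mode=mode)
            expect = dp.proximity_score_bruteforce(
                query, prof, random_embedding, tau=0.5, weight_mode=mode
            )
            assert got.score == pytest.approx(expect, rel=1e-12, abs=1e-12)


@given(st.integers(min_value=1, max_value=6))
def test_weight_linearity_raw_mode(factor):
    rng = np.random.default_rng(7)
    emb = dp.EmbeddingMatrix([f"N{i}" for i in range(10)], rng.normal(size=(10, 5)))
    weights = {f"N{i}": i + 1 for i in range(5)}
    prof1 = dp.EntityProfile("C", "chemical", weights)
    prof2 = dp.EntityProfile("C", "chemical", {k: v * factor for k, v in weights.items()})
    q = [f"N{i}" for i in range(5, 10)]
    s1 = dp.proximity_score(q, prof1, emb, tau=0.5).score
    s2 = dp.proximity_score(q, prof2, emb, tau=0.5).score
    assert s2 == pytest.approx(factor * s1, rel=1e-12, abs=1e-12)


def test_score_monotone_in_threshold(random_embedding):
    prof = dp.EntityProfile("C", "chemical", {n: 2 for n in random_embedding.nodes[:8]})
    q = random_embedding.nodes[10:20]
    scores = [
        dp.proximity_score(q, prof, random_embedding, tau=t).score
        for t in (0.0, 0.25, 0.5, 0.75, 0.9)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


def test_adding_profile_protein_never_decreases_score(random_embedding):
    q = random_embedding.nodes[:5]
    base = {n: 3 for n in random_embedding.nodes[10:14]}
    s0 = dp.proximity_score(q, dp.EntityProfile("C", "chemical", base), random_embedding).score
    for extra in random_embedding.nodes[14:20]:
        grown = {**base, extra: 5}
        s1 = dp.proximity_score(
            q, dp.EntityProfile("C", "chemical", grown), random_embedding
        ).score
        assert s1 >= s0 - 1e-12


def test_invalid_tau_and_empty_profile_rejected(random_embedding):
    prof = dp.EntityProfile("C", "chemical", {"P000001": 1})
    with pytest.raises(ValueError):
        dp.proximity_score(["P000002"], prof, random_embedding, tau=1.5)
    with pytest.raises(ValueError):
        dp.EntityProfile("C", "chemical", {})
    with pytest.raises(ValueError):
        dp.EntityProfile("C", "chemical", {"P000001": 0})


# -- ranking ----------------------------------------------------------------


def test_identical_profiles_tie_lexicographically(random_embedding):
    weights = {n: 2 for n in random_embedding.nodes[:6]}
    profs = [
        dp.EntityProfile(e, "chemical", weights) for e in ("CHEM_B", "CHEM_A", "CHEM_C")
    ]
    ranking, unscorable = dp.rank_chemicals(
        random_embedding.nodes[8:16], profs, random_embedding
    )
    assert list(ranking.entity) == ["CHEM_A", "CHEM_B", "CHEM_C"]
    assert ranking.network_score.nunique() == 1
    assert list(ranking["rank"]) == [1, 2, 3]
    assert unscorable == []


def test_self_profile_outranks_disjoint_random_profile():
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        g, _ = dp.gen_ppi_network(
            dp.SynthGraphConfig(block_sizes=(20, 20), p_in=0.4, p_out=0.02, seed=seed)
        )
        emb = dp.embed_graph(
            g,
            dp.WalkParams(num_walks_per_node=5, walk_length=20, seed=seed),
            dp.TrainParams(dimension=16, window=4, epochs=3, seed=seed),
        )
        query = [f"P{i + 1:06d}" for i in range(8)]  # block-0 members
        other = [f"P{i + 21:06d}" for i in range(8)]  # block-1 members
        profs = [
            dp.EntityProfile("CHEM_SELF", "chemical", {p: 1 for p in query}),
            dp.EntityProfile("CHEM_RAND", "chemical", {p: 1 for p in other}),
        ]
        ranking, _ = dp.rank_chemicals(query, profs, emb)
        if ranking.iloc[0].entity == "CHEM_SELF":
            wins += 1
    assert wins >= 3


def test_unscorable_profiles_reported(random_embedding):
    profs = [
        dp.EntityProfile("CHEM_OK", "chemical", {random_embedding.nodes[0]: 1}),
        dp.EntityProfile("CHEM_GHOST", "chemical", {"UNKNOWN": 1}),
    ]
    ranking, unscorable = dp.rank_chemicals(
        random_embedding.nodes[:4], profs, random_embedding
    )
    assert list(ranking.entity) == ["CHEM_OK"]
    assert unscorable[0][0] == "CHEM_GHOST"


# -- disease link -----------------------------------------------------------


def test_disease_score_self_similarity_is_maximal(random_embedding):
    nodes = random_embedding.nodes
    disease = dp.EntityProfile("DIS", "disease", {n: 2 for n in nodes[:6]})
    same = dp.EntityProfile("CHEM_SAME", "chemical", {n: 1 for n in nodes[:6]})
    other = dp.EntityProfile("CHEM_OTHER", "chemical", {n: 1 for n in nodes[6:12]})
    ranking, _ = dp.rank_chemicals(nodes[:10], [same, other], random_embedding)
    filled = dp.disease_link_scores(ranking, disease, [same, other], random_embedding)
    scores = dict(zip(filled.entity, filled.disease_score))
    assert scores["CHEM_SAME"] >= scores["CHEM_OTHER"]


def test_disease_score_zero_when_all_below_threshold():
    emb = unit_embedding({"A": [1.0, 0.0], "B": [0.0, 1.0], "Q": [1.0, 0.0]})
    chem = dp.EntityProfile("CHEM1", "chemical", {"A": 1})
    disease = dp.EntityProfile("DIS", "disease", {"B": 4})
    ranking, _ = dp.rank_chemicals(["Q"], [chem], emb, tau=0.5)
    filled = dp.disease_link_scores(ranking, disease, [chem], emb, tau=0.5)
    assert filled.iloc[0].disease_score == 0.0


def test_disease_scores_match_bruteforce(random_embedding):
    rng = np.random.default_rng(11)
    nodes = random_embedding.nodes
    chems = []
    for i in range(4):
        sup = rng.choice(nodes, 6, replace=False)
        chems.append(
            dp.EntityProfile(f"CHEM{i}", "chemical", {n: int(rng.integers(1, 5)) for n in sup})
        )
    disease = dp.EntityProfile(
        "DIS", "disease", {n: int(rng.integers(1, 5)) for n in rng.choice(nodes, 8, replace=False)}
    )
    ranking, _ = dp.rank_chemicals(nodes[:10], chems, random_embedding)
    filled = dp.disease_link_scores(ranking, disease, chems, random_embedding)
    for row in filled.itertuples():
        prof = next(c for c in chems if c.entity_id == row.entity)
        expect = dp.proximity_score_bruteforce(
            sorted(prof.weights), disease, random_embedding, tau=0.5
        )
        assert row.disease_score == pytest.approx(expect, rel=1e-12, abs=1e-12)


# -- candidate selection ----------------------------------------------------


def make_ranking(n, metabolite=()):
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "entity": [f"CHEM{i:02d}" for i in range(n)],
            "network_score": np.linspace(100, 10, n),
            "disease_score": np.linspace(5, 50, n),  # inverted on purpose
            "n_contributing_pairs": 1,
            "n_scored_pairs": 1,
            "is_metabolite": [f"CHEM{i:02d}" in metabolite for i in range(n)],
        }
    )


def test_select_candidates_two_stage_sort():
    out = dp.select_candidates(make_ranking(10), top_n=5, top_k=3)
    assert len(out) == 3
    # within the network top-5, re-ranked by disease score descending
    assert list(out.entity) == ["CHEM04", "CHEM03", "CHEM02"]
    assert (out.network_rank <= 5).all()
    assert list(out.final_rank) == [1, 2, 3]


def test_select_candidates_excludes_metabolites():
    out = dp.select_candidates(
        make_ranking(10, metabolite={"CHEM04"}), top_n=5, top_k=3
    )
    assert "CHEM04" not in set(out.entity)


def test_select_candidates_all_metabolites_returns_empty():
    ranking = make_ranking(4, metabolite={f"CHEM{i:02d}" for i in range(4)})
    out = dp.select_candidates(ranking, top_n=4, top_k=2)
    assert out.empty


def test_select_candidates_rejects_topk_over_topn():
    with pytest.raises(ValueError):
        dp.select_candidates(make_ranking(10), top_n=3, top_k=5)
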