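"""Annotation-based restriction and summarisation of dysregulated proteins.

Holds flat protein -> term-set annotations (GO biological-process terms and
PIR-style keywords), the fixed five-term metabolic GO scope used to restrict
the dysregulated set before network scoring, per-category tallies, and a
one-sided hypergeometric over-representation test.

No GO-graph ancestor propagation is performed: annotations are taken as
given flat sets.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

#: The five metabolic GO biological processes used to restrict the
#: dysregulated set (union semantics: any of the five qualifies).
METABOLIC_GO_TERMS: dict[str, str] = {
    "GO:0046034": "ATP metabolic process",
    "GO:0055114": "oxidation-reduction process",
    "GO:0005975": "carbohydrate metabolic process",
    "GO:0006629": "lipid metabolic process",
    "GO:0044267": "cellular protein metabolic process",
}

NAMESPACES = ("GO_BP", "PIR_keyword")


class AnnotationTable:
    """Flat protein -> term annotations plus term metadata.

    Parameters
    ----------
    protein_terms:
        mapping protein id -> iterable of term ids.
    term_info:
        mapping term id -> (namespace, description); every term referenced
        by a protein must be present.
    """

    def __init__(
        self,
        protein_terms: Mapping[str, Iterable[str]],
        term_info: Mapping[str, tuple[str, str]],
    ) -> None:
        self.protein_terms = {p: frozenset(ts) for p, ts in protein_terms.items()}
        self.term_info = dict(term_info)
        referenced = set().union(*self.protein_terms.values()) if self.protein_terms else set()
        dangling = referenced.difference(self.term_info)
        if dangling:
            raise ValueError(f"terms referenced but not defined: {sorted(dangling)[:5]}")

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.protein_terms.get(protein, frozenset())

    def members_of(self, term: str) -> frozenset[str]:
        return frozenset(p for p, ts in self.protein_terms.items() if term in ts)

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(t for t, (ns, _) in self.term_info.items() if ns == namespace)

    # -- GMT round trip -----------------------------------------------------
    # The GMT description field carries the namespace as "NAMESPACE|text";
    # files without the prefix default to GO_BP.

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.term_info):
                ns, desc = self.term_info[term]
                members = sorted(self.members_of(term))
                fh.write("\t".join([term, f"{ns}|{desc}"] + members) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "AnnotationTable":
        protein_terms: dict[str, set[str]] = {}
        term_info: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed GMT line {lineno}: {line!r}")
                term, desc = fields[0], fields[1]
                if "|" in desc:
                    ns, text = desc.split("|", 1)
                else:
                    ns, text = "GO_BP", desc
                term_info[term] = (ns, text)
                for p in fields[2:]:
                    protein_terms.setdefault(p, set()).add(term)
        return cls(protein_terms, term_info)


def filter_by_go(
    calls: pd.DataFrame,
    table: AnnotationTable,
    terms: Iterable[str] = METABOLIC_GO_TERMS,
    channel: int | None = None,
) -> set[str]:
    """Dysregulated proteins restricted to an annotation scope.

    Returns the proteins whose call in ``channel`` is up or down AND that
    carry at least one of ``terms`` (union semantics).  ``channel=None``
    pools calls over all channels.  Terms absent from the annotation table
    are ignored with a warning.
    """
    known = [t for t in terms if t in table.term_info]
    unknown = sorted(set(terms).difference(known))
    if unknown:
        warnings.warn(f"ignoring unknown annotation terms: {unknown}")
    sub = calls if channel is None else calls[calls["channel"] == channel]
    if channel is not None and sub.empty:
        raise ValueError(f"channel {channel} absent from the calls table")
    dysregulated = set(sub.loc[sub["call"] != "ns", "protein"])
    scope = frozenset(known)
    return {p for p in dysregulated if table.terms_of(p) & scope}


def tally_categories(
    selected: Iterable[str],
    table: AnnotationTable,
    namespace: str = "GO_BP",
    denominator: int | None = None,
) -> pd.DataFrame:
    """Per-term counts and percentages among a selected protein set.

    ``percent = 100 * count / denominator`` where the denominator defaults
    to ``|selected|`` but may be overridden (e.g. all quantified proteins).
    Terms with zero count are suppressed; rows are sorted by descending
    percent, ties lexicographic by term id.
    """
    selected = sorted(set(selected))
    if not selected:
        raise ValueError("tally_categories requires a non-empty selection")
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    denom = len(selected) if denominator is None else int(denominator)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    counts: dict[str, int] = {}
    for p in selected:
        for t in table.terms_of(p):
            if table.term_info[t][0] == namespace:
                counts[t] = counts.get(t, 0) + 1
    rows = [
        (t, table.term_info[t][1], k, 100.0 * k / denom) for t, k in counts.items()
    ]
    rows.sort(key=lambda r: (-r[3], r[0]))
    return pd.DataFrame(rows, columns=["term", "description", "count", "percent"])


def ora_hypergeometric(
    selected: Iterable[str],
    universe: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    fdr: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test.

    For each term with K members in the universe of size N, and k members
    among the n selected proteins, p = P(X >= k) for X ~
    Hypergeometric(N, K, n).  Term members outside the universe are
    dropped.  ``fdr=True`` appends Benjamini-Hochberg q-values.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected proteins must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term in sorted(term_sets):
        members = set(term_sets[term]) & universe
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_one_sided"])
    if fdr and len(out):
        out["q_bh"] = stats.false_discovery_control(out["p_one_sided"], method="bh")
    return out
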