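"""Metabolite-set over-representation analysis and pathway networks.

Given a query list of altered metabolites and a GMT-style set library,
each set is scored with the upper-tail hypergeometric probability of
observing at least the seen number of members in a random draw of the
query size from the universe, plus an enrichment ratio (observed hits /
expected hits).  Sets sharing member metabolites are linked into a
pathway network whose node attributes carry the enrichment ratio and
p-value (the usual size/color encoding of enrichment plots).

Metabolite names are normalized (lowercase, punctuation stripped) and
mapped through an editable alias table before matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_adjust

__all__ = [
    "MetaboliteSetLibrary",
    "EnrichmentResult",
    "read_gmt",
    "load_builtin_library",
    "hypergeometric_ora",
    "pathway_network",
]

_PUNCT = re.compile(r"[^a-z0-9\- ]+")


def _load_aliases() -> dict[str, str]:
    text = resources.files("psametab.data").joinpath("aliases.tsv").read_text()
    aliases = {}
    for line in text.strip().splitlines()[1:]:
        alias, canonical = line.split("\t")
        aliases[alias.strip().lower()] = canonical.strip().lower()
    return aliases


def normalize_name(name: str, aliases: dict[str, str] | None = None) -> str:
    """Lowercase, strip punctuation, fold common synonyms."""
    s = _PUNCT.sub("", str(name).strip().lower())
    s = re.sub(r"\s+", " ", s)
    if aliases is None:
        aliases = _load_aliases()
    return aliases.get(s, s)


@dataclass
class MetaboliteSetLibrary:
    """Named metabolite sets (GMT semantics) with normalized members."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty set(s): {empty}")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


def read_gmt(path, aliases: dict[str, str] | None = None) -> MetaboliteSetLibrary:
    """Parse a GMT file: name <tab> description <tab> member...

    Trailing empty fields are dropped per GMT convention; member names are
    normalized through the alias table.
    """
    if aliases is None:
        aliases = _load_aliases()
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = fields[0].strip()
            members = [normalize_name(m, aliases) for m in fields[2:] if m.strip()]
            sets[name] = sorted(set(members))
            desc[name] = fields[1].strip()
    return MetaboliteSetLibrary(sets=sets, descriptions=desc)


def load_builtin_library() -> MetaboliteSetLibrary:
    """The small curated pathway library shipped with the package."""
    import io as _io
    text = resources.files("psametab.data").joinpath("pathways.gmt").read_text()
    aliases = _load_aliases()
    sets, desc = {}, {}
    for line in text.strip().splitlines():
        fields = line.split("\t")
        sets[fields[0]] = sorted({normalize_name(m, aliases)
                                  for m in fields[2:] if m.strip()})
        desc[fields[0]] = fields[1]
    return MetaboliteSetLibrary(sets=sets, descriptions=desc)


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus what is needed to build the network."""

    table: pd.DataFrame           # index: set name; k, K, n, N, ratio, p, p_adj
    query: list[str]
    universe: list[str]
    hit_members: dict[str, list[str]]
    library: MetaboliteSetLibrary


def hypergeometric_ora(query, library: MetaboliteSetLibrary,
                       universe=None) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation across all sets.

    p = sum_{k' >= k} C(K,k') C(N-K, n-k') / C(N,n) per set, BH-adjusted
    across sets; sets ranked by raw p then by descending enrichment ratio.
    Query metabolites missing from the universe raise an error listing the
    unmapped names (no silent dropping).
    """
    aliases = _load_aliases()
    query_n = [normalize_name(q, aliases) for q in query]
    if len(set(query_n)) != len(query_n):
        raise ValueError("duplicate metabolites in query after normalization")
    if universe is None:
        uni = sorted(library.universe)
    else:
        uni = sorted({normalize_name(u, aliases) for u in universe})
    uniset = set(uni)
    unmapped = [q for q in query_n if q not in uniset]
    if unmapped:
        raise ValueError(f"query metabolites absent from universe: {unmapped}")

    N = len(uni)
    n = len(query_n)
    qset = set(query_n)
    rows, hits = [], {}
    for name, members in library.sets.items():
        mem = [m for m in members if m in uniset]
        K = len(mem)
        hit = sorted(qset.intersection(mem))
        k = len(hit)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        expected = n * K / N
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "enrichment_ratio": k / expected if expected > 0 else 0.0,
                     "p": min(1.0, p)})
        hits[name] = hit
    table = pd.DataFrame(rows).set_index("set")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["p", "enrichment_ratio"],
                              ascending=[True, False])
    return EnrichmentResult(table=table, query=query_n, universe=uni,
                            hit_members=hits, library=library)


def pathway_network(result: EnrichmentResult,
                    min_shared: int = 1) -> nx.Graph:
    """Graph of scored sets sharing member metabolites.

    Nodes are sets with at least one query hit, carrying their enrichment
    ratio (plot size) and p-value (plot color); edges join sets sharing at
    least ``min_shared`` universe members, weighted by the overlap count
    and annotated with the shared metabolites.
    """
    if len(result.table) < 2:
        raise ValueError("need at least 2 scored sets")
    G = nx.Graph()
    active = [s for s in result.table.index if result.table.loc[s, "k"] >= 1]
    uniset = set(result.universe)
    for s in active:
        G.add_node(s, enrichment_ratio=float(
            result.table.loc[s, "enrichment_ratio"]),
            p=float(result.table.loc[s, "p"]),
            k=int(result.table.loc[s, "k"]))
    for i, a in enumerate(active):
        mem_a = set(result.library.sets[a]) & uniset
        for b in active[i + 1:]:
            shared = mem_a & set(result.library.sets[b]) & uniset
            if len(shared) >= min_shared:
                G.add_edge(a, b, weight=len(shared),
                           shared=sorted(shared))
    return G
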