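"""CDRH3 sequence-similarity networks within clonotypes.

Each node is a unique clone; an edge connects two clones of the same clonotype
whose CDRH3 amino-acid sequences have equal length and Hamming distance exactly
1 (single somatic variants of one another).  Node sizes are log-scaled clonal
frequencies rescaled per mouse for display.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import ValidationError
from .repertoire import Clone, MultiOrganRepertoire

__all__ = [
    "build_similarity_network",
    "degree_distribution",
    "select_top_diverse_clonotypes",
    "clonotype_networks",
    "rescale_node_sizes",
]


def _hamming1(a: str, b: str) -> bool:
    """True iff equal-length strings differ at exactly one position."""
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def build_similarity_network(
    clonotype_members: Sequence[Clone], organ: Optional[str] = None
) -> nx.Graph:
    """Hamming-distance-1 CDRH3 network over the clones of one clonotype.

    Node attributes: ``frequency`` (clonal frequency in ``organ``, or summed
    over occupied organs when no organ is given), ``organs`` (occupancy set),
    ``clonotype_id`` and ``log_size`` (log10 frequency; rescale with
    :func:`rescale_node_sizes` for display).
    """
    ids = {c.clonotype_id for c in clonotype_members}
    if len(ids) > 1:
        raise ValidationError(f"members span multiple clonotypes: {sorted(ids)}")
    g = nx.Graph()
    members = sorted(clonotype_members, key=lambda c: c.key)
    for c in members:
        if organ is not None:
            freq = c.frequencies.get(organ, 0.0)
        else:
            freq = sum(c.frequencies.values())
        g.add_node(
            c.key,
            frequency=freq,
            log_size=math.log10(freq) if freq > 0 else float("nan"),
            organs=",".join(sorted(c.organs)),
            clonotype_id=c.clonotype_id or "",
        )
    # clonotype members share CDRH3 length by construction, but stay defensive
    by_len: dict[int, list[Clone]] = {}
    for c in members:
        by_len.setdefault(len(c.cdrh3_aa), []).append(c)
    for group in by_len.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if _hamming1(a.cdrh3_aa, b.cdrh3_aa):
                    g.add_edge(a.key, b.key)
    return g


def degree_distribution(networks: Iterable[nx.Graph]) -> dict[int, float]:
    """Fraction of clones per node degree, pooled over networks."""
    counts: dict[int, int] = {}
    total = 0
    for g in networks:
        for _, deg in g.degree():
            counts[deg] = counts.get(deg, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {d: c / total for d, c in sorted(counts.items())}


def select_top_diverse_clonotypes(
    repertoire: MultiOrganRepertoire,
    k: int = 5,
    organ: Optional[str] = None,
    mouse_id: Optional[str] = None,
) -> list[str]:
    """The k clonotypes with the most unique member clones in one organ.

    Ties are broken by higher summed clonal frequency, then lexicographic
    clonotype id.  Returns fewer than k ids when fewer clonotypes exist.
    """
    mice = repertoire.mice if mouse_id is None else [mouse_id]
    if len(mice) != 1:
        raise ValidationError("select_top_diverse_clonotypes needs a single mouse")
    clones = repertoire.clones if organ is None else repertoire.organ_clones(organ)
    clones = [c for c in clones if c.mouse_id == mice[0]]
    stats: dict[str, list] = {}
    for c in clones:
        if c.clonotype_id is None:
            raise ValidationError("clonotypes must be assigned before selection")
        entry = stats.setdefault(c.clonotype_id, [0, 0.0])
        entry[0] += 1
        entry[1] += c.frequencies.get(organ, 0.0) if organ else sum(
            c.frequencies.values()
        )
    ranked = sorted(stats.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    return [ct for ct, _ in ranked[:k]]


def clonotype_networks(
    repertoire: MultiOrganRepertoire,
    mouse_id: str,
    k: int = 5,
    size_range: tuple[float, float] = (1.0, 10.0),
) -> dict[str, dict[str, nx.Graph]]:
    """Per-organ networks of the k most diverse clonotypes of one mouse.

    Node sizes are rescaled jointly across all returned networks so that sizes
    are comparable within the mouse.
    """
    out: dict[str, dict[str, nx.Graph]] = {}
    members: dict[str, list[Clone]] = {}
    for c in repertoire.clones:
        if c.mouse_id == mouse_id and c.clonotype_id is not None:
            members.setdefault(c.clonotype_id, []).append(c)
    for organ in repertoire.organs:
        top = select_top_diverse_clonotypes(
            repertoire, k=k, organ=organ, mouse_id=mouse_id
        )
        out[organ] = {
            ct: build_similarity_network(
                [c for c in members[ct] if organ in c.counts], organ=organ
            )
            for ct in top
        }
    rescale_node_sizes(
        [g for per_organ in out.values() for g in per_organ.values()], size_range
    )
    return out


def rescale_node_sizes(
    networks: Iterable[nx.Graph], size_range: tuple[float, float] = (1.0, 10.0)
) -> None:
    """Linearly rescale log10-frequency node sizes into ``size_range`` in place."""
    lo, hi = size_range
    logs = [
        d["log_size"]
        for g in networks
        for _, d in g.nodes(data=True)
        if not math.isnan(d["log_size"])
    ]
    if not logs:
        return
    lmin, lmax = min(logs), max(logs)
    span = lmax - lmin
    for g in networks:
        for _, d in g.nodes(data=True):
            if math.isnan(d["log_size"]):
                d["size"] = lo
            elif span == 0:
                d["size"] = hi
            else:
                d["size"] = lo + (d["log_size"] - lmin) / span * (hi - lo)
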