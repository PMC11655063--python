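"""Clone sharing and repertoire similarity across lymphoid organs.

Pairwise similarity uses the Jaccard index on clone sets,

    J(A, B) = |A n B| / (|A| + |B| - |A n B|),

and cosine similarity on clonal frequency vectors over the union of clones,

    cos(A, B) = sum_i A_i B_i / (sqrt(sum_i A_i^2) * sqrt(sum_i B_i^2)).

V-gene usage similarity is the Pearson correlation of per-sample unique-clone
counts per germline V gene (unweighted by clonal frequency).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .repertoire import MultiOrganRepertoire

__all__ = [
    "jaccard_index",
    "cosine_similarity",
    "pairwise_similarity",
    "organ_overlap_counts",
    "vgene_usage_correlation",
    "match_binders",
    "SimilarityMatrix",
    "OverlapResult",
    "BinderResult",
]


def jaccard_index(rep_a: Iterable, rep_b: Iterable) -> float:
    """Intersection-over-union of two clone sets; NaN if both are empty."""
    a, b = set(rep_a), set(rep_b)
    union = len(a) + len(b) - len(a & b)
    if union == 0:
        return float("nan")
    return len(a & b) / union


def cosine_similarity(freq_a: Mapping, freq_b: Mapping) -> float:
    """Frequency-weighted similarity over the union of clones of A and B.

    Clones absent from one repertoire contribute 0 to its vector; a zero
    vector yields NaN.
    """
    norm_a = math.sqrt(sum(v * v for v in freq_a.values()))
    norm_b = math.sqrt(sum(v * v for v in freq_b.values()))
    if norm_a == 0 or norm_b == 0:
        return float("nan")
    shared = set(freq_a) & set(freq_b)
    dot = sum(freq_a[k] * freq_b[k] for k in shared)
    return dot / (norm_a * norm_b)


@dataclass
class SimilarityMatrix:
    """Square pairwise-similarity matrix with its metric name."""

    values: pd.DataFrame
    metric: str
    leaf_order: Optional[list] = None

    @property
    def labels(self) -> list:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def pairwise_similarity(
    repertoire: MultiOrganRepertoire,
    metric: str = "jaccard",
    mouse_id: Optional[str] = None,
) -> SimilarityMatrix:
    """All-organ pairwise Jaccard or cosine similarity for one mouse."""
    mice = repertoire.mice if mouse_id is None else [mouse_id]
    if len(mice) != 1:
        raise ValidationError("pairwise_similarity needs a single mouse")
    mouse = mice[0]
    organs = repertoire.organs
    mat = pd.DataFrame(np.eye(len(organs)), index=organs, columns=organs)
    for a, b in itertools.combinations(organs, 2):
        if metric == "jaccard":
            val = jaccard_index(
                repertoire.clone_keys(a, mouse), repertoire.clone_keys(b, mouse)
            )
        elif metric == "cosine":
            val = cosine_similarity(
                repertoire.frequencies(a, mouse), repertoire.frequencies(b, mouse)
            )
        else:
            raise ValidationError(f"unknown metric {metric!r}")
        mat.loc[a, b] = mat.loc[b, a] = val
    return SimilarityMatrix(values=mat, metric=metric)


@dataclass
class OverlapResult:
    """Organ-occupancy structure of a multi-organ repertoire."""

    degrees: pd.DataFrame  # one row per clone: key, degree, organ set
    degree_histogram: dict  # degree -> number of clones
    venn: Optional[dict] = None  # frozenset(organs) -> exact-cell clone count

    def clones_in_at_least(self, n: int) -> int:
        return sum(v for d, v in self.degree_histogram.items() if d >= n)

    def clones_in_exactly(self, n: int) -> int:
        return self.degree_histogram.get(n, 0)


def organ_overlap_counts(
    repertoire: MultiOrganRepertoire,
    mouse_id: Optional[str] = None,
    max_venn_organs: int = 16,
) -> OverlapResult:
    """Per-clone organ-occupancy degree, degree histogram and Venn partition.

    The full 2^k - 1 Venn partition is refused for more than
    ``max_venn_organs`` organs (combinatorial guard); degrees are always
    computed.
    """
    mice = repertoire.mice if mouse_id is None else [mouse_id]
    if len(mice) != 1:
        raise ValidationError("organ_overlap_counts needs a single mouse")
    clones = [c for c in repertoire.clones if c.mouse_id == mice[0]]
    if len(repertoire.organs) < 2:
        raise ValidationError("overlap analysis requires at least 2 organs")

    rows = []
    hist: dict[int, int] = {}
    venn: Optional[dict] = (
        {} if len(repertoire.organs) <= max_venn_organs else None
    )
    for c in clones:
        occ = c.organs
        rows.append({"key": c.key, "degree": c.degree, "organs": tuple(sorted(occ))})
        hist[c.degree] = hist.get(c.degree, 0) + 1
        if venn is not None:
            venn[occ] = venn.get(occ, 0) + 1
    return OverlapResult(
        degrees=pd.DataFrame(rows, columns=["key", "degree", "organs"]),
        degree_histogram=hist,
        venn=venn,
    )


def vgene_usage_correlation(
    clone_tables: Mapping[str, Iterable], cluster: bool = True
) -> SimilarityMatrix:
    """Pearson correlation of germline V-gene usage between samples.

    ``clone_tables`` maps a sample label to its clone keys (tuples starting
    with the V gene).  Usage counts unique clones per V gene without frequency
    weighting; correlations are taken over the union of V genes with absent
    genes counted as 0.  With ``cluster`` an average-linkage hierarchy on
    1 - r supplies a heatmap leaf order.
    """
    labels = list(clone_tables)
    if len(labels) < 2:
        raise ValidationError("need at least 2 samples")
    counts: dict[str, dict[str, int]] = {}
    all_v: set[str] = set()
    for label in labels:
        usage: dict[str, int] = {}
        for key in set(clone_tables[label]):
            v = key[0] if isinstance(key, tuple) else str(key)
            usage[v] = usage.get(v, 0) + 1
        counts[label] = usage
        all_v.update(usage)
    vgenes = sorted(all_v)
    mat = np.array(
        [[counts[label].get(v, 0) for v in vgenes] for label in labels], dtype=float
    )

    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, j in itertools.combinations(range(len(labels)), 2):
        xi, xj = mat[i], mat[j]
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            val = float("nan")  # constant usage vector: correlation undefined
        else:
            val = float(np.corrcoef(xi, xj)[0, 1])
        r.iloc[i, j] = r.iloc[j, i] = val

    leaf_order = None
    if cluster and not r.isna().any().any():
        dist = squareform((1.0 - r.values), checks=False)
        order = leaves_list(linkage(dist, method="average"))
        leaf_order = [labels[i] for i in order]
    return SimilarityMatrix(values=r, metric="pearson_vgene", leaf_order=leaf_order)


@dataclass
class BinderResult:
    """Antigen-binder annotation of a repertoire by CDRH3 matching."""

    flags: pd.DataFrame  # key, degree, binder flag, mean frequency
    ratio_by_degree: dict  # degree -> (# binder clones) / (# clones)
    frequency_table: pd.DataFrame  # long format for frequency-vs-degree stats

    @property
    def n_binders(self) -> int:
        return int(self.flags["binder"].sum())


def match_binders(
    binder_cdrh3: Iterable[str],
    repertoire: MultiOrganRepertoire,
    mouse_id: Optional[str] = None,
    match_vj: bool = False,
    binder_keys: Optional[Iterable[tuple]] = None,
) -> BinderResult:
    """Flag antigen-binding clones and relate binding to organ overlap.

    Matching is by CDRH3 amino-acid sequence alone (the screening readout);
    ``match_vj`` switches to strict (V, J, CDRH3) key matching, in which case
    ``binder_keys`` must supply full keys.  Returns per-degree binder/all
    ratios and the clonal-frequency table underlying frequency-vs-overlap
    correlations.
    """
    binder_set = set(binder_cdrh3)
    if match_vj:
        if binder_keys is None:
            raise ValidationError("match_vj=True requires binder_keys")
        binder_key_set = {tuple(k[:3]) for k in binder_keys}
    if not binder_set and not (match_vj and binder_key_set):
        raise ValidationError("binder set must be non-empty")

    mice = repertoire.mice if mouse_id is None else [mouse_id]
    if len(mice) != 1:
        raise ValidationError("match_binders needs a single mouse")
    clones = [c for c in repertoire.clones if c.mouse_id == mice[0]]

    rows = []
    freq_rows = []
    per_degree: dict[int, list[int]] = {}
    for c in clones:
        if match_vj:
            is_binder = tuple(c.key[:3]) in binder_key_set
        else:
            is_binder = c.cdrh3_aa in binder_set
        rows.append(
            {
                "key": c.key,
                "degree": c.degree,
                "binder": is_binder,
                "mean_frequency": c.mean_frequency(),
            }
        )
        per_degree.setdefault(c.degree, []).append(int(is_binder))
        for organ, freq in c.frequencies.items():
            freq_rows.append(
                {
                    "key": c.key,
                    "organ": organ,
                    "degree": c.degree,
                    "binder": is_binder,
                    "frequency": freq,
                }
            )

    ratios = {d: sum(v) / len(v) for d, v in sorted(per_degree.items())}
    return BinderResult(
        flags=pd.DataFrame(rows, columns=["key", "degree", "binder", "mean_frequency"]),
        ratio_by_degree=ratios,
        frequency_table=pd.DataFrame(
            freq_rows, columns=["key", "organ", "degree", "binder", "frequency"]
        ),
    )
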