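"""Clone assignment, clonotype clustering, clonal expansion and diversity.

Diversity is quantified with Hill numbers: for a clonal frequency distribution
f = (f_1, ..., f_n),

    D(alpha) = (sum_i f_i**alpha) ** (1 / (1 - alpha)),

with the limits D(0) = n (species richness, SR) and
D(1) = exp(-sum_i f_i ln f_i) (exponential Shannon entropy).  Evenness is
E(alpha) = D(alpha) / SR, equal to 1 for a uniform repertoire and close to 0
when a few expanded clones dominate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import default_alpha_grid
from .errors import ValidationError
from .repertoire import Clone, MultiOrganRepertoire, SequenceRecord, strip_allele

__all__ = [
    "assign_clones",
    "cluster_clonotypes",
    "expansion_profile",
    "hill_diversity",
    "evenness_profile",
    "shm_load",
    "DiversityProfile",
]


def clone_key(record: SequenceRecord, mode: str = "heavy") -> tuple:
    """Clone aggregation key: germline V and J (allele-stripped) plus CDRH3.

    In 'paired' mode the light-chain CDRL3 is part of the key as well, following
    the single-cell definition of a clone.
    """
    v = strip_allele(record.v_gene)
    j = strip_allele(record.j_gene)
    if mode == "heavy":
        return (v, j, record.cdrh3_aa)
    if mode == "paired":
        if record.cdrl3_aa is None:
            raise ValidationError(
                f"record {record.sequence_id} lacks cdrl3_aa required by paired mode"
            )
        return (v, j, record.cdrh3_aa, record.cdrl3_aa)
    raise ValidationError(f"unknown clone-key mode {mode!r}")


def assign_clones(
    records: Iterable[SequenceRecord], mode: str = "heavy"
) -> MultiOrganRepertoire:
    """Aggregate reads into clones, one per distinct key per mouse.

    Per-organ frequency of a clone is its organ read count divided by the total
    read count of that (mouse, organ) sample.
    """
    records = list(records)
    if not records:
        raise ValidationError("assign_clones requires at least one record")

    clones: dict[tuple, Clone] = {}
    organ_totals: dict[tuple, int] = {}
    for rec in records:
        key = clone_key(rec, mode)
        ck = (rec.mouse_id, key)
        clone = clones.get(ck)
        if clone is None:
            clone = clones[ck] = Clone(key=key, mouse_id=rec.mouse_id)
        clone.counts[rec.organ] = clone.counts.get(rec.organ, 0) + rec.count
        clone.member_ids.append(rec.sequence_id)
        tk = (rec.mouse_id, rec.organ)
        organ_totals[tk] = organ_totals.get(tk, 0) + rec.count

    for (mouse, _), clone in clones.items():
        for organ, count in clone.counts.items():
            clone.frequencies[organ] = count / organ_totals[(mouse, organ)]

    return MultiOrganRepertoire(clones.values())


def _identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length strings."""
    return sum(x == y for x, y in zip(a, b)) / len(a)


def cluster_clonotypes(
    clones: Sequence[Clone],
    identity_threshold: float = 0.90,
    inclusive: bool = False,
) -> dict:
    """Single-linkage clonotype clustering of clones.

    Two clones are linked iff they share V gene, J gene and CDRH3 length, and
    their CDRH3 amino-acid identity exceeds ``identity_threshold`` (strictly;
    with ``inclusive`` the boundary case, normalised Hamming distance exactly
    1 - threshold, also links).  Connected components are clonotypes, clustered
    within each mouse.  Assigns ``clonotype_id`` on the clones and returns a
    mapping (mouse_id, key) -> clonotype id.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValidationError("identity threshold must lie in (0, 1]")

    order = sorted(range(len(clones)), key=lambda i: (clones[i].mouse_id, clones[i].key))
    parent = list(range(len(clones)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            # keep the smaller index as root for stable ids
            if ri > rj:
                ri, rj = rj, ri
            parent[rj] = ri

    groups: dict[tuple, list[int]] = {}
    for idx in order:
        c = clones[idx]
        groups.setdefault(
            (c.mouse_id, c.v_gene, c.j_gene, len(c.cdrh3_aa)), []
        ).append(idx)

    for members in groups.values():
        for a_pos, i in enumerate(members):
            ci = clones[i].cdrh3_aa
            for j in members[a_pos + 1 :]:
                ident = _identity(ci, clones[j].cdrh3_aa)
                if ident > identity_threshold or (
                    inclusive and math.isclose(ident, identity_threshold)
                ):
                    union(i, j)

    assignment: dict = {}
    root_to_id: dict[int, str] = {}
    counters: dict[str, int] = {}
    for idx in order:
        root = find(idx)
        if root not in root_to_id:
            mouse = clones[root].mouse_id
            counters[mouse] = counters.get(mouse, 0) + 1
            root_to_id[root] = f"{mouse}.CT{counters[mouse]:05d}"
        clones[idx].clonotype_id = root_to_id[root]
        assignment[(clones[idx].mouse_id, clones[idx].key)] = root_to_id[root]
    return assignment


def expansion_profile(
    frequencies: Mapping, rank_bins: Sequence[int]
) -> list[tuple[str, float]]:
    """Fraction of the repertoire occupied by frequency-ranked clone bins.

    ``frequencies`` maps clone key -> frequency; ``rank_bins`` is an ascending
    list of upper rank cutoffs (e.g. [3, 10] gives bins ranks 1-3 and 4-10).  A
    final residual bin is appended if the last cutoff does not cover all clones.
    Ties in frequency are broken lexicographically on CDRH3 for determinism.
    """
    if not frequencies:
        return []
    cutoffs = list(rank_bins)
    if cutoffs != sorted(cutoffs) or any(c < 1 for c in cutoffs):
        raise ValidationError("rank_bins must be ascending positive rank cutoffs")

    def sort_key(item):
        key, freq = item
        cdrh3 = key[2] if isinstance(key, tuple) and len(key) >= 3 else str(key)
        return (-freq, cdrh3, str(key))

    ranked = [f for _, f in sorted(frequencies.items(), key=sort_key)]
    n = len(ranked)
    if not cutoffs or cutoffs[-1] < n:
        cutoffs.append(n)
    out: list[tuple[str, float]] = []
    start = 0
    for cut in cutoffs:
        stop = min(cut, n)
        if stop <= start:
            continue
        out.append((f"{start + 1}-{stop}", float(sum(ranked[start:stop]))))
        start = stop
        if start >= n:
            break
    return out


def _check_frequencies(f: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValidationError("frequency vector is empty")
    if np.any(f <= 0):
        raise ValidationError("all frequencies must be > 0 (drop zero-frequency clones)")
    if abs(f.sum() - 1.0) > tol:
        raise ValidationError(f"frequencies sum to {f.sum():.8f}, not 1 within {tol}")
    return f


def hill_diversity(frequencies, alpha: float) -> float:
    """Hill number D(alpha) of a clonal frequency distribution.

    alpha = 0 returns species richness; alpha = 1 returns the Shannon limit
    exp(-sum f ln f); otherwise the closed form (sum f**alpha)**(1/(1-alpha)).
    """
    f = _check_frequencies(frequencies)
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    if alpha == 0:
        return float(f.size)
    if math.isclose(alpha, 1.0, abs_tol=1e-12):
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f**alpha) ** (1.0 / (1.0 - alpha)))


@dataclass
class DiversityProfile:
    """Hill diversity and evenness evaluated over a grid of orders alpha."""

    alphas: np.ndarray
    diversity: np.ndarray
    evenness: np.ndarray
    richness: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"alpha": self.alphas, "D": self.diversity, "E": self.evenness}
        )


def evenness_profile(
    frequencies, alpha_grid: Optional[Sequence[float]] = None
) -> DiversityProfile:
    """Evenness E(alpha) = D(alpha)/SR over a grid of alpha values."""
    f = _check_frequencies(frequencies)
    alphas = np.asarray(
        default_alpha_grid() if alpha_grid is None else list(alpha_grid), dtype=float
    )
    d = np.array([hill_diversity(f, a) for a in alphas])
    sr = f.size
    return DiversityProfile(alphas=alphas, diversity=d, evenness=d / sr, richness=sr)


#: characters treated as uninformative when counting mutations
_AMBIGUOUS_NT = frozenset("Nn.-")


def shm_load(
    v_region_nt: str, germline_nt: str, region_end: int = 312
) -> Optional[float]:
    """Somatic-hypermutation load of one sequence.

    Length-normalised Hamming distance to the germline over IMGT positions
    1..``region_end`` of the V region.  Positions where either sequence carries
    an ambiguous nucleotide (N) or a gap are excluded from both numerator and
    denominator.  Returns None when no position is comparable.
    """
    limit = min(region_end, len(v_region_nt), len(germline_nt))
    mismatches = comparable = 0
    for i in range(limit):
        a, b = v_region_nt[i], germline_nt[i]
        if a in _AMBIGUOUS_NT or b in _AMBIGUOUS_NT:
            continue
        comparable += 1
        if a.upper() != b.upper():
            mismatches += 1
    if comparable == 0:
        return None
    return mismatches / comparable
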