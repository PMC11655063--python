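"""Synthetic multi-organ antibody repertoires and organ-labeled lineage trees.

The generator emulates the structure of an IgG VH deep-sequencing study of
murine lymphoid organs: six organs (bone marrow, spleen, paired axillary and
inguinal lymph nodes) per mouse, three mice per cohort, heavy-tailed
clone-frequency distributions (a discrete power law, so a handful of expanded
clones dominate each organ), partial clone sharing between organs, somatic
point-mutation variants attached to each founder clone, and Yule lineage
trees whose tip organs evolve under a Markov migration process.  Every output
is reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .clonal import assign_clones
from .errors import ValidationError
from .repertoire import CANONICAL_ORGANS, MultiOrganRepertoire, SequenceRecord
from .trees import LineageTree

__all__ = [
    "SimulationConfig",
    "simulate_records",
    "simulate_repertoire",
    "simulate_lineage_trees",
    "uniform_migration_matrix",
    "biased_migration_matrix",
    "study_config",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


def _default_v_pool() -> tuple:
    return tuple(
        [f"IGHV1-{i}" for i in range(1, 16)]
        + [f"IGHV5-{i}" for i in range(1, 10)]
        + [f"IGHV9-{i}" for i in range(1, 6)]
    )


def uniform_migration_matrix(organs: Sequence[str]) -> np.ndarray:
    """Identical uniform rows: tip organs become i.i.d. (exchangeable labels)."""
    k = len(organs)
    return np.full((k, k), 1.0 / k)


def biased_migration_matrix(
    organs: Sequence[str],
    source: str,
    target: str,
    rate: float,
    stay: float = 0.9,
) -> np.ndarray:
    """Mostly-diagonal matrix with extra ``source`` -> ``target`` mass ``rate``.

    Off-diagonal leakage (1 - stay) is spread uniformly from every organ; the
    source row additionally moves ``rate`` of its mass to the target.
    """
    organs = list(organs)
    k = len(organs)
    q = np.full((k, k), (1.0 - stay) / (k - 1))
    np.fill_diagonal(q, stay)
    si, ti = organs.index(source), organs.index(target)
    q[si, si] -= rate
    q[si, ti] += rate
    if np.any(q < 0):
        raise ValidationError("bias rate too large for the chosen stay probability")
    return q


@dataclass
class SimulationConfig:
    """Parameters of the synthetic repertoire and lineage-tree generator.

    Repertoire: ``n_founder_clones`` founders per mouse each receive a V gene,
    J gene and CDRH3; every founder has a home organ and joins each other
    organ with probability ``p_share`` (global float, or a mapping
    (home, other) -> probability).  Per-organ clone weights follow
    rank**(-expansion_exponent) modulated by lognormal noise of sigma
    ``frequency_noise_sigma``; counts are multinomial draws of
    ``reads_per_organ`` reads (``count_mode='expected'`` rounds the expected
    counts instead, for exactly reproducible frequency vectors).  Each founder
    spawns Poisson(``variants_per_clone_mean``) somatic variants; a variant
    copies a random existing member with max(1, Binomial(L, shm_rate)) CDRH3
    substitutions, capped so single-linkage clustering at 90% identity keeps
    the family in one clonotype.

    Trees: Yule topologies of Poisson(``tree_size_mean``) tips (min
    ``tree_size_min``); tip organs evolve from ``founder_organ`` by one
    application of ``migration_matrix`` per branch (``migration_mode='per_length'``
    applies it Poisson(length x migration_length_rate) times instead).
    """

    organs: tuple = CANONICAL_ORGANS
    mice: tuple = ("m1", "m2", "m3")
    n_founder_clones: int = 300
    p_share: Union[float, Mapping] = 0.05
    expansion_exponent: Union[float, Mapping] = 1.3
    frequency_noise_sigma: float = 0.5
    reads_per_organ: int = 3000
    count_mode: str = "multinomial"
    shm_rate: float = 0.02
    variants_per_clone_mean: float = 2.0
    clonotype_identity: float = 0.90
    v_gene_pool: tuple = field(default_factory=_default_v_pool)
    v_gene_decay: float = 0.90
    j_gene_pool: tuple = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4")
    j_gene_weights: tuple = (0.2, 0.3, 0.3, 0.2)
    cdrh3_length_mean: float = 14.0
    cdrh3_length_sd: float = 2.0
    cdrh3_length_bounds: tuple = (8, 22)
    with_nt: bool = True
    nt_region_length: int = 330
    nt_shm_rate: float = 0.01
    migration_matrix: Optional[np.ndarray] = None
    founder_organ: str = "spleen"
    migration_mode: str = "per_branch"
    migration_length_rate: float = 1.0
    n_trees: int = 60
    tree_size_mean: float = 20.0
    tree_size_min: int = 10
    branch_length_mean: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.organs) == 0:
            raise ValidationError("at least one organ is required")
        if self.n_founder_clones < 1:
            raise ValidationError("n_founder_clones must be positive")
        if isinstance(self.p_share, (int, float)) and not 0 <= self.p_share <= 1:
            raise ValidationError("p_share must lie in [0, 1]")
        if self.count_mode not in ("multinomial", "expected"):
            raise ValidationError("count_mode must be 'multinomial' or 'expected'")
        if self.migration_mode not in ("per_branch", "per_length"):
            raise ValidationError("migration_mode must be 'per_branch' or 'per_length'")
        if self.migration_matrix is not None:
            q = np.asarray(self.migration_matrix, dtype=float)
            k = len(self.organs)
            if q.shape != (k, k):
                raise ValidationError(
                    f"migration matrix must be {k}x{k} for {k} organs, got {q.shape}"
                )
            if np.any(q < 0) or np.any(q > 1) or not np.allclose(q.sum(axis=1), 1.0):
                raise ValidationError(
                    "migration matrix rows must be probability distributions"
                )
            self.migration_matrix = q

    def share_probability(self, home: str, other: str) -> float:
        if isinstance(self.p_share, Mapping):
            return float(self.p_share[(home, other)])
        return float(self.p_share)

    def expansion_for(self, organ: str) -> float:
        """Power-law exponent of the clone-frequency law in one organ."""
        if isinstance(self.expansion_exponent, Mapping):
            return float(self.expansion_exponent[organ])
        return float(self.expansion_exponent)


def study_config(cohort: str = "1x", **overrides) -> SimulationConfig:
    """Preset emulating one immunization cohort.

    Cohort '1x' (single immunization): little organ sharing and the strongest
    clonal expansion in the lymph nodes, milder in spleen and mildest in bone
    marrow.  Cohort '3x' (triple immunization): substantial sharing across
    organs and uniformly strong expansion everywhere.
    """
    if cohort == "1x":
        exponent = {
            "aLN-L": 1.9,
            "aLN-R": 1.9,
            "iLN-L": 1.9,
            "iLN-R": 1.9,
            "spleen": 1.5,
            "BM": 1.2,
        }
        base = dict(p_share=0.05, expansion_exponent=exponent, frequency_noise_sigma=0.8)
    elif cohort == "3x":
        base = dict(p_share=0.35, expansion_exponent=1.6, frequency_noise_sigma=0.4)
    else:
        raise ValidationError(f"unknown cohort {cohort!r}")
    base.update(overrides)
    return SimulationConfig(**base)


def _random_cdrh3(rng: np.random.Generator, length: int) -> str:
    middle = "".join(rng.choice(list(_AA), size=length - 2))
    return "C" + middle + "W"


def _mutate_cdrh3(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    chars = list(seq)
    positions = rng.choice(np.arange(1, len(chars) - 1), size=n_subs, replace=False)
    for p in positions:
        choices = [a for a in _AA if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n = rng.binomial(len(chars), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(chars), size=n, replace=False)
    for p in positions:
        choices = [a for a in _NT if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def simulate_records(config: SimulationConfig) -> list[SequenceRecord]:
    """Generate per-read sequence records for every mouse in the config."""
    rng = np.random.default_rng(config.seed)
    organs = list(config.organs)
    v_pool = list(config.v_gene_pool)
    v_weights = np.array([config.v_gene_decay**i for i in range(len(v_pool))])
    v_weights /= v_weights.sum()
    j_weights = np.asarray(config.j_gene_weights, dtype=float)
    j_weights = j_weights / j_weights.sum()
    lo, hi = config.cdrh3_length_bounds

    records: list[SequenceRecord] = []
    for mouse in config.mice:
        # founders: key attributes, home organ, organ membership
        clones: list[dict] = []
        for i in range(config.n_founder_clones):
            length = int(
                np.clip(
                    round(rng.normal(config.cdrh3_length_mean, config.cdrh3_length_sd)),
                    lo,
                    hi,
                )
            )
            cdrh3 = _random_cdrh3(rng, length)
            home = organs[rng.integers(len(organs))]
            membership = {home}
            for o in organs:
                if o != home and rng.random() < config.share_probability(home, o):
                    membership.add(o)
            germline = (
                "".join(rng.choice(list(_NT), size=config.nt_region_length))
                if config.with_nt
                else None
            )
            founder = {
                "v": v_pool[rng.choice(len(v_pool), p=v_weights)],
                "j": config.j_gene_pool[rng.choice(len(j_weights), p=j_weights)],
                "cdrh3": cdrh3,
                "rank": i + 1.0,
                "rel": 1.0,
                "organs": membership,
                "germline_nt": germline,
                "v_region_nt": _mutate_nt(rng, germline, config.nt_shm_rate)
                if germline
                else None,
                "family": i,
            }
            clones.append(founder)

            # somatic variants: single-linkage chain within the clonotype
            n_var = rng.poisson(config.variants_per_clone_mean)
            family = [founder]
            # mismatch budget keeping identity > clonotype threshold
            max_mm = max(1, int(np.ceil((1 - config.clonotype_identity) * length)) - 1)
            seen = {cdrh3}
            for _ in range(n_var):
                parent = family[rng.integers(len(family))]
                n_subs = min(max(1, rng.binomial(length, config.shm_rate)), max_mm)
                variant_seq = None
                for _attempt in range(20):
                    cand = _mutate_cdrh3(rng, parent["cdrh3"], n_subs)
                    if cand not in seen:
                        variant_seq = cand
                        break
                if variant_seq is None:
                    continue
                seen.add(variant_seq)
                variant = {
                    "v": founder["v"],
                    "j": founder["j"],
                    "cdrh3": variant_seq,
                    "rank": founder["rank"],
                    "rel": parent["rel"] * rng.uniform(0.05, 0.4),
                    "organs": membership,
                    "germline_nt": founder["germline_nt"],
                    "v_region_nt": _mutate_nt(rng, parent["v_region_nt"], config.nt_shm_rate)
                    if founder["germline_nt"]
                    else None,
                    "family": i,
                }
                family.append(variant)
                clones.append(variant)

        # per-organ frequencies and counts
        seq_no = 0
        for organ in organs:
            members = [c for c in clones if organ in c["organs"]]
            if not members:
                continue
            s = config.expansion_for(organ)
            weights = np.array([c["rank"] ** (-s) * c["rel"] for c in members])
            if config.frequency_noise_sigma > 0:
                weights = weights * rng.lognormal(
                    0.0, config.frequency_noise_sigma, size=len(members)
                )
            probs = weights / weights.sum()
            if config.count_mode == "multinomial":
                counts = rng.multinomial(config.reads_per_organ, probs)
            else:
                counts = np.rint(probs * config.reads_per_organ).astype(int)
            for c, n in zip(members, counts):
                if n == 0:
                    continue
                seq_no += 1
                records.append(
                    SequenceRecord(
                        sequence_id=f"{mouse}_{organ}_{seq_no:06d}",
                        organ=organ,
                        mouse_id=mouse,
                        v_gene=c["v"],
                        j_gene=c["j"],
                        cdrh3_aa=c["cdrh3"],
                        count=int(n),
                        v_region_nt=c["v_region_nt"],
                        germline_nt=c["germline_nt"],
                    )
                )
    return records


def simulate_repertoire(config: SimulationConfig) -> MultiOrganRepertoire:
    """Generate records and aggregate them into a multi-organ repertoire."""
    return assign_clones(simulate_records(config))


def _yule_topology(rng: np.random.Generator, n_tips: int, blen_mean: float):
    """Random bifurcating topology grown by uniform tip splitting."""
    parent = [-1]
    length = [0.0]
    tips = [0]
    while len(tips) < n_tips:
        pick = int(rng.integers(len(tips)))
        node = tips.pop(pick)
        for _ in range(2):
            parent.append(node)
            length.append(float(rng.exponential(blen_mean)))
            tips.append(len(parent) - 1)
    return parent, length, tips


def simulate_lineage_trees(
    config: SimulationConfig, n_trees: Optional[int] = None
) -> list[LineageTree]:
    """Organ-labeled Yule lineage trees under a Markov migration process.

    The root (basal ancestor, sitting just below the unlabeled germline) starts
    in ``config.founder_organ``; each branch applies the migration matrix once
    (or Poisson(length x rate) times in 'per_length' mode).  The true simulated
    transition counts and node organs are stored in ``tree.attrs`` for oracle
    comparisons.  Trees are assigned to mice round-robin.
    """
    if config.migration_matrix is None:
        raise ValidationError("config.migration_matrix is required to simulate trees")
    q = config.migration_matrix
    organs = list(config.organs)
    if config.founder_organ not in organs:
        raise ValidationError(f"founder organ {config.founder_organ!r} not in organs")
    rng = np.random.default_rng(config.seed)
    n_trees = config.n_trees if n_trees is None else n_trees

    trees: list[LineageTree] = []
    for t_idx in range(n_trees):
        n_tips = max(config.tree_size_min, int(rng.poisson(config.tree_size_mean)))
        parent, length, _ = _yule_topology(rng, n_tips, config.branch_length_mean)
        n = len(parent)
        # evolve organ states from the root down
        state = [-1] * n
        state[0] = organs.index(config.founder_organ)
        true_counts = np.zeros((len(organs), len(organs)), dtype=int)
        for v in range(1, n):  # parents precede children by construction
            s = state[parent[v]]
            if config.migration_mode == "per_branch":
                steps = 1
            else:
                steps = rng.poisson(length[v] * config.migration_length_rate)
            for _ in range(steps):
                nxt = int(rng.choice(len(organs), p=q[s]))
                if nxt != s:
                    true_counts[s, nxt] += 1
                s = nxt
            state[v] = s

        children = [[] for _ in range(n)]
        for v in range(1, n):
            children[parent[v]].append(v)
        names = [None] * n
        organ_labels = [None] * n
        tip_no = 0
        for v in range(n):
            if not children[v]:
                tip_no += 1
                names[v] = f"t{t_idx + 1}s{tip_no}"
                organ_labels[v] = organs[state[v]]
        mouse = config.mice[t_idx % len(config.mice)]
        trees.append(
            LineageTree(
                parent,
                length,
                names,
                organ_labels,
                clonotype_id=f"{mouse}.sim{t_idx + 1:04d}",
                mouse_id=mouse,
                attrs={
                    "true_transitions": true_counts,
                    "true_node_organs": [organs[s] for s in state],
                    "organs": organs,
                },
            )
        )
    return trees
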