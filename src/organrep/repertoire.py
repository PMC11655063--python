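"""In-memory containers for error-corrected antibody heavy-chain repertoires.

A *clone* is the set of reads with identical V gene, J gene and CDRH3 amino-acid
sequence (optionally also CDRL3 in paired heavy+light mode).  Clones are held per
mouse with per-organ read counts and frequencies normalised within each
(mouse, organ) sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ValidationError

#: the 20 proteinogenic amino acids plus X for an ambiguous residue
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: canonical lymphoid-organ labels used by the synthetic generator
CANONICAL_ORGANS = ("BM", "spleen", "aLN-L", "aLN-R", "iLN-L", "iLN-R")


def strip_allele(gene: str) -> str:
    """Truncate a germline gene call at the allele separator ('*')."""
    return gene.split("*", 1)[0]


@dataclass
class SequenceRecord:
    """One error-corrected VH read with its organ of origin.

    ``count`` is the number of reads (or duplicates) supporting the sequence.
    ``v_region_nt``/``germline_nt`` are optional aligned nucleotide sequences
    used only for somatic-hypermutation quantification.
    """

    sequence_id: str
    organ: str
    v_gene: str
    j_gene: str
    cdrh3_aa: str
    count: int = 1
    mouse_id: str = "m1"
    v_region_nt: Optional[str] = None
    germline_nt: Optional[str] = None
    cdrl3_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cdrh3_aa:
            raise ValidationError("cdrh3_aa must be non-empty")
        bad = set(self.cdrh3_aa) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"cdrh3_aa {self.cdrh3_aa!r} contains non-amino-acid symbols {sorted(bad)}"
            )
        if self.count < 1:
            raise ValidationError("count must be >= 1 for an observed record")


@dataclass
class Clone:
    """A unique (V, J, CDRH3[, CDRL3]) key within one mouse.

    ``counts``/``frequencies`` map organ label to the summed read count and the
    frequency normalised within that (mouse, organ) sample; organs where the
    clone was not observed are absent from both mappings.
    """

    key: tuple
    mouse_id: str
    counts: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    clonotype_id: Optional[str] = None
    member_ids: list = field(default_factory=list)

    @property
    def v_gene(self) -> str:
        return self.key[0]

    @property
    def j_gene(self) -> str:
        return self.key[1]

    @property
    def cdrh3_aa(self) -> str:
        return self.key[2]

    @property
    def organs(self) -> frozenset:
        return frozenset(self.counts)

    @property
    def degree(self) -> int:
        """Number of organs in which the clone was observed."""
        return len(self.counts)

    def mean_frequency(self) -> float:
        """Mean clonal frequency over the organs occupied by the clone."""
        return sum(self.frequencies.values()) / len(self.frequencies)


class MultiOrganRepertoire:
    """Organ-indexed clone tables for one or several mice."""

    def __init__(self, clones: Iterable[Clone], organs: Optional[Iterable[str]] = None):
        self.clones: list[Clone] = list(clones)
        if organs is None:
            seen: set[str] = set()
            for c in self.clones:
                seen.update(c.counts)
            organs = sorted(seen)
        self.organs: list[str] = list(organs)

    @property
    def mice(self) -> list[str]:
        return sorted({c.mouse_id for c in self.clones})

    def for_mouse(self, mouse_id: str) -> "MultiOrganRepertoire":
        return MultiOrganRepertoire(
            [c for c in self.clones if c.mouse_id == mouse_id], organs=self.organs
        )

    def organ_clones(self, organ: str, mouse_id: Optional[str] = None) -> list[Clone]:
        return [
            c
            for c in self.clones
            if organ in c.counts and (mouse_id is None or c.mouse_id == mouse_id)
        ]

    def clone_keys(self, organ: str, mouse_id: Optional[str] = None) -> set:
        return {c.key for c in self.organ_clones(organ, mouse_id)}

    def frequencies(self, organ: str, mouse_id: Optional[str] = None) -> dict:
        """Clone-key -> frequency table for one organ (single mouse only)."""
        mice = self.mice if mouse_id is None else [mouse_id]
        if len(mice) > 1:
            raise ValidationError(
                "frequencies() needs a single mouse; pass mouse_id explicitly"
            )
        mouse = mice[0] if mice else None
        return {
            c.key: c.frequencies[organ] for c in self.organ_clones(organ, mouse)
        }

    def to_frame(self):
        """Long-format clone table (one row per clone x occupied organ)."""
        import pandas as pd

        rows = []
        for c in self.clones:
            for organ in sorted(c.counts):
                rows.append(
                    {
                        "mouse_id": c.mouse_id,
                        "organ": organ,
                        "v_gene": c.v_gene,
                        "j_gene": c.j_gene,
                        "cdrh3_aa": c.cdrh3_aa,
                        "cdrl3_aa": c.key[3] if len(c.key) > 3 else None,
                        "clonotype_id": c.clonotype_id,
                        "count": c.counts[organ],
                        "frequency": c.frequencies[organ],
                    }
                )
        return pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.clones)

    def __repr__(self) -> str:
        return (
            f"MultiOrganRepertoire({len(self.clones)} clones, "
            f"{len(self.organs)} organs, {len(self.mice)} mice)"
        )
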