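"""Reading and writing external formats.

Repertoires travel as AIRR-Rearrangement-style TSV (``sequence_id``,
``v_call``, ``j_call``, ``junction_aa``, ``duplicate_count`` plus ``organ``
and ``mouse_id`` sample columns, overridable via a column map); lineage trees
as Newick plus a two-column tip -> organ label TSV.  All analysis modules
consume only the in-memory types produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import networkx as nx
import pandas as pd

from .errors import ConfigurationError, NewickParseError, ValidationError
from .repertoire import SequenceRecord
from .trees import LineageTree

__all__ = [
    "read_airr_table",
    "write_airr_table",
    "read_labeled_trees",
    "write_labeled_trees",
    "write_graphml",
    "FilterReport",
    "DEFAULT_COLUMNS",
]

#: AIRR Rearrangement column names for each record field
DEFAULT_COLUMNS = {
    "sequence_id": "sequence_id",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "cdrh3_aa": "junction_aa",
    "count": "duplicate_count",
    "organ": "organ",
    "mouse_id": "mouse_id",
    "v_region_nt": "sequence_alignment",
    "germline_nt": "germline_alignment",
    "cdrl3_aa": "junction_aa_light",
}

_OPTIONAL_FIELDS = ("v_region_nt", "germline_nt", "cdrl3_aa", "mouse_id")


@dataclass
class FilterReport:
    """Row-level filter counts from reading a repertoire table."""

    n_rows: int = 0
    dropped_empty_cdr3: int = 0
    dropped_stop_codon: int = 0
    dropped_zero_count: int = 0

    @property
    def n_kept(self) -> int:
        return (
            self.n_rows
            - self.dropped_empty_cdr3
            - self.dropped_stop_codon
            - self.dropped_zero_count
        )

    def as_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "dropped_empty_cdr3": self.dropped_empty_cdr3,
            "dropped_stop_codon": self.dropped_stop_codon,
            "dropped_zero_count": self.dropped_zero_count,
        }


def read_airr_table(
    path,
    organ_column: str = "organ",
    count_column: str = "duplicate_count",
    column_map: Optional[dict] = None,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Read an AIRR-style TSV into sequence records.

    Rows with an empty CDRH3, a stop codon ('*') in the CDRH3, or a
    non-positive/missing read count are dropped and tallied in the returned
    :class:`FilterReport`.  ``column_map`` overrides the AIRR default column
    for any record field (keys are field names such as ``cdrh3_aa``).
    """
    columns = dict(DEFAULT_COLUMNS)
    columns["organ"] = organ_column
    columns["count"] = count_column
    if column_map:
        unknown = set(column_map) - set(columns)
        if unknown:
            raise ConfigurationError(f"unknown record fields in column_map: {sorted(unknown)}")
        columns.update(column_map)

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read repertoire table {path}: {exc}") from exc

    required = [
        columns[f] for f in ("sequence_id", "v_gene", "j_gene", "cdrh3_aa", "count", "organ")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"repertoire table {path} lacks required column(s): {', '.join(missing)}"
        )

    report = FilterReport(n_rows=len(df))
    records: list[SequenceRecord] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        cdrh3 = row[columns["cdrh3_aa"]]
        if pd.isna(cdrh3) or cdrh3 == "":
            report.dropped_empty_cdr3 += 1
            continue
        if "*" in cdrh3:
            report.dropped_stop_codon += 1
            continue
        raw_count = row[columns["count"]]
        try:
            count = int(float(raw_count))
        except (TypeError, ValueError):
            count = 0
        if count <= 0:
            report.dropped_zero_count += 1
            continue
        kwargs = {}
        for f in _OPTIONAL_FIELDS:
            col = columns[f]
            if col in df.columns:
                val = row[col]
                if not (pd.isna(val) or val == ""):
                    kwargs[f] = val
        records.append(
            SequenceRecord(
                sequence_id=row[columns["sequence_id"]],
                organ=row[columns["organ"]],
                v_gene=row[columns["v_gene"]],
                j_gene=row[columns["j_gene"]],
                cdrh3_aa=cdrh3,
                count=count,
                **kwargs,
            )
        )
    return records, report


def write_airr_table(records: Iterable[SequenceRecord], path) -> None:
    """Write sequence records as an AIRR-style TSV (inverse of read)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "organ": r.organ,
                "mouse_id": r.mouse_id,
                "v_call": r.v_gene,
                "j_call": r.j_gene,
                "junction_aa": r.cdrh3_aa,
                "duplicate_count": r.count,
                "sequence_alignment": r.v_region_nt or "",
                "germline_alignment": r.germline_nt or "",
                "junction_aa_light": r.cdrl3_aa or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees


def _read_label_table(labels_path) -> dict:
    df = pd.read_csv(labels_path, sep="\t", header=None, names=["tip", "organ"], dtype=str)
    if len(df) and df.iloc[0, 0].lower() in ("tip", "sequence_id", "name"):
        df = df.iloc[1:]
    return dict(zip(df["tip"], df["organ"]))


def _from_dendropy(
    tree: dendropy.Tree, organ_map: dict, clonotype_id: str, mouse_id: str
) -> LineageTree:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, length, names, organs = [], [], [], []
    for nd in nodes:
        parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
        length.append(nd.edge.length or 0.0)
        if nd.is_leaf():
            name = nd.taxon.label if nd.taxon else None
            names.append(name)
            organs.append(organ_map.get(name))
        else:
            names.append(None)
            organs.append(None)
    return LineageTree(
        parent, length, names, organs, clonotype_id=clonotype_id, mouse_id=mouse_id
    )


def read_labeled_trees(
    newick_path, labels_path, mouse_id: str = "m1"
) -> list[LineageTree]:
    """Read Newick trees with a tip -> organ label table.

    Every tip must appear in the label table.  A tip labeled with organ
    ``germline`` is treated as the unmutated germline outgroup: the tree is
    rerooted on its branch and the tip removed, so the returned root is the
    ancestral node at the germline attachment point (excluded from
    organ-transition counting).
    """
    organ_map = _read_label_table(labels_path)
    text = Path(newick_path).read_text()
    statements = [s.strip() for s in text.split(";") if s.strip()]

    out: list[LineageTree] = []
    for i, stmt in enumerate(statements):
        try:
            tree = dendropy.Tree.get(
                data=stmt + ";", schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise NewickParseError(f"tree {i} in {newick_path}: {exc}") from exc

        leaves = list(tree.leaf_node_iter())
        tip_names = [lf.taxon.label if lf.taxon else None for lf in leaves]
        unlabeled = [n for n in tip_names if n is None or n not in organ_map]
        if unlabeled:
            raise ValidationError(
                f"tree {i}: tips without organ label: {sorted(str(n) for n in unlabeled)}"
            )

        germ = [
            lf
            for lf in leaves
            if organ_map[lf.taxon.label].lower() == "germline"
        ]
        if len(germ) > 1:
            raise ValidationError(f"tree {i}: more than one germline tip")
        if germ:
            g = germ[0]
            tree.reroot_at_edge(g.edge, update_bipartitions=False)
            tree.prune_taxa([g.taxon], suppress_unifurcations=True)
            # dendropy can leave a unary seed node after pruning the outgroup
            while (
                tree.seed_node.num_child_nodes() == 1
                and not tree.seed_node.child_nodes()[0].is_leaf()
            ):
                child = tree.seed_node.child_nodes()[0]
                tree.seed_node = child
                child.parent_node = None
        out.append(_from_dendropy(tree, organ_map, clonotype_id=f"tree{i}", mouse_id=mouse_id))
    return out


def write_labeled_trees(trees: Iterable[LineageTree], newick_path, labels_path) -> None:
    """Write trees as Newick plus a two-column tip -> organ TSV."""
    trees = list(trees)
    with open(newick_path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
    rows = []
    for t in trees:
        for tip in t.tips:
            rows.append({"tip": t.names[tip], "organ": t.organs[tip]})
    pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False, header=False)


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export of a clone network (stringify tuple node keys)."""
    g = nx.relabel_nodes(graph, {n: "|".join(map(str, n)) for n in graph.nodes})
    nx.write_graphml(g, path)
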