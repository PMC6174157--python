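"""Negative miRNA-mRNA regulatory network assembly and hub statistics.

An interaction edge records a predicted target relationship whose two ends
were called differentially expressed in *opposite* directions within the
same tumor/normal pair; the set of pairs certifying this is kept on the
edge.  The recurrence filter keeps edges supported by at least
``min_pairs`` pairs (default 2).  The two sign patterns
(miRNA up / gene down, and the converse) are kept separate: mixed-direction
evidence never sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .targets import TargetCall

MIR_UP_GENE_DOWN = "miR_up_gene_down"
MIR_DOWN_GENE_UP = "miR_down_gene_up"
PATTERNS = (MIR_UP_GENE_DOWN, MIR_DOWN_GENE_UP)


@dataclass(frozen=True)
class InteractionEdge:
    """A miRNA -> gene negative-regulation edge with its supporting pairs."""

    mirna_id: str
    gene_id: str
    pattern: str
    supporting_pairs: frozenset

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise InputError(f"unknown pattern {self.pattern!r}")
        if not self.supporting_pairs:
            raise InputError("an edge must have at least one supporting pair")


@dataclass
class RegulatoryNetwork:
    """Bipartite miRNA -> gene network; nodes carry role and TF flag."""

    edges: list[InteractionEdge]
    tf_ids: frozenset = frozenset()
    min_pairs: int = 1
    nodes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = {}
        for e in self.edges:
            self.nodes[e.mirna_id] = {"role": "miRNA", "is_tf": False}
        for e in self.edges:
            if e.gene_id in self.nodes and self.nodes[e.gene_id]["role"] == "miRNA":
                raise InputError(f"id {e.gene_id!r} used as both miRNA and gene")
            self.nodes[e.gene_id] = {"role": "gene", "is_tf": e.gene_id in self.tf_ids}

    @property
    def n_mirnas(self) -> int:
        return sum(1 for v in self.nodes.values() if v["role"] == "miRNA")

    @property
    def n_genes(self) -> int:
        return sum(1 for v in self.nodes.values() if v["role"] == "gene")

    def to_networkx(self):
        """Export as a directed networkx graph (miRNA -> gene)."""
        import networkx as nx

        g = nx.DiGraph()
        for node, attrs in self.nodes.items():
            g.add_node(node, **attrs)
        for e in self.edges:
            g.add_edge(
                e.mirna_id,
                e.gene_id,
                pattern=e.pattern,
                n_supporting_pairs=len(e.supporting_pairs),
            )
        return g


def _direction_map(de: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """feature -> {'up': pairs, 'down': pairs} from a concatenated DE table."""
    out: dict[str, dict[str, set[str]]] = {}
    called = de[de["direction"].isin(["up", "down"])]
    for row in called.itertuples(index=False):
        d = out.setdefault(row.feature_id, {"up": set(), "down": set()})
        d[row.direction].add(row.pair_id)
    return out


def match_negative_pairs(
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    target_calls: list[TargetCall],
    strict: bool = True,
) -> list[InteractionEdge]:
    """Sign-opposite DE support for every passing target call.

    For each passing ``(miRNA, gene)`` call and each pair where the miRNA
    is up and the gene is down (or vice versa), that pair supports the
    corresponding pattern's edge.  Calls with no supporting pair yield no
    edge.  With ``strict`` (default), call ids absent from the DE tables
    raise :class:`InputError`.
    """
    mirna_features = set(de_mirna["feature_id"])
    mrna_features = set(de_mrna["feature_id"])
    mir_dir = _direction_map(de_mirna)
    gene_dir = _direction_map(de_mrna)
    edges: list[InteractionEdge] = []
    for call in target_calls:
        if not call.passes:
            continue
        if strict and (
            call.mirna_id not in mirna_features or call.gene_id not in mrna_features
        ):
            raise InputError(
                f"target call ({call.mirna_id}, {call.gene_id}) has ids absent "
                "from the DE tables"
            )
        m = mir_dir.get(call.mirna_id, {"up": set(), "down": set()})
        g = gene_dir.get(call.gene_id, {"up": set(), "down": set()})
        up_down = m["up"] & g["down"]
        down_up = m["down"] & g["up"]
        if up_down:
            edges.append(
                InteractionEdge(call.mirna_id, call.gene_id, MIR_UP_GENE_DOWN, frozenset(up_down))
            )
        if down_up:
            edges.append(
                InteractionEdge(call.mirna_id, call.gene_id, MIR_DOWN_GENE_UP, frozenset(down_up))
            )
    return edges


def apply_recurrence_filter(
    edges: list[InteractionEdge], min_pairs: int = 2
) -> list[InteractionEdge]:
    """Keep edges supported by at least ``min_pairs`` tumor/normal pairs."""
    if min_pairs < 1:
        raise InputError("min_pairs must be >= 1")
    return [e for e in edges if len(e.supporting_pairs) >= min_pairs]


def build_network(
    edges: list[InteractionEdge],
    tf_ids=(),
    min_pairs: int = 2,
) -> RegulatoryNetwork:
    """Recurrence-filter the edges and wrap them in a network."""
    kept = apply_recurrence_filter(edges, min_pairs)
    return RegulatoryNetwork(kept, tf_ids=frozenset(tf_ids), min_pairs=min_pairs)


def build_tf_subnetwork(
    network: RegulatoryNetwork,
    tf_ids=None,
    pattern: str = MIR_UP_GENE_DOWN,
) -> RegulatoryNetwork:
    """Restrict to edges of one pattern whose gene is a transcription factor.

    Isolated nodes are dropped (the node set is exactly the endpoints of
    the retained edges).
    """
    tfs = frozenset(tf_ids) if tf_ids is not None else network.tf_ids
    kept = [e for e in network.edges if e.pattern == pattern and e.gene_id in tfs]
    return RegulatoryNetwork(kept, tf_ids=tfs, min_pairs=network.min_pairs)


def hub_statistics(network: RegulatoryNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene targeting-miRNA counts and per-miRNA out-degrees.

    Both tables are sorted by count descending then id ascending, a
    deterministic total order.  Returns ``(gene_table, mirna_table)``.
    """
    gene_counts: dict[str, set[str]] = {}
    mirna_counts: dict[str, set[str]] = {}
    for e in network.edges:
        gene_counts.setdefault(e.gene_id, set()).add(e.mirna_id)
        mirna_counts.setdefault(e.mirna_id, set()).add(e.gene_id)
    gene_table = pd.DataFrame(
        sorted(
            ((g, len(ms)) for g, ms in gene_counts.items()),
            key=lambda t: (-t[1], t[0]),
        ),
        columns=["gene_id", "n_targeting_mirnas"],
    )
    if not gene_table.empty:
        gene_table["is_tf"] = [network.nodes[g]["is_tf"] for g in gene_table["gene_id"]]
    else:
        gene_table["is_tf"] = pd.Series(dtype=bool)
    mirna_table = pd.DataFrame(
        sorted(
            ((m, len(gs)) for m, gs in mirna_counts.items()),
            key=lambda t: (-t[1], t[0]),
        ),
        columns=["mirna_id", "out_degree"],
    )
    return gene_table, mirna_table


def edges_to_frame(edges: list[InteractionEdge]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": e.mirna_id,
            "gene_id": e.gene_id,
            "pattern": e.pattern,
            "n_supporting_pairs": len(e.supporting_pairs),
            "supporting_pairs": ",".join(sorted(e.supporting_pairs)),
        }
        for e in sorted(edges, key=lambda e: (e.mirna_id, e.gene_id, e.pattern))
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "pattern", "n_supporting_pairs", "supporting_pairs"],
    )


def export_edge_list(network: RegulatoryNetwork, path, format: str = "tsv") -> None:
    """Write the edges as TSV (full attributes) or Cytoscape SIF."""
    if format == "tsv":
        edges_to_frame(network.edges).to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for e in sorted(
                network.edges, key=lambda e: (e.mirna_id, e.gene_id, e.pattern)
            ):
                fh.write(f"{e.mirna_id}\trepresses\t{e.gene_id}\n")
    else:
        raise InputError(f"unknown edge-list format {format!r}")


def read_edge_list(path) -> list[InteractionEdge]:
    """Re-import a TSV written by :func:`export_edge_list`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        InteractionEdge(
            row.mirna_id,
            row.gene_id,
            row.pattern,
            frozenset(row.supporting_pairs.split(",")),
        )
        for row in df.itertuples(index=False)
    ]


def export_node_attributes(network: RegulatoryNetwork, path) -> None:
    """Node attribute TSV: id, role, is_TF."""
    rows = [
        {"id": n, "role": a["role"], "is_tf": a["is_tf"]}
        for n, a in sorted(network.nodes.items())
    ]
    pd.DataFrame(rows, columns=["id", "role", "is_tf"]).to_csv(path, sep="\t", index=False)
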