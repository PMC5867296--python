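"""Cross-species comparative candidate networks.

Per-species record tables (top candidates per functional term) are joined
through orthogroup (gene-family) membership: a candidate enters the network
only if its family contains, in a different species, another candidate for
the same term (or a bait gene, when bait partners are allowed). Candidates
connect to a per-species bait-set hub node; cross-species same-family
candidate pairs are joined by orthology edges. Bait genes themselves are
not emitted as nodes.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core import BaitSet
from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)

REGULATORY_CLASSES = ("TF", "kinase/receptor", "transporter", "other", "unknown")

#: default keyword rules, first match wins; user-editable via classify_regulatory(rules=...)
DEFAULT_REGULATORY_RULES: list[tuple[str, str]] = [
    ("TF", r"transcription factor|\bwrky\b|\bmyb\b|\bbhlh\b|\bbzip\b|ap2/erf|nac domain"),
    ("kinase/receptor", r"kinase|receptor"),
    ("transporter", r"transporter|atpase.*transport|transport.*atpase"),
]


@dataclass
class OrthogroupTable:
    """family_id -> set of (species_id, gene_id) members."""

    families: dict[str, set[tuple[str, str]]]
    _member_index: dict[tuple[str, str], str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[tuple[str, str], str] = {}
        for fam, members in self.families.items():
            for member in members:
                if member in index:
                    raise ValidationError(
                        f"gene {member[1]!r} ({member[0]}) in families "
                        f"{index[member]!r} and {fam!r}"
                    )
                index[member] = fam
        self._member_index = index

    def family_of(self, species: str, gene: str) -> str | None:
        return self._member_index.get((species, gene))

    def members(self, family_id: str) -> set[tuple[str, str]]:
        return self.families.get(family_id, set())

    def __len__(self) -> int:
        return len(self.families)


def read_orthogroups(path) -> OrthogroupTable:
    """Read ``family_id<TAB>species_id<TAB>gene_id`` rows (PLAZA-style)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["family_id", "species_id", "gene_id"],
        dtype=str, skip_blank_lines=True,
    )
    if len(df) and df["family_id"].iloc[0] == "family_id":
        df = df.iloc[1:]
    families: dict[str, set[tuple[str, str]]] = {}
    for fam, sp, gene in df.itertuples(index=False):
        families.setdefault(str(fam), set()).add((str(sp), str(gene)))
    if not families:
        logger.warning("%s: empty orthogroup table", path)
    return OrthogroupTable(families=families)


def classify_regulatory(
    descriptions: dict[str, str] | pd.DataFrame | None,
    genes=None,
    rules: list[tuple[str, str]] = None,
) -> dict[str, str]:
    """Map genes to coarse regulatory classes by description keywords.

    ``descriptions`` is a gene_id -> description mapping (or a two-column
    DataFrame). Matching is case-insensitive; the first matching rule wins;
    a described gene matching nothing is ``other``; a gene absent from the
    table is ``unknown``. Pass ``genes`` to force entries for undescribed
    genes.
    """
    if rules is None:
        rules = DEFAULT_REGULATORY_RULES
    compiled = [(cls, re.compile(pat, re.IGNORECASE)) for cls, pat in rules]
    if descriptions is None:
        table: dict[str, str] = {}
    elif isinstance(descriptions, pd.DataFrame):
        gcol, dcol = descriptions.columns[:2]
        table = dict(zip(descriptions[gcol].astype(str), descriptions[dcol].astype(str)))
    else:
        table = {str(g): str(d) for g, d in descriptions.items()}
    out: dict[str, str] = {}
    for gene, desc in table.items():
        cls = next((c for c, pat in compiled if pat.search(desc)), "other")
        out[gene] = cls
    for gene in genes or ():
        out.setdefault(str(gene), "unknown")
    return out


def load_regulatory_rules(path) -> list[tuple[str, str]]:
    """Load keyword rules from YAML: a list of {class, pattern} entries."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [(entry["class"], entry["pattern"]) for entry in raw]


def build_network(
    term_id: str,
    records: dict[str, pd.DataFrame],
    baits: dict[str, BaitSet] | None = None,
    orthogroups: OrthogroupTable | None = None,
    include_baits_as_partners: bool = True,
    regulatory_class: dict[str, str] | None = None,
) -> nx.Graph:
    """Comparative candidate network for one functional term.

    ``records`` maps species -> record table (columns term_id, gene_id, z,
    rank). A candidate is included iff another candidate for the same term
    — or, with ``include_baits_as_partners``, a bait gene — from a
    *different* species shares its gene family. Included candidates link to
    a per-(species, term) hub node; cross-species same-family candidate
    pairs get orthology edges.
    """
    if len(records) < 2:
        raise ParameterError("comparative networks need records from >= 2 species")
    if orthogroups is None:
        orthogroups = OrthogroupTable(families={})
    baits = baits or {}
    regulatory_class = regulatory_class or {}

    species_list = sorted(records)
    cand: dict[str, pd.DataFrame] = {}
    for sp in species_list:
        df = records[sp]
        cand[sp] = df[df["term_id"] == term_id].copy() if len(df) else df
    if all(len(df) == 0 for df in cand.values()):
        logger.warning("term %s absent from every record table", term_id)
        return nx.Graph(term_id=term_id)

    # family -> candidate members / bait members per species
    fam_candidates: dict[str, set[tuple[str, str]]] = {}
    for sp, df in cand.items():
        for gene in df["gene_id"].astype(str):
            fam = orthogroups.family_of(sp, gene)
            if fam is not None:
                fam_candidates.setdefault(fam, set()).add((sp, gene))
    fam_baits: dict[str, set[tuple[str, str]]] = {}
    for sp, bs in baits.items():
        for gene in bs.genes:
            fam = orthogroups.family_of(sp, gene)
            if fam is not None:
                fam_baits.setdefault(fam, set()).add((sp, gene))

    def included(sp: str, gene: str) -> bool:
        fam = orthogroups.family_of(sp, gene)
        if fam is None:
            return False
        partners = {m for m in fam_candidates.get(fam, ()) if m[0] != sp}
        if include_baits_as_partners:
            partners |= {m for m in fam_baits.get(fam, ()) if m[0] != sp}
        return bool(partners)

    g = nx.Graph(term_id=term_id)
    node_members: dict[str, list[tuple[str, str]]] = {}
    for sp in species_list:
        df = cand[sp]
        kept = [
            row for row in df.itertuples(index=False)
            if included(sp, str(row.gene_id))
        ]
        if not kept:
            continue
        hub = f"{sp}::{term_id}"
        g.add_node(hub, node_type="bait_hub", species=sp, term_id=term_id)
        for row in sorted(kept, key=lambda r: str(r.gene_id)):
            gene = str(row.gene_id)
            node = f"{sp}:{gene}"
            fam = orthogroups.family_of(sp, gene)
            g.add_node(
                node,
                node_type="candidate",
                species=sp,
                gene_id=gene,
                z=float(row.z),
                rank=int(row.rank),
                family_id=fam or "",
                regulatory_class=regulatory_class.get(gene, "unknown"),
                is_bait=False,
            )
            g.add_edge(node, hub, edge_type="member")
            node_members.setdefault(fam, []).append((sp, gene))
    for fam, members in node_members.items():
        for i, (sp_a, ga) in enumerate(members):
            for sp_b, gb in members[i + 1:]:
                if sp_a != sp_b:
                    g.add_edge(f"{sp_a}:{ga}", f"{sp_b}:{gb}", edge_type="orthology")
    return g


def _node_sort_key(graph: nx.Graph, node: str):
    data = graph.nodes[node]
    # hubs first within a species, then genes alphabetically
    return (data.get("species", ""), data.get("node_type") != "bait_hub",
            data.get("gene_id", ""))


def export_network(net: nx.Graph, path, fmt: str = "json") -> None:
    """Write the network losslessly as node-link JSON or GraphML.

    Node order is stable (species, hubs first, then gene_id) so repeated
    exports of the same network are byte-identical.
    """
    ordered = nx.Graph(**net.graph)
    for node in sorted(net.nodes, key=lambda n: _node_sort_key(net, n)):
        ordered.add_node(node, **net.nodes[node])
    for a, b in sorted(net.edges, key=lambda e: tuple(sorted(e))):
        ordered.add_edge(a, b, **net.edges[a, b])
    if fmt == "json":
        data = nx.node_link_data(ordered, edges="links")
        data["links"] = sorted(
            data["links"], key=lambda e: (str(e["source"]), str(e["target"]))
        )
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    elif fmt == "graphml":
        nx.write_graphml(ordered, path)
    else:
        raise ParameterError(f"unknown format {fmt!r}; use 'json' or 'graphml'")


def import_network(path, fmt: str = "json") -> nx.Graph:
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        return nx.node_link_graph(data, edges="links")
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ParameterError(f"unknown format {fmt!r}; use 'json' or 'graphml'")
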