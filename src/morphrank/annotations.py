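"""Functional annotation gene sets (GO, MapMan, or custom terms).

Terms are read either from GMT files (``term<TAB>description<TAB>gene1...``)
or from long-format two-column TSVs (``gene_id<TAB>term_id``). Each term's
gene set becomes a candidate bait set for the bulk pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import BaitSet
from .exceptions import ParameterError, ParseError

SOURCES = ("GO", "MapMan", "custom")


@dataclass
class AnnotationSet:
    """term_id -> (description, gene set) for one annotation source."""

    source: str
    terms: dict[str, tuple[str, frozenset[str]]]
    sub_ontology: dict[str, str] = field(default_factory=dict)  # GO term -> BP/CC/MF

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ParameterError(f"source must be one of {SOURCES}, got {self.source!r}")
        empty = [t for t, (_, genes) in self.terms.items() if not genes]
        if empty:
            raise ParameterError(f"terms with empty gene sets: {sorted(empty)[:5]}")

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for _, gene_set in self.terms.values():
            out |= gene_set
        return frozenset(out)

    def bait_sets(self) -> list[BaitSet]:
        return [
            BaitSet(term_id=t, genes=g, description=d)
            for t, (d, g) in sorted(self.terms.items())
        ]


def read_gmt(path, source: str = "custom") -> AnnotationSet:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (desc, frozenset(genes))
    return AnnotationSet(source=source, terms=terms)


def read_annotation_tsv(path, source: str = "custom") -> AnnotationSet:
    """Read long-format annotation: ``gene_id<TAB>term_id`` per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    if df["gene_id"].iloc[0] == "gene_id":
        df = df.iloc[1:]
    terms = {
        str(term): ("", frozenset(group["gene_id"].astype(str)))
        for term, group in df.groupby("term_id")
    }
    return AnnotationSet(source=source, terms=terms)


def write_gmt(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in sorted(ann.terms.items()):
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")
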