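"""Gene-set catalogs (GO namespaces + pathways) and GMT IO.

Terms live in one of four namespaces: the three Gene Ontology branches
(BP = biological process, CC = cellular component, MF = molecular
function) and a pathway namespace standing in for KEGG-style maps. The
GMT format is the usual tab-separated ``term <TAB> description <TAB>
gene...`` layout; the namespace is carried in the description field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

GO_NAMESPACES = ("BP", "CC", "MF")
PATHWAY = "pathway"
NAMESPACES = GO_NAMESPACES + (PATHWAY,)


@dataclass
class GeneSetCatalog:
    """Mapping of term id -> member genes, each term in one namespace."""

    sets: dict[str, frozenset[str]]
    namespaces: dict[str, str]
    planted_terms: dict[str, list[str]] = field(default_factory=dict)
    # planted_terms: hub id -> term ids engineered to overlap its mRNA block
    # (synthetic catalogs only; empty for real GMT input).

    def __post_init__(self) -> None:
        missing = set(self.sets) - set(self.namespaces)
        if missing:
            raise ValueError(f"terms without namespace: {sorted(missing)[:5]}")
        bad = {t: ns for t, ns in self.namespaces.items() if ns not in NAMESPACES}
        if bad:
            raise ValueError(f"unknown namespaces: {bad}")

    @property
    def terms(self) -> list[str]:
        return list(self.sets)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def in_namespace(self, namespace: str) -> list[str]:
        return [t for t, ns in self.namespaces.items() if ns == namespace]

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term, members in self.sets.items():
                genes = "\t".join(sorted(members))
                fh.write(f"{term}\t{self.namespaces[term]}\t{genes}\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCatalog":
        sets: dict[str, frozenset[str]] = {}
        namespaces: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                term, desc, genes = fields[0], fields[1], fields[2:]
                sets[term] = frozenset(g for g in genes if g)
                namespaces[term] = desc if desc in NAMESPACES else PATHWAY
        return cls(sets, namespaces)
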