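"""Metabolic reaction network: metabolite nodes, enzyme-bearing edges,
transporters, and regulators.

The network is an undirected reaction graph.  Every reaction edge carries
one or more enzyme gene ids; transporters attach to the metabolites they
carry (their cargo); regulators attach to a single entry node with a sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

GROUPS = ("glycolysis", "bcaa", "other_aa", "ketone")


@dataclass(frozen=True)
class Reaction:
    """One reaction edge between two metabolites."""

    u: str
    v: str
    enzymes: tuple[str, ...]
    reversible: bool = True

    def __post_init__(self):
        if self.u == self.v:
            raise ValueError(f"self-loop reaction on {self.u!r}")


@dataclass
class MetaboliteNetwork:
    """Reaction graph with gene attachments.

    Attributes
    ----------
    groups : mapping metabolite id -> biochemical group name
    reactions : list of :class:`Reaction`
    transporters : mapping transporter gene id -> tuple of cargo metabolites
    regulators : mapping regulator gene id -> (entry node, sign in {+1,-1})
    """

    groups: dict[str, str]
    reactions: list[Reaction]
    transporters: dict[str, tuple[str, ...]] = field(default_factory=dict)
    regulators: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, grp in self.groups.items():
            if grp not in GROUPS:
                raise ValueError(f"unknown group {grp!r} for metabolite {met!r}")
        nodes = set(self.groups)
        for r in self.reactions:
            if r.u not in nodes or r.v not in nodes:
                raise ValueError(f"reaction {r.u}-{r.v} references unknown metabolite")
        for gene, cargo in self.transporters.items():
            for m in cargo:
                if m not in nodes:
                    raise ValueError(f"transporter {gene!r} cargo {m!r} not in network")
        for gene, (entry, sign) in self.regulators.items():
            if entry not in nodes:
                raise ValueError(f"regulator {gene!r} entry {entry!r} not in network")
            if sign not in (-1, 1):
                raise ValueError(f"regulator {gene!r} sign must be +/-1")
        if self.metabolites and not nx.is_connected(self.graph()):
            raise ValueError("reaction graph must be connected")

    # -- views ---------------------------------------------------------------

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.groups)

    def graph(self) -> nx.Graph:
        """Undirected networkx view; edge attribute ``enzymes``."""
        g = nx.Graph()
        g.add_nodes_from(self.groups)
        for r in self.reactions:
            g.add_edge(r.u, r.v, enzymes=r.enzymes, reversible=r.reversible)
        return g

    def enzyme_edges(self) -> dict[str, tuple[str, str]]:
        """Map each enzyme gene id to the (u, v) reaction it catalyzes."""
        out: dict[str, tuple[str, str]] = {}
        for r in self.reactions:
            for e in r.enzymes:
                out[e] = (r.u, r.v)
        return out

    def attached_genes(self) -> dict[str, str]:
        """Map every attached gene id to its mechanism class."""
        genes = {e: "enzyme" for e in self.enzyme_edges()}
        genes.update({t: "transporter" for t in self.transporters})
        genes.update({r: "tf" for r in self.regulators})
        return genes

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "nodes": [{"id": m, "group": g} for m, g in sorted(self.groups.items())],
            "edges": [
                {"u": r.u, "v": r.v, "enzymes": list(r.enzymes), "reversible": r.reversible}
                for r in self.reactions
            ],
            "transporters": {g: list(c) for g, c in sorted(self.transporters.items())},
            "regulators": {g: [n, s] for g, (n, s) in sorted(self.regulators.items())},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "MetaboliteNetwork":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            groups={n["id"]: n["group"] for n in doc["nodes"]},
            reactions=[
                Reaction(e["u"], e["v"], tuple(e["enzymes"]), e.get("reversible", True))
                for e in doc["edges"]
            ],
            transporters={g: tuple(c) for g, c in doc.get("transporters", {}).items()},
            regulators={g: (n, int(s)) for g, (n, s) in doc.get("regulators", {}).items()},
        )
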