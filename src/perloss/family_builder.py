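"""Gene-family construction from the similarity graph.

Families are the connected components of an undirected graph over genes,
with an edge wherever either direction of a cross-species hit reaches the
E-value cutoff (the better direction of an asymmetric pair decides, which
mirrors a symmetrised ortholog graph).  Component clustering is a
desk-scale stand-in for Markov clustering: the downstream screen consumes
only per-species presence/absence, which components preserve; precomputed
OrthoMCL groups can be ingested instead and flow through identical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import SimilarityHit, qualified_id, split_qualified


@dataclass
class GeneFamily:
    """A cluster of genes across species; membership keyed by species."""

    family_id: str
    members: dict[str, set[str]] = field(default_factory=dict)

    @property
    def presence(self) -> dict[str, bool]:
        return {sp: bool(genes) for sp, genes in self.members.items()}

    def present_in(self, species: str) -> bool:
        return bool(self.members.get(species))

    def qualified_members(self) -> list[str]:
        return sorted(
            qualified_id(sp, g) for sp, genes in self.members.items() for g in genes
        )

    def genes_of(self, species: str) -> list[str]:
        return sorted(self.members.get(species, ()))


def select_primary_transcript(transcripts: Mapping[str, str]) -> str:
    """Pick the primary transcript of one gene: the longest sequence.

    Ties break to the lexicographically smallest transcript id.
    """
    if not transcripts:
        raise ValueError("gene has no transcripts")
    return min(transcripts, key=lambda tid: (-len(transcripts[tid]), tid))


def cluster_families(
    hits: Iterable[SimilarityHit],
    universe: Mapping[str, Iterable[str]],
    evalue_cutoff: float = 1e-5,
    identity_cutoff: float | None = None,
) -> list[GeneFamily]:
    """Cluster the gene universe into families by similarity-graph components.

    ``universe`` maps species -> gene ids and defines the node set; genes
    with no qualifying edge become singleton families.  An edge requires the
    better direction of a hit pair to satisfy ``E <= evalue_cutoff`` (and
    the identity cutoff, when given).  Family ids are deterministic:
    components are ordered by their sorted member lists.
    """
    graph = nx.Graph()
    for species in sorted(universe):
        for gene in sorted(universe[species]):
            graph.add_node(qualified_id(species, gene))
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        if identity_cutoff is not None and hit.identity_pct < identity_cutoff:
            continue
        if hit.query in graph and hit.subject in graph and hit.query != hit.subject:
            graph.add_edge(hit.query, hit.subject)
    components = sorted(
        (sorted(component) for component in nx.connected_components(graph)),
        key=lambda members: members[0],
    )
    families = []
    for i, members in enumerate(components):
        by_species: dict[str, set[str]] = {}
        for qid in members:
            species, gene = split_qualified(qid)
            by_species.setdefault(species, set()).add(gene)
        families.append(GeneFamily(family_id=f"FAM{i:05d}", members=by_species))
    return families


def family_of_gene(families: Sequence[GeneFamily]) -> dict[str, GeneFamily]:
    """Index families by qualified member id."""
    index: dict[str, GeneFamily] = {}
    for fam in families:
        for qid in fam.qualified_members():
            index[qid] = fam
    return index
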