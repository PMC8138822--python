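"""Mechanism inference: propagate targets and diseases from similar
knowledge-base compounds into a compound–target–disease network.

A query compound is linked to every KB compound whose structural Tanimoto
similarity (or expression-profile Spearman correlation) clears a
threshold; those compounds' KB-backed target and disease annotations, plus
any explicit target–disease links among them, form a typed evidence graph
that suggests how the query might act.  No annotation is invented: every
non-similarity edge traces back to a KB evidence link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from .errors import FibroscreenError, LookupError_
from .featurize import smiles_to_maccs, spearman, tanimoto
from .kb import KnowledgeBase, LinkType

__all__ = [
    "SimilarityConfig",
    "find_similar",
    "build_network",
    "export_network",
    "import_network",
    "match_substructure",
]

_DEFAULT_MIN_SIM = {"structural": 0.5, "biological": 0.6}


@dataclass(frozen=True)
class SimilarityConfig:
    modality: str = "structural"
    min_similarity: Optional[float] = None
    top_k: int = 10

    def __post_init__(self):
        if self.modality not in _DEFAULT_MIN_SIM:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.min_similarity is None:
            object.__setattr__(
                self, "min_similarity", _DEFAULT_MIN_SIM[self.modality]
            )
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @property
    def metric(self) -> str:
        return "tanimoto" if self.modality == "structural" else "spearman"


def find_similar(
    query_features,
    kb: KnowledgeBase,
    config: SimilarityConfig = SimilarityConfig(),
    profiles: Optional[dict] = None,
) -> list[tuple[str, float]]:
    """Rank KB compounds by similarity to the query.

    Structural: ``query_features`` is a fingerprint (or SMILES string);
    KB fingerprints are computed on demand from stored SMILES.  Biological:
    ``query_features`` is a rank profile and ``profiles`` maps KB compound
    IDs to their registered profiles.

    Returns ``(compound_id, similarity)`` pairs with similarity at or above
    the configured minimum, sorted by descending similarity with ties
    broken by compound ID, truncated to ``top_k``.
    """
    sims: list[tuple[str, float]] = []
    if config.modality == "structural":
        qfp = (
            smiles_to_maccs(query_features)
            if isinstance(query_features, str)
            else query_features
        )
        any_features = False
        for c in kb.compounds.values():
            if not c.smiles:
                continue
            any_features = True
            sims.append((c.compound_id, tanimoto(qfp, smiles_to_maccs(c.smiles))))
        if not any_features:
            raise FibroscreenError("no KB compound has a SMILES structure")
    else:
        if not profiles:
            raise FibroscreenError("no KB compound has a registered profile")
        for cid, prof in profiles.items():
            if cid not in kb.compounds:
                raise LookupError_(f"profile for unknown KB compound {cid!r}")
            sims.append((cid, spearman(query_features, prof)))
    kept = [(c, s) for c, s in sims if s >= config.min_similarity]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return kept[: config.top_k]


def build_network(
    query_id: str,
    similar_list: list[tuple[str, float]],
    kb: KnowledgeBase,
) -> nx.MultiDiGraph:
    """Assemble the typed compound–target–disease network for a query.

    Nodes carry a ``kind`` attribute (query_compound | kb_compound |
    target | disease); edges carry ``edge_type`` plus either the similarity
    weight or the backing evidence link's source and reference.  A query
    that is itself a KB compound has its own annotations included with the
    similarity edge flagged ``direct_evidence``.
    """
    g = nx.MultiDiGraph()
    g.add_node(query_id, kind="query_compound")
    compound_ids = []
    for cid, sim in similar_list:
        if cid not in kb.compounds:
            raise LookupError_(f"similar compound {cid!r} not in KB")
        if cid == query_id:
            g.nodes[query_id]["direct_evidence"] = True
            g.add_edge(
                query_id, cid, edge_type="similarity", weight=float(sim),
                direct_evidence=True,
            )
        else:
            g.add_node(cid, kind="kb_compound")
            g.add_edge(query_id, cid, edge_type="similarity", weight=float(sim))
        compound_ids.append(cid)

    for cid in compound_ids:
        for ln in kb.links_of(cid, LinkType.COMPOUND_TARGET):
            g.add_node(ln.object_id, kind="target")
            g.add_edge(
                cid, ln.object_id, edge_type="compound-target",
                source=ln.source, reference=ln.reference,
            )
        for ln in kb.links_of(cid, LinkType.COMPOUND_DISEASE):
            g.add_node(ln.object_id, kind="disease")
            g.add_edge(
                cid, ln.object_id, edge_type="compound-disease",
                source=ln.source, reference=ln.reference,
            )
    # explicit target-disease links among nodes already in the network
    targets = {n for n, d in g.nodes(data=True) if d.get("kind") == "target"}
    diseases = {n for n, d in g.nodes(data=True) if d.get("kind") == "disease"}
    for ln in kb.links:
        if (
            ln.link_type is LinkType.TARGET_DISEASE
            and ln.subject_id in targets
            and ln.object_id in diseases
        ):
            g.add_edge(
                ln.subject_id, ln.object_id, edge_type="target-disease",
                source=ln.source, reference=ln.reference,
            )
    return g


_FORMATS = ("json", "graphml", "tsv")


def export_network(network: nx.MultiDiGraph, path, fmt: str = "json") -> Path:
    """Write the network to node-link JSON, GraphML or a TSV edge list.

    JSON and GraphML are lossless (re-import reproduces the graph); the
    edge list is a flat view for spreadsheets.
    """
    path = Path(path)
    if fmt not in _FORMATS:
        raise FibroscreenError(f"unsupported format {fmt!r}; choose from {_FORMATS}")
    if fmt == "json":
        data = nx.node_link_data(network, edges="edges")
        # deterministic ordering for reproducible artifacts
        data["nodes"] = sorted(data["nodes"], key=lambda n: str(n["id"]))
        data["edges"] = sorted(
            data["edges"],
            key=lambda e: (str(e["source"]), str(e["target"]), str(e.get("key"))),
        )
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        rows = [
            {
                "source": u,
                "target": v,
                "edge_type": d.get("edge_type", ""),
                "weight": d.get("weight", ""),
                "evidence_source": d.get("source", ""),
                "reference": d.get("reference", ""),
            }
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(
            rows,
            columns=[
                "source", "target", "edge_type", "weight",
                "evidence_source", "reference",
            ],
        ).to_csv(path, sep="\t", index=False)
    return path


def import_network(path, fmt: str = "json") -> nx.MultiDiGraph:
    path = Path(path)
    if fmt == "json":
        return nx.node_link_graph(
            json.loads(path.read_text()), directed=True, multigraph=True, edges="edges"
        )
    if fmt == "graphml":
        return nx.read_graphml(path, force_multigraph=True)
    raise FibroscreenError(f"cannot re-import format {fmt!r}")


def match_substructure(smarts: str, library: dict[str, str]) -> list[str]:
    """Return IDs of library compounds containing the SMARTS substructure.

    ``library`` maps compound IDs to SMILES; unparseable entries are
    skipped.
    """
    from rdkit import Chem

    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise FibroscreenError(f"invalid SMARTS {smarts!r}")
    hits = []
    for cid, smi in library.items():
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is not None and mol.HasSubstructMatch(patt):
            hits.append(cid)
    return sorted(hits)
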