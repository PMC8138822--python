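"""Anti-fibrosis knowledge base: compounds, targets, diseases and evidence links.

The knowledge base (KB) is the curated ground truth of the screening
pipeline.  It defines which compounds count as *positive* (known
anti-fibrosis agents) when labeling a training corpus, and it supplies the
compound–target–disease annotations that mechanism inference propagates to
query compounds.

Storage is four tab-separated tables with fixed headers::

    compounds.tsv   compound_id  name  smiles  is_approved  sources
    targets.tsv     target_id    symbol  entrez
    diseases.tsv    disease_id   name
    links.tsv       subject_id   object_id  link_type  source  reference

``sources`` is a ``|``-separated set of provenance tags; ``link_type`` is
one of ``compound-target``, ``compound-disease``, ``target-disease``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import IntegrityError, LookupError_, SchemaError, SmilesParseError

__all__ = [
    "CompoundRecord",
    "TargetRecord",
    "DiseaseRecord",
    "EvidenceLink",
    "LinkType",
    "KnowledgeBase",
    "Candidate",
    "LabeledCandidate",
    "load_kb",
    "write_kb",
    "label_candidates",
    "query_annotations",
]


class LinkType(str, Enum):
    COMPOUND_TARGET = "compound-target"
    COMPOUND_DISEASE = "compound-disease"
    TARGET_DISEASE = "target-disease"


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str = ""
    smiles: Optional[str] = None
    is_approved: bool = False
    sources: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    symbol: Optional[str] = None
    entrez: Optional[str] = None

    def __post_init__(self):
        if not self.symbol and not self.entrez:
            raise SchemaError(
                f"target {self.target_id!r} needs at least one of symbol/entrez"
            )
        if self.symbol:
            # gene symbols are stored uppercased for case-insensitive matching
            object.__setattr__(self, "symbol", self.symbol.upper())


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    name: str = ""


@dataclass(frozen=True)
class EvidenceLink:
    subject_id: str
    object_id: str
    link_type: LinkType
    source: str = ""
    reference: str = ""


@dataclass(frozen=True)
class Candidate:
    """A compound to be labeled and scored: an ID plus an optional SMILES."""

    candidate_id: str
    smiles: Optional[str] = None


@dataclass(frozen=True)
class LabeledCandidate:
    candidate_id: str
    label: str  # "positive" | "negative"
    modality: str  # "structural" | "biological"


@dataclass
class KnowledgeBase:
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    targets: dict[str, TargetRecord] = field(default_factory=dict)
    diseases: dict[str, DiseaseRecord] = field(default_factory=dict)
    links: list[EvidenceLink] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- integrity ---------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity of every link and reject duplicates."""
        seen = set()
        for ln in self.links:
            if ln.link_type is LinkType.COMPOUND_TARGET:
                ok = ln.subject_id in self.compounds and ln.object_id in self.targets
            elif ln.link_type is LinkType.COMPOUND_DISEASE:
                ok = ln.subject_id in self.compounds and ln.object_id in self.diseases
            elif ln.link_type is LinkType.TARGET_DISEASE:
                ok = ln.subject_id in self.targets and ln.object_id in self.diseases
            else:  # pragma: no cover - enum exhausts this
                ok = False
            if not ok:
                raise IntegrityError(
                    f"dangling link {ln.link_type.value}: "
                    f"{ln.subject_id!r} -> {ln.object_id!r}"
                )
            key = (ln.subject_id, ln.object_id, ln.link_type, ln.source)
            if key in seen:
                raise IntegrityError(f"duplicate link tuple {key}")
            seen.add(key)

    # -- indexes -----------------------------------------------------------
    def links_of(self, subject_id: str, link_type: LinkType) -> list[EvidenceLink]:
        return [
            ln
            for ln in self.links
            if ln.subject_id == subject_id and ln.link_type is link_type
        ]

    def summary(self) -> dict:
        by_source: dict[str, int] = {}
        for ln in self.links:
            by_source[ln.source] = by_source.get(ln.source, 0) + 1
        return {
            "n_compounds": len(self.compounds),
            "n_targets": len(self.targets),
            "n_diseases": len(self.diseases),
            "n_links": len(self.links),
            "links_by_source": dict(sorted(by_source.items())),
        }

    def __eq__(self, other):
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.targets == other.targets
            and self.diseases == other.diseases
            and sorted(self.links, key=_link_key) == sorted(other.links, key=_link_key)
        )


def _link_key(ln: EvidenceLink):
    return (ln.subject_id, ln.object_id, ln.link_type.value, ln.source, ln.reference)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED = {
    "compounds": ["compound_id", "name", "smiles", "is_approved", "sources"],
    "targets": ["target_id", "symbol", "entrez"],
    "diseases": ["disease_id", "name"],
    "links": ["subject_id", "object_id", "link_type", "source", "reference"],
}


def _read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table {path}: missing column(s) {missing}")
    return df


def load_kb(compound_table, target_table, disease_table, link_table) -> KnowledgeBase:
    """Load a knowledge base from its four TSV tables.

    Raises :class:`SchemaError` on a missing column and
    :class:`IntegrityError` on dangling or duplicate links.
    """
    cdf = _read_table(compound_table, "compounds")
    tdf = _read_table(target_table, "targets")
    ddf = _read_table(disease_table, "diseases")
    ldf = _read_table(link_table, "links")

    compounds = {}
    for row in cdf.itertuples(index=False):
        cid = row.compound_id
        if cid in compounds:
            raise IntegrityError(f"duplicate compound_id {cid!r}")
        compounds[cid] = CompoundRecord(
            compound_id=cid,
            name=row.name,
            smiles=row.smiles or None,
            is_approved=str(row.is_approved).strip().lower() in {"1", "true", "yes"},
            sources=frozenset(s for s in str(row.sources).split("|") if s),
        )
    targets = {}
    for row in tdf.itertuples(index=False):
        if row.target_id in targets:
            raise IntegrityError(f"duplicate target_id {row.target_id!r}")
        targets[row.target_id] = TargetRecord(
            target_id=row.target_id,
            symbol=row.symbol or None,
            entrez=row.entrez or None,
        )
    diseases = {}
    for row in ddf.itertuples(index=False):
        if row.disease_id in diseases:
            raise IntegrityError(f"duplicate disease_id {row.disease_id!r}")
        diseases[row.disease_id] = DiseaseRecord(
            disease_id=row.disease_id, name=row.name
        )
    links = [
        EvidenceLink(
            subject_id=row.subject_id,
            object_id=row.object_id,
            link_type=LinkType(row.link_type),
            source=row.source,
            reference=row.reference,
        )
        for row in ldf.itertuples(index=False)
    ]
    return KnowledgeBase(compounds, targets, diseases, links)


def write_kb(kb: KnowledgeBase, out_dir) -> dict[str, Path]:
    """Write the four KB tables to ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    cdf = pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "name": c.name,
                "smiles": c.smiles or "",
                "is_approved": str(c.is_approved).lower(),
                "sources": "|".join(sorted(c.sources)),
            }
            for c in kb.compounds.values()
        ],
        columns=_REQUIRED["compounds"],
    )
    tdf = pd.DataFrame(
        [
            {"target_id": t.target_id, "symbol": t.symbol or "", "entrez": t.entrez or ""}
            for t in kb.targets.values()
        ],
        columns=_REQUIRED["targets"],
    )
    ddf = pd.DataFrame(
        [{"disease_id": d.disease_id, "name": d.name} for d in kb.diseases.values()],
        columns=_REQUIRED["diseases"],
    )
    ldf = pd.DataFrame(
        [
            {
                "subject_id": ln.subject_id,
                "object_id": ln.object_id,
                "link_type": ln.link_type.value,
                "source": ln.source,
                "reference": ln.reference,
            }
            for ln in kb.links
        ],
        columns=_REQUIRED["links"],
    )
    for name, df in [
        ("compounds", cdf),
        ("targets", tdf),
        ("diseases", ddf),
        ("links", ldf),
    ]:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


def load_kb_dir(kb_dir) -> KnowledgeBase:
    """Convenience: load a KB from a directory written by :func:`write_kb`."""
    d = Path(kb_dir)
    return load_kb(
        d / "compounds.tsv", d / "targets.tsv", d / "diseases.tsv", d / "links.tsv"
    )


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------


def _canonical_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


def label_candidates(
    candidates: Iterable[Candidate],
    kb: KnowledgeBase,
    matching: str = "id",
    modality: str = "structural",
) -> list[LabeledCandidate]:
    """Label each candidate positive iff it matches a KB compound.

    ``matching='id'`` matches on compound ID only; ``matching='smiles'``
    additionally matches on canonical SMILES when both sides carry a
    structure.  An unparseable candidate SMILES degrades to ID matching for
    that candidate with a warning.
    """
    if matching not in {"id", "smiles"}:
        raise ValueError(f"unknown matching rule {matching!r}")
    kb_canonical: dict[str, str] = {}
    if matching == "smiles":
        for c in kb.compounds.values():
            if c.smiles:
                try:
                    kb_canonical[_canonical_smiles(c.smiles)] = c.compound_id
                except SmilesParseError:
                    warnings.warn(
                        f"KB compound {c.compound_id} has unparseable SMILES; "
                        "excluded from structure matching"
                    )
    out = []
    for cand in candidates:
        positive = cand.candidate_id in kb.compounds
        if not positive and matching == "smiles" and cand.smiles:
            try:
                positive = _canonical_smiles(cand.smiles) in kb_canonical
            except SmilesParseError:
                warnings.warn(
                    f"candidate {cand.candidate_id}: unparseable SMILES, "
                    "falling back to ID match"
                )
        out.append(
            LabeledCandidate(
                candidate_id=cand.candidate_id,
                label="positive" if positive else "negative",
                modality=modality,
            )
        )
    return out


def query_annotations(compound_id: str, kb: KnowledgeBase) -> tuple[list[str], list[str]]:
    """Return the (sorted) target IDs and disease IDs directly linked to a compound."""
    if compound_id not in kb.compounds:
        raise LookupError_(f"unknown compound_id {compound_id!r}")
    targets = {
        ln.object_id for ln in kb.links_of(compound_id, LinkType.COMPOUND_TARGET)
    }
    diseases = {
        ln.object_id for ln in kb.links_of(compound_id, LinkType.COMPOUND_DISEASE)
    }
    return sorted(targets), sorted(diseases)
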