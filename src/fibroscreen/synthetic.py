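"""Synthetic corpora for exercising every pipeline stage without downloads.

The generators emulate the statistical shape of the real training data:

* a *structural* corpus of binary 166-bit fingerprint rows in which a few
  planted bits fire more often in the positive class (known anti-fibrosis
  compounds) than in the negative class;
* a *biological* corpus of Gaussian expression profiles, several profiles
  per synthetic compound, with planted genes mean-shifted in profiles of
  positive compounds, additive + multiplicative batch distortions, and a
  small fraction of grossly corrupted outlier samples;
* a toy knowledge base whose compounds are exactly the corpus positives
  plus decoys, with referentially consistent target/disease links.

Each generator is a pure function of its config (including the seed), and
every corpus carries its ground truth so tests can assert recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .featurize import FeatureMatrix, N_MACCS_BITS, maccs_feature_names
from .kb import (
    CompoundRecord,
    DiseaseRecord,
    EvidenceLink,
    KnowledgeBase,
    LinkType,
    TargetRecord,
)

__all__ = [
    "SynthConfig",
    "SynthCorpus",
    "bundled_smiles",
    "generate_structural_corpus",
    "generate_biological_corpus",
    "generate_toy_kb",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    Structural defaults: 500 positive + 500 negative fingerprints over the
    166 MACCS-shaped bits, 5 informative bits whose firing rate is
    ``base_rate + effect_size`` in positives (0.75 vs 0.25, i.e. a
    single-bit marginal AUC of about 0.75).  Biological ``effect_size`` is
    instead a mean shift in noise-SD units.
    """

    n_pos: int = 500
    n_neg: int = 500
    n_features: int = N_MACCS_BITS
    n_informative: int = 5
    effect_size: float = 0.5
    base_rate: float = 0.25
    outlier_fraction: float = 0.02
    batch_count: int = 3
    batch_shift: float = 1.0
    profiles_per_compound: tuple[int, int] = (2, 6)
    n_targets: int = 20
    n_diseases: int = 6
    n_decoys: int = 20
    links_per_compound: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")


@dataclass
class SynthCorpus:
    matrix: FeatureMatrix
    labels: pd.Series                       # 1 = positive, 0 = negative
    informative_features: list[str]
    outlier_ids: list[str]
    groups: Optional[pd.Series] = None      # sample -> synthetic compound ID
    smiles: dict[str, str] = field(default_factory=dict)
    kb: Optional[KnowledgeBase] = None


def bundled_smiles() -> dict[str, str]:
    """The shipped fixture library of hand-checked drug-like SMILES."""
    text = (
        resources.files("fibroscreen.data").joinpath("smiles_library.smi").read_text()
    )
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, smi = line.split("\t")
        out[name] = smi
    return out


# ---------------------------------------------------------------------------
# Structural
# ---------------------------------------------------------------------------


def generate_structural_corpus(config: SynthConfig = SynthConfig()) -> SynthCorpus:
    """Binary fingerprint corpus with planted informative bits and outliers.

    Informative bits fire with probability ``base_rate + effect_size`` in
    the positive class and ``base_rate`` in the negative class; all other
    bits fire at ``base_rate`` in both.  Planted outlier rows are redrawn
    with an extreme firing rate (0.95), far outside the data cloud.
    """
    if config.n_features > N_MACCS_BITS:
        raise ValueError(
            f"MACCS-shaped corpus supports at most {N_MACCS_BITS} features"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    y = np.array([1] * config.n_pos + [0] * config.n_neg)
    p = np.full((n, config.n_features), config.base_rate)
    informative_idx = rng.choice(
        config.n_features, size=config.n_informative, replace=False
    )
    p[y == 1][:, informative_idx] = config.base_rate  # no-op, clarity
    p[np.ix_(y == 1, informative_idx)] = min(config.base_rate + config.effect_size, 1.0)
    X = (rng.random((n, config.n_features)) < p).astype(np.uint8)

    sample_ids = [f"cmp{i:04d}" for i in range(n)]
    n_out = int(round(config.outlier_fraction * n))
    outlier_pos = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    for i in outlier_pos:
        X[i] = (rng.random(config.n_features) < 0.95).astype(np.uint8)

    cols = maccs_feature_names()[: config.n_features]
    df = pd.DataFrame(X, index=sample_ids, columns=cols)
    labels = pd.Series(y, index=sample_ids)

    library = bundled_smiles()
    names = sorted(library)
    smiles = {
        sid: library[names[i % len(names)]] for i, sid in enumerate(sample_ids)
    }
    corpus = SynthCorpus(
        matrix=FeatureMatrix(values=df, modality="structural"),
        labels=labels,
        informative_features=[cols[i] for i in sorted(informative_idx)],
        outlier_ids=[sample_ids[i] for i in sorted(outlier_pos)],
        smiles=smiles,
    )
    corpus.kb = generate_toy_kb(config, positives=list(labels.index[labels == 1]))
    return corpus


# ---------------------------------------------------------------------------
# Biological
# ---------------------------------------------------------------------------


def generate_biological_corpus(config: SynthConfig = SynthConfig(
    n_pos=200, n_neg=200, n_features=300, n_informative=20, effect_size=1.0
)) -> SynthCorpus:
    """Gaussian expression corpus with planted genes, batches and outliers.

    ``n_pos``/``n_neg`` count profiles (samples); profiles are grouped into
    synthetic compounds with 2–6 profiles each, mimicking a perturbation
    compendium where one compound has several instances.  Planted genes
    are shifted by ``effect_size`` noise-SDs in positive-compound
    profiles.  Each batch applies an additive shift and a positive scaling
    (a monotone distortion that a per-profile rank transform removes).
    Outlier profiles are corrupted with an 8-SD random displacement.
    """
    if config.batch_count < 1:
        raise ValueError("batch_count must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    y = np.array([1] * config.n_pos + [0] * config.n_neg)

    # group profiles into compounds with 2-6 profiles each, per class
    lo, hi = config.profiles_per_compound
    groups = np.empty(n, dtype=object)
    cmp_counter = 0
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        i = 0
        while i < len(idx):
            k = int(rng.integers(lo, hi + 1))
            cid = f"synth{cmp_counter:04d}"
            for j in idx[i : i + k]:
                groups[j] = cid
            cmp_counter += 1
            i += k

    genes = [f"G{i:04d}" for i in range(config.n_features)]
    informative_idx = rng.choice(
        config.n_features, size=config.n_informative, replace=False
    )
    X = rng.standard_normal((n, config.n_features))
    X[np.ix_(y == 1, informative_idx)] += config.effect_size

    batches = rng.integers(0, config.batch_count, size=n)
    shifts = rng.normal(0, config.batch_shift, size=config.batch_count)
    scales = np.exp(rng.normal(0, 0.2, size=config.batch_count))
    for b in range(config.batch_count):
        mask = batches == b
        X[mask] = X[mask] * scales[b] + shifts[b]

    sample_ids = [f"prof{i:04d}" for i in range(n)]
    n_out = int(round(config.outlier_fraction * n))
    outlier_pos = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    for i in outlier_pos:
        direction = rng.standard_normal(config.n_features)
        X[i] = X[i] + 8.0 * direction / np.linalg.norm(direction) * np.sqrt(
            config.n_features
        )

    df = pd.DataFrame(X, index=sample_ids, columns=genes)
    labels = pd.Series(y, index=sample_ids)
    group_s = pd.Series(groups, index=sample_ids)
    corpus = SynthCorpus(
        matrix=FeatureMatrix(values=df, modality="biological"),
        labels=labels,
        informative_features=[genes[i] for i in sorted(informative_idx)],
        outlier_ids=[sample_ids[i] for i in sorted(outlier_pos)],
        groups=group_s,
    )
    corpus.kb = generate_toy_kb(
        config, positives=sorted(group_s[labels == 1].unique())
    )
    return corpus


# ---------------------------------------------------------------------------
# Toy knowledge base
# ---------------------------------------------------------------------------


def generate_toy_kb(config: SynthConfig, positives: list[str]) -> KnowledgeBase:
    """KB whose compounds are exactly ``positives`` plus decoy compounds.

    Labeling a corpus against this KB by ID therefore reproduces the
    generator's labels.  Targets/diseases and their links are drawn
    deterministically from the config seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    library = bundled_smiles()
    names = sorted(library)

    compounds = {}
    for i, cid in enumerate(positives):
        compounds[cid] = CompoundRecord(
            compound_id=cid,
            name=f"synthetic positive {i}",
            smiles=library[names[i % len(names)]],
            is_approved=bool(rng.random() < 0.4),
            sources=frozenset({"literature"}),
        )
    for i in range(config.n_decoys):
        cid = f"decoy{i:03d}"
        compounds[cid] = CompoundRecord(
            compound_id=cid,
            name=f"synthetic decoy {i}",
            smiles=library[names[(i * 7 + 3) % len(names)]],
            is_approved=False,
            sources=frozenset({"ctd"}),
        )

    targets = {
        f"T{i:03d}": TargetRecord(target_id=f"T{i:03d}", symbol=f"GENE{i}", entrez=str(1000 + i))
        for i in range(config.n_targets)
    }
    diseases = {
        f"D{i:02d}": DiseaseRecord(disease_id=f"D{i:02d}", name=f"fibrosis subtype {i}")
        for i in range(config.n_diseases)
    }

    links: list[EvidenceLink] = []
    seen = set()
    target_ids = sorted(targets)
    disease_ids = sorted(diseases)
    for cid in sorted(compounds):
        picked = rng.choice(
            len(target_ids),
            size=min(config.links_per_compound, len(target_ids)),
            replace=False,
        )
        for t in picked:
            key = (cid, target_ids[t])
            if key in seen:
                continue
            seen.add(key)
            links.append(
                EvidenceLink(
                    subject_id=cid,
                    object_id=target_ids[t],
                    link_type=LinkType.COMPOUND_TARGET,
                    source="literature",
                    reference=f"PMID:{int(rng.integers(10_000_000, 40_000_000))}",
                )
            )
        d = int(rng.integers(0, len(disease_ids)))
        links.append(
            EvidenceLink(
                subject_id=cid,
                object_id=disease_ids[d],
                link_type=LinkType.COMPOUND_DISEASE,
                source="trial",
                reference=f"NCT{int(rng.integers(10_000_000, 99_999_999))}",
            )
        )
    for t in target_ids[: config.n_diseases]:
        d = disease_ids[int(rng.integers(0, len(disease_ids)))]
        links.append(
            EvidenceLink(
                subject_id=t,
                object_id=d,
                link_type=LinkType.TARGET_DISEASE,
                source="ctd",
                reference="CTD:synthetic",
            )
        )
    return KnowledgeBase(compounds, targets, diseases, links)
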