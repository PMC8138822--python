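"""Featurization: MACCS fingerprints, rank-quantile expression profiles,
and the two similarity metrics used throughout the pipeline.

Structural candidates are encoded as 166-bit MACCS key fingerprints
(substructure presence bits) and compared with Tanimoto similarity.
Biological candidates are compound-induced expression profiles; each
profile is transformed *within itself* to rank quantiles in [0, 1], which
makes profiles from different batches and platforms comparable, and pairs
of profiles are compared with Spearman rank correlation over their shared
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AssemblyError,
    ConfigurationError,
    DimensionError,
    InsufficientOverlapError,
    SmilesParseError,
    UndefinedCorrelationError,
)

__all__ = [
    "N_MACCS_BITS",
    "StructuralFingerprint",
    "ExpressionProfile",
    "RankProfile",
    "FeatureMatrix",
    "GeneIdMap",
    "smiles_to_maccs",
    "tanimoto",
    "harmonize_ids",
    "quantile_rank_transform",
    "spearman",
    "assemble_matrix",
    "maccs_feature_names",
]

#: MACCS keys 1..166; bit i of the vector corresponds to key i+1.
N_MACCS_BITS = 166


def maccs_feature_names() -> list[str]:
    return [f"maccs_{i}" for i in range(1, N_MACCS_BITS + 1)]


@dataclass(frozen=True)
class StructuralFingerprint:
    compound_id: Optional[str]
    bits: np.ndarray  # uint8 vector of length 166

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (N_MACCS_BITS,):
            raise DimensionError(
                f"fingerprint must have length {N_MACCS_BITS}, got {bits.shape}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")
        object.__setattr__(self, "bits", bits)


@dataclass
class ExpressionProfile:
    """One sample's expression values keyed by gene identifier."""

    sample_id: str
    compound_id: Optional[str]
    id_space: str  # "probe" | "entrez" | "symbol"
    values: pd.Series

    def __post_init__(self):
        s = pd.Series(self.values, dtype=float)
        if s.index.has_duplicates:
            raise ValueError(f"profile {self.sample_id}: duplicate gene identifiers")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError(f"profile {self.sample_id}: non-finite values")
        self.values = s


@dataclass
class RankProfile:
    """Rank-quantile transformed profile; values lie in [0, 1]."""

    sample_id: str
    compound_id: Optional[str]
    values: pd.Series


@dataclass
class FeatureMatrix:
    """Samples × features container shared by QC and modeling.

    ``values`` is a DataFrame indexed by sample ID with unique feature
    columns; ``modality`` is ``"structural"`` or ``"biological"``.
    """

    values: pd.DataFrame
    modality: str
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.columns.has_duplicates:
            raise AssemblyError("duplicate feature IDs in matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Structural
# ---------------------------------------------------------------------------


def smiles_to_maccs(smiles: str, compound_id: Optional[str] = None) -> StructuralFingerprint:
    """Compute the 166-bit MACCS key fingerprint of a molecule.

    RDKit's MACCS generator returns 167 bits with bit 0 always unset
    (keys are 1-indexed); we drop bit 0 so that position ``i`` of the
    result corresponds to MACCS key ``i + 1``.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    fp = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(N_MACCS_BITS, dtype=np.uint8)
    for b in fp.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1
    return StructuralFingerprint(compound_id=compound_id, bits=bits)


def _as_bits(fp) -> np.ndarray:
    if isinstance(fp, StructuralFingerprint):
        return fp.bits
    arr = np.asarray(fp)
    return arr


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two binary fingerprints.

    Returns 0.0 when both fingerprints are all-zero (documented convention).
    """
    a, b = _as_bits(fp_a).astype(bool), _as_bits(fp_b).astype(bool)
    if a.shape != b.shape:
        raise DimensionError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# Biological
# ---------------------------------------------------------------------------


class GeneIdMap:
    """Mappings between probe, Entrez and symbol gene-identifier spaces.

    Built from two-column tables (``probe → entrez`` and
    ``entrez → symbol``); derived conversions (e.g. probe → symbol) are
    composed on demand, and inverse lookups are supported when the forward
    map is one-to-one for the IDs involved.
    """

    SPACES = ("probe", "entrez", "symbol")

    def __init__(
        self,
        probe_to_entrez: Optional[dict[str, str]] = None,
        entrez_to_symbol: Optional[dict[str, str]] = None,
    ):
        self.probe_to_entrez = dict(probe_to_entrez or {})
        self.entrez_to_symbol = {
            k: v.upper() for k, v in (entrez_to_symbol or {}).items()
        }

    @classmethod
    def from_tables(cls, probe_to_entrez_tsv=None, entrez_to_symbol_tsv=None):
        def read(path):
            if path is None:
                return {}
            df = pd.read_csv(path, sep="\t", dtype=str, header=0)
            return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))

        return cls(read(probe_to_entrez_tsv), read(entrez_to_symbol_tsv))

    def _step(self, src: str, dst: str) -> dict[str, str]:
        if (src, dst) == ("probe", "entrez"):
            return self.probe_to_entrez
        if (src, dst) == ("entrez", "symbol"):
            return self.entrez_to_symbol
        if (src, dst) == ("entrez", "probe"):
            return _invert(self.probe_to_entrez)
        if (src, dst) == ("symbol", "entrez"):
            return _invert(self.entrez_to_symbol)
        raise ConfigurationError(f"no direct mapping {src} -> {dst}")

    def convert(self, ids: Sequence[str], src: str, dst: str) -> dict[str, str]:
        """Map each source ID to the destination space; unmapped IDs omitted."""
        for sp in (src, dst):
            if sp not in self.SPACES:
                raise ConfigurationError(f"unknown id space {sp!r}")
        if src == dst:
            return {i: i for i in ids}
        path = {"probe": 0, "entrez": 1, "symbol": 2}
        chain = (
            [self._step(src, dst)]
            if abs(path[src] - path[dst]) == 1
            else [
                self._step(src, "entrez"),
                self._step("entrez", dst),
            ]
        )
        if any(len(step) == 0 for step in chain):
            raise ConfigurationError(f"empty mapping table for {src} -> {dst}")
        out = {}
        for i in ids:
            cur = i
            for step in chain:
                cur = step.get(cur)
                if cur is None:
                    break
            if cur is not None:
                out[i] = cur
        return out


def _invert(mapping: dict[str, str]) -> dict[str, str]:
    inv: dict[str, str] = {}
    for k, v in mapping.items():
        inv.setdefault(v, k)
    return inv


_AGGREGATORS = ("mean", "median", "max")


def harmonize_ids(
    profile: ExpressionProfile,
    gene_id_map: GeneIdMap,
    target_space: str,
    aggregator: str = "mean",
) -> ExpressionProfile:
    """Convert a profile's gene identifiers to ``target_space``.

    Several source IDs mapping to one target ID are collapsed with the
    configured aggregator; unmapped IDs are dropped with a warning that
    reports their count.
    """
    if aggregator not in _AGGREGATORS:
        raise ConfigurationError(f"unknown aggregator {aggregator!r}")
    if profile.id_space == target_space:
        return profile
    mapping = gene_id_map.convert(list(profile.values.index), profile.id_space, target_space)
    unmapped = [i for i in profile.values.index if i not in mapping]
    if unmapped:
        warnings.warn(
            f"profile {profile.sample_id}: {len(unmapped)} of "
            f"{len(profile.values)} identifiers unmapped "
            f"({profile.id_space} -> {target_space}); dropped"
        )
    mapped = profile.values[profile.values.index.isin(mapping)]
    grouped = mapped.groupby([mapping[i] for i in mapped.index]).agg(aggregator)
    return ExpressionProfile(
        sample_id=profile.sample_id,
        compound_id=profile.compound_id,
        id_space=target_space,
        values=grouped,
    )


def _rank_quantiles(x: np.ndarray) -> np.ndarray:
    """Average ranks rescaled so min -> 0 and max -> 1; constant input -> 0.5."""
    n = len(x)
    if np.all(x == x[0]):
        return np.full(n, 0.5)
    r = stats.rankdata(x, method="average")
    return (r - 1.0) / (n - 1.0)


def quantile_rank_transform(profile: ExpressionProfile) -> RankProfile:
    """Replace each gene's value by its rank quantile within the profile.

    Value -> (average rank − 1)/(n − 1), so the minimum maps to 0 and the
    maximum to 1 and ties share the mean of their ranks.  The transform is
    invariant under any strictly increasing transform of the input, which
    is what makes profiles from different platforms comparable.
    """
    vals = profile.values.to_numpy()
    if len(vals) < 2:
        raise ValueError("need at least 2 genes for a rank transform")
    if np.all(vals == vals[0]):
        warnings.warn(
            f"profile {profile.sample_id}: all values identical; "
            "degenerate rank profile (all 0.5)"
        )
    q = _rank_quantiles(vals)
    return RankProfile(
        sample_id=profile.sample_id,
        compound_id=profile.compound_id,
        values=pd.Series(q, index=profile.values.index),
    )


def spearman(profile_a, profile_b) -> float:
    """Spearman rank correlation of two profiles over their shared genes.

    Accepts :class:`ExpressionProfile`, :class:`RankProfile` or a plain
    ``pandas.Series``.  Computed as the Pearson correlation of average
    ranks over the intersection of gene identifiers (ties get the mean of
    their ranks), so it is insensitive to monotone rescalings.
    """

    def values_of(p):
        return p.values if hasattr(p, "values") and not isinstance(p, pd.Series) else pd.Series(p)

    a, b = values_of(profile_a), values_of(profile_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"profiles share only {len(shared)} genes (need >= 3)"
        )
    ra = stats.rankdata(a[shared].to_numpy())
    rb = stats.rankdata(b[shared].to_numpy())
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        raise UndefinedCorrelationError("zero variance in a rank vector")
    return float(np.corrcoef(ra, rb)[0, 1])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_matrix(items: Iterable, modality: str) -> FeatureMatrix:
    """Stack fingerprints or rank profiles into one samples × features matrix.

    Structural items become rows over ``maccs_1 .. maccs_166``; biological
    items are restricted to the intersection of their gene vocabularies
    (dropped genes are reported on the result) with columns sorted
    lexicographically.  Rows keep input order.
    """
    items = list(items)
    if not items:
        raise AssemblyError("no items to assemble")
    if modality == "structural":
        rows, index = [], []
        for i, it in enumerate(items):
            if not isinstance(it, StructuralFingerprint):
                raise AssemblyError(f"item {i} is not a StructuralFingerprint")
            rows.append(it.bits)
            index.append(it.compound_id if it.compound_id is not None else f"s{i}")
        df = pd.DataFrame(
            np.vstack(rows).astype(np.uint8), index=index, columns=maccs_feature_names()
        )
        return FeatureMatrix(values=df, modality="structural")
    if modality == "biological":
        vocab = None
        union: set = set()
        for it in items:
            genes = set(it.values.index)
            union |= genes
            vocab = genes if vocab is None else (vocab & genes)
        if not vocab:
            raise AssemblyError("empty intersection of gene vocabularies")
        cols = sorted(vocab)
        dropped = sorted(union - vocab)
        rows = [it.values[cols].to_numpy() for it in items]
        index = [it.sample_id for it in items]
        df = pd.DataFrame(np.vstack(rows), index=index, columns=cols)
        return FeatureMatrix(values=df, modality="biological", dropped_features=dropped)
    raise AssemblyError(f"unknown modality {modality!r}")
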