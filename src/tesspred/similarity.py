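"""Compound featurization and generalized Jaccard (Ruzicka) similarity.

Compounds are represented as sparse nonnegative frequency vectors over
substructure features, and compared with

    sim(x, y) = sum_i min(x_i, y_i) / sum_i max(x_i, y_i)

over the union support.  On 0/1 vectors this reduces to the set Jaccard
index |A ∩ B| / |A ∪ B|.  The feature scheme is pluggable: any sparse
counted-substructure vocabulary works, including precomputed descriptor
files; a default featurizer based on RDKit Morgan count fingerprints is
provided for SMILES input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .model import DomainError, ParseError

__all__ = [
    "FeatureVector",
    "FeaturizerConfig",
    "generalized_jaccard",
    "similarity_matrix",
    "featurize",
]


@dataclass(frozen=True)
class FeatureVector:
    """Sparse map feature_id → count.

    Zero entries are dropped at construction; negative counts are
    rejected.  An empty support is allowed (a degenerate compound with
    no detected substructures) and compares with similarity 0 to
    everything.
    """

    counts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for fid, c in self.counts.items():
            if c < 0:
                raise DomainError(f"negative count {c!r} for feature {fid!r}")
            if c > 0:
                clean[fid] = float(c)
        object.__setattr__(self, "counts", clean)

    @property
    def support(self) -> frozenset:
        return frozenset(self.counts)

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def scaled(self, factor: float) -> "FeatureVector":
        if factor <= 0:
            raise DomainError(f"scale factor must be positive, got {factor!r}")
        return FeatureVector({f: c * factor for f, c in self.counts.items()})


def generalized_jaccard(x: FeatureVector, y: FeatureVector) -> float:
    """Ruzicka similarity Σ min / Σ max in [0, 1].

    Symmetric; 1 for identical nonempty vectors; 0 for disjoint
    supports.  When both vectors are empty the similarity is defined as
    0 and a warning is emitted (keeps downstream rankings total).
    """
    if not x.counts and not y.counts:
        warnings.warn(
            "generalized_jaccard of two empty feature vectors; returning 0",
            stacklevel=2,
        )
        return 0.0
    num = 0.0
    den = 0.0
    for fid in x.support | y.support:
        xi = x.counts.get(fid, 0.0)
        yi = y.counts.get(fid, 0.0)
        num += min(xi, yi)
        den += max(xi, yi)
    return num / den if den > 0 else 0.0


def _stack(vectors: Sequence[FeatureVector], feature_index: Mapping[str, int]):
    """CSR matrix of shape (len(vectors), n_features)."""
    rows, cols, data = [], [], []
    for i, v in enumerate(vectors):
        for fid, c in v.counts.items():
            rows.append(i)
            cols.append(feature_index[fid])
            data.append(c)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(vectors), len(feature_index))
    )


def similarity_matrix(
    queries: Sequence[FeatureVector], references: Sequence[FeatureVector]
) -> np.ndarray:
    """Pairwise generalized Jaccard similarities, entry (i, j) =
    sim(queries[i], references[j]).

    Vectorized over the reference set: for each query only the columns
    in its support are materialised, using
    Σ max = Σx + Σy − Σ min over the shared support.
    """
    if len(queries) == 0 or len(references) == 0:
        raise DomainError("similarity_matrix requires non-empty query/reference lists")

    feats = sorted({f for v in queries for f in v.counts}
                   | {f for v in references for f in v.counts})
    index = {f: i for i, f in enumerate(feats)}
    R = _stack(references, index)
    r_tot = np.asarray(R.sum(axis=1)).ravel()

    out = np.zeros((len(queries), len(references)))
    empty_pair = False
    for i, q in enumerate(queries):
        if not q.counts:
            if any(r_tot == 0):
                empty_pair = True
            continue
        q_ids = sorted(q.counts)
        q_vals = np.array([q.counts[f] for f in q_ids])
        cols = [index[f] for f in q_ids]
        sub = R[:, cols].toarray()
        shared_min = np.minimum(sub, q_vals[None, :]).sum(axis=1)
        denom = q_vals.sum() + r_tot - shared_min
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(denom > 0, shared_min / denom, 0.0)
        out[i] = sims
    if empty_pair:
        warnings.warn(
            "similarity_matrix saw an empty-vs-empty pair; its similarity is 0",
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class FeaturizerConfig:
    """Settings for the default SMILES featurizer.

    ``radius`` is the circular-substructure radius of the Morgan count
    fingerprint; features are the unhashed environment identifiers, so
    identical structures always map to identical vectors.
    """

    radius: int = 2
    prefix: str = "m"


def featurize(structure: str, config: Optional[FeaturizerConfig] = None) -> FeatureVector:
    """Counted-substructure vector for a SMILES string.

    Deterministic: the same structure string always yields the same
    vector.  Raises :class:`ParseError` for unparseable input.
    """
    config = config or FeaturizerConfig()
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError:  # pragma: no cover
        from .model import ConfigurationError

        raise ConfigurationError(
            "the default featurizer needs RDKit (install the 'chem' extra); "
            "alternatively supply precomputed fingerprints"
        ) from None
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ParseError(f"unparseable structure string: {structure!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=config.radius)
    fp = gen.GetSparseCountFingerprint(mol)
    return FeatureVector(
        {f"{config.prefix}{bit}": count for bit, count in fp.GetNonzeroElements().items()}
    )
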