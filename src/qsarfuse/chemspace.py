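"""Chemical-space diagnostics of misclassification.

Chemicals are described by binary fingerprints (e.g. 1024-bit circular
fingerprints of radius 2); pairwise Jaccard–Tanimoto similarities define a
distance d = 1 - s, which classical (Torgerson) multidimensional scaling
embeds in two dimensions via double-centering and eigendecomposition. The
embedding is overlaid with per-chemical error counts and prediction
fractions, and chemicals that every in-AD model gets wrong are flagged as
systematic false negatives or false positives.

Classical MDS was chosen over stress-majorization because it is
deterministic and exactly recovers configurations that are Euclidean-
embeddable in the target dimension, which makes it testable; a fixed sign
convention (the largest-magnitude loading on each axis is made positive)
removes the remaining reflection ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.linalg

from .io import ACTIVE, INACTIVE, NO_PREDICTION, UNKNOWN, PredictionTable


@dataclass
class FingerprintMatrix:
    """Chemicals x bits boolean matrix, rows aligned with a PredictionTable.

    Every row must have at least one set bit, otherwise its Tanimoto
    similarity to anything is undefined; offending chemicals are reported
    by id at construction.
    """

    bits: np.ndarray
    chemical_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("fingerprint matrix must be 2-D (chemicals x bits)")
        if self.chemical_ids is not None and len(self.chemical_ids) != self.bits.shape[0]:
            raise ValueError("chemical_ids must align with fingerprint rows")
        empty = ~self.bits.any(axis=1)
        if empty.any():
            which = (
                [self.chemical_ids[i] for i in np.flatnonzero(empty)]
                if self.chemical_ids is not None
                else list(np.flatnonzero(empty))
            )
            raise ValueError(f"empty fingerprints (no set bits) for chemicals: {which[:5]}")

    @property
    def n_chemicals(self) -> int:
        return self.bits.shape[0]

    @property
    def bit_length(self) -> int:
        return self.bits.shape[1]


@dataclass
class MDSEmbedding:
    """Low-dimensional coordinates with the retained eigenvalues.

    Columns are ordered by decreasing eigenvalue and the configuration is
    centered (column means zero).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray


def _as_bitset(fp) -> frozenset:
    if isinstance(fp, (set, frozenset)):
        return frozenset(fp)
    arr = np.asarray(fp)
    if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
        if arr.ndim == 1 and arr.dtype == bool:
            return frozenset(np.flatnonzero(arr).tolist())
        if arr.ndim == 1 and set(np.unique(arr)).issubset({0, 1}):
            return frozenset(np.flatnonzero(arr).tolist())
        return frozenset(int(x) for x in arr)
    raise ValueError("fingerprint must be a bit vector or a set of bit indices")


def tanimoto_similarity(fp_a, fp_b) -> float:
    """Jaccard–Tanimoto coefficient |A ∩ B| / |A ∪ B| on set bits.

    Accepts boolean/0-1 vectors or explicit sets of bit indices. Undefined
    (raises) when both fingerprints are empty.
    """
    a, b = _as_bitset(fp_a), _as_bitset(fp_b)
    union = a | b
    if not union:
        raise ValueError("Tanimoto similarity undefined for two empty fingerprints")
    return len(a & b) / len(union)


def distance_matrix(fps: FingerprintMatrix) -> np.ndarray:
    """Pairwise Tanimoto distances d_ij = 1 - s_ij (zero diagonal, symmetric)."""
    f = fps.bits.astype(np.float64)
    inter = f @ f.T
    counts = f.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    # construction guarantees nonempty rows, so union > 0 everywhere
    sim = inter / union
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def classical_mds(D: np.ndarray, d: int = 2) -> MDSEmbedding:
    """Torgerson metric MDS: double-center, eigendecompose, scale.

    B = -1/2 J (D ∘ D) J with J the centering operator; coordinates are the
    top-``d`` eigenvectors scaled by the square roots of their eigenvalues,
    negative eigenvalues clipped to zero. The sign of each axis is fixed by
    making its largest-magnitude loading positive, so repeated runs agree.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(B, subset_by_index=(max(0, n - d), n - 1))
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    coords = eigvecs * np.sqrt(eigvals)[None, :]
    if coords.shape[1] < d:
        coords = np.pad(coords, ((0, 0), (0, d - coords.shape[1])))
        eigvals = np.pad(eigvals, (0, d - eigvals.shape[0]))
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col.any():
            pivot = np.argmax(np.abs(col))
            if col[pivot] < 0:
                coords[:, axis] = -col
    coords -= coords.mean(axis=0, keepdims=True)
    return MDSEmbedding(coordinates=coords, eigenvalues=eigvals)


def misclassification_summary(table: PredictionTable,
                              predictions_by_source: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-chemical error and coverage overlay for embedding plots.

    For each chemical, across the named prediction sources (individual
    models or consensus strategies): ``n_wrong`` sources predicting the
    wrong class (NA where the true label is unknown), ``n_predicting``
    sources not abstaining, and ``fraction_predicting`` of all sources.
    """
    sources = list(predictions_by_source)
    if not sources:
        raise ValueError("at least one prediction source is required")
    preds = np.stack([np.asarray(predictions_by_source[s]) for s in sources], axis=1)
    if preds.shape[0] != table.n_chemicals:
        raise ValueError("prediction sources must align with the table's chemicals")
    labels = table.true_labels
    predicting = preds != NO_PREDICTION
    n_predicting = predicting.sum(axis=1)
    wrong = predicting & (preds != labels[:, None])
    n_wrong = wrong.sum(axis=1).astype(float)
    n_wrong[labels == UNKNOWN] = np.nan
    return pd.DataFrame(
        {
            "chemical_id": table.chemical_ids,
            "n_wrong": n_wrong,
            "n_predicting": n_predicting,
            "fraction_predicting": n_predicting / len(sources),
        }
    )


def find_always_wrong(table: PredictionTable) -> pd.DataFrame:
    """Chemicals misclassified by every model whose AD covers them.

    Only chemicals with a known label and at least one in-AD class vote
    qualify; each is tagged ``false-negative`` (a true active that every
    covering model calls inactive) or ``false-positive`` (the converse).
    """
    eff = table.effective_votes()
    labels = table.true_labels
    voting = eff != NO_PREDICTION
    n_votes = voting.sum(axis=1)
    wrong = voting & (eff != labels[:, None])
    all_wrong = (wrong.sum(axis=1) == n_votes) & (n_votes >= 1) & (labels != UNKNOWN)
    idx = np.flatnonzero(all_wrong)
    return pd.DataFrame(
        {
            "chemical_id": [table.chemical_ids[i] for i in idx],
            "error_type": [
                "false-negative" if labels[i] == ACTIVE else "false-positive" for i in idx
            ],
            "n_votes": n_votes[idx],
        }
    )


def morgan_fingerprints(smiles: Iterable[str], n_bits: int = 1024, radius: int = 2,
                        chemical_ids: list[str] | None = None) -> FingerprintMatrix:
    """Hashed circular (Morgan) fingerprints from SMILES via RDKit.

    Optional helper for when structures rather than precomputed fingerprints
    are available; requires the ``chem`` extra. Unparsable SMILES raise.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("morgan_fingerprints requires rdkit (install the 'chem' extra)") from exc

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES at position {i}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) == ord("1"))
    return FingerprintMatrix(np.stack(rows), chemical_ids=chemical_ids)


def read_fingerprints(path, chemical_ids: list[str] | None = None) -> FingerprintMatrix:
    """Read a dense 0/1 fingerprint CSV (first column = chemical id)."""
    df = pd.read_csv(path, dtype=str)
    ids = [str(x) for x in df.iloc[:, 0]]
    bits = df.iloc[:, 1:].astype(int).to_numpy().astype(bool)
    fps = FingerprintMatrix(bits, chemical_ids=ids)
    if chemical_ids is not None and ids != list(chemical_ids):
        raise ValueError("fingerprint rows do not match the prediction table's chemicals")
    return fps


def write_fingerprints(fps: FingerprintMatrix, path) -> None:
    ids = fps.chemical_ids or [str(i) for i in range(fps.n_chemicals)]
    df = pd.DataFrame(fps.bits.astype(int), columns=[f"bit_{j}" for j in range(fps.bit_length)])
    df.insert(0, "chemical_id", ids)
    df.to_csv(path, index=False)


def plot_embedding(embedding: MDSEmbedding, summary: pd.DataFrame, path) -> None:
    """Scatter of the first two MDS dimensions; color encodes the number of
    misclassifications, point size the fraction of sources predicting."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = embedding.coordinates[:, :2]
    color = summary["n_wrong"].to_numpy(dtype=float)
    size = 10 + 60 * summary["fraction_predicting"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=color, s=size, cmap="Greys", edgecolors="k",
                    linewidths=0.3)
    fig.colorbar(sc, ax=ax, label="misclassifications")
    ax.set_xlabel("MDS dimension 1")
    ax.set_ylabel("MDS dimension 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
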