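"""Fixed-length numeric encoding of CDR3 amino-acid sequences.

Each residue is mapped to a d-dimensional embedding derived from the BLOSUM62
substitution matrix (rows of the symmetric 20x20 similarity matrix projected
onto its leading eigencomponents, scaled by sqrt(|eigenvalue|)), so Euclidean
distance between residue embeddings approximates substitution dissimilarity.

Length handling mimics IMGT-style junction alignment: after trimming ``trim``
residues from each end, the remaining sequence is split at its midpoint; the
left half is left-aligned and the right half right-aligned into ``max_len``
slots, with the unused center slots gap-coded as zero vectors. The output is
the concatenation of the max_len slot vectors (length max_len * d).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ArgumentError
from .repertoire import AA_ALPHABET


@lru_cache(maxsize=None)
def blosum_embedding(n_components: int = 8) -> dict[str, np.ndarray]:
    """Residue -> d-vector from the spectral decomposition of BLOSUM62."""
    if not 1 <= n_components <= 20:
        raise ArgumentError("n_components must be in [1, 20]")
    mat = substitution_matrices.load("BLOSUM62")
    idx = [mat.alphabet.index(a) for a in AA_ALPHABET]
    b = np.asarray(mat)[np.ix_(idx, idx)].astype(float)
    w, v = np.linalg.eigh(b)
    order = np.argsort(-np.abs(w))[:n_components]
    comps = v[:, order] * np.sqrt(np.abs(w[order]))
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(comps.shape[1]):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    return {aa: comps[i].copy() for i, aa in enumerate(AA_ALPHABET)}


def encode_cdr3(cdr3aa: str, max_len: int = 22, trim: int = 0, n_components: int = 8) -> np.ndarray:
    """Deterministic fixed-length vector for one CDR3 (see module docstring)."""
    emb = blosum_embedding(n_components)
    core = cdr3aa[trim : len(cdr3aa) - trim] if trim else cdr3aa
    L = len(core)
    if L > max_len:
        raise ArgumentError(f"sequence length {L} exceeds max_len {max_len}")
    bad = set(core) - set(AA_ALPHABET)
    if bad:
        raise ArgumentError(f"non-standard residues {sorted(bad)} in {cdr3aa!r}")
    d = n_components
    out = np.zeros((max_len, d))
    n_left = (L + 1) // 2
    for i in range(n_left):
        out[i] = emb[core[i]]
    for j, ch in enumerate(core[n_left:]):
        out[max_len - (L - n_left) + j] = emb[ch]
    return out.ravel()


class CDR3Encoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping :func:`encode_cdr3`.

    Parameters
    ----------
    max_len : maximum (trimmed) CDR3 length; 22 covers conventional TCRbeta
        junctions.
    trim : residues removed from each end before alignment (0 for the
        classifier; terminal trimming is the motif module's concern).
    n_components : dimensionality of the per-residue BLOSUM62 embedding.
    """

    def __init__(self, max_len: int = 22, trim: int = 0, n_components: int = 8):
        self.max_len = max_len
        self.trim = trim
        self.n_components = n_components

    def fit(self, X, y=None):
        self.n_features_out_ = self.max_len * self.n_components
        return self

    def transform(self, X) -> np.ndarray:
        return np.array(
            [encode_cdr3(s, self.max_len, self.trim, self.n_components) for s in X]
        )
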