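"""Identity-by-descent relationship matrices for the 36 genotype classes.

The expected proportion of alleles shared IBD between two genotype
classes u and v is counted per parent (homologs of different parents
are never IBD in an outcross F1):

    share(u, v) = (|u.p1 ∩ v.p1| + |u.p2 ∩ v.p2|) / 4

collected into the 36 x 36 matrix Π.  At a locus q with conditional
class probabilities Z_q (n x 36), the locus relationship matrix is
G_q = Z_q Π Z_q', and the genomic relationship matrix K_g is the
unweighted average of G_q over every grid position of the map.
"""

from __future__ import annotations

import numpy as np

from .core import N_CLASSES, GenotypeProbabilities, class_pairs
from .hmm_probs import GenotypeClass


def ibd_share(u: GenotypeClass, v: GenotypeClass) -> float:
    """Expected proportion of alleles shared IBD between two classes."""
    s1 = len(set(u.p1_pair) & set(v.p1_pair))
    s2 = len(set(u.p2_pair) & set(v.p2_pair))
    return (s1 + s2) / 4.0


def build_pi() -> np.ndarray:
    """The 36 x 36 Π matrix of pairwise expected IBD sharing."""
    pi = np.empty((N_CLASSES, N_CLASSES))
    classes = [GenotypeClass(*class_pairs(k)) for k in range(N_CLASSES)]
    for i, u in enumerate(classes):
        for j, v in enumerate(classes):
            pi[i, j] = ibd_share(u, v)
    return pi

_PI = build_pi()


def locus_G(Z: np.ndarray, pi: np.ndarray | None = None) -> np.ndarray:
    """Locus relationship matrix G_q = Z Π Z' from class probabilities.

    Rows of ``Z`` (n x 36) must each sum to 1 (tolerance 1e-6).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != N_CLASSES:
        raise ValueError("Z must be n x 36")
    if not np.allclose(Z.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of Z must sum to 1")
    pi = _PI if pi is None else pi
    G = Z @ pi @ Z.T
    return 0.5 * (G + G.T)


def map_average_K(probs: GenotypeProbabilities) -> np.ndarray:
    """Genomic relationship matrix: mean of G_q over all grid positions.

    Positions are weighted equally regardless of linkage-group length.
    """
    if probs.n_positions == 0:
        raise ValueError("empty probability grid")
    n = probs.n
    K = np.zeros((n, n))
    for t in range(probs.n_positions):
        K += locus_G(probs.at(t))
    return K / probs.n_positions


def is_psd(mat: np.ndarray, tol: float = 1e-8) -> bool:
    """Check symmetric positive semidefiniteness (eigenvalues >= -tol)."""
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        return False
    return bool(np.linalg.eigvalsh(mat).min() >= -tol * max(1.0, np.abs(mat).max()))
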