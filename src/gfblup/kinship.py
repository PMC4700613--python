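"""Relationship matrices: genomic (whole-panel and feature-partitioned)
and pedigree-based.

The genomic relationship matrix follows the centered/scaled allele-count
construction G = WW'/m, with column i of W equal to
(m_i - 2 p_i) / sqrt(2 p_i (1 - p_i)) where p_i is the frequency of the
counted (minor) allele.  Feature matrices G_f and the complementary G_r
restrict W to a marker subset, so that m_f G_f + m_r G_r = m G exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .io_qc import MISSING, GenotypeMatrix

__all__ = [
    "ScaledGenotypes",
    "RelationshipMatrix",
    "center_scale",
    "build_grm",
    "pedigree_amatrix",
    "pseudo_inverse",
]


@dataclass
class ScaledGenotypes:
    """Centered and scaled genotypes W with the frequencies used to scale.

    The frequencies are frozen at construction so that feature submatrices
    reuse identical scaling.  Missing calls contribute 0 to W (mean
    imputation of the count to ``2 p_i``).
    """

    W: np.ndarray
    freqs: np.ndarray
    markers: np.ndarray
    samples: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    @property
    def n_markers(self) -> int:
        return self.W.shape[1]


@dataclass
class RelationshipMatrix:
    """A symmetric PSD covariance structure among individuals."""

    values: np.ndarray
    labels: np.ndarray
    n_markers: int = 0
    kind: str = "genomic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if len(self.labels) != n:
            raise ValueError("label length does not match matrix size")
        if len(set(self.labels)) != n:
            raise ValueError("duplicated labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def center_scale(g: GenotypeMatrix) -> ScaledGenotypes:
    """Center and scale allele counts: w_i = (m_i - 2 p_i)/sqrt(2 p_i (1-p_i)).

    ``p_i`` is the empirical frequency of the counted allele among
    non-missing calls.  Monomorphic markers (p in {0, 1}) make the scale
    factor zero and are rejected; run QC first.
    """
    p = g.allele_freq()
    mono = (p <= 0.0) | (p >= 1.0) | ~np.isfinite(p)
    if mono.any():
        bad = g.markers[np.flatnonzero(mono)[:5]]
        raise ZeroDivisionError(
            f"monomorphic marker(s) cannot be scaled (p in {{0,1}}): {list(bad)}"
        )
    counts = g.counts.astype(float)
    counts[g.counts == MISSING] = np.nan
    W = (counts - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    W = np.nan_to_num(W, nan=0.0)
    return ScaledGenotypes(W=W, freqs=p, markers=g.markers, samples=g.samples)


def build_grm(w: ScaledGenotypes, subset=None) -> RelationshipMatrix:
    """Genomic relationship matrix G = W_s W_s'/|s| over a marker subset.

    With ``subset`` absent the whole panel is used.  An empty subset is an
    error: a feature with no markers cannot define a relationship matrix.
    """
    if subset is None:
        Ws = w.W
        m = w.n_markers
    else:
        idx = np.asarray(sorted(subset), dtype=int)
        if idx.size == 0:
            raise ValueError("empty marker subset cannot define a GRM")
        if idx.min() < 0 or idx.max() >= w.n_markers:
            raise IndexError("marker subset out of range")
        Ws = w.W[:, idx]
        m = idx.size
    values = (Ws @ Ws.T) / m
    return RelationshipMatrix(values=values, labels=w.samples, n_markers=m, kind="genomic")


def pedigree_amatrix(pedigree) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    ``pedigree`` is an iterable of ``(id, sire, dam)`` with ``None`` for
    unknown parents.  Rows may arrive in any order; they are sorted so
    parents precede offspring, and a cycle raises an error.  The diagonal
    is ``1 + F`` with ``F`` the inbreeding coefficient.
    """
    entries = [(str(i), None if s is None else str(s), None if d is None else str(d))
               for i, s, d in pedigree]
    ids = [e[0] for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated ids in pedigree")
    parents = {i: (s, d) for i, s, d in entries}
    for i, (s, d) in parents.items():
        for par in (s, d):
            if par is not None and par not in parents:
                raise ValueError(f"parent {par!r} of {i!r} has no pedigree row")

    # topological sort (Kahn); leftover nodes indicate a cycle
    order: list[str] = []
    placed: set[str] = set()
    remaining = dict(parents)
    while remaining:
        ready = [i for i, (s, d) in remaining.items()
                 if (s is None or s in placed) and (d is None or d in placed)]
        if not ready:
            raise ValueError("cyclic pedigree: an animal is its own ancestor")
        for i in ready:
            order.append(i)
            placed.add(i)
            del remaining[i]

    pos = {i: k for k, i in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        s, d = parents[i]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        f = 0.0 if si is None or di is None else 0.5 * A[si, di]
        A[k, k] = 1.0 + f
        for j in range(k):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[k, j] = A[j, k] = a

    # restore input order
    perm = np.array([pos[i] for i in ids])
    A = A[np.ix_(perm, perm)]
    return RelationshipMatrix(values=A, labels=np.array(ids, dtype=object),
                              n_markers=0, kind="pedigree")


def pseudo_inverse(r, rel_tol: float = 1e-8) -> np.ndarray:
    """Generalized (Moore-Penrose) inverse of a symmetric matrix.

    Eigenvalues below ``rel_tol`` times the largest eigenvalue are treated
    as zero; relationship matrices are rank deficient by centering (and
    whenever markers are fewer than individuals), so a plain inverse does
    not exist in general.
    """
    M = r.values if isinstance(r, RelationshipMatrix) else np.asarray(r, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("pseudo_inverse expects a symmetric matrix")
    d, U = sla.eigh(M)
    cutoff = rel_tol * np.abs(d).max() if d.size else 0.0
    keep = np.abs(d) > cutoff
    if not keep.any():
        raise np.linalg.LinAlgError("matrix has no eigenvalue above tolerance (rank 0)")
    dinv = np.where(keep, 1.0 / np.where(keep, d, 1.0), 0.0)
    return (U * dinv) @ U.T
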