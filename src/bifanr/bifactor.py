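"""Bi-factor analysis: eigenvalue null, varimax rotation, sector assignment.

The reduced coupling matrix is eigendecomposed; the number of
non-random factors t is set by a column-shuffle null: every column of
the alignment (restricted to the kept sites) is permuted independently
across sequences, the full weighting pipeline is recomputed, and all n
eigenvalues are pooled over ``n_shuffles`` shuffles into the set E.
With N(i) the number of elements of E strictly greater than the i-th
real eigenvalue, t is the largest index with N(t) < n_shuffles.

The first t eigenvectors are varimax-rotated and sites are assigned to
sectors bidirectionally: for each factor and each sign, coefficients
p(i) are compared against the mean w of the top 50 %, and a site enters
the candidate sector when (p(i)/w >= r0 and p(i) > p0) or p(i) >= p1.
Overlapping candidates are merged greedily around their intersection.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .covariance import _position_coupling, conservation_weights
from .msa_io import Alignment, frequencies_from_matrix


def eigendecompose(W_reduced: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and orthonormal eigenvectors of a
    symmetric matrix; each eigenvector's largest-magnitude entry is
    made positive so downstream sign handling is reproducible."""
    W = np.asarray(W_reduced, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("eigendecompose requires a symmetric square matrix")
    if not np.isfinite(W).all():
        raise ValueError("matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh(W)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vals, vecs


def null_eigenvalues(
    al: Alignment,
    kept,
    n_shuffles: int = 100,
    seed=None,
    denominator: str = "all",
    background=None,
    eps: float | None = None,
    reuse_weights: bool = True,
) -> np.ndarray:
    """Pooled eigenvalue null from independently column-shuffled alignments.

    Each shuffle permutes every kept column independently across
    sequences and recomputes the covariance -> weight -> reduce pipeline
    on the kept sites; all n eigenvalues per shuffle are pooled, so the
    result has ``n_shuffles * len(kept)`` entries.

    ``reuse_weights=True`` exploits that single-site frequencies and the
    background are invariant under within-column permutation, so the
    conservation weights are computed once; ``False`` recomputes them
    per shuffle (equivalent, used as a cross-check).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    kept = list(kept)
    sub = al.matrix[:, kept]
    rng = np.random.default_rng(seed)

    fm0 = frequencies_from_matrix(sub, denominator=denominator, background=background)
    phi0 = conservation_weights(fm0, eps).ravel()
    f1_0 = fm0.f1.ravel()

    out = []
    for _ in range(n_shuffles):
        shuf = rng.permuted(sub, axis=0)
        fm = frequencies_from_matrix(shuf, denominator=denominator, background=background)
        if reuse_weights:
            W = _position_coupling(fm.f2_flat, f1_0, phi0)
        else:
            phi = conservation_weights(fm, eps).ravel()
            W = _position_coupling(fm.f2_flat, fm.f1.ravel(), phi)
        out.append(np.linalg.eigvalsh(W))
    return np.concatenate(out)


def select_factors(eigenvalues: np.ndarray, E: np.ndarray, threshold: int = 100) -> tuple[int, np.ndarray]:
    """Number of non-random factors under the pooled null.

    Returns ``(t, N)`` where ``N[i]`` counts null eigenvalues strictly
    greater than ``eigenvalues[i]`` and t is the largest (1-based) index
    with ``N < threshold`` (0 when even the top eigenvalue fails).
    """
    eigenvalues = np.asarray(eigenvalues, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    if E.size == 0:
        raise ValueError("null eigenvalue set E is empty")
    Es = np.sort(E)
    N = E.size - np.searchsorted(Es, eigenvalues, side="right")
    t = int(np.sum(N < threshold))  # N is non-decreasing for descending eigenvalues
    return t, N


def varimax_criterion(B: np.ndarray) -> float:
    """Varimax simplicity: sum_k [ mean_i b_ik^4 - (mean_i b_ik^2)^2 ]."""
    B2 = np.asarray(B) ** 2
    return float(np.sum((B2 ** 2).mean(axis=0) - B2.mean(axis=0) ** 2))


def varimax_rotate(
    V: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    kaiser: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax-rotate loading columns; returns ``(loadings, rotation)``.

    The rotation R is orthogonal and ``loadings = V @ R`` maximizes the
    varimax criterion; iteration stops when the criterion gain drops
    below ``tol``. ``kaiser=True`` row-normalizes by communality before
    computing the rotation (the rotation is still applied to the raw
    loadings, so communalities are preserved either way).
    """
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2 or V.shape[1] < 1:
        raise ValueError("V must be an (n, t) loading matrix with t >= 1")
    n, t = V.shape
    if t == 1:
        R = np.eye(1)
        B = V.copy()
        j = np.argmax(np.abs(B[:, 0]))
        if B[j, 0] < 0:
            B = -B
            R = -R
        return B, R

    A = V.copy()
    if kaiser:
        h = np.sqrt((A ** 2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]

    R = np.eye(t)
    crit = varimax_criterion(A @ R)
    for _ in range(max_iter):
        Lr = A @ R
        G = A.T @ (Lr ** 3 - Lr * ((Lr ** 2).sum(axis=0) / n)[None, :])
        if np.allclose(G, 0.0, atol=1e-15):
            break
        U, _, Vt = np.linalg.svd(G)
        R_new = U @ Vt
        new_crit = varimax_criterion(A @ R_new)
        gain = new_crit - crit
        R = R_new
        crit = new_crit
        if gain < tol:
            break

    B = V @ R
    for k in range(t):
        j = np.argmax(np.abs(B[:, k]))
        if B[j, k] < 0:
            B[:, k] = -B[:, k]
            R[:, k] = -R[:, k]
    return B, R


@dataclasses.dataclass
class FactorModel:
    """Spectrum, shuffle null, and rotated loadings of the reduced matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    null_eigenvalues: np.ndarray
    N: np.ndarray
    t: int
    loadings: np.ndarray | None = None
    rotation: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class Sector:
    """A candidate or final protein sector over kept-site indices."""

    sites: tuple[int, ...]
    source_factor: int
    sign: str
    merged_from: tuple | None = None

    @property
    def size(self) -> int:
        return len(self.sites)

    def to_dict(self) -> dict:
        d = {
            "sites": list(self.sites),
            "source_factor": self.source_factor,
            "sign": self.sign,
        }
        if self.merged_from is not None:
            d["merged_from"] = [p.to_dict() for p in self.merged_from]
        return d


@dataclasses.dataclass
class SectorSet:
    """A list of sectors together with the thresholds that produced them."""

    sectors: list[Sector]
    r0: float = 0.8
    p0: float = 0.1
    p1: float = 0.4

    def __iter__(self):
        return iter(self.sectors)

    def __len__(self) -> int:
        return len(self.sectors)

    @property
    def site_lists(self) -> list[tuple[int, ...]]:
        return [s.sites for s in self.sectors]

    def to_dict(self) -> dict:
        return {
            "thresholds": {"r0": self.r0, "p0": self.p0, "p1": self.p1},
            "sectors": [s.to_dict() for s in self.sectors],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def assign_sites(
    loadings: np.ndarray,
    r0: float = 0.8,
    p0: float = 0.1,
    p1: float = 0.4,
    min_size: int = 2,
) -> SectorSet:
    """Bidirectional threshold selection of sites for each rotated factor.

    For factor k and sign s, with p(i) = s * b_ik sorted descending and
    w the mean of the top ``ceil(n/2)`` values, site i joins the
    candidate sector when ``(p(i)/w >= r0 and p(i) > p0) or p(i) >= p1``.
    A sign pass with w <= 0 yields no sector; candidates smaller than
    ``min_size`` are discarded (a one-site sector carries no
    coevolution meaning).
    """
    B = np.asarray(loadings, dtype=np.float64)
    n, t = B.shape
    top = math.ceil(n / 2)
    sectors: list[Sector] = []
    for k in range(t):
        for sign, label in ((1.0, "+"), (-1.0, "-")):
            p = sign * B[:, k]
            w = float(np.sort(p)[::-1][:top].mean())
            if w <= 0:
                continue
            r = p / w
            mask = ((r >= r0) & (p > p0)) | (p >= p1)
            sites = tuple(int(i) for i in np.nonzero(mask)[0])
            if len(sites) >= min_size:
                sectors.append(Sector(sites=sites, source_factor=k, sign=label))
    return SectorSet(sectors=sectors, r0=r0, p0=p0, p1=p1)


def _merge_pair(A: Sector, B: Sector, W: np.ndarray) -> Sector:
    a, b = set(A.sites), set(B.sites)
    ssame = a & b
    sdiff = a ^ b
    target = min(len(a), len(b))
    while len(ssame) < target:
        idx = sorted(ssame)
        # ties in the coupling sum break toward the lowest column index
        best = min(sdiff, key=lambda d: (-float(W[d, idx].sum()), d))
        sdiff.remove(best)
        ssame.add(best)
    return Sector(
        sites=tuple(sorted(ssame)),
        source_factor=A.source_factor,
        sign=A.sign,
        merged_from=(A, B),
    )


def merge_sectors(sector_set: SectorSet, W_reduced: np.ndarray) -> SectorSet:
    """Merge overlapping sectors until all are pairwise disjoint.

    Each overlapping pair is replaced by the greedy growth of its
    intersection: the symmetric-difference site with the largest summed
    coupling to the intersection is absorbed until the merged sector
    reaches the size of the smaller parent.
    """
    W = np.asarray(W_reduced, dtype=np.float64)
    sectors = list(sector_set.sectors)
    while True:
        hit = None
        for i in range(len(sectors)):
            for j in range(i + 1, len(sectors)):
                if set(sectors[i].sites) & set(sectors[j].sites):
                    hit = (i, j)
                    break
            if hit:
                break
        if hit is None:
            break
        i, j = hit
        merged = _merge_pair(sectors[i], sectors[j], W)
        sectors[i] = merged
        del sectors[j]
    return SectorSet(sectors=sectors, r0=sector_set.r0, p0=sector_set.p0, p1=sector_set.p1)
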