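"""Weighted position-coupling matrix and noise-site reduction.

The coupling statistic is the conservation-weighted covariance of
amino-acid occurrences. For columns i, j and amino acids a, b

    C_ij^ab   = f_ij^ab - f_i^a f_j^b
    phi_i^a   = ln[ f_i^a (1 - q^a) / ((1 - f_i^a) q^a) ]   (log-odds weight)
    W_ij      = sqrt( sum_ab (phi_i^a phi_j^b C_ij^ab)^2 )  (Frobenius reduction)

with the diagonal of W set to 0 (self-coupling carries no coevolution
signal). Frequencies entering the log-odds weight are clamped to
[eps, 1-eps], eps = 1/(2S), so conserved columns never produce infinite
weights; the same clamp is applied to the background q.

Noise sites are columns weakly coupled to almost all others: Rmax(i) is
the mean of the top ``ceil(top_fraction*(L-1))`` off-diagonal couplings
of site i, ``plus`` the mean of Rmax over sites, and any site with
Rmax(i) <= factor*plus (defaults 5 % and 0.8) is removed before factor
analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd

from .msa_io import N_AA, FrequencyModel


class NoSignalError(RuntimeError):
    """Noise reduction removed every site: no coevolution signal."""


@dataclasses.dataclass
class CouplingMatrices:
    """Covariance tensor C, weight grid phi, and reduced coupling W."""

    C: np.ndarray | None = None     # (L, 20, L, 20)
    W: np.ndarray | None = None     # (L, L)
    phi: np.ndarray | None = None   # (L, 20)


def conservation_weights(fm: FrequencyModel, eps: float | None = None) -> np.ndarray:
    """Log-odds conservation weight phi_i^a, regularized by clamping."""
    if eps is None:
        eps = 1.0 / (2 * fm.n_sequences)
    f = np.clip(fm.f1, eps, 1.0 - eps)
    q = np.clip(fm.q, eps, 1.0 - eps)
    return np.log(f * (1.0 - q)[None, :] / ((1.0 - f) * q[None, :]))


def covariance_tensor(fm: FrequencyModel) -> CouplingMatrices:
    """Raw covariance tensor C_ij^ab = f_ij^ab - f_i^a f_j^b."""
    C = fm.f2 - np.einsum("ia,jb->iajb", fm.f1, fm.f1)
    return CouplingMatrices(C=C)


def _position_coupling(f2_flat: np.ndarray, f1_flat: np.ndarray, phi_flat: np.ndarray) -> np.ndarray:
    """Weighted coupling W from flat frequency arrays (shared fast path)."""
    L = f1_flat.size // N_AA
    C = f2_flat - np.outer(f1_flat, f1_flat)
    C *= phi_flat[:, None]
    C *= phi_flat[None, :]
    np.square(C, out=C)
    W = np.sqrt(C.reshape(L, N_AA, L, N_AA).sum(axis=(1, 3)))
    np.fill_diagonal(W, 0.0)
    return W


def weight_and_reduce(cm: CouplingMatrices, fm: FrequencyModel, eps: float | None = None) -> CouplingMatrices:
    """Apply conservation weights and reduce over amino-acid dimensions.

    Fills ``phi`` and ``W`` of the coupling matrices; ``C`` is kept as
    the unweighted covariance tensor.
    """
    if cm.C is None:
        raise ValueError("covariance tensor C must be computed first")
    phi = conservation_weights(fm, eps)
    L = fm.n_columns
    Cw = cm.C.reshape(L * N_AA, L * N_AA).copy()
    P = phi.ravel()
    Cw *= P[:, None]
    Cw *= P[None, :]
    np.square(Cw, out=Cw)
    W = np.sqrt(Cw.reshape(L, N_AA, L, N_AA).sum(axis=(1, 3)))
    np.fill_diagonal(W, 0.0)
    return CouplingMatrices(C=cm.C, W=W, phi=phi)


def coupling_matrix(fm: FrequencyModel, eps: float | None = None) -> CouplingMatrices:
    """Convenience: covariance tensor + weighting + reduction in one call."""
    return weight_and_reduce(covariance_tensor(fm), fm, eps)


@dataclasses.dataclass
class NoiseReductionResult:
    """Outcome of the Rmax noise filter."""

    rmax: np.ndarray
    plus: float
    kept: list[int]
    removed: list[int]
    W_reduced: np.ndarray
    top_fraction: float = 0.05
    factor: float = 0.8

    def to_dict(self) -> dict:
        return {
            "plus": float(self.plus),
            "top_fraction": float(self.top_fraction),
            "factor": float(self.factor),
            "rmax": [float(x) for x in self.rmax],
            "kept": [int(i) for i in self.kept],
            "removed": [int(i) for i in self.removed],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def noise_filter(W: np.ndarray, top_fraction: float = 0.05, factor: float = 0.8) -> NoiseReductionResult:
    """Remove noise sites from the coupling matrix.

    Raises
    ------
    ValueError
        If W is not a symmetric matrix with at least two sites, or
        ``top_fraction`` is outside (0, 1].
    NoSignalError
        If every site falls at or below the ``factor * plus`` threshold.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    L = W.shape[0]
    if L < 2:
        raise ValueError("need at least 2 sites for noise filtering")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("W must be symmetric")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")

    k = max(1, math.ceil(top_fraction * (L - 1)))
    off = W[~np.eye(L, dtype=bool)].reshape(L, L - 1)
    # mean of the k largest neighbors of each site
    top = np.partition(off, L - 1 - k, axis=1)[:, L - 1 - k:]
    rmax = top.mean(axis=1)
    plus = float(rmax.mean())
    removed = np.nonzero(rmax <= factor * plus)[0]
    kept = np.nonzero(rmax > factor * plus)[0]
    if kept.size == 0:
        raise NoSignalError("noise reduction removed all sites (no coevolution signal)")
    W_reduced = W[np.ix_(kept, kept)]
    return NoiseReductionResult(
        rmax=rmax,
        plus=plus,
        kept=[int(i) for i in kept],
        removed=[int(i) for i in removed],
        W_reduced=W_reduced,
        top_fraction=top_fraction,
        factor=factor,
    )


def write_coupling_tsv(W: np.ndarray, labels: list[str], path) -> None:
    """Write a square coupling matrix as TSV with residue-label headers."""
    pd.DataFrame(W, index=labels, columns=labels).to_csv(path, sep="\t", float_format="%.10g")
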