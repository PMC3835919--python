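"""Statistical and evolutionary checks for predicted protein sectors.

Covers: internal-correlation tests against equal-size random site sets,
MDI-entropy statistical independence (generalized iterative scaling),
evolutionary-rate summaries from Rate4Site output, PCA-based
evolutionary independence, and sensitivity/PPV against reference
sector definitions.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings

import numpy as np
import pandas as pd

from .bifactor import SectorSet
from .msa_io import Alignment


# ---------------------------------------------------------------------------
# internal correlation

@dataclasses.dataclass
class InternalCorrelation:
    """Mean pairwise coupling of a sector vs equal-size random site sets."""

    observed: float
    random_mean: float
    random_sd: float
    p_value: float
    n_random: int
    sector_size: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _mean_pairwise(W: np.ndarray, sites) -> float:
    idx = np.asarray(sorted(sites), dtype=int)
    sub = W[np.ix_(idx, idx)]
    n = idx.size
    return float(sub.sum() / (n * (n - 1)))


def internal_correlation(
    W: np.ndarray,
    sector,
    n_random: int = 1000,
    seed=None,
) -> InternalCorrelation:
    """Observed mean off-diagonal coupling of ``sector`` against the
    distribution over ``n_random`` random site sets of the same size
    drawn from all analyzed sites (the rows of W)."""
    W = np.asarray(W, dtype=np.float64)
    L = W.shape[0]
    sector = sorted(set(int(i) for i in sector))
    if len(sector) < 2:
        raise ValueError("sector must contain at least 2 sites")
    if len(sector) > L:
        raise ValueError("sector larger than the analyzed site pool")
    if n_random < 1:
        raise ValueError("n_random must be >= 1 (baseline undefined otherwise)")
    rng = np.random.default_rng(seed)
    observed = _mean_pairwise(W, sector)
    draws = np.empty(n_random)
    for r in range(n_random):
        draws[r] = _mean_pairwise(W, rng.choice(L, size=len(sector), replace=False))
    return InternalCorrelation(
        observed=observed,
        random_mean=float(draws.mean()),
        random_sd=float(draws.std(ddof=1)) if n_random > 1 else 0.0,
        p_value=float(np.mean(draws >= observed)),
        n_random=n_random,
        sector_size=len(sector),
    )


# ---------------------------------------------------------------------------
# MDI entropy via generalized iterative scaling

class MDIEntropy(float):
    """MDI entropy value (nats) carrying GIS convergence diagnostics."""

    converged: bool
    marginal_gap: float
    n_iter: int
    support: str

    def __new__(cls, value, converged=True, marginal_gap=0.0, n_iter=0, support="product"):
        obj = super().__new__(cls, value)
        obj.converged = converged
        obj.marginal_gap = marginal_gap
        obj.n_iter = n_iter
        obj.support = support
        return obj


def mdi_entropy(
    al: Alignment,
    sites,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> MDIEntropy:
    """Minimal-discriminant-information entropy of a group of columns.

    The Kullback-Leibler divergence (nats) between the empirical joint
    distribution of the selected columns and the closest maximum-entropy
    distribution with the same single-site marginals, fitted by
    generalized iterative scaling. Gap characters count as a state of
    their own; per-column alphabets are restricted to the states
    actually observed (unobserved states have zero marginal and carry no
    probability). A single site gives exactly 0.

    Because the constraints are single-site marginals, the
    maximum-entropy model factorizes over columns, so the scaling
    updates act on per-column factors and the joint state space is
    never enumerated: groups of any size are handled exactly.
    Non-convergence is flagged on the returned value (``converged``,
    ``marginal_gap``) rather than raised.
    """
    sites = sorted(set(int(i) for i in sites))
    if len(sites) < 1:
        raise ValueError("need at least one site")
    if len(sites) == 1:
        return MDIEntropy(0.0, converged=True, n_iter=0, support="product")

    cols = al.matrix[:, sites]
    S, m = cols.shape

    # recode each column to 0..k_i-1 over its observed states
    coded = np.empty_like(cols, dtype=np.int64)
    ks = []
    for i in range(m):
        _, inv = np.unique(cols[:, i], return_inverse=True)
        coded[:, i] = inv
        ks.append(int(inv.max()) + 1)

    patterns, counts = np.unique(coded, axis=0, return_counts=True)
    p_emp = counts / S
    marginals = [np.bincount(coded[:, i], minlength=ks[i]) / S for i in range(m)]

    # GIS in factor form: the model is q(x) = prod_i mu_i(x_i) and its
    # column-i marginal is mu_i itself, so each scaling step replaces
    # mu_i by the empirical marginal at full strength (per-column state
    # indicators are mutually exclusive features).
    logmu = [np.full(k, -math.log(k)) for k in ks]
    converged = False
    gap = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        gap = max(
            float(np.abs(np.exp(logmu[i]) - marginals[i]).max()) for i in range(m)
        )
        if gap < tol:
            converged = True
            break
        logmu = [np.log(marginals[i]) for i in range(m)]

    logq_at = np.zeros(patterns.shape[0])
    for i in range(m):
        logq_at += logmu[i][patterns[:, i]]
    mdi = float(np.sum(p_emp * (np.log(p_emp) - logq_at)))
    return MDIEntropy(max(mdi, 0.0), converged=converged, marginal_gap=gap,
                      n_iter=it, support="product")


@dataclasses.dataclass
class IndependenceTest:
    """Additivity of MDI entropy over two disjoint sector site sets."""

    mdi_a: float
    mdi_b: float
    mdi_joint: float
    random_mean: float
    random_sd: float
    n_random: int

    @property
    def mdi_sum(self) -> float:
        return self.mdi_a + self.mdi_b

    @property
    def additivity_gap(self) -> float:
        return self.mdi_joint - self.mdi_sum

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mdi_sum"] = self.mdi_sum
        d["additivity_gap"] = self.additivity_gap
        return d


def independence_test(
    al: Alignment,
    sector_a,
    sector_b,
    n_random: int = 100,
    seed=None,
    **mdi_kwargs,
) -> IndependenceTest:
    """Compare MDI(A) + MDI(B) with MDI(A u B).

    Statistical independence of the sectors is supported when the joint
    MDI entropy matches the sum of the individual ones and exceeds the
    random expectation, computed as the mean of MDI(A') + MDI(B') over
    random re-splits of A u B into groups of the original sizes.
    """
    a = sorted(set(int(i) for i in sector_a))
    b = sorted(set(int(i) for i in sector_b))
    if set(a) & set(b):
        raise ValueError("sectors must be disjoint")
    mdi_a = float(mdi_entropy(al, a, **mdi_kwargs)) if a else 0.0
    mdi_b = float(mdi_entropy(al, b, **mdi_kwargs)) if b else 0.0
    mdi_joint = float(mdi_entropy(al, a + b, **mdi_kwargs))

    rng = np.random.default_rng(seed)
    union = np.array(a + b)
    draws = []
    for _ in range(n_random):
        perm = rng.permutation(union)
        ga, gb = perm[: len(a)], perm[len(a):]
        va = float(mdi_entropy(al, ga, **mdi_kwargs)) if ga.size else 0.0
        vb = float(mdi_entropy(al, gb, **mdi_kwargs)) if gb.size else 0.0
        draws.append(va + vb)
    draws = np.asarray(draws) if draws else np.array([np.nan])
    return IndependenceTest(
        mdi_a=mdi_a,
        mdi_b=mdi_b,
        mdi_joint=mdi_joint,
        random_mean=float(np.nanmean(draws)),
        random_sd=float(np.nanstd(draws, ddof=1)) if len(draws) > 1 else 0.0,
        n_random=n_random,
    )


# ---------------------------------------------------------------------------
# Rate4Site

class MappingError(ValueError):
    """Sector sites could not be reconciled with rate positions."""


def read_rate4site(path, strict: bool = False) -> pd.DataFrame:
    """Parse a Rate4Site plain-text output file.

    Returns a DataFrame with columns ``pos`` (int), ``aa`` (str) and
    ``score`` (float, the normalized evolutionary rate). Comment lines
    (``#``) and blanks are skipped; other unparsable lines are skipped
    leniently unless ``strict=True``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            try:
                pos = int(parts[0])
                aa = parts[1]
                score = float(parts[2])
            except (IndexError, ValueError):
                if strict:
                    raise ValueError(f"unparsable Rate4Site line {lineno}: {text!r}")
                continue
            rows.append((pos, aa, score))
    if not rows:
        raise ValueError("no rate records found")
    return pd.DataFrame(rows, columns=["pos", "aa", "score"])


@dataclasses.dataclass
class RateSummary:
    """Per-sector and overall normalized evolutionary-rate summaries."""

    sector_mean: list[float]
    sector_fraction_negative: list[float]
    overall_mean: float
    overall_fraction_negative: float
    pooled_sector_fraction_negative: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def rate_summary(rates: pd.DataFrame, sectors, column_map=None) -> RateSummary:
    """Summarize Rate4Site rates over predicted sectors.

    ``sectors`` is a :class:`~bifanr.bifactor.SectorSet` or a list of
    site collections (alignment column indices). ``column_map`` maps a
    column index to the residue number used in the rate file; by
    default column i maps to position i+1. Columns with no matching
    rate position raise :class:`MappingError` listing the offenders.
    """
    if isinstance(sectors, SectorSet):
        site_lists = sectors.site_lists
    else:
        site_lists = [tuple(s) for s in sectors]
    by_pos = dict(zip(rates["pos"].astype(int), rates["score"].astype(float)))

    def pos_of(col: int) -> int:
        if column_map is None:
            return col + 1
        return int(column_map[col])

    sector_mean, sector_neg = [], []
    pooled: list[float] = []
    for sites in site_lists:
        missing = [c for c in sites if c not in (column_map or {})] if column_map is not None else []
        if missing:
            raise MappingError(f"sector columns without residue mapping: {sorted(missing)}")
        unmatched = [c for c in sites if pos_of(c) not in by_pos]
        if unmatched:
            raise MappingError(
                "sector columns with no rate entry: "
                + ", ".join(f"{c}->{pos_of(c)}" for c in sorted(unmatched))
            )
        vals = np.array([by_pos[pos_of(c)] for c in sites])
        sector_mean.append(float(vals.mean()))
        sector_neg.append(float((vals < 0).mean()))
        pooled.extend(vals.tolist())
    scores = rates["score"].to_numpy()
    pooled_arr = np.asarray(pooled) if pooled else np.array([np.nan])
    return RateSummary(
        sector_mean=sector_mean,
        sector_fraction_negative=sector_neg,
        overall_mean=float(scores.mean()),
        overall_fraction_negative=float((scores < 0).mean()),
        pooled_sector_fraction_negative=float((pooled_arr < 0).mean()),
    )


# ---------------------------------------------------------------------------
# evolutionary independence (PCA split)

@dataclasses.dataclass
class PCASplit:
    """First-principal-component split of sequences over a sector."""

    coordinates: np.ndarray
    labels: np.ndarray
    explained_ratio: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "coordinates": [float(x) for x in self.coordinates],
            "labels": [int(x) for x in self.labels],
            "explained_ratio": float(self.explained_ratio),
            "degenerate": bool(self.degenerate),
        }


def evolutionary_independence(al: Alignment, sector) -> PCASplit:
    """Split sequences in two by PC1 of their sector-restricted similarity.

    The S x S matrix M holds the pairwise fraction of identical residues
    over the sector's columns (gaps always mismatch); sequences are
    separated by the sign of their first-principal-component coordinate
    (threshold 0 after column-centering M).
    """
    sites = sorted(set(int(i) for i in sector))
    if len(sites) < 2:
        raise ValueError("sector must contain at least 2 sites")
    if al.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    sub = al.matrix[:, sites]
    eq = (sub[:, None, :] == sub[None, :, :]) & (sub[:, None, :] > 0)
    M = eq.mean(axis=2)

    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    total = float((s ** 2).sum())
    if total <= 1e-12 or s[0] <= 1e-12:
        warnings.warn("similarity matrix is degenerate; returning a single group", stacklevel=2)
        return PCASplit(
            coordinates=np.zeros(al.n_sequences),
            labels=np.zeros(al.n_sequences, dtype=int),
            explained_ratio=0.0,
            degenerate=True,
        )
    degenerate = False
    if s.size > 1 and (s[0] - s[1]) <= 1e-9 * s[0]:
        # tied top singular values: PC1 direction is not unique
        warnings.warn("first principal component is degenerate (tied spectrum)", stacklevel=2)
        degenerate = True
    v1 = Vt[0]
    j = np.argmax(np.abs(v1))
    if v1[j] < 0:
        v1 = -v1
    coords = Mc @ v1
    labels = (coords >= 0).astype(int)
    return PCASplit(
        coordinates=coords,
        labels=labels,
        explained_ratio=float(s[0] ** 2 / total),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# sensitivity / PPV

@dataclasses.dataclass
class SectorMatch:
    """Best-match accuracy of one reference sector."""

    reference_index: int
    matched_sector: int | None
    overlap: int
    sensitivity: float
    ppv: float | None
    lost_sites: tuple[int, ...]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sensitivity_ppv(predicted, reference) -> list[SectorMatch]:
    """Sensitivity and PPV of predicted sectors against reference site sets.

    Each reference sector is matched to the single predicted sector
    containing most of its sites (ties toward the lower sector index).
    Sensitivity = |match n ref| / |ref| * 100 and PPV = |match n ref| /
    |matched predicted| * 100; with no predictions sensitivity is 0 and
    PPV is reported as undefined (None). Reference sites outside the
    matched sector are listed as lost.
    """
    if isinstance(predicted, SectorSet):
        pred_lists = [set(s) for s in predicted.site_lists]
    else:
        pred_lists = [set(s) for s in predicted]
    out = []
    for ri, ref in enumerate(reference):
        ref = set(int(i) for i in ref)
        if not ref:
            raise ValueError("empty reference sector")
        if not pred_lists:
            out.append(SectorMatch(ri, None, 0, 0.0, None, tuple(sorted(ref))))
            continue
        overlaps = [len(ref & p) for p in pred_lists]
        best = int(np.argmax(overlaps))
        inter = ref & pred_lists[best]
        out.append(
            SectorMatch(
                reference_index=ri,
                matched_sector=best,
                overlap=len(inter),
                sensitivity=100.0 * len(inter) / len(ref),
                ppv=100.0 * len(inter) / len(pred_lists[best]),
                lost_sites=tuple(sorted(ref - inter)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# report container

@dataclasses.dataclass
class EvaluationReport:
    """Bundle of every verification run for a set of predicted sectors."""

    internal: list[InternalCorrelation] = dataclasses.field(default_factory=list)
    independence: list[tuple[tuple[int, int], IndependenceTest]] = dataclasses.field(default_factory=list)
    pca: list[PCASplit] = dataclasses.field(default_factory=list)
    rates: RateSummary | None = None
    accuracy: list[SectorMatch] | None = None

    def to_dict(self) -> dict:
        return {
            "internal_correlation": [x.to_dict() for x in self.internal],
            "independence": [
                {"pair": list(pair), **test.to_dict()} for pair, test in self.independence
            ],
            "pca_split": [x.to_dict() for x in self.pca],
            "rates": self.rates.to_dict() if self.rates else None,
            "accuracy": [x.to_dict() for x in self.accuracy] if self.accuracy is not None else None,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = ["Sector evaluation report", "=" * 24]
        for i, ic in enumerate(self.internal):
            lines.append(
                f"sector {i}: mean coupling {ic.observed:.4f} "
                f"(random {ic.random_mean:.4f} +/- {ic.random_sd:.4f}, "
                f"p = {ic.p_value:.4g}, {ic.sector_size} sites)"
            )
        for (a, b), t in self.independence:
            lines.append(
                f"sectors {a}+{b}: MDI joint {t.mdi_joint:.4f} vs sum {t.mdi_sum:.4f} "
                f"(gap {t.additivity_gap:+.4f}; random split {t.random_mean:.4f})"
            )
        if self.rates is not None:
            lines.append(
                f"rates: sector means {['%.4f' % m for m in self.rates.sector_mean]}, "
                f"{100 * self.rates.pooled_sector_fraction_negative:.1f}% of sector sites negative"
            )
        if self.accuracy is not None:
            for m in self.accuracy:
                ppv = f"{m.ppv:.2f}%" if m.ppv is not None else "undefined"
                lines.append(
                    f"reference {m.reference_index}: sensitivity {m.sensitivity:.2f}%, PPV {ppv}"
                )
        return "\n".join(lines)
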