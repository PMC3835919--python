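"""Model/results interface over the full sector-detection pipeline.

`SectorModel` holds an alignment plus the analysis configuration;
`fit()` runs frequencies -> weighted coupling -> noise reduction ->
eigenvalue null -> factor selection -> varimax -> bidirectional site
assignment -> merging, and returns a `SectorResults` carrying every
intermediate together with `summary()`, a sector table, spectrum
plotting and the statistical evaluation suite.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import bifactor, covariance, evaluation, msa_io


class SectorModel:
    """Noise-reduced bi-factor model of coevolving sites in an MSA.

    Parameters
    ----------
    alignment : msa_io.Alignment
        Integer-encoded multiple sequence alignment.
    noise_top_fraction, noise_factor : float
        Rmax neighbor fraction (default 5 %) and removal factor
        (default 0.8) of the noise filter.
    n_shuffles : int
        Column-shuffle replicates for the eigenvalue null (default 100;
        the retention rule keeps eigenvalue i while fewer than
        ``n_shuffles`` pooled null eigenvalues exceed it).
    r0, p0, p1 : float
        Bidirectional selection thresholds on rotated coefficients.
    min_sector_size : int
        Candidate sectors smaller than this are discarded (default 2).
    kaiser : bool
        Kaiser-normalized varimax instead of raw varimax.
    freq_denominator : {"all", "nongap"}
        Frequency denominator convention.
    background : array-like of 20 floats, optional
        External background amino-acid frequencies (default: pooled
        counts of the input alignment).
    """

    def __init__(
        self,
        alignment: msa_io.Alignment,
        *,
        noise_top_fraction: float = 0.05,
        noise_factor: float = 0.8,
        n_shuffles: int = 100,
        r0: float = 0.8,
        p0: float = 0.1,
        p1: float = 0.4,
        min_sector_size: int = 2,
        kaiser: bool = False,
        freq_denominator: str = "all",
        background=None,
        weight_eps: float | None = None,
        varimax_tol: float = 1e-6,
        varimax_max_iter: int = 1000,
    ) -> None:
        self.alignment = alignment
        self.noise_top_fraction = noise_top_fraction
        self.noise_factor = noise_factor
        self.n_shuffles = n_shuffles
        self.r0 = r0
        self.p0 = p0
        self.p1 = p1
        self.min_sector_size = min_sector_size
        self.kaiser = kaiser
        self.freq_denominator = freq_denominator
        self.background = background
        self.weight_eps = weight_eps
        self.varimax_tol = varimax_tol
        self.varimax_max_iter = varimax_max_iter

    @classmethod
    def from_file(cls, path, format=None, template=None, numbering=None, **kwargs) -> "SectorModel":
        """Build the model from a FASTA/Clustal file.

        ``template`` (id or row index) attaches residue numbering;
        ``numbering`` is a TSV path overriding the default numbering.
        """
        al = msa_io.read_alignment(path, format=format)
        if template is not None:
            num = msa_io.read_numbering(numbering) if numbering is not None else None
            al = al.with_template(template, numbering=num)
        return cls(al, **kwargs)

    def params(self) -> dict:
        return {
            "noise_top_fraction": self.noise_top_fraction,
            "noise_factor": self.noise_factor,
            "n_shuffles": self.n_shuffles,
            "r0": self.r0,
            "p0": self.p0,
            "p1": self.p1,
            "min_sector_size": self.min_sector_size,
            "kaiser": self.kaiser,
            "freq_denominator": self.freq_denominator,
            "weight_eps": self.weight_eps,
            "varimax_tol": self.varimax_tol,
            "varimax_max_iter": self.varimax_max_iter,
        }

    def fit(self, seed=None) -> "SectorResults":
        """Run the full pipeline; reproducible for a fixed seed."""
        al = self.alignment
        fm = msa_io.frequencies(al, denominator=self.freq_denominator, background=self.background)
        cm = covariance.coupling_matrix(fm, eps=self.weight_eps)
        noise = covariance.noise_filter(cm.W, self.noise_top_fraction, self.noise_factor)
        eigenvalues, eigenvectors = bifactor.eigendecompose(noise.W_reduced)
        E = bifactor.null_eigenvalues(
            al,
            noise.kept,
            n_shuffles=self.n_shuffles,
            seed=seed,
            denominator=self.freq_denominator,
            background=self.background,
            eps=self.weight_eps,
        )
        t, N = bifactor.select_factors(eigenvalues, E, threshold=self.n_shuffles)
        loadings = rotation = None
        if t >= 1:
            loadings, rotation = bifactor.varimax_rotate(
                eigenvectors[:, :t],
                tol=self.varimax_tol,
                max_iter=self.varimax_max_iter,
                kaiser=self.kaiser,
            )
            candidates = bifactor.assign_sites(
                loadings, r0=self.r0, p0=self.p0, p1=self.p1, min_size=self.min_sector_size
            )
            sectors = bifactor.merge_sectors(candidates, noise.W_reduced)
        else:
            sectors = bifactor.SectorSet(sectors=[], r0=self.r0, p0=self.p0, p1=self.p1)
        factors = bifactor.FactorModel(
            eigenvalues=eigenvalues,
            eigenvectors=eigenvectors,
            null_eigenvalues=E,
            N=N,
            t=t,
            loadings=loadings,
            rotation=rotation,
        )
        return SectorResults(
            model=self,
            seed=seed,
            frequencies=fm,
            coupling=cm,
            noise=noise,
            factors=factors,
            sectors=sectors,
        )


@dataclasses.dataclass
class SectorResults:
    """Fitted sector decomposition with diagnostics and evaluation hooks.

    Sector site indices inside ``sectors`` refer to rows of the reduced
    matrix (kept sites); ``sector_columns`` translates them back to
    original alignment columns and ``sector_labels`` to template residue
    labels when a template was attached.
    """

    model: SectorModel
    seed: object
    frequencies: msa_io.FrequencyModel
    coupling: covariance.CouplingMatrices
    noise: covariance.NoiseReductionResult
    factors: bifactor.FactorModel
    sectors: bifactor.SectorSet

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def sector_columns(self) -> list[tuple[int, ...]]:
        kept = self.noise.kept
        return [tuple(kept[i] for i in sec.sites) for sec in self.sectors]

    @property
    def sector_labels(self) -> list[list[str]]:
        labels = self.model.alignment.column_labels()
        return [[labels[c] for c in cols] for cols in self.sector_columns]

    def sector_table(self) -> pd.DataFrame:
        """Tidy per-site table: sector id, column, residue label, loading."""
        labels = self.model.alignment.column_labels()
        kept = self.noise.kept
        rows = []
        for sid, sec in enumerate(self.sectors):
            for site in sec.sites:
                loading = float("nan")
                if self.factors.loadings is not None:
                    loading = float(self.factors.loadings[site, sec.source_factor])
                col = kept[site]
                rows.append(
                    {
                        "sector": sid,
                        "column": col,
                        "residue": labels[col],
                        "source_factor": sec.source_factor,
                        "sign": sec.sign,
                        "loading": loading,
                    }
                )
        return pd.DataFrame(rows, columns=["sector", "column", "residue", "source_factor", "sign", "loading"])

    def summary(self) -> str:
        al = self.model.alignment
        f = self.factors
        lines = [
            "Bi-factor protein sector analysis",
            "=" * 42,
            f"sequences:             {al.n_sequences}",
            f"alignment columns:     {al.n_columns}",
            f"noise sites removed:   {len(self.noise.removed)}  (Rmax <= "
            f"{self.model.noise_factor:g} * plus, plus = {self.noise.plus:.4f})",
            f"sites analyzed:        {len(self.noise.kept)}",
            f"null eigenvalues:      {f.null_eigenvalues.size} "
            f"({self.model.n_shuffles} column shuffles)",
            f"non-random factors t:  {f.t}",
        ]
        for i in range(min(f.eigenvalues.size, max(f.t, 3))):
            mark = "*" if i < f.t else " "
            lines.append(
                f"  eigenvalue {i + 1:2d}{mark}  {f.eigenvalues[i]:10.4f}   N = {int(f.N[i])}"
            )
        lines.append(f"sectors detected:      {self.n_sectors}")
        labels = self.sector_labels
        for sid, sec in enumerate(self.sectors):
            lines.append(
                f"  sector {sid}: {sec.size} sites (factor {sec.source_factor}, sign {sec.sign})"
            )
            lines.append("    " + " ".join(labels[sid]))
        if f.t == 0:
            lines.append("note: no eigenvalue beat the shuffle null; empty sector list")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def evaluate(
        self,
        reference=None,
        rate4site=None,
        n_random_correlation: int = 1000,
        n_random_mdi: int = 100,
        seed=None,
        rate_positions: str = "template",
    ) -> evaluation.EvaluationReport:
        """Run the verification suite on the fitted sectors.

        ``reference`` is a list of reference site sets (alignment
        columns) for sensitivity/PPV; ``rate4site`` a Rate4Site output
        path. Random baselines resample from the kept (analyzed) sites.
        """
        rng = np.random.default_rng(seed)
        report = evaluation.EvaluationReport()
        al = self.model.alignment
        cols = self.sector_columns
        for sec in self.sectors:
            report.internal.append(
                evaluation.internal_correlation(
                    self.noise.W_reduced,
                    sec.sites,
                    n_random=n_random_correlation,
                    seed=int(rng.integers(2 ** 31)),
                )
            )
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                report.independence.append(
                    (
                        (a, b),
                        evaluation.independence_test(
                            al,
                            cols[a],
                            cols[b],
                            n_random=n_random_mdi,
                            seed=int(rng.integers(2 ** 31)),
                        ),
                    )
                )
        for c in cols:
            report.pca.append(evaluation.evolutionary_independence(al, c))
        if rate4site is not None:
            rates = evaluation.read_rate4site(rate4site)
            column_map = None
            if rate_positions == "template" and al.column_to_residue is not None:
                import re

                column_map = {
                    c: int(re.match(r"(-?\d+)", al.column_to_residue[c]).group(1))
                    for c in al.column_to_residue
                }
            report.rates = evaluation.rate_summary(rates, cols, column_map=column_map)
        if reference is not None:
            report.accuracy = evaluation.sensitivity_ppv(cols, reference)
        return report

    # ------------------------------------------------------------------
    def plot_spectrum(self, ax=None):
        """Real eigenvalues against the pooled shuffle-null spectrum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.factors
        ax.hist(f.null_eigenvalues, bins=60, density=True, alpha=0.6,
                color="0.6", label="shuffle null")
        for i, lam in enumerate(f.eigenvalues):
            ax.axvline(lam, color="C3" if i < f.t else "C0",
                       lw=1.5 if i < f.t else 0.6, alpha=0.9 if i < f.t else 0.4)
        ax.set_xlabel("eigenvalue")
        ax.set_ylabel("null density")
        ax.legend(loc="upper right")
        return ax

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        f = self.factors
        return {
            "seed": self.seed,
            "params": self.model.params(),
            "n_sequences": self.model.alignment.n_sequences,
            "n_columns": self.model.alignment.n_columns,
            "noise": self.noise.to_dict(),
            "eigenvalues": [float(x) for x in f.eigenvalues],
            "N": [int(x) for x in f.N],
            "t": f.t,
            "null_summary": {
                "size": int(f.null_eigenvalues.size),
                "max": float(f.null_eigenvalues.max()),
                "mean": float(f.null_eigenvalues.mean()),
                "p99": float(np.percentile(f.null_eigenvalues, 99)),
            },
            "sectors": self.sectors.to_dict(),
            "sector_columns": [list(c) for c in self.sector_columns],
            "sector_labels": self.sector_labels,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text
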