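"""Alignment input, integer residue encoding, and site-frequency models.

The twenty standard amino acids are encoded 1-20 in alphabetical
one-letter-code order (A=1, C=2, D=3, ..., Y=20). Gaps and any ambiguous
or non-standard characters (``B Z X U O J . - *``) encode to 0, so a
column vector lives in ``{0, ..., 20}``.

Frequencies follow the statistical-coupling-analysis convention by
default: the denominator is the full number of sequences S and gapped
cells contribute to no amino-acid count, so per-site frequencies sum to
at most 1. ``denominator="nongap"`` switches to per-site (and per-pair)
non-gap counts.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy import sparse

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_AA = 20
AA_TO_CODE = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET)}
CODE_TO_AA = "-" + AA_ALPHABET

_ENCODE_TABLE = np.zeros(128, dtype=np.int8)
for _aa, _code in AA_TO_CODE.items():
    _ENCODE_TABLE[ord(_aa)] = _code
    _ENCODE_TABLE[ord(_aa.lower())] = _code


class AlignmentFormatError(ValueError):
    """The input does not parse as a valid alignment."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode one aligned sequence as an int8 vector in {0..20}."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _ENCODE_TABLE[np.where(raw < 128, raw, 0)]


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` (unknowns come back as ``-``)."""
    return "".join(CODE_TO_AA[c] for c in np.asarray(codes, dtype=int))


@dataclasses.dataclass
class Alignment:
    """An integer-encoded multiple sequence alignment.

    Parameters
    ----------
    seq_ids : list of str
        One identifier per row, input order preserved.
    matrix : ndarray of shape (S, L)
        Integer codes, 0 = gap/unknown, 1-20 = amino acids.
    template_index : int, optional
        Row used to map columns to residue numbers.
    column_to_residue : dict, optional
        Map from column index to a residue label such as ``"57H"``;
        defined exactly on the columns where the template row is
        non-gap, strictly increasing in residue number.
    """

    seq_ids: list[str]
    matrix: np.ndarray
    template_index: int | None = None
    column_to_residue: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        S, L = self.matrix.shape
        if S < 2 or L < 2:
            raise AlignmentFormatError(
                f"alignment needs at least 2 sequences and 2 columns, got {S}x{L}"
            )
        if len(self.seq_ids) != S:
            raise AlignmentFormatError("number of ids does not match number of rows")
        if self.matrix.min() < 0 or self.matrix.max() > N_AA:
            raise AlignmentFormatError("matrix entries must lie in {0,...,20}")
        if self.template_index is not None and not (0 <= self.template_index < S):
            raise AlignmentFormatError("template_index out of range")
        if self.column_to_residue is not None:
            self._check_numbering()
        if (self.matrix == 0).all(axis=0).any():
            warnings.warn("alignment contains all-gap columns", stacklevel=2)

    def _check_numbering(self) -> None:
        nums = []
        for col in sorted(self.column_to_residue):
            if not (0 <= col < self.n_columns):
                raise AlignmentFormatError(f"numbering refers to column {col} out of range")
            m = re.match(r"(-?\d+)", str(self.column_to_residue[col]))
            if m is None:
                raise AlignmentFormatError(
                    f"residue label {self.column_to_residue[col]!r} has no leading number"
                )
            nums.append(int(m.group(1)))
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise AlignmentFormatError("residue numbers must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return decode_sequence(self.matrix[i])

    def subset_columns(self, columns) -> "Alignment":
        """New alignment restricted to ``columns`` (order preserved)."""
        cols = list(columns)
        sub = self.matrix[:, cols]
        mapping = None
        if self.column_to_residue is not None:
            mapping = {
                new: self.column_to_residue[old]
                for new, old in enumerate(cols)
                if old in self.column_to_residue
            }
        return Alignment(list(self.seq_ids), sub, self.template_index, mapping)

    def with_template(self, template, numbering: dict[int, str] | None = None) -> "Alignment":
        """Attach a template row and the column -> residue-number map.

        ``template`` is a row index or a sequence id. By default residues
        of the template are numbered 1..N skipping its gaps; a
        ``numbering`` dict (e.g. from :func:`read_numbering`) overrides
        the labels, which supports chymotrypsin-style numbering.
        """
        if isinstance(template, str):
            try:
                idx = self.seq_ids.index(template)
            except ValueError:
                raise KeyError(f"template id {template!r} not found") from None
        else:
            idx = int(template)
        row = self.matrix[idx]
        mapping: dict[int, str] = {}
        resnum = 0
        for col in np.nonzero(row > 0)[0]:
            resnum += 1
            mapping[int(col)] = f"{resnum}{CODE_TO_AA[row[col]]}"
        if numbering is not None:
            unknown = set(numbering) - set(mapping)
            if unknown:
                raise AlignmentFormatError(
                    f"numbering file refers to gap/absent template columns: {sorted(unknown)}"
                )
            mapping.update({int(k): str(v) for k, v in numbering.items()})
        return Alignment(list(self.seq_ids), self.matrix.copy(), idx, mapping)

    def column_labels(self) -> list[str]:
        """Per-column labels: template residue where mapped, else ``col<i>``."""
        cmap = self.column_to_residue or {}
        return [cmap.get(i, f"col{i}") for i in range(self.n_columns)]


_FORMAT_BY_SUFFIX = {
    ".fasta": "fasta", ".fa": "fasta", ".faa": "fasta", ".mfa": "fasta",
    ".aln": "clustal", ".clustal": "clustal", ".clu": "clustal",
}


def read_alignment(path, format: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment into an :class:`Alignment`.

    Sequence order is preserved; unequal sequence lengths or an empty
    file raise :class:`AlignmentFormatError`.
    """
    path = Path(path)
    if format is None:
        format = _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "fasta")
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [encode_sequence(str(rec.seq)) for rec in msa]
    return Alignment(ids, np.vstack(rows))


def write_fasta(al: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(al.seq_ids, al.matrix):
            fh.write(f">{sid}\n{decode_sequence(row)}\n")


def read_numbering(path) -> dict[int, str]:
    """Read a TSV numbering map: ``column<TAB>residue_number<TAB>residue_code``.

    Lines starting with ``#`` and a header line are ignored. Returns a
    dict from 0-based column index to label like ``"57H"``.
    """
    mapping: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            try:
                col = int(parts[0])
            except ValueError:
                continue  # header
            num = parts[1]
            code = parts[2] if len(parts) > 2 else ""
            mapping[col] = f"{num}{code}"
    return mapping


@dataclasses.dataclass
class FrequencyModel:
    """Single-site, joint, and background amino-acid frequencies.

    ``f1[i, a-1]`` is the frequency of amino acid ``a`` at column ``i``;
    ``f2[i, a-1, j, b-1]`` the joint frequency of ``(a @ i, b @ j)``;
    ``q`` the 20-vector of background frequencies (sums to 1).
    """

    f1: np.ndarray
    f2: np.ndarray
    q: np.ndarray
    n_sequences: int
    denominator: str = "all"

    @property
    def n_columns(self) -> int:
        return self.f1.shape[0]

    @property
    def f2_flat(self) -> np.ndarray:
        L = self.n_columns
        return self.f2.reshape(L * N_AA, L * N_AA)


def _onehot(matrix: np.ndarray) -> sparse.csr_matrix:
    S, L = matrix.shape
    s_idx, l_idx = np.nonzero(matrix > 0)
    cols = l_idx * N_AA + (matrix[s_idx, l_idx].astype(np.int64) - 1)
    data = np.ones(len(s_idx), dtype=np.float64)
    return sparse.csr_matrix((data, (s_idx, cols)), shape=(S, L * N_AA))


def frequencies_from_matrix(
    matrix: np.ndarray,
    denominator: str = "all",
    background=None,
) -> FrequencyModel:
    """Frequency model straight from an encoded (S, L) matrix."""
    if denominator not in ("all", "nongap"):
        raise ValueError("denominator must be 'all' or 'nongap'")
    matrix = np.asarray(matrix)
    S, L = matrix.shape
    X = _onehot(matrix)
    counts1 = np.asarray(X.sum(axis=0)).ravel()            # (20L,)
    pair = np.asarray((X.T @ X).todense())                 # (20L, 20L) counts

    if denominator == "all":
        f1 = counts1.reshape(L, N_AA) / S
        f2 = (pair / S).reshape(L, N_AA, L, N_AA)
    else:
        nongap = (matrix > 0).astype(np.float64)
        n_i = nongap.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = counts1.reshape(L, N_AA) / n_i[:, None]
        f1 = np.nan_to_num(f1)
        n_ij = nongap.T @ nongap                           # (L, L)
        denom = np.repeat(np.repeat(n_ij, N_AA, axis=0), N_AA, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f2 = pair / denom
        f2 = np.nan_to_num(f2).reshape(L, N_AA, L, N_AA)

    if background is not None:
        q = np.asarray(background, dtype=np.float64)
        if q.shape != (N_AA,) or (q < 0).any():
            raise ValueError("background must be a nonnegative 20-vector")
        q = q / q.sum()
    else:
        pooled = counts1.reshape(L, N_AA).sum(axis=0)
        total = pooled.sum()
        q = pooled / total if total > 0 else np.full(N_AA, 1.0 / N_AA)
    return FrequencyModel(f1=f1, f2=f2, q=q, n_sequences=S, denominator=denominator)


def frequencies(al: Alignment, denominator: str = "all", background=None) -> FrequencyModel:
    """Compute the :class:`FrequencyModel` of an alignment by counting."""
    return frequencies_from_matrix(al.matrix, denominator=denominator, background=background)
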