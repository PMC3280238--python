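"""Pairwise and progressive alignment plus the complete-deletion matrix.

Pairwise global alignment is delegated to :class:`Bio.Align.PairwiseAligner`
(Needleman-Wunsch with affine gaps).  The progressive multiple aligner is a
small classic implementation: identity distances -> neighbor-joining guide
tree -> profile-profile merges in guide-tree order.  A user-supplied curated
alignment can bypass the progressive step entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, AlignIO, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, PipelineError

__all__ = [
    "PairwiseAlignment",
    "Msa",
    "CharacterMatrix",
    "global_align",
    "percent_identity",
    "progressive_msa",
    "complete_deletion",
    "read_fasta",
    "write_fasta",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


# ---------------------------------------------------------------------------
# pairwise


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences (gap character ``-``)."""

    seq_a: str
    seq_b: str
    score: float
    matches: int

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned strings differ in length")


def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    try:
        aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from None
    # first gap position costs gap_open, each further position gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Among
    co-optimal alignments the aligner's first enumeration order is used,
    which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != GAP)
    return PairwiseAlignment(seq_a=sa, seq_b=sb, score=float(aln.score), matches=matches)


def percent_identity(alignment: PairwiseAlignment, reference: str = "a") -> int:
    """Identity as matches over the ungapped reference length, in percent.

    ``reference`` selects which input counts as 100% ("a" or "b").
    Rounded half-up to the nearest integer.
    """
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    ref = alignment.seq_a if reference == "a" else alignment.seq_b
    ref_len = len(ref) - ref.count(GAP)
    if ref_len == 0:
        raise ValueError("reference sequence is empty")
    return int(100.0 * alignment.matches / ref_len + 0.5)


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass
class Msa:
    """A multiple sequence alignment: parallel ``names`` and ``rows``."""

    names: list
    rows: list

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.rows))

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(r), id=n, description="") for n, r in zip(self.names, self.rows)]
        SeqIO.write(records, str(path), "fasta")

    def write_clustal(self, path: str | Path) -> None:
        from Bio.Align import MultipleSeqAlignment

        msa = MultipleSeqAlignment(
            SeqRecord(Seq(r), id=n, description="") for n, r in zip(self.names, self.rows)
        )
        AlignIO.write(msa, str(path), "clustal")

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None) -> "Msa":
        """Read an alignment from FASTA or Clustal (guessed from suffix)."""
        path = Path(path)
        if fmt is None:
            fmt = "clustal" if path.suffix in {".aln", ".clustal"} else "fasta"
        try:
            records = list(AlignIO.read(str(path), fmt))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot read alignment {path}: {exc}") from exc
        return cls(names=[r.id for r in records], rows=[str(r.seq).upper() for r in records])


def _identity_distance(a: str, b: str, **kw) -> float:
    aln = global_align(a, b, **kw)
    return 1.0 - aln.matches / max(len(a), len(b))


def _nj_merge_order(dist: np.ndarray) -> list:
    """Neighbor-joining, returning the merge order as nested tuples of indices."""
    n = dist.shape[0]
    if n == 1:
        return [0]
    active = list(range(n))
    nodes: dict[int, object] = {i: i for i in range(n)}
    d = dist.astype(float).copy()
    next_id = n
    # work on a dict-of-dicts to allow deletion
    dd = {i: {j: d[i, j] for j in active if j != i} for i in active}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dd[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dd[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        new = next_id
        next_id += 1
        dd[new] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dd[i][k] + dd[j][k] - dd[i][j])
            dd[new][k] = dk
            dd[k][new] = dk
        nodes[new] = (nodes[i], nodes[j])
        for k in (i, j):
            active.remove(k)
            del dd[k]
        for k in list(dd):
            dd[k].pop(i, None)
            dd[k].pop(j, None)
        active.append(new)
    i, j = active
    return [(nodes[i], nodes[j])]


class _Profile:
    """Columns of an alignment restricted to a subset of rows."""

    def __init__(self, names: list, rows: list):
        self.names = names
        self.rows = rows  # list of equal-length strings


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _col_score(col_a: str, col_b: str, gap_pen: float) -> float:
    total = 0.0
    n = 0
    for x in col_a:
        for y in col_b:
            if x == GAP and y == GAP:
                s = 0.0
            elif x == GAP or y == GAP:
                s = -gap_pen
            else:
                s = float(_BLOSUM62[x][y])
            total += s
            n += 1
    return total / n


def _merge_profiles(pa: _Profile, pb: _Profile, gap_open: float, gap_extend: float) -> _Profile:
    """Needleman-Wunsch on profile columns with linear gap cost.

    Linear (not affine) gaps are sufficient here: profiles are merged in
    guide-tree order on closely related sequences.
    """
    la = len(pa.rows[0]) if pa.rows else 0
    lb = len(pb.rows[0]) if pb.rows else 0
    gap = gap_open / 2.0 + gap_extend  # single per-column gap cost
    cols_a = ["".join(r[i] for r in pa.rows) for i in range(la)]
    cols_b = ["".join(r[i] for r in pb.rows) for i in range(lb)]

    score = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        score[i, 0] = -gap * i
        ptr[i, 0] = 1
    for j in range(1, lb + 1):
        score[0, j] = -gap * j
        ptr[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + _col_score(cols_a[i - 1], cols_b[j - 1], gap)
            up = score[i - 1, j] - gap
            left = score[i, j - 1] - gap
            best, which = diag, 0
            if up > best + 1e-12:
                best, which = up, 1
            if left > best + 1e-12:
                best, which = left, 2
            score[i, j] = best
            ptr[i, j] = which

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        w = ptr[i, j]
        if i > 0 and j > 0 and w == 0:
            out_a.append(cols_a[i - 1]); out_b.append(cols_b[j - 1]); i -= 1; j -= 1
        elif i > 0 and w == 1:
            out_a.append(cols_a[i - 1]); out_b.append(GAP * len(pb.names)); i -= 1
        else:
            out_a.append(GAP * len(pa.names)); out_b.append(cols_b[j - 1]); j -= 1
    out_a.reverse()
    out_b.reverse()
    ncols = len(out_a)
    rows_a = ["".join(out_a[c][r] for c in range(ncols)) for r in range(len(pa.names))]
    rows_b = ["".join(out_b[c][r] for c in range(ncols)) for r in range(len(pb.names))]
    return _Profile(pa.names + pb.names, rows_a + rows_b)


def progressive_msa(seqs: dict | Sequence, gap_open: float = 10.0,
                    gap_extend: float = 0.5, matrix_name: str = "BLOSUM62") -> Msa:
    """Progressive multiple alignment with an NJ guide tree.

    Accepts ``{name: sequence}`` or an iterable of ``(name, sequence)``.
    Raises ``ValueError`` for fewer than two sequences.
    """
    if isinstance(seqs, dict):
        items = list(seqs.items())
    else:
        items = [tuple(p) for p in seqs]
    if len(items) < 2:
        raise ValueError("progressive_msa needs at least two sequences")
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    raw = [s.upper() for _, s in items]

    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _identity_distance(
                raw[i], raw[j], matrix_name=matrix_name,
                gap_open=gap_open, gap_extend=gap_extend)

    order = _nj_merge_order(dist)[0]

    def build(node) -> _Profile:
        if isinstance(node, int):
            return _Profile([names[node]], [raw[node]])
        left, right = node
        return _merge_profiles(build(left), build(right), gap_open, gap_extend)

    prof = build(order)
    # restore input order
    idx = {nm: k for k, nm in enumerate(prof.names)}
    rows = [prof.rows[idx[nm]] for nm in names]
    return Msa(names=list(names), rows=rows)


# ---------------------------------------------------------------------------
# character matrix


@dataclass
class CharacterMatrix:
    """Gap-free residue matrix feeding parsimony scoring."""

    taxa: list
    rows: list  # one string per taxon, equal lengths

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.taxa)} {self.n_positions}\n")
            for name, row in zip(self.taxa, self.rows):
                fh.write(f"{name}  {row}\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "CharacterMatrix":
        """Relaxed PHYLIP: header line then ``name  sequence`` lines."""
        taxa, rows = [], []
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise FormatError("bad PHYLIP header")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"bad PHYLIP line: {line!r}")
                taxa.append(parts[0])
                rows.append(parts[1])
        m = cls(taxa=taxa, rows=rows)
        if len(taxa) != int(header[0]) or m.n_positions != int(header[1]):
            raise FormatError("PHYLIP header disagrees with body")
        return m


def complete_deletion(msa: Msa) -> CharacterMatrix:
    """Keep only columns where every taxon has one of the 20 residues.

    Gaps and unknown states ('X', 'x', '?', '.') eliminate a column.
    """
    keep = []
    valid = set(AA20)
    for i in range(msa.n_columns):
        col = msa.column(i).upper()
        if all(c in valid for c in col):
            keep.append(i)
    if not keep:
        raise PipelineError(
            "complete deletion removed every column; alignment too gappy "
            f"({msa.n_columns} columns, {len(msa)} taxa)")
    rows = ["".join(row[i] for i in keep) for row in msa.rows]
    return CharacterMatrix(taxa=list(msa.names), rows=rows)


# ---------------------------------------------------------------------------
# FASTA helpers


def read_fasta(path: str | Path) -> dict:
    """Read FASTA into an ordered ``{id: sequence}`` dict."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    out: dict = {}
    for rec in records:
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
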