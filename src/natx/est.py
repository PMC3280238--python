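"""EST cleanup and clustering: quality trimming, vector masking,
contig/singlet partition.

Trimming keeps the longest stretch whose every sliding window passes the
mean-quality cutoff.  Vector masking strips exact end matches against a
vector (either strand).  Clustering is single linkage under the
">95 identical per 100" overlap rule with a gapless shift scan, and
contig consensus is a column-wise majority over the read layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = [
    "Read",
    "TrimmedRead",
    "ContigSet",
    "trim_quality",
    "mask_vector",
    "cluster_ests",
    "read_fastq",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    id: str
    seq: str
    qual: list

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.qual)})")


@dataclass
class TrimmedRead:
    """A read restricted to its retained interval (0-based half-open)."""

    id: str
    seq: str
    qual: list
    kept_interval: tuple

    def __post_init__(self) -> None:
        start, end = self.kept_interval
        if end - start != len(self.seq) or len(self.seq) != len(self.qual):
            raise FormatError(f"read {self.id}: inconsistent trimmed interval")


@dataclass
class Contig:
    consensus: str
    members: list


@dataclass
class ContigSet:
    contigs: list = field(default_factory=list)
    singlets: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# trimming / masking


def trim_quality(read: Read, window: int = 100, min_q: int = 20):
    """Longest interval whose every length-``window`` sliding window has
    mean quality >= ``min_q``; ``None`` when no such interval exists."""
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(read.qual, dtype=float)
    n = len(q)
    if n < window:
        return None
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    ok = means >= min_q - 1e-9
    if not ok.any():
        return None
    # longest run of consecutive passing window starts
    best_len = best_start = -1
    run_start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    start = best_start
    end = best_start + best_len - 1 + window
    return TrimmedRead(
        id=read.id,
        seq=read.seq[start:end],
        qual=list(read.qual[start:end]),
        kept_interval=(start, end),
    )


def mask_vector(read: TrimmedRead, vector: str, min_match: int = 15) -> TrimmedRead:
    """Strip vector-matching ends (forward or reverse-complement strand)."""
    if min_match < 10:
        raise ValueError("min_match must be >= 10")
    vec = vector.upper()
    targets = (vec, revcomp(vec))
    seq = read.seq.upper()
    start, end = read.kept_interval

    cut_front = 0
    for L in range(min(len(seq), len(vec)), min_match - 1, -1):
        piece = seq[:L]
        if any(piece in t for t in targets):
            cut_front = L
            break
    cut_back = 0
    for L in range(min(len(seq) - cut_front, len(vec)), min_match - 1, -1):
        piece = seq[len(seq) - L:]
        if any(piece in t for t in targets):
            cut_back = L
            break
    if cut_front == 0 and cut_back == 0:
        return read
    lo, hi = cut_front, len(seq) - cut_back
    return TrimmedRead(
        id=read.id,
        seq=read.seq[lo:hi],
        qual=list(read.qual[lo:hi]),
        kept_interval=(start + lo, start + cut_front + (hi - lo)),
    )


# ---------------------------------------------------------------------------
# clustering


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def best_overlap(a: str, b: str):
    """Best gapless overlap between two reads.

    Returns ``(matches, overlap_len, shift)`` where ``shift`` is the offset
    of ``b`` relative to ``a`` (b starts at a-coordinate ``shift``).  The
    shift maximizing matches wins; ties prefer the smaller shift.
    """
    ea, eb = _encode(a.upper()), _encode(b.upper())
    la, lb = len(ea), len(eb)
    best = (-1, 0, 0)
    for shift in range(-(lb - 1), la):
        a_lo, a_hi = max(0, shift), min(la, shift + lb)
        if a_hi <= a_lo:
            continue
        seg_a = ea[a_lo:a_hi]
        seg_b = eb[a_lo - shift:a_hi - shift]
        matches = int((seg_a == seg_b).sum())
        if matches > best[0]:
            best = (matches, a_hi - a_lo, shift)
    return best


def cluster_ests(reads: list, min_overlap: int = 100,
                 min_identical_per_100: float = 95.0) -> ContigSet:
    """Single-linkage clustering of reads into contigs and singlets.

    Two reads link when their best gapless overlap spans at least
    ``min_overlap`` bases with strictly more than ``min_identical_per_100``
    identical positions per 100.  Consensus is the column-wise majority
    over the linked layout, ties resolved alphabetically.
    """
    if not reads:
        return ContigSet()
    reads = sorted(reads, key=lambda r: r.id)
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    links: dict[tuple, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            matches, olen, shift = best_overlap(reads[i].seq, reads[j].seq)
            if olen >= min_overlap and 100.0 * matches / olen > min_identical_per_100:
                links[(i, j)] = shift
                parent[find(i)] = find(j)

    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    out = ContigSet()
    for members in sorted(groups.values(), key=lambda g: reads[g[0]].id):
        if len(members) == 1:
            out.singlets.append(reads[members[0]].id)
            continue
        out.contigs.append(Contig(
            consensus=_layout_consensus(reads, members, links),
            members=[reads[i].id for i in members],
        ))
    return out


def _layout_consensus(reads: list, members: list, links: dict) -> str:
    offsets = {members[0]: 0}
    frontier = [members[0]]
    member_set = set(members)
    while frontier:
        cur = frontier.pop(0)
        for (i, j), shift in links.items():
            if i == cur and j in member_set and j not in offsets:
                offsets[j] = offsets[cur] + shift
                frontier.append(j)
            elif j == cur and i in member_set and i not in offsets:
                offsets[i] = offsets[cur] - shift
                frontier.append(i)
    lo = min(offsets.values())
    hi = max(offsets[i] + len(reads[i].seq) for i in offsets)
    counts = [dict() for _ in range(hi - lo)]
    for i, off in offsets.items():
        for k, base in enumerate(reads[i].seq.upper()):
            col = counts[off - lo + k]
            col[base] = col.get(base, 0) + 1
    consensus = []
    for col in counts:
        if not col:
            continue
        best = max(sorted(col), key=lambda b: col[b])  # alphabetic tie-break
        consensus.append(best)
    return "".join(consensus)


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)


def read_fastq(path: str | Path) -> list:
    reads = []
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: FASTQ line count not a multiple of 4")
    for k in range(0, len(lines), 4):
        head, seq, plus, qual = lines[k:k + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record near line {k + 1}")
        reads.append(Read(
            id=head[1:].split()[0],
            seq=seq,
            qual=[ord(c) - 33 for c in qual],
        ))
    return reads


def write_fastq(reads: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
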