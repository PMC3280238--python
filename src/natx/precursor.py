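"""Precursor annotation: ORF finding, signal-peptide cleavage, C-terminal
propeptide removal with amidation, and alpha/beta candidate labelling.

A precursor protein is signal peptide + mature toxin + optional C-terminal
pro-sequence.  When the translated sequence ends in Gly followed by one to
three basic residues (K/R), a carboxypeptidase is assumed to remove those
residues and the Gly amide-donates to the new C-terminal residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .align import global_align, percent_identity
from .errors import AnnotationError

__all__ = [
    "PrecursorRecord",
    "MaturePeptide",
    "find_orf",
    "cleave_signal",
    "process_cterm",
    "classify_candidate",
    "annotate_cds",
]

AMIDATION_MOTIF = re.compile(r"G[KR]{1,3}$")
MIN_MATURE_LEN = 55
MAX_MATURE_LEN = 79


@dataclass
class PrecursorRecord:
    """A precursor with 1-based inclusive segment intervals."""

    id: str
    cds: str
    protein: str
    signal: tuple
    mature: tuple
    cterm_pro: tuple | None
    amidated: bool

    def __post_init__(self) -> None:
        s, m = self.signal, self.mature
        if s[0] != 1 or m[0] != s[1] + 1:
            raise ValueError(f"{self.id}: segments are not contiguous")
        last = self.mature[1]
        if self.cterm_pro is not None:
            if self.cterm_pro[0] != m[1] + 1:
                raise ValueError(f"{self.id}: segments are not contiguous")
            last = self.cterm_pro[1]
        if last != len(self.protein):
            raise ValueError(f"{self.id}: segments do not cover the protein")
        if self.amidated:
            if self.cterm_pro is None:
                raise ValueError(f"{self.id}: amidated without a pro-peptide")
            if self.protein[self.cterm_pro[0] - 1] != "G":
                raise ValueError(f"{self.id}: pro-peptide must begin with G")

    @property
    def signal_seq(self) -> str:
        return self.protein[self.signal[0] - 1:self.signal[1]]

    @property
    def mature_seq(self) -> str:
        return self.protein[self.mature[0] - 1:self.mature[1]]

    @property
    def cterm_pro_seq(self) -> str:
        if self.cterm_pro is None:
            return ""
        return self.protein[self.cterm_pro[0] - 1:self.cterm_pro[1]]


@dataclass
class MaturePeptide:
    id: str
    seq: str
    n_cys: int
    n_disulfides: int
    amidated: bool

    def __post_init__(self) -> None:
        if self.n_cys != self.seq.count("C"):
            raise ValueError(f"{self.id}: n_cys does not match sequence")

    @property
    def length_ok(self) -> bool:
        return MIN_MATURE_LEN <= len(self.seq) <= MAX_MATURE_LEN


def find_orf(cds: str, min_codons: int = 50) -> str:
    """Translate the longest ATG-initiated ORF on the forward strand.

    All three frames are scanned; an ORF may end at a stop codon or at the
    end of the sequence.  Raises :class:`AnnotationError` when no ORF of at
    least ``min_codons`` codons exists.
    """
    cds = cds.upper().replace("U", "T")
    best = ""
    for frame in range(3):
        i = frame
        while i + 3 <= len(cds):
            if cds[i:i + 3] != "ATG":
                i += 3
                continue
            j = i
            while j + 3 <= len(cds) and cds[j:j + 3] not in ("TAA", "TAG", "TGA"):
                j += 3
            orf = cds[i:j]
            if len(orf) > len(best):
                best = orf
            i = j + 3
    if len(best) < 3 * min_codons:
        raise AnnotationError(
            f"no ATG-initiated ORF of >= {min_codons} codons found")
    return str(Seq(best).translate())


def cleave_signal(protein: str, cleavage_site="auto",
                  reference_matures: dict | None = None,
                  k_min: int = 18, k_max: int = 22,
                  min_identity: float = 0.5):
    """Split a precursor protein into (signal, proprotein).

    With an integer ``cleavage_site`` k the signal is residues 1..k.  With
    "auto" the site within [k_min, k_max] whose downstream 10-mer best
    matches a reference mature N-terminus is chosen; a best identity not
    above ``min_identity`` is an annotation error.
    """
    if cleavage_site != "auto":
        k = int(cleavage_site)
        if not 0 < k < len(protein):
            raise ValueError(f"cleavage site {k} outside protein")
        return protein[:k], protein[k:]
    if not reference_matures:
        raise ValueError("auto cleavage requires reference mature sequences")
    best_k, best_ident = None, -1.0
    for k in range(k_min, min(k_max, len(protein) - 10) + 1):
        window = protein[k:k + 10]
        for ref in reference_matures.values():
            head = ref[:10]
            ident = sum(a == b for a, b in zip(window, head)) / 10.0
            if ident > best_ident:
                best_k, best_ident = k, ident
    if best_k is None or best_ident <= min_identity:
        raise AnnotationError(
            f"no reference mature N-terminus matched above identity "
            f"{min_identity} (best {best_ident:.2f})")
    return protein[:best_k], protein[best_k:]


def process_cterm(proprotein: str, id: str = "") -> MaturePeptide:
    """Apply the terminal Gly+basic processing/amidation rule.

    A C-terminal ``G[KR]{1,3}`` is removed and the remaining peptide is
    flagged amidated; anything else passes through unchanged.
    """
    if not proprotein:
        raise ValueError("empty sequence")
    m = AMIDATION_MOTIF.search(proprotein)
    if m:
        seq = proprotein[:m.start()]
        amidated = True
    else:
        seq = proprotein
        amidated = False
    n_cys = seq.count("C")
    return MaturePeptide(id=id, seq=seq, n_cys=n_cys,
                         n_disulfides=n_cys // 2, amidated=amidated)


def classify_candidate(mature: str, alpha_refs: dict, beta_refs: dict,
                       margin: float = 5.0) -> str:
    """Label by nearest reference class: alpha-like, beta-like, ambiguous.

    ``ambiguous`` when the best alpha and beta identities are within
    ``margin`` percentage points of each other.
    """
    if not alpha_refs or not beta_refs:
        raise ValueError("both reference sets must be non-empty")

    def best(refs: dict) -> float:
        scores = []
        for ref in refs.values():
            aln = global_align(mature, ref)
            scores.append(percent_identity(aln, reference="b"))
        return max(scores)

    a, b = best(alpha_refs), best(beta_refs)
    if abs(a - b) < margin:
        return "ambiguous"
    return "alpha-like" if a > b else "beta-like"


def annotate_cds(id: str, cds: str, reference_matures: dict | None = None,
                 cleavage_site="auto") -> tuple:
    """Full annotation of one CDS: ORF, signal cleavage, C-terminal rule.

    Returns ``(PrecursorRecord, MaturePeptide)``.
    """
    protein = find_orf(cds)
    signal, proprotein = cleave_signal(protein, cleavage_site, reference_matures)
    mature = process_cterm(proprotein, id=id)
    k = len(signal)
    mature_end = k + len(mature.seq)
    cterm = None
    if mature.amidated:
        cterm = (mature_end + 1, len(protein))
    record = PrecursorRecord(
        id=id, cds=cds, protein=protein,
        signal=(1, k),
        mature=(k + 1, mature_end),
        cterm_pro=cterm,
        amidated=mature.amidated,
    )
    return record, mature
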