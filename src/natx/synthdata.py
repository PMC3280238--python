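"""Synthetic toxin gene families with known ground truth.

Everything here is a pure function of its arguments (including the seed),
so any downstream stage can be tested against a planted truth without
external downloads.  The family layout is a set of monophyletic
subfamily clades hanging off a short backbone, plus one outgroup leaf:
long clade stems carry most of the substitution signal, backbone edges
almost none, so subfamilies are recoverable while the backbone stays soft.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .est import Read
from .precursor import PrecursorRecord
from .tree import Node, Tree

__all__ = [
    "TruthBundle",
    "simulate_family_tree",
    "evolve_mature_peptides",
    "build_precursor",
    "fragment_to_ests",
    "generate_truth_bundle",
    "mock_vector",
    "OUTGROUP_LABEL",
]

OUTGROUP_LABEL = "OUTG"

AA_NO_CYS = "ADEFGHIKLMNPQRSTVWY"  # 19 residues; C is reserved for the scaffold
SIGNAL_POOL = "ALIVFMSTWG"  # hydrophobic-leaning signal-peptide residues

# most-frequent codon per residue (fixed built-in table; codon choice is
# irrelevant downstream, only round-tripping matters)
CODON = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGA", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}
STOP = "TAA"

CTERM_MOTIFS = ("", "GK", "GKK", "GKRK")

# branch-length layout (substitution probability multipliers)
STEM_LENGTH = 1.0
BACKBONE_LENGTH = 0.001
WITHIN_CLADE_MIN, WITHIN_CLADE_MAX = 0.15, 0.35
OUTGROUP_LENGTH = 1.5


@dataclass
class TruthBundle:
    """Planted ground truth for one synthetic family."""

    true_tree: Tree
    true_subfamily_of: dict
    true_precursors: list
    seed: int
    matures: dict = field(default_factory=dict)
    signal_lens: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)


def simulate_family_tree(n_subfamilies: int, taxa_per_subfamily: int,
                         seed: int) -> Tree:
    """Rooted binary tree with planted monophyletic clades plus an outgroup.

    Leaves are labelled ``SF<i>_T<j>``; the outgroup leaf is ``OUTG``.
    """
    if n_subfamilies < 2 or taxa_per_subfamily < 1:
        raise ValueError("need n_subfamilies >= 2 and taxa_per_subfamily >= 1")
    rng = np.random.default_rng([seed, 101])

    def clade(i: int) -> Node:
        labels = [f"SF{i:02d}_T{j:02d}" for j in range(1, taxa_per_subfamily + 1)]
        nodes = [Node(lab, length=float(rng.uniform(WITHIN_CLADE_MIN,
                                                    WITHIN_CLADE_MAX)))
                 for lab in labels]
        while len(nodes) > 1:
            # join the first two, push the joint to a random slot
            a = nodes.pop(0)
            b = nodes.pop(0)
            joint = Node(length=float(rng.uniform(WITHIN_CLADE_MIN,
                                                  WITHIN_CLADE_MAX)))
            joint.add(a)
            joint.add(b)
            nodes.insert(int(rng.integers(0, len(nodes) + 1)), joint)
        top = nodes[0]
        top.length = STEM_LENGTH
        return top

    backbone = clade(n_subfamilies)
    for i in range(n_subfamilies - 1, 0, -1):
        joint = Node(length=BACKBONE_LENGTH)
        joint.add(clade(i))
        joint.add(backbone)
        backbone = joint
    root = Node()
    root.add(Node(OUTGROUP_LABEL, length=OUTGROUP_LENGTH))
    root.add(backbone)
    return Tree(root)


def subfamily_of_label(label: str) -> int | None:
    if label == OUTGROUP_LABEL:
        return None
    return int(label.split("_")[0][2:])


def evolve_mature_peptides(tree: Tree, scaffold_len: int = 65, n_cys: int = 8,
                           sub_rate: float = 0.3, seed: int = 0) -> dict:
    """Evolve mature-peptide sequences down ``tree``.

    Cysteine scaffold positions are chosen once and never substituted, so
    every leaf carries exactly ``n_cys`` cysteines at identical positions.
    Substitutions hit other sites i.i.d. with probability
    ``sub_rate * branch_length``, replaced uniformly among the 18 other
    non-cysteine residues (cysteine is excluded from the pool to keep the
    scaffold count exact).
    """
    if n_cys % 2 != 0:
        raise ValueError("n_cys must be even")
    if not 6 <= n_cys <= 8:
        raise ValueError("n_cys must be 6 or 8")
    if not 55 <= scaffold_len <= 79:
        raise ValueError("scaffold_len must be within [55, 79]")
    if sub_rate < 0:
        raise ValueError("sub_rate must be >= 0")
    rng = np.random.default_rng([seed, 202])
    cys_pos = np.sort(rng.choice(scaffold_len, size=n_cys, replace=False))
    root_seq = np.array([rng.choice(list(AA_NO_CYS)) for _ in range(scaffold_len)],
                        dtype="<U1")
    root_seq[cys_pos] = "C"
    variable = np.array([i for i in range(scaffold_len) if i not in set(cys_pos.tolist())])

    leaves: dict = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.length:
            p = min(0.95, sub_rate * node.length)
            hit = variable[rng.random(len(variable)) < p]
            if len(hit):
                seq = seq.copy()
                for i in hit:
                    current = seq[i]
                    pool = [a for a in AA_NO_CYS if a != current]
                    seq[i] = pool[int(rng.integers(0, len(pool)))]
        if node.is_leaf:
            leaves[node.label] = "".join(seq)
            return
        for child in node.children:
            walk(child, seq)

    walk(tree.root, root_seq)
    return leaves


def reverse_translate(protein: str) -> str:
    """Most-frequent-codon reverse translation, with a stop codon."""
    return "".join(CODON[a] for a in protein) + STOP


def build_precursor(mature: str, signal_len: int = 20, cterm_motif: str = "GK",
                    seed: int = 0, id: str = "synth") -> PrecursorRecord:
    """Assemble signal + mature + C-terminal motif and emit a valid CDS."""
    if not 18 <= signal_len <= 22:
        raise ValueError("signal_len must be within [18, 22]")
    if cterm_motif not in CTERM_MOTIFS:
        raise ValueError(f"cterm_motif must be one of {CTERM_MOTIFS}")
    rng = np.random.default_rng([seed, 303])
    signal = "M" + "".join(rng.choice(list(SIGNAL_POOL))
                           for _ in range(signal_len - 1))
    protein = signal + mature + cterm_motif
    mature_end = signal_len + len(mature)
    return PrecursorRecord(
        id=id,
        cds=reverse_translate(protein),
        protein=protein,
        signal=(1, signal_len),
        mature=(signal_len + 1, mature_end),
        cterm_pro=(mature_end + 1, len(protein)) if cterm_motif else None,
        amidated=bool(cterm_motif),
    )


def mock_vector() -> str:
    """The bundled 50-nt mock cloning-vector sequence."""
    text = resources.files("natx.data").joinpath("vector50.fa").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if not line.startswith(">"))


def fragment_to_ests(cds: str, n_reads: int, read_len: int,
                     error_rate: float = 0.0, vector: str | None = None,
                     seed: int = 0, vector_fraction: float = 0.3,
                     id_prefix: str = "read") -> list:
    """Fragment a CDS into single-pass reads with Phred+33-style qualities.

    A ``vector_fraction`` of reads is prefixed with the vector sequence.
    Qualities follow a two-state profile: a high-quality head and a
    low-quality tail, so a Q20 window rule has something to cut.  Errors
    are i.i.d. substitutions at ``error_rate``.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    vec = vector or ""
    if read_len > len(vec) + len(cds):
        raise ValueError("read_len longer than vector + template")
    rng = np.random.default_rng([seed, 404])
    bases = "ACGT"
    reads = []
    span = max(0, len(cds) - read_len)
    jitter = max(1, read_len // 10)
    for k in range(n_reads):
        with_vector = vec and rng.random() < vector_fraction
        if with_vector:
            template = vec + cds
            start = 0  # vector is an exact prefix of the read
        else:
            # stratified starts with bounded jitter so that coverage is
            # contiguous whenever n_reads * read_len >= 2 * len(cds)
            template = cds
            if k == 0 or n_reads == 1:
                start = 0
            elif k == n_reads - 1:
                start = span
            else:
                base = span * k / (n_reads - 1)
                start = int(round(base)) + int(rng.integers(-jitter, jitter + 1))
                start = min(max(start, 0), span)
        seq = list(template[start:start + read_len])
        # two-state quality profile: high head, low tail
        n = len(seq)
        tail = int(rng.integers(0, max(1, n // 3)))
        qual = [int(rng.integers(28, 41)) for _ in range(n - tail)] + \
               [int(rng.integers(3, 13)) for _ in range(tail)]
        if error_rate > 0:
            for i in range(n):
                if rng.random() < error_rate:
                    others = [b for b in bases if b != seq[i]]
                    seq[i] = others[int(rng.integers(0, len(others)))]
        reads.append(Read(id=f"{id_prefix}{k:04d}", seq="".join(seq), qual=qual))
    return reads


def generate_truth_bundle(n_subfamilies: int = 4, taxa_per_subfamily: int = 3,
                          scaffold_len: int = 65, n_cys: int = 8,
                          sub_rate: float = 0.15, seed: int = 0) -> TruthBundle:
    """Compose tree + sequences + precursors into one reproducible bundle."""
    tree = simulate_family_tree(n_subfamilies, taxa_per_subfamily, seed)
    matures = evolve_mature_peptides(tree, scaffold_len, n_cys, sub_rate, seed)
    rng = np.random.default_rng([seed, 505])
    precursors = []
    signal_lens: dict = {}
    motifs: dict = {}
    subfam: dict = {}
    for label in sorted(matures):
        signal_len = int(rng.integers(18, 23))
        motif = CTERM_MOTIFS[int(rng.integers(0, len(CTERM_MOTIFS)))]
        precursors.append(build_precursor(
            matures[label], signal_len=signal_len, cterm_motif=motif,
            seed=seed + len(precursors), id=label))
        signal_lens[label] = signal_len
        motifs[label] = motif
        sf = subfamily_of_label(label)
        if sf is not None:
            subfam[label] = sf
    return TruthBundle(
        true_tree=tree,
        true_subfamily_of=subfam,
        true_precursors=precursors,
        seed=seed,
        matures=matures,
        signal_lens=signal_lens,
        motifs=motifs,
    )
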