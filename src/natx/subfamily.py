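"""Subfamily extraction, consensus sequences, and systematic nomenclature.

Subfamilies are the maximal supported ingroup clades of the rooted
consensus tree; taxa attached directly to the unsupported backbone are
promoted to singleton subfamilies.  Each subfamily gets a column-majority
consensus sequence (variable positions shown as lower-case ``x``) and
systematic names ``NaTx<subfamily>.<k>`` assigned in chronological order
of description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .align import GAP, Msa, global_align, percent_identity
from .tree import Node, Tree

__all__ = [
    "Subfamily",
    "extract_subfamilies",
    "consensus_sequence",
    "assign_nomenclature",
    "report",
    "load_membership_table",
    "subfamilies_from_table",
]

AMBIGUOUS = "x"


@dataclass
class Subfamily:
    index: int
    members: list
    consensus: str = ""
    name_map: dict = field(default_factory=dict)


def extract_subfamilies(rooted_tree: Tree, min_support: float = 50.0,
                        singleton_policy: str = "own") -> list:
    """Partition the ingroup into subfamilies.

    The tree must be rooted with the outgroup as a direct child of the
    root.  Walking down from the ingroup crown, the first node whose edge
    support reaches ``min_support`` founds a subfamily containing its
    leaves; leaves reached without entering a supported clade are handled
    per ``singleton_policy`` ("own": one subfamily each; "drop": excluded).
    """
    root = rooted_tree.root
    if len(root.children) != 2:
        raise ValueError("tree is not rooted as (outgroup, ingroup)")
    leaf_children = [c for c in root.children if c.is_leaf]
    if len(leaf_children) != 1:
        raise ValueError("root must have exactly one leaf child (the outgroup)")
    if singleton_policy not in ("own", "drop"):
        raise ValueError("singleton_policy must be 'own' or 'drop'")
    crown = next(c for c in root.children if not c.is_leaf)

    groups: list[list] = []

    def collect(node: Node) -> None:
        if node.is_leaf:
            if singleton_policy == "own":
                groups.append([node.label])
            return
        if node.support is not None and node.support >= min_support:
            groups.append([leaf.label for leaf in node.leaves()])
            return
        for child in node.children:
            collect(child)

    for child in crown.children:
        collect(child)
    return [Subfamily(index=i + 1, members=members)
            for i, members in enumerate(groups)]


def consensus_sequence(aligned_members: list, majority_threshold: float = 0.5) -> str:
    """Column-majority consensus of an aligned subfamily.

    Per column: the residue with relative frequency above the threshold,
    else ``x``; columns where gaps hold the majority are dropped.
    """
    if not aligned_members:
        raise ValueError("empty subfamily")
    if len({len(r) for r in aligned_members}) > 1:
        raise ValueError("members are not aligned")
    n = len(aligned_members)
    out = []
    for i in range(len(aligned_members[0])):
        col = [row[i] for row in aligned_members]
        n_gap = col.count(GAP)
        if n_gap / n > majority_threshold:
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        best = max(sorted(counts), key=lambda c: counts[c])
        out.append(best if counts[best] / n > majority_threshold else AMBIGUOUS)
    return "".join(out)


def assign_nomenclature(subfamilies: list, description_order: dict) -> dict:
    """Systematic names ``NaTx<subfamily>.<k>`` by description order.

    ``description_order`` maps taxon to its chronological rank (smaller =
    described earlier).  Trivial names are retained as the keys of the
    returned map.  Duplicate ranks within a subfamily are an error.
    """
    name_map: dict = {}
    for sf in subfamilies:
        try:
            ranks = {m: description_order[m] for m in sf.members}
        except KeyError as exc:
            raise ValueError(f"no description rank for taxon {exc}") from None
        if len(set(ranks.values())) != len(ranks):
            raise ValueError(f"duplicate description ranks in subfamily {sf.index}")
        ordered = sorted(sf.members, key=lambda m: ranks[m])
        sf.name_map = {m: f"NaTx{sf.index}.{k}" for k, m in enumerate(ordered, 1)}
        name_map.update(sf.name_map)
    return name_map


def report(subfamilies: list, sequences: dict,
           reconciliation=None) -> pd.DataFrame:
    """Per-member table: subfamily, names, identity to the first-described
    member, and mass-reconciliation status when available."""
    mass_status: dict = {}
    if reconciliation is not None:
        for pid, _, _, _, verdict in reconciliation.pairs:
            mass_status[pid] = verdict
        for pid, _ in reconciliation.unmatched_theoretical:
            mass_status[pid] = "unmatched"
    rows = []
    for sf in subfamilies:
        ordered = sorted(sf.members, key=lambda m: sf.name_map.get(m, m))
        if sf.name_map:
            ordered = sorted(sf.members,
                             key=lambda m: int(sf.name_map[m].split(".")[1]))
        anchor = ordered[0]
        for member in ordered:
            if member == anchor:
                ident = 100
            else:
                aln = global_align(sequences[member], sequences[anchor])
                ident = percent_identity(aln, reference="b")
            rows.append({
                "subfamily": sf.index,
                "taxon": member,
                "systematic_name": sf.name_map.get(member, ""),
                "identity_pct": ident,
                "consensus": sf.consensus,
                "mass_status": mass_status.get(member, ""),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published membership table


def load_membership_table(path: str | Path | None = None) -> pd.DataFrame:
    """The bundled subfamily membership table (subfamily 0 = outgroup)."""
    if path is None:
        with resources.files("natx.data").joinpath("subfamily_members.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def subfamilies_from_table(table: pd.DataFrame) -> list:
    """Build :class:`Subfamily` objects (ingroup only) from a membership
    table with ``subfamily``, ``taxon`` and ``rank`` columns."""
    subs = []
    for idx, grp in table[table["subfamily"] > 0].groupby("subfamily"):
        members = list(grp.sort_values("rank")["taxon"])
        subs.append(Subfamily(index=int(idx), members=members))
    ranks = {row.taxon: int(row.rank)
             for row in table[table["subfamily"] > 0].itertuples()}
    assign_nomenclature(subs, ranks)
    return subs
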