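"""Theoretical peptide masses with disulfide/amidation corrections.

Average and monoisotopic masses are computed from bundled residue tables
(``data/residue_masses.json``) so results are bit-stable across
environments.  Each disulfide bridge removes two hydrogens; C-terminal
amidation replaces the terminal hydroxyl with an amine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError

__all__ = [
    "MASS_TABLE_VERSION",
    "MassResult",
    "MassReconciliation",
    "average_mass",
    "monoisotopic_mass",
    "mass_result",
    "reconcile",
]


def _load_tables() -> dict:
    with resources.files("natx.data").joinpath("residue_masses.json").open() as fh:
        return json.load(fh)


_TABLES = _load_tables()
MASS_TABLE_VERSION: str = _TABLES["version"]

_AVG = _TABLES["average"]
_MONO = _TABLES["monoisotopic"]
_WATER_AVG = _TABLES["water_average"]
_WATER_MONO = _TABLES["water_monoisotopic"]
_SS_AVG = _TABLES["disulfide_average"]
_SS_MONO = _TABLES["disulfide_monoisotopic"]
_AMIDE_AVG = _TABLES["amidation_average"]
_AMIDE_MONO = _TABLES["amidation_monoisotopic"]


@dataclass(frozen=True)
class MassResult:
    """Theoretical masses for one mature peptide."""

    id: str
    average_da: float
    monoisotopic_da: float
    n_disulfides: int
    amidated: bool


@dataclass
class MassReconciliation:
    """Outcome of matching theoretical against experimental masses.

    ``pairs`` holds one ``(id, theoretical, experimental, delta, verdict)``
    tuple per match attempt; ``delta`` is experimental minus theoretical.
    """

    pairs: list = field(default_factory=list)
    unmatched_theoretical: list = field(default_factory=list)
    unmatched_experimental: list = field(default_factory=list)
    tolerance_da: float = 1.5

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": i, "theoretical_da": round(t, 1), "experimental_da": round(e, 1),
             "delta_da": round(d, 1), "verdict": v}
            for i, t, e, d, v in self.pairs
        ]
        for i, t in self.unmatched_theoretical:
            rows.append({"id": i, "theoretical_da": round(t, 1),
                         "experimental_da": None, "delta_da": None,
                         "verdict": "unmatched"})
        for i, e in self.unmatched_experimental:
            rows.append({"id": i, "theoretical_da": None,
                         "experimental_da": round(e, 1), "delta_da": None,
                         "verdict": "unmatched"})
        return pd.DataFrame(rows)


def _residue_sum(seq: str, table: dict) -> float:
    total = 0.0
    for aa in seq:
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"nonstandard residue {aa!r} in sequence") from None
    return total


def _check_bridges(seq: str, n_disulfides: int | None) -> int:
    n_cys = seq.count("C")
    if n_disulfides is None:
        n_disulfides = n_cys // 2
    if n_disulfides < 0 or 2 * n_disulfides > n_cys:
        raise ValueError(
            f"{n_disulfides} disulfides impossible with {n_cys} cysteines"
        )
    return n_disulfides


def average_mass(seq: str, n_disulfides: int | None = None,
                 amidated: bool = False) -> float:
    """Average molecular mass of a peptide in Da.

    ``n_disulfides`` defaults to ``n_cys // 2`` (all cysteines paired).
    """
    if not seq:
        raise ValueError("empty sequence")
    n_ss = _check_bridges(seq, n_disulfides)
    mass = _residue_sum(seq, _AVG) + _WATER_AVG - _SS_AVG * n_ss
    if amidated:
        mass += _AMIDE_AVG
    return mass


def monoisotopic_mass(seq: str, n_disulfides: int | None = None,
                      amidated: bool = False) -> float:
    """Monoisotopic molecular mass of a peptide in Da."""
    if not seq:
        raise ValueError("empty sequence")
    n_ss = _check_bridges(seq, n_disulfides)
    mass = _residue_sum(seq, _MONO) + _WATER_MONO - _SS_MONO * n_ss
    if amidated:
        mass += _AMIDE_MONO
    return mass


def mass_result(id: str, seq: str, n_disulfides: int | None = None,
                amidated: bool = False) -> MassResult:
    n_ss = _check_bridges(seq, n_disulfides)
    return MassResult(
        id=id,
        average_da=average_mass(seq, n_ss, amidated),
        monoisotopic_da=monoisotopic_mass(seq, n_ss, amidated),
        n_disulfides=n_ss,
        amidated=amidated,
    )


def read_experimental_table(path: str | Path) -> list[tuple[str, float]]:
    """Read a TSV with columns ``id`` and ``experimental_da``."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise FormatError(f"cannot parse experimental table {path}: {exc}") from exc
    if "id" not in df.columns or "experimental_da" not in df.columns:
        raise FormatError(
            "experimental table needs 'id' and 'experimental_da' columns"
        )
    try:
        masses = df["experimental_da"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric experimental mass: {exc}") from exc
    return list(zip(df["id"].astype(str), masses))


def reconcile(theoretical: Iterable[tuple[str, float]],
              experimental: Iterable[tuple[str, float]] | str | Path,
              tolerance_da: float = 1.5) -> MassReconciliation:
    """Greedy one-to-one matching of theoretical vs experimental masses.

    Candidate pairs within ``tolerance_da`` are accepted smallest-|delta|
    first; every theoretical and experimental entry is used at most once.
    Input order does not affect the result (ties broken by id).
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be positive")
    if isinstance(experimental, (str, Path)):
        experimental = read_experimental_table(experimental)
    theo = sorted(theoretical, key=lambda p: (p[0], p[1]))
    expm = sorted(experimental, key=lambda p: (p[0], p[1]))

    candidates = []
    for it, (tid, tmass) in enumerate(theo):
        for ie, (eid, emass) in enumerate(expm):
            delta = emass - tmass
            if abs(delta) <= tolerance_da:
                candidates.append((abs(delta), tid, eid, it, ie))
    candidates.sort()

    used_t: set[int] = set()
    used_e: set[int] = set()
    recon = MassReconciliation(tolerance_da=tolerance_da)
    for _, tid, eid, it, ie in candidates:
        if it in used_t or ie in used_e:
            continue
        used_t.add(it)
        used_e.add(ie)
        tmass, emass = theo[it][1], expm[ie][1]
        recon.pairs.append((tid, tmass, emass, emass - tmass, "match"))
    recon.unmatched_theoretical = [theo[i] for i in range(len(theo)) if i not in used_t]
    recon.unmatched_experimental = [expm[i] for i in range(len(expm)) if i not in used_e]
    return recon
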