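"""Protein net charge versus pH and isoelectric point.

A null-model Henderson-Hasselbalch titration: every titratable residue
(Asp, Glu, His, Cys, Tyr, Lys, Arg and the two termini) carries an
intrinsic pKa and titrates independently,

    Q(pH) = sum_bases 1 / (1 + 10^(pH - pKa))
          - sum_acids 1 / (1 + 10^(pKa - pH)).

Structure- and environment-dependent pKa shifts (the province of
semi-empirical predictors such as PropKa) are deliberately not modelled;
intrinsic pKa values can be overridden globally or per site to mimic
such shifts.  Q is strictly decreasing in pH, so the isoelectric point
is the unique root when both acids and bases are present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TitratableSite",
    "ChargeCurve",
    "DEFAULT_PKA",
    "sites_from_sequence",
    "net_charge",
    "isoelectric_point",
    "charge_curve",
]

#: Intrinsic pKa values of titratable groups (standard textbook table).
DEFAULT_PKA: dict[str, float] = {
    "Asp": 3.65,
    "Glu": 4.25,
    "His": 6.0,
    "Cys": 8.3,
    "Tyr": 10.1,
    "Lys": 10.5,
    "Arg": 12.5,
    "N-term": 9.0,
    "C-term": 3.6,
}

_ACIDS = frozenset({"Asp", "Glu", "Cys", "Tyr", "C-term"})
_BASES = frozenset({"His", "Lys", "Arg", "N-term"})

_LETTER_TO_KIND = {
    "D": "Asp",
    "E": "Glu",
    "H": "His",
    "C": "Cys",
    "Y": "Tyr",
    "K": "Lys",
    "R": "Arg",
}

_VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TitratableSite:
    """One ionizable group: residue class, pKa and acid/base character."""

    kind: str
    pKa: float
    is_acid: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.pKa <= 14.0):
            raise ValueError(f"pKa must lie in [0, 14], got {self.pKa}")


@dataclass(frozen=True)
class ChargeCurve:
    """Net protein charge Q(pH) on a pH grid, with its isoelectric point."""

    pH_grid: np.ndarray
    net_charge: np.ndarray
    pI: float | None

    def charge_at(self, pH: float) -> float:
        """Linear interpolation of Q at an arbitrary pH inside the grid."""
        return float(np.interp(pH, self.pH_grid, self.net_charge))


def sites_from_sequence(
    sequence: str,
    pka_table: Mapping[str, float] | None = None,
) -> tuple[TitratableSite, ...]:
    """Titratable sites of a one-letter amino-acid sequence plus termini."""
    table = dict(DEFAULT_PKA)
    if pka_table:
        table.update(pka_table)
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = [i for i, ch in enumerate(seq) if ch not in _VALID_LETTERS]
    if bad:
        raise ValueError(
            f"unknown amino-acid letters at positions {bad[:10]} in sequence"
        )
    sites = [
        TitratableSite("N-term", table["N-term"], is_acid=False),
        TitratableSite("C-term", table["C-term"], is_acid=True),
    ]
    for ch in seq:
        kind = _LETTER_TO_KIND.get(ch)
        if kind is not None:
            sites.append(TitratableSite(kind, table[kind], kind in _ACIDS))
    return tuple(sites)


def net_charge(sites: Sequence[TitratableSite], pH: float) -> float:
    """Henderson-Hasselbalch net charge in units of e."""
    if not sites:
        raise ValueError("no titratable sites")
    q = 0.0
    for s in sites:
        if s.is_acid:
            q -= 1.0 / (1.0 + 10.0 ** (s.pKa - pH))
        else:
            q += 1.0 / (1.0 + 10.0 ** (pH - s.pKa))
    return q


def isoelectric_point(
    sites: Sequence[TitratableSite], tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Requires at least one acid and one base so that Q changes sign.
    """
    if not any(s.is_acid for s in sites) or not any(not s.is_acid for s in sites):
        raise ValueError(
            "charge curve is single-signed (need both acidic and basic sites)"
        )
    q0 = net_charge(sites, 0.0)
    q14 = net_charge(sites, 14.0)
    if q0 * q14 > 0:
        raise ValueError("net charge does not change sign on [0, 14]")
    return float(brentq(lambda p: net_charge(sites, p), 0.0, 14.0, xtol=tol))


def charge_curve(
    sites: Sequence[TitratableSite],
    pH_grid: Iterable[float] | None = None,
) -> ChargeCurve:
    """Evaluate Q on a grid (default pH 2..12 in 0.25 steps) and locate pI."""
    grid = np.arange(2.0, 12.0 + 1e-9, 0.25) if pH_grid is None else np.asarray(
        list(pH_grid), dtype=float
    )
    q = np.array([net_charge(sites, p) for p in grid])
    try:
        pi = isoelectric_point(sites)
    except ValueError:
        pi = None
    return ChargeCurve(pH_grid=grid, net_charge=q, pI=pi)
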