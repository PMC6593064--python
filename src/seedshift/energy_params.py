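"""Nearest-neighbor free-energy parameters (37 degC, kcal/mol).

The bundled table is a Turner-2004-style set: Watson-Crick and G.U wobble
stacks, tabulated hairpin/bulge/internal loop initiation penalties with a
1.75*RT*ln(s/s0) logarithmic extrapolation beyond the tabulated sizes, an
affine multibranch-loop penalty, a duplex initiation term, and an AU/GU
helix-end penalty (applied at duplex ends).  All energies are stored
internally as integer centi-kcal/mol so that dynamic programming and
structure scoring are exact and tie-breaking is well defined.

Users can swap the whole table via a documented TSV file
(``EnergyModel.from_tsv``); the format is three columns ``kind  key  value``
where kind is one of stack / hairpin / bulge / internal / const.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

#: gas constant * 310.15 K, kcal/mol
RT37 = 0.0019872 * 310.15
#: prefactor of the Jacobson-Stockmayer loop-size extrapolation
LOOP_EXTRAPOLATION = 1.75 * RT37

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair-type codes; -1 marks a non-pairable combination
PAIR_STRINGS = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_CODE = {p: i for i, p in enumerate(PAIR_STRINGS)}
WOBBLE_CODES = frozenset({PAIR_CODE["GU"], PAIR_CODE["UG"],
                          PAIR_CODE["AU"], PAIR_CODE["UA"]})

PTYPE = np.full((4, 4), -1, dtype=np.int8)
for _p, _c in PAIR_CODE.items():
    PTYPE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _c


def _flip(pair: str) -> str:
    return pair[::-1]


# Generating set of stack free energies.  Key (closing, inner) means the
# closing pair (i, j) stacked over the inner pair (i+1, j-1); written as a
# helix this is 5'-close[0] inner[0]-3' / 3'-close[1] inner[1]-5'.  The
# remaining 15 of the 36 entries follow from the 180-degree rotational
# symmetry stack[p][q] == stack[flip(q)][flip(p)].
_RAW_STACKS: dict[tuple[str, str], float] = {
    # Watson-Crick over Watson-Crick
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # stacks involving a G.U wobble pair
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.80,
    ("GC", "UG"): -2.51,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): +1.29,
    ("UG", "GU"): -0.50,
}

_HAIRPIN37 = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE37 = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL37 = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0, 7: 2.2,
               8: 2.3, 9: 2.4, 10: 2.5}


def _centi(x: float) -> int:
    return int(round(x * 100))


def _expand_stacks(raw: dict[tuple[str, str], float]) -> np.ndarray:
    """Fill the 6x6 stack matrix (centi-kcal) from the generating set."""
    m = np.full((6, 6), 10**6, dtype=np.int64)
    for (close, inner), v in raw.items():
        i, j = PAIR_CODE[close], PAIR_CODE[inner]
        fi, fj = PAIR_CODE[_flip(inner)], PAIR_CODE[_flip(close)]
        cv = _centi(v)
        for a, b in ((i, j), (fi, fj)):
            if m[a, b] != 10**6 and m[a, b] != cv:
                raise ValueError(
                    f"inconsistent stack entry for {PAIR_STRINGS[a]}/{PAIR_STRINGS[b]}")
            m[a, b] = cv
    if (m == 10**6).any():
        missing = [(PAIR_STRINGS[a], PAIR_STRINGS[b])
                   for a, b in zip(*np.nonzero(m == 10**6))]
        raise ValueError(f"stack table incomplete: {missing}")
    return m


def _loop_table(tab: dict[int, float], max_size: int) -> np.ndarray:
    """Tabulated loop penalties extended by logarithmic extrapolation.

    Index s holds the penalty (centi-kcal) of a loop with s unpaired
    nucleotides; index 0 (and sizes below the table minimum) are +inf-like.
    """
    smax_tab = max(tab)
    out = np.full(max_size + 1, 10**6, dtype=np.int64)
    for s, v in tab.items():
        if s <= max_size:
            out[s] = _centi(v)
    anchor = tab[smax_tab]
    for s in range(smax_tab + 1, max_size + 1):
        out[s] = _centi(anchor + LOOP_EXTRAPOLATION * math.log(s / smax_tab))
    return out


@dataclass(frozen=True)
class EnergyModel:
    """A complete nearest-neighbor parameter set (integer centi-kcal/mol)."""

    stack: np.ndarray = field(default_factory=lambda: _expand_stacks(_RAW_STACKS))
    hairpin_tab: dict = field(default_factory=lambda: dict(_HAIRPIN37))
    bulge_tab: dict = field(default_factory=lambda: dict(_BULGE37))
    internal_tab: dict = field(default_factory=lambda: dict(_INTERNAL37))
    ml_close: int = _centi(3.4)     # multiloop closing penalty
    ml_branch: int = _centi(0.4)    # per branch, closing helix included
    ml_unpaired: int = 0            # per unpaired nucleotide in a multiloop
    duplex_init: int = _centi(4.09)
    au_end: int = _centi(0.5)       # AU/GU duplex helix-end penalty
    max_interior: int = 30          # interior/bulge loop size cap in the fold DP
    duplex_loop_cap: int = 4        # per-side interior loop cap in the duplex DP

    # --- loop penalties -------------------------------------------------
    def hairpin_array(self, n: int) -> np.ndarray:
        return _loop_table(self.hairpin_tab, max(n, 3))

    def bulge_array(self, n: int) -> np.ndarray:
        return _loop_table(self.bulge_tab, max(n, 1))

    def internal_array(self, n: int) -> np.ndarray:
        return _loop_table(self.internal_tab, max(n, 2))

    def hairpin(self, size: int) -> int:
        if size < 3:
            raise ValueError("hairpin loop must contain >= 3 unpaired bases")
        return int(self.hairpin_array(size)[size])

    def bulge(self, size: int) -> int:
        return int(self.bulge_array(size)[size])

    def internal(self, size: int) -> int:
        return int(self.internal_array(size)[size])

    def stack_energy(self, close_code: int, inner_code: int) -> int:
        return int(self.stack[close_code, inner_code])

    def end_penalty(self, pair_code: int) -> int:
        return self.au_end if pair_code in WOBBLE_CODES else 0

    # --- TSV round trip -------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergyModel":
        stacks: dict[tuple[str, str], float] = {}
        hp, bu, il = {}, {}, {}
        consts: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, key, value = line.split("\t")
            v = float(value)
            if kind == "stack":
                close, inner = key.split("/")
                stacks[(close, inner)] = v
            elif kind == "hairpin":
                hp[int(key)] = v
            elif kind == "bulge":
                bu[int(key)] = v
            elif kind == "internal":
                il[int(key)] = v
            elif kind == "const":
                consts[key] = v
            else:
                raise ValueError(f"unknown parameter kind {kind!r}")
        kwargs = {}
        for name in ("ml_close", "ml_branch", "ml_unpaired", "duplex_init", "au_end"):
            if name in consts:
                kwargs[name] = _centi(consts.pop(name))
        for name in ("max_interior", "duplex_loop_cap"):
            if name in consts:
                kwargs[name] = int(consts.pop(name))
        if consts:
            raise ValueError(f"unknown const entries {sorted(consts)}")
        return cls(stack=_expand_stacks(stacks) if stacks else _expand_stacks(_RAW_STACKS),
                   hairpin_tab=hp or dict(_HAIRPIN37),
                   bulge_tab=bu or dict(_BULGE37),
                   internal_tab=il or dict(_INTERNAL37),
                   **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# seedshift nearest-neighbor parameters (kcal/mol, 37C)"]
        for (close, inner) in sorted(_RAW_STACKS):
            v = self.stack[PAIR_CODE[close], PAIR_CODE[inner]] / 100
            lines.append(f"stack\t{close}/{inner}\t{v:.2f}")
        for kind, tab in (("hairpin", self.hairpin_tab),
                          ("bulge", self.bulge_tab),
                          ("internal", self.internal_tab)):
            for s in sorted(tab):
                lines.append(f"{kind}\t{s}\t{tab[s]:.2f}")
        for name in ("ml_close", "ml_branch", "ml_unpaired", "duplex_init", "au_end"):
            lines.append(f"const\t{name}\t{getattr(self, name) / 100:.2f}")
        lines.append(f"const\tmax_interior\t{self.max_interior}")
        lines.append(f"const\tduplex_loop_cap\t{self.duplex_loop_cap}")
        Path(path).write_text("\n".join(lines) + "\n")


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    return EnergyModel()


def encode(residues: str) -> np.ndarray:
    """Residue string -> int codes (A=0 C=1 G=2 U=3)."""
    return np.fromiter((BASE_INDEX[b] for b in residues), dtype=np.int8,
                       count=len(residues))


def pair_code(b1: str, b2: str) -> int:
    return int(PTYPE[BASE_INDEX[b1], BASE_INDEX[b2]])
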