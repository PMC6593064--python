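"""Intermolecular miRNA:target hybridization energy.

A duplex is a single contiguous helix interrupted by bulges/interior loops
(each side capped at ``model.duplex_loop_cap`` unpaired bases), scored with
the same stack and loop tables as intramolecular folding, plus a duplex
initiation term and an AU/GU penalty at each helix end.  Intramolecular
structure of either strand is not part of this term; site accessibility is
accounted for separately via the constrained fold (two-step decomposition).

A hybridization is only reported when its total free energy is below zero;
otherwise the result is "no binding" with energy 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy_params import PTYPE, EnergyModel, default_model, encode
from .sequences import NucSequence


@dataclass(frozen=True)
class DuplexResult:
    """Hybridization energy (kcal/mol) with the base-pairing trace.

    ``pairs`` holds (miRNA index, target index) tuples, both 0-based 5'->3'
    on their own strand; miRNA indices increase while target indices
    decrease along the helix (antiparallel duplex).  Empty pairs = no
    binding.
    """

    energy: float
    pairs: tuple = field(default_factory=tuple)

    @property
    def bound(self) -> bool:
        return bool(self.pairs)


def duplex_energy(mirna: NucSequence | str, site: NucSequence | str,
                  model: EnergyModel | None = None) -> DuplexResult:
    """Minimum hybridization energy between a miRNA and a target site."""
    model = model or default_model()
    m = mirna.residues if isinstance(mirna, NucSequence) else NucSequence("_", mirna).residues
    t = site.residues if isinstance(site, NucSequence) else NucSequence("_", site).residues
    if not m or not t:
        return DuplexResult(0.0)
    mi = encode(m)
    ti = encode(t)
    cap = model.duplex_loop_cap
    bu = model.bulge_array(2 * cap)
    il = model.internal_array(2 * cap)

    BIG = 10**9
    nm, nt = len(m), len(t)
    # D[i][j]: best energy of a duplex whose last pair (3'-most on the miRNA)
    # is (i, j); includes initiation and the penalty of the starting end.
    D = [[BIG] * nt for _ in range(nm)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    best_total = BIG
    best_cell = None
    for i in range(nm):
        for j in range(nt - 1, -1, -1):
            p = int(PTYPE[mi[i], ti[j]])
            if p < 0:
                continue
            val = model.duplex_init + model.end_penalty(p)
            parent = None
            for i0 in range(max(0, i - cap - 1), i):
                row = D[i0]
                for j0 in range(j + 1, min(nt, j + cap + 2)):
                    prev = row[j0]
                    if prev >= BIG:
                        continue
                    g1, g2 = i - i0 - 1, j0 - j - 1
                    if g1 == 0 and g2 == 0:
                        q0 = int(PTYPE[mi[i0], ti[j0]])
                        cost = model.stack_energy(q0, p)
                    elif g1 == 0 or g2 == 0:
                        cost = int(bu[g1 + g2])
                    else:
                        cost = int(il[g1 + g2])
                    cand = prev + cost
                    if cand < val:
                        val = cand
                        parent = (i0, j0)
            D[i][j] = val
            back[(i, j)] = parent
            total = val + model.end_penalty(p)
            if total < best_total:
                best_total = total
                best_cell = (i, j)

    if best_cell is None or best_total >= 0:
        return DuplexResult(0.0)
    pairs = []
    cell = best_cell
    while cell is not None:
        pairs.append(cell)
        cell = back[cell]
    pairs.sort()
    return DuplexResult(best_total / 100.0, tuple(pairs))
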