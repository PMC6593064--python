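"""Minimum-free-energy RNA secondary structure by Zuker-style dynamic
programming, with optional hard "forced unpaired" constraints.

Model (see :mod:`seedshift.energy_params` for parameters):

* legal pairs: Watson-Crick and G.U, hairpin loops >= 3 unpaired;
* loop decomposition: hairpin, helix stack, bulge/interior loop (penalty a
  function of total unpaired size, capped at ``model.max_interior`` in the
  search), multibranch loop with affine penalty a + b*(branches) +
  c*(unpaired), external bases free;
* no pseudoknots, no dangles, no coaxial stacking.

Energies are integer centi-kcal/mol.  The DP state packs
``energy*64 + number_of_pairs`` into one int64, so the optimum is the
lexicographic minimum of (energy, pair count): among iso-energetic optima the
structure with the fewest pairs is returned, with remaining ties resolved by
a fixed traceback option order.  ``structure_energy`` scores an explicit
dot-bracket under exactly the same model and is the reference the DP is
tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_params import PTYPE, EnergyModel, default_model, encode
from .sequences import NucSequence

INF = np.int64(1) << 40
_CUT = np.int64(1) << 39
_SCALE = 64
_OFF = 32  # padding so interior-loop slices never leave the array


class StructureError(ValueError):
    """Raised for ill-formed dot-bracket structures."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing secondary structure with its free energy."""

    dotbracket: str
    energy: float  # kcal/mol
    n_pairs: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_dotbracket(self.dotbracket)

    def vienna(self, seq: NucSequence) -> str:
        """Vienna-style two-line record: sequence, then structure (energy)."""
        return f"{seq.residues}\n{self.dotbracket} ({self.energy:.2f})"


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise StructureError("unbalanced ')' in dot-bracket")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} in dot-bracket")
    if stack:
        raise StructureError("unbalanced '(' in dot-bracket")
    return sorted(pairs)


def dotbracket_from_pairs(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def _pack(centi: int, npairs: int = 0) -> np.int64:
    return np.int64(centi * _SCALE + npairs)


def _unpack(packed) -> tuple[int, int]:
    q, r = divmod(int(packed), _SCALE)
    return q, r


def _interior_penalty_matrix(model: EnergyModel) -> np.ndarray:
    """Packed bulge/interior penalties indexed [d1, 30-d2] to match the
    V-submatrix slice orientation used in the fill loop."""
    cap = model.max_interior
    bu = model.bulge_array(cap)
    il = model.internal_array(cap)
    P = np.full((cap + 1, cap + 1), INF, dtype=np.int64)
    for d1 in range(cap + 1):
        for d2 in range(cap + 1):
            s = d1 + d2
            if s < 1 or s > cap:
                continue
            if d1 == 0 or d2 == 0:
                P[d1, d2] = _pack(int(bu[s]))
            else:
                P[d1, d2] = _pack(int(il[s]))
    return P[:, ::-1].copy()


def _fill(seq: str, model: EnergyModel, forced: np.ndarray):
    """Run the DP fill; returns (V, M, W, tables-needed-for-traceback)."""
    n = len(seq)
    idx = encode(seq)
    pt = PTYPE[idx[:, None], idx[None, :]]  # pair type of (i, j); -1 illegal
    N = n + 2 * _OFF
    V = np.full((N, N), INF, dtype=np.int64)
    M = np.full((N, N), INF, dtype=np.int64)
    stack_p = model.stack.astype(np.int64) * _SCALE
    hp = model.hairpin_array(n)
    hp_p = hp.astype(np.int64) * _SCALE
    P2 = _interior_penalty_matrix(model)
    cap = model.max_interior
    ml_cb = _pack(model.ml_close + model.ml_branch)
    b_p = _pack(model.ml_branch)
    c_p = _pack(model.ml_unpaired)

    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            p = int(pt[i, j])
            o_i, o_j = _OFF + i, _OFF + j
            if p >= 0 and not forced[i] and not forced[j]:
                best = hp_p[span - 1] if span - 1 >= 3 else INF
                # helix stack
                q = int(pt[i + 1, j - 1])
                inner = V[o_i + 1, o_j - 1]
                if q >= 0 and inner < _CUT:
                    cand = inner + stack_p[p, q]
                    if cand < best:
                        best = cand
                # bulge / interior loops (size-capped)
                sub = V[o_i + 1: o_i + cap + 2, o_j - cap - 1: o_j]
                cand = (sub + P2).min()
                if cand < best:
                    best = cand
                # multibranch closure: a + b + min_k M(i+1,k-1) + M(k,j-1)
                if span >= 10:
                    A = M[o_i + 1, o_i + 1: o_j - 2]
                    B = M[o_i + 2: o_j - 1, o_j - 1]
                    if A.size:
                        cand = (A + B).min() + ml_cb
                        if cand < best:
                            best = cand
                if best < _CUT:
                    V[o_i, o_j] = best + 1  # +1: the (i, j) pair itself

            # multiloop segment with >= 1 branch
            m = min(M[o_i + 1, o_j] + c_p, M[o_i, o_j - 1] + c_p)
            v = V[o_i, o_j]
            if v < _CUT and v + b_p < m:
                m = v + b_p
            A = M[o_i, o_i: o_j]
            B = M[o_i + 1: o_j + 1, o_j]
            cand = (A + B).min()
            if cand < m:
                m = cand
            if m < _CUT:
                M[o_i, o_j] = m

    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        best = W[j - 1]
        col = V[_OFF: _OFF + j, _OFF + j - 1]
        cand = (W[:j] + col).min()
        W[j] = min(best, cand)
    return V, M, W, pt, stack_p, hp_p, ml_cb, b_p, c_p, cap


def _traceback(n, V, M, W, pt, stack_p, hp_p, ml_cb, b_p, c_p, cap,
               bulge_p, internal_p) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    agenda: list[tuple[str, int, int]] = [("W", 0, n)]
    while agenda:
        tag, i, j = agenda.pop()
        if tag == "W":
            while j > 0:
                if W[j] == W[j - 1]:
                    j -= 1
                    continue
                for k in range(1, j + 1):
                    if W[k - 1] + V[_OFF + k - 1, _OFF + j - 1] == W[j]:
                        agenda.append(("V", k - 1, j - 1))
                        j = k - 1
                        break
                else:  # pragma: no cover - defensive
                    raise AssertionError("traceback failed in W")
        elif tag == "V":
            pairs.append((i, j))
            t = V[_OFF + i, _OFF + j] - 1
            span = j - i
            if span - 1 >= 3 and t == hp_p[span - 1]:
                continue
            p = int(pt[i, j])
            q = int(pt[i + 1, j - 1])
            if q >= 0 and V[_OFF + i + 1, _OFF + j - 1] + stack_p[p, q] == t:
                agenda.append(("V", i + 1, j - 1))
                continue
            found = False
            for size in range(1, cap + 1):
                for d1 in range(0, size + 1):
                    d2 = size - d1
                    k, l = i + 1 + d1, j - 1 - d2
                    if not (i < k < l < j) or l - k < 4:
                        continue
                    pen = bulge_p[size] if (d1 == 0 or d2 == 0) else internal_p[size]
                    if V[_OFF + k, _OFF + l] + _pack(int(pen)) == t:
                        agenda.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 1):
                if M[_OFF + i + 1, _OFF + k - 1] + M[_OFF + k, _OFF + j - 1] + ml_cb == t:
                    agenda.append(("M", i + 1, k - 1))
                    agenda.append(("M", k, j - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in V")
        else:  # M
            while True:
                m = M[_OFF + i, _OFF + j]
                if M[_OFF + i + 1, _OFF + j] + c_p == m:
                    i += 1
                    continue
                if M[_OFF + i, _OFF + j - 1] + c_p == m:
                    j -= 1
                    continue
                if V[_OFF + i, _OFF + j] + b_p == m:
                    agenda.append(("V", i, j))
                    break
                for k in range(i + 1, j + 1):
                    if M[_OFF + i, _OFF + k - 1] + M[_OFF + k, _OFF + j] == m:
                        agenda.append(("M", i, k - 1))
                        agenda.append(("M", k, j))
                        break
                else:  # pragma: no cover - defensive
                    raise AssertionError("traceback failed in M")
                break
    return sorted(pairs)


def _fold(seq: str, model: EnergyModel, forced: np.ndarray) -> SecondaryStructure:
    n = len(seq)
    if n < 5:
        return SecondaryStructure("." * n, 0.0, 0)
    V, M, W, pt, stack_p, hp_p, ml_cb, b_p, c_p, cap = _fill(seq, model, forced)
    centi, npairs = _unpack(W[n])
    bulge_p = model.bulge_array(cap)
    internal_p = model.internal_array(cap)
    pairs = _traceback(n, V, M, W, pt, stack_p, hp_p, ml_cb, b_p, c_p, cap,
                       bulge_p, internal_p)
    assert len(pairs) == npairs
    return SecondaryStructure(dotbracket_from_pairs(n, pairs), centi / 100.0, npairs)


def mfe_fold(seq: NucSequence | str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-free-energy structure of a single strand (open chain = 0)."""
    model = model or default_model()
    s = seq.residues if isinstance(seq, NucSequence) else NucSequence("_", seq).residues
    forced = np.zeros(len(s), dtype=bool)
    return _fold(s, model, forced)


def constrained_mfe(seq: NucSequence | str, unpaired: tuple[int, int],
                    model: EnergyModel | None = None) -> SecondaryStructure:
    """MFE over structures leaving the half-open interval ``unpaired`` free.

    The forced-unpaired interval models the transition state in which the
    miRNA binding site is opened; with an empty interval this is identical
    to :func:`mfe_fold`.
    """
    model = model or default_model()
    s = seq.residues if isinstance(seq, NucSequence) else NucSequence("_", seq).residues
    start, end = unpaired
    if not (0 <= start <= end <= len(s)):
        raise ValueError(f"constraint interval {unpaired} outside sequence of length {len(s)}")
    forced = np.zeros(len(s), dtype=bool)
    forced[start:end] = True
    return _fold(s, model, forced)


# ---------------------------------------------------------------------------
# explicit structure scoring (the model's definition, independent of the DP)
# ---------------------------------------------------------------------------

def structure_energy_centi(seq: str, dotbracket: str,
                           model: EnergyModel | None = None) -> int:
    """Score an explicit structure, in centi-kcal/mol.

    Loops are scored exactly as in the DP decomposition; the interior-loop
    size cap does *not* apply here (oversized loops get the extrapolated
    penalty), so this function also scores structures the search would not
    propose.
    """
    model = model or default_model()
    if len(dotbracket) != len(seq):
        raise StructureError("structure/sequence length mismatch")
    pairs = pairs_from_dotbracket(dotbracket)
    partner = {}
    for i, j in pairs:
        if PTYPE[encode(seq[i])[0], encode(seq[j])[0]] < 0:
            raise StructureError(f"illegal pair {seq[i]}{i}-{seq[j]}{j}")
        partner[i] = j
        partner[j] = i
    total = 0
    big = max(len(seq) + 1, 31)
    hp = model.hairpin_array(big)
    bu = model.bulge_array(big)
    il = model.internal_array(big)
    for i, j in pairs:
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        p = PTYPE[encode(seq[i])[0], encode(seq[j])[0]]
        if not children:
            size = j - i - 1
            if size < 3:
                raise StructureError(f"hairpin loop of size {size} at ({i},{j})")
            total += int(hp[size])
        elif len(children) == 1:
            (k, l) = children[0]
            d1, d2 = k - i - 1, j - 1 - l
            if d1 == 0 and d2 == 0:
                q = PTYPE[encode(seq[k])[0], encode(seq[l])[0]]
                total += model.stack_energy(int(p), int(q))
            elif d1 == 0 or d2 == 0:
                total += int(bu[d1 + d2])
            else:
                total += int(il[d1 + d2])
        else:
            total += (model.ml_close
                      + model.ml_branch * (len(children) + 1)
                      + model.ml_unpaired * unpaired)
    return total


def structure_energy(seq: NucSequence | str, dotbracket: str,
                     model: EnergyModel | None = None) -> float:
    s = seq.residues if isinstance(seq, NucSequence) else NucSequence("_", seq).residues
    return structure_energy_centi(s, dotbracket, model) / 100.0
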