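"""Independent brute-force oracles used to validate the dynamic programs
and the exact test.  These deliberately use naive enumeration (and exact
rational arithmetic for the hypergeometric sum) so they share no search
logic with the implementations they check."""

from fractions import Fraction
from functools import lru_cache
from math import comb

from seedshift.energy_params import default_model, pair_code
from seedshift.fold import dotbracket_from_pairs, structure_energy_centi


def enumerate_pairsets(seq, forced=frozenset()):
    """All non-crossing sets of legal pairs (hairpin >= 3 unpaired)."""
    n = len(seq)

    def ok(i, j):
        return (i not in forced and j not in forced and j - i >= 4
                and pair_code(seq[i], seq[j]) >= 0)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if j - i < 4:
            return [()]
        res = list(rec(i + 1, j))
        for k in range(i + 4, j + 1):
            if ok(i, k):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        res.append(((i, k),) + left + right)
        return res

    out = rec(0, n - 1) if n >= 5 else [()]
    rec.cache_clear()
    return out


def oracle_mfe(seq, forced=frozenset(), model=None):
    """(energy_centi, n_pairs, dotbracket) minimizing (energy, pairs)."""
    model = model or default_model()
    best = (0, 0, "." * len(seq))
    for ps in enumerate_pairsets(seq, forced):
        db = dotbracket_from_pairs(len(seq), ps)
        e = structure_energy_centi(seq, db, model)
        if (e, len(ps)) < best[:2]:
            best = (e, len(ps), db)
    return best


def oracle_duplex(m, t, model=None):
    """Minimum duplex energy (kcal/mol) over all pair chains; 0 = no binding."""
    model = model or default_model()
    cap = model.duplex_loop_cap
    bu = model.bulge_array(2 * cap)
    il = model.internal_array(2 * cap)
    nm, nt = len(m), len(t)
    best = 0

    def score(chain):
        e = model.duplex_init
        e += model.end_penalty(pair_code(m[chain[0][0]], t[chain[0][1]]))
        e += model.end_penalty(pair_code(m[chain[-1][0]], t[chain[-1][1]]))
        for (a, b), (c, d) in zip(chain, chain[1:]):
            g1, g2 = c - a - 1, b - d - 1
            if g1 == 0 and g2 == 0:
                e += model.stack_energy(pair_code(m[a], t[b]), pair_code(m[c], t[d]))
            elif g1 == 0 or g2 == 0:
                e += int(bu[g1 + g2])
            else:
                e += int(il[g1 + g2])
        return e

    def extend(chain):
        nonlocal best
        best = min(best, score(chain))
        i0, j0 = chain[-1]
        for i in range(i0 + 1, min(nm, i0 + cap + 2)):
            for j in range(max(0, j0 - cap - 1), j0):
                if pair_code(m[i], t[j]) >= 0:
                    extend(chain + [(i, j)])

    for i in range(nm):
        for j in range(nt):
            if pair_code(m[i], t[j]) >= 0:
                extend([(i, j)])
    return best / 100


def oracle_fisher(a, b, c, d):
    """Two-sided Fisher exact p by exact-rational hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
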