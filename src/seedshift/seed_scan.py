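"""Canonical miRNA seed-site scanning and SNP effect classification.

Seed classes follow the canonical TargetScan-style hierarchy.  The seed is
miRNA positions 2-8 (1-based, from the 5' end of the mature guide strand);
a site on the target (read 5'->3') is the reverse complement of the seed:

* 8mer     -- Watson-Crick match to positions 2-8 plus an A opposite
              position 1 (the A is required on the target regardless of the
              miRNA base);
* 7mer-m8  -- match to positions 2-8;
* 7mer-A1  -- match to positions 2-7 plus the A1 anchor;
* 6mer     -- match to positions 2-7 only.

Matches are strict Watson-Crick by default; ``allow_wobble=True`` also
accepts G.U pairs in the seed.  Coordinates are 0-based half-open on the
provided window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .sequences import NucSequence, SequenceError, complement

SEED_CLASSES = ("none", "6mer", "7mer-A1", "7mer-m8", "8mer")
SEED_RANK = {c: r for r, c in enumerate(SEED_CLASSES)}

EFFECT_LABELS = ("site_created", "site_destroyed", "class_up", "class_down", "no_change")

_WOBBLE_MATCH = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class SNPVariant:
    """A biallelic substitution at a 0-based position of a target window."""

    snp_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise SequenceError("ref and alt alleles must differ")

    def check_window(self, window: NucSequence) -> None:
        if not 0 <= self.position < len(window):
            raise SequenceError(
                f"{self.snp_id}: position {self.position} outside window of length {len(window)}")
        if window[self.position] != self.ref_allele:
            raise SequenceError(
                f"{self.snp_id}: window has {window[self.position]!r} at {self.position}, "
                f"expected ref allele {self.ref_allele!r}")


@dataclass(frozen=True)
class SeedSite:
    """A located seed match: 0-based half-open interval on the window."""

    target_interval: tuple[int, int]
    seed_class: str
    mirna_id: str
    window_id: str = ""
    snp_in_seed: bool = False

    @property
    def rank(self) -> int:
        return SEED_RANK[self.seed_class]

    def overlaps(self, position: int) -> bool:
        return self.target_interval[0] <= position < self.target_interval[1]


def _matches(target_base: str, mirna_base: str, allow_wobble: bool) -> bool:
    if target_base == complement(mirna_base):
        return True
    return allow_wobble and (target_base, mirna_base) in _WOBBLE_MATCH


def scan_seed_sites(window: NucSequence, mirna: NucSequence,
                    allow_wobble: bool = False) -> list[SeedSite]:
    """All seed matches of ``mirna`` in ``window``, strongest class per locus.

    Overlapping candidate sites are deduplicated to the strongest class
    (ties to the 5'-most site); disjoint sites are all reported in
    coordinate order.
    """
    if len(mirna) < 8:
        raise SequenceError("miRNA must be at least 8 nt to define a seed")
    w = window.residues
    if len(w) < 6:
        warnings.warn(f"window {window.id!r} shorter than 6 nt; no seed scan performed")
        return []
    # core = positions 2-7; target segment [s, s+6) pairs core antiparallel:
    # window[s + k] pairs miRNA position (7 - k), k = 0..5
    core = mirna.residues[1:7]
    m8 = mirna.residues[7]
    candidates: list[SeedSite] = []
    for s in range(0, len(w) - 5):
        if not all(_matches(w[s + k], core[5 - k], allow_wobble) for k in range(6)):
            continue
        has_m8 = s - 1 >= 0 and _matches(w[s - 1], m8, allow_wobble)
        has_a1 = s + 6 < len(w) and w[s + 6] == "A"
        if has_m8 and has_a1:
            cls, iv = "8mer", (s - 1, s + 7)
        elif has_m8:
            cls, iv = "7mer-m8", (s - 1, s + 6)
        elif has_a1:
            cls, iv = "7mer-A1", (s, s + 7)
        else:
            cls, iv = "6mer", (s, s + 6)
        candidates.append(SeedSite(iv, cls, mirna.id, window.id))
    # deduplicate overlapping candidates to the strongest
    candidates.sort(key=lambda st: st.target_interval)
    result: list[SeedSite] = []
    for site in candidates:
        if result and site.target_interval[0] < result[-1].target_interval[1]:
            if site.rank > result[-1].rank:
                result[-1] = site
        else:
            result.append(site)
    return result


def best_site_at(sites: list[SeedSite], position: int) -> SeedSite | None:
    """Strongest site overlapping ``position`` (ties to the 5'-most)."""
    over = [s for s in sites if s.overlaps(position)]
    if not over:
        return None
    return max(over, key=lambda s: (s.rank, -s.target_interval[0]))


def classify_snp_effect(window: NucSequence, snp: SNPVariant, mirna: NucSequence,
                        allow_wobble: bool = False,
                        ) -> tuple[SeedSite | None, SeedSite | None, str]:
    """Compare seed sites at the SNP locus between the two alleles.

    Returns the best SNP-overlapping site in the ref- and alt-allele windows
    (None when absent, i.e. seed class "none") and an effect label for the
    ref -> alt change: site_created / site_destroyed / class_up /
    class_down / no_change.
    """
    snp.check_window(window)
    window_alt = window.with_substitution(snp.position, snp.alt_allele,
                                          id=f"{window.id}|{snp.snp_id}:{snp.alt_allele}")
    sites_ref = scan_seed_sites(window, mirna, allow_wobble)
    sites_alt = scan_seed_sites(window_alt, mirna, allow_wobble)
    ref_site = best_site_at(sites_ref, snp.position)
    alt_site = best_site_at(sites_alt, snp.position)

    # same-locus fallback: a SNP at the m8/A1 flank of one allele's site can
    # fall just outside the other allele's (shorter-class) interval
    def _best_overlapping(sites, interval):
        over = [s for s in sites
                if s.target_interval[0] < interval[1] and interval[0] < s.target_interval[1]]
        return max(over, key=lambda s: (s.rank, -s.target_interval[0])) if over else None

    if ref_site is None and alt_site is not None:
        ref_site = _best_overlapping(sites_ref, alt_site.target_interval)
    elif alt_site is None and ref_site is not None:
        alt_site = _best_overlapping(sites_alt, ref_site.target_interval)
    if ref_site is not None:
        ref_site = replace(ref_site, snp_in_seed=True)
    if alt_site is not None:
        alt_site = replace(alt_site, snp_in_seed=True)
    r = ref_site.rank if ref_site else 0
    a = alt_site.rank if alt_site else 0
    if r == a:
        label = "no_change"
    elif r == 0:
        label = "site_created"
    elif a == 0:
        label = "site_destroyed"
    elif a > r:
        label = "class_up"
    else:
        label = "class_down"
    return ref_site, alt_site, label
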