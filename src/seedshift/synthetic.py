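"""Synthetic data generators with the statistical structure the analysis
pipeline assumes, so every stage runs and is testable without external data.

Three generators:

* :func:`gen_genotypes` -- a case-control cohort under Hardy-Weinberg
  controls and a multiplicative per-allele risk model in cases.  Defaults
  mirror the study the pipeline emulates: 66 cases / 42 controls, control
  risk-allele frequency 0.357, allele odds ratio 1.8.
* :func:`gen_expression` -- per-sample qPCR Ct pairs back-computed so that
  2^-dCt recovers the intended log10 expression exactly; target expression
  shifts down per risk allele, and miRNA levels are negatively correlated
  with the target (shared latent factor, analytically tuned to a target
  within-genotype R^2; default 0.255).
* :func:`gen_snp_window` -- a target UTR window carrying a perfect seed
  site for a random miRNA in the alt allele, broken by the ref allele at a
  chosen offset inside the seed heptamer (default window 60 nt).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seed_scan import SNPVariant, best_site_at, scan_seed_sites
from .sequences import NucSequence, complement, random_rna, reverse_complement

GENOTYPES = ("CC", "CT", "TT")  # 0, 1, 2 copies of the risk allele T

_LOG2_10 = math.log2(10.0)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling model for a case-control cohort at one biallelic SNP."""

    n_cases: int = 66
    n_controls: int = 42
    control_allele_freq: float = 0.357   # risk (T) allele frequency in controls
    allele_or: float = 1.8               # multiplicative per-allele odds ratio
    snp_id: str = "snp_sim"
    seed: int = 0

    def genotype_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(control, case) genotype probability vectors for 0/1/2 risk alleles."""
        q = self.control_allele_freq
        if not 0.0 < q < 1.0:
            raise ValueError("control_allele_freq must lie strictly in (0, 1)")
        if self.allele_or <= 0:
            raise ValueError("allele_or must be positive")
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        w = hwe * self.allele_or ** np.arange(3)
        return hwe, w / w.sum()


@dataclass(frozen=True)
class ExpressionSpec:
    """Allele-dependent expression model on the log10 relative-expression scale."""

    base_log10_mean: float = -1.5      # CC-genotype mean of log10(2^-dCt)
    per_T_allele_shift: float = -0.3   # expression drop per risk allele
    noise_sd: float = 0.3
    mirna_target_r2: float = 0.255     # within-genotype squared correlation
    mirna_log10_mean: float = -2.0
    mirna_log10_sd: float = 0.3
    ct_reference: float = 20.0
    cell_type: str = "B"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.mirna_target_r2 < 1.0:
            raise ValueError("mirna_target_r2 must lie in [0, 1)")


@dataclass(frozen=True)
class SequenceSpec:
    """A UTR window with an embedded allele-toggled seed site."""

    window_len: int = 60
    gc_background: float = 0.5
    mirna_len: int = 22
    snp_offset_in_seed: int = 3   # 0-based within the 7-nt m8..m2 stretch
    snp_id: str = "snp_sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mirna_len < 18:
            raise ValueError("mirna_len must be >= 18 (a mature miRNA)")
        if not 0 <= self.snp_offset_in_seed < 7:
            raise ValueError("snp_offset_in_seed must lie in [0, 7)")
        if self.window_len < 12:
            raise ValueError("window too short to embed a seed site")


# ---------------------------------------------------------------------------

def gen_genotype_counts(spec: CohortSpec) -> pd.DataFrame:
    """Genotype counts per group drawn from the cohort model
    (columns snp_id, genotype, case_n, control_n)."""
    rng = np.random.default_rng(spec.seed)
    p_control, p_case = spec.genotype_probs()
    case_n = rng.multinomial(spec.n_cases, p_case)
    control_n = rng.multinomial(spec.n_controls, p_control)
    return pd.DataFrame({"snp_id": spec.snp_id, "genotype": GENOTYPES,
                         "case_n": case_n, "control_n": control_n})


def gen_genotypes(spec: CohortSpec) -> pd.DataFrame:
    """Per-sample genotype records (sample_id, group, <snp_id>)."""
    counts = gen_genotype_counts(spec)
    rows = []
    for group, col in (("case", "case_n"), ("control", "control_n")):
        k = 0
        for geno, n in zip(counts["genotype"], counts[col]):
            for _ in range(int(n)):
                rows.append({"sample_id": f"{group}{k:04d}", "group": group,
                             spec.snp_id: geno})
                k += 1
    return pd.DataFrame(rows, columns=["sample_id", "group", spec.snp_id])


def gen_expression(genotypes: pd.DataFrame, spec: ExpressionSpec,
                   snp_col: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct records plus the underlying true log10 levels.

    Returns ``(ct_records, levels)``.  ``ct_records`` holds one target-gene
    row and one miRNA row per sample in CtRecord layout; Ct pairs are
    back-computed so 2^-dCt reproduces the intended relative expression
    exactly.  ``levels`` carries the generating log10 values for testing.

    The miRNA level shares the target's within-genotype residual z with
    loading -sqrt(R^2), so the squared correlation between miRNA and target
    inside any genotype class targets ``mirna_target_r2`` with a negative
    sign, while genotype shifts affect only the target.
    """
    if snp_col is None:
        snp_col = [c for c in genotypes.columns if c not in ("sample_id", "group")][0]
    rng = np.random.default_rng(spec.seed)
    n = len(genotypes)
    g = genotypes[snp_col].astype(str).str.count("T").to_numpy()
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    target_log10 = spec.base_log10_mean + spec.per_T_allele_shift * g + spec.noise_sd * z
    r = math.sqrt(spec.mirna_target_r2)
    mirna_log10 = (spec.mirna_log10_mean
                   + spec.mirna_log10_sd * (-r * z + math.sqrt(1 - spec.mirna_target_r2) * eps))

    def back_ct(log10_level: np.ndarray) -> np.ndarray:
        # rel = 10^log10 = 2^-dCt  =>  ct_target = ct_reference - log2(10)*log10
        return spec.ct_reference - _LOG2_10 * log10_level

    base = genotypes[["sample_id", "group"]].copy()
    base["cell_type"] = spec.cell_type
    base["genotype"] = genotypes[snp_col].to_numpy()
    rows = []
    for gene, levels in (("target", target_log10), ("mirna", mirna_log10)):
        blk = base.copy()
        blk["gene"] = gene
        blk["ct_target"] = back_ct(levels)
        blk["ct_reference"] = spec.ct_reference
        rows.append(blk)
    ct_records = pd.concat(rows, ignore_index=True)
    levels = base.copy()
    levels["target_log10"] = target_log10
    levels["mirna_log10"] = mirna_log10
    return ct_records, levels


def gen_snp_window(spec: SequenceSpec) -> tuple[NucSequence, NucSequence, SNPVariant, NucSequence]:
    """(window_ref, window_alt, snp, mirna) with an allele-toggled 8mer site.

    The alt allele completes a perfect 8mer seed site for a freshly drawn
    miRNA; the ref allele carries a non-pairing base at
    ``snp_offset_in_seed`` within the seed heptamer, so the two windows
    differ at exactly one position.  Backgrounds are redrawn (bounded) if a
    spurious seed match survives at the SNP locus in the ref window.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.window_len
    site_len = 8
    start = (L - site_len) // 2
    snp_pos = start + spec.snp_offset_in_seed

    for _ in range(64):
        mirna_res = random_rna(rng, spec.mirna_len, gc=0.5)
        # guarantee some seed GC content so a perfect duplex is stably negative
        seed27 = list(mirna_res[1:8])
        if sum(b in "GC" for b in seed27) < 2:
            continue
        site = reverse_complement(mirna_res[1:8]) + "A"   # m8..m2 then the A1 anchor
        background = random_rna(rng, L, gc=spec.gc_background)
        alt_window = background[:start] + site + background[start + site_len:]
        alt_base = alt_window[snp_pos]
        # ref base: breaks Watson-Crick pairing (and G.U wobble) at the SNP
        mirna_partner = mirna_res[1:8][::-1][spec.snp_offset_in_seed]
        forbidden = {alt_base, complement(mirna_partner)}
        forbidden |= {"G" if mirna_partner == "U" else "", "U" if mirna_partner == "G" else ""}
        choices = [b for b in "ACGU" if b and b not in forbidden]
        ref_base = str(rng.choice(choices))
        ref_window = alt_window[:snp_pos] + ref_base + alt_window[snp_pos + 1:]

        mirna = NucSequence(f"mirna_{spec.seed}", mirna_res)
        w_ref = NucSequence(f"{spec.snp_id}_ref", ref_window)
        w_alt = NucSequence(f"{spec.snp_id}_alt", alt_window)
        alt_hit = best_site_at(scan_seed_sites(w_alt, mirna), snp_pos)
        ref_hit = best_site_at(scan_seed_sites(w_ref, mirna), snp_pos)
        if alt_hit is None or alt_hit.rank < 3:   # want >= 7mer on the alt allele
            continue
        # a core mismatch (offset 1..6) must erase the site; an m8 mismatch
        # (offset 0) only weakens it -- either way the alt site must dominate
        if ref_hit is not None and (spec.snp_offset_in_seed != 0
                                    or ref_hit.rank >= alt_hit.rank):
            continue
        snp = SNPVariant(spec.snp_id, snp_pos, ref_base, alt_base)
        return w_ref, w_alt, snp, mirna
    raise RuntimeError("failed to construct an allele-toggled seed window")
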