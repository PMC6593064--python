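"""Case-control genotype and allele association for biallelic SNPs.

Implements the classic single-SNP toolkit: Hardy-Weinberg equilibrium
chi-square tests per group, genotype odds ratios against the major-allele
homozygote reference, the allele odds ratio, Woolf (log-OR) 95% confidence
intervals, and both the Pearson chi-square and the two-sided Fisher exact
p-value for every 2x2 comparison.  Both p-values are always reported side by
side: statistics packages label their output inconsistently, and silently
choosing one hides the difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile used for Woolf intervals
Z_95 = 1.959964


class AssociationError(ValueError):
    """Structural problem with genotype input."""


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (the convention of most stats packages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contingency2x2:
    """2x2 table; rows = exposure level (a,b top row), columns = case/control.

    Layout::

                      case   control
        exposed        a        b
        reference      c        d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise AssociationError("negative cell count")
        if sum(cells) == 0:
            raise AssociationError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_columns(self) -> "Contingency2x2":
        return Contingency2x2(self.b, self.a, self.d, self.c)

    def swapped_rows(self) -> "Contingency2x2":
        return Contingency2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class GenotypeTable:
    """Genotype counts for one biallelic SNP in cases and controls.

    ``genotype_labels`` is ordered (major hom, het, minor hom); "major" is
    defined by control allele frequency.
    """

    snp_id: str
    genotype_labels: tuple[str, str, str]
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.genotype_labels) != 3:
            raise AssociationError("a biallelic SNP has exactly 3 genotype classes")
        alleles = sorted({a for g in self.genotype_labels for a in g})
        if len(alleles) != 2:
            raise AssociationError(f"{self.snp_id}: genotype labels are not biallelic")

    @property
    def alleles(self) -> tuple[str, str]:
        """(major, minor) as implied by the label ordering."""
        return self.genotype_labels[0][0], self.genotype_labels[2][0]

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    @property
    def monomorphic(self) -> bool:
        return (self.case_counts[1] + self.case_counts[2]
                + self.control_counts[1] + self.control_counts[2]) == 0


@dataclass(frozen=True)
class AssociationResult:
    comparison_label: str
    table: Contingency2x2
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_chisq: float | None
    p_fisher: float | None
    ci_defined: bool = True


@dataclass(frozen=True)
class HWEResult:
    group_label: str
    chi2: float | None
    df: int
    p: float | None
    applicable: bool = True


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def alleles_from_genotypes(table: GenotypeTable) -> Contingency2x2:
    """Allele 2x2 table (minor allele = exposed row): count = 2*hom + het."""
    ca = table.case_counts
    co = table.control_counts
    minor_case = 2 * ca[2] + ca[1]
    minor_control = 2 * co[2] + co[1]
    major_case = 2 * ca[0] + ca[1]
    major_control = 2 * co[0] + co[1]
    return Contingency2x2(minor_case, minor_control, major_case, major_control)


def odds_ratio_ci(t: Contingency2x2, z: float = Z_95, haldane: bool = False,
                  label: str = "") -> AssociationResult:
    """Odds ratio with the Woolf log-scale confidence interval.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- z*SE), SE = sqrt(1/a+1/b+1/c+1/d).
    With a zero cell the OR/CI are undefined unless ``haldane=True``
    requests the Haldane-Anscombe +0.5 correction.
    """
    cells = [t.a, t.b, t.c, t.d]
    if 0 in cells:
        if not haldane:
            return AssociationResult(label, t, None, None, None,
                                     chisq_test_2x2(t)[1], fisher_exact_2x2(t),
                                     ci_defined=False)
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return AssociationResult(label, t, or_, lo, hi,
                             chisq_test_2x2(t)[1], fisher_exact_2x2(t))


def chisq_test_2x2(t: Contingency2x2, continuity: bool = False) -> tuple[float, float | None]:
    """Pearson chi-square (df=1) for a 2x2 table; returns (chi2, p).

    With ``continuity`` the Yates correction replaces |ad-bc| by
    max(0, |ad-bc| - N/2).  A zero margin makes the statistic undefined:
    (nan, None) is returned.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return math.nan, None
    det = abs(a * d - b * c)
    if continuity:
        det = max(0.0, det - n / 2)
    chi2 = n * det * det / math.prod(margins)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def fisher_exact_2x2(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (relative tolerance
    1e-7, the standard convention).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def hwe_test(genotype_counts, group_label: str = "") -> HWEResult:
    """Hardy-Weinberg chi-square goodness-of-fit (df=1) from genotype counts.

    ``genotype_counts`` is (hom1, het, hom2).  A monomorphic sample has no
    testable heterozygosity; the result is flagged inapplicable rather than
    reported as 0/0.
    """
    h1, het, h2 = (int(x) for x in genotype_counts)
    n = h1 + het + h2
    if n <= 0:
        raise AssociationError("empty genotype sample")
    p_hat = (2 * h1 + het) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HWEResult(group_label, None, 1, None, applicable=False)
    q_hat = 1 - p_hat
    expected = np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2]) * n
    observed = np.array([h1, het, h2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(group_label, chi2, 1, float(stats.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

@dataclass
class SNPReport:
    """Everything reported for one SNP: a block of the association table."""

    table: GenotypeTable
    hwe_case: HWEResult | None
    hwe_control: HWEResult | None
    genotype_results: list[AssociationResult] = field(default_factory=list)
    allele_result: AssociationResult | None = None
    monomorphic: bool = False
    n_missing: int = 0


def _order_genotypes(counts_by_genotype: dict[str, tuple[int, int]], snp_id: str) -> GenotypeTable:
    """Orient genotype counts as (major hom, het, minor hom) by control allele
    frequency (case counts used as a tie-break/fallback)."""
    alleles: dict[str, int] = {}
    for g in counts_by_genotype:
        if len(g) != 2:
            raise AssociationError(f"{snp_id}: genotype {g!r} is not diploid")
        for al in g:
            alleles[al] = 0
    if len(alleles) == 1:
        al = next(iter(alleles))
        other = "T" if al != "T" else "C"
        case_n, control_n = counts_by_genotype[al + al]
        return GenotypeTable(snp_id, (al + al, "".join(sorted(al + other)), other + other),
                             (case_n, 0, 0), (control_n, 0, 0))
    if len(alleles) != 2:
        raise AssociationError(f"{snp_id}: more than two alleles observed: {sorted(alleles)}")
    a1, a2 = sorted(alleles)
    def counts_for(g: str) -> tuple[int, int]:
        key = "".join(sorted(g))
        for cand in (key, key[::-1]):
            if cand in counts_by_genotype:
                return counts_by_genotype[cand]
        return (0, 0)
    hom1, het, hom2 = counts_for(a1 + a1), counts_for(a1 + a2), counts_for(a2 + a2)
    ctrl_freq_a1 = (2 * hom1[1] + het[1], 2 * hom2[1] + het[1])
    if ctrl_freq_a1[0] == ctrl_freq_a1[1]:  # tie: use cases
        major_is_a1 = (2 * hom1[0] + het[0]) >= (2 * hom2[0] + het[0])
    else:
        major_is_a1 = ctrl_freq_a1[0] > ctrl_freq_a1[1]
    if major_is_a1:
        labels = (a1 + a1, a1 + a2, a2 + a2)
        ordered = (hom1, het, hom2)
    else:
        labels = (a2 + a2, a1 + a2, a1 + a1)
        ordered = (hom2, het, hom1)
    return GenotypeTable(snp_id, labels,
                         tuple(x[0] for x in ordered), tuple(x[1] for x in ordered))


def analyze_snp(table: GenotypeTable, haldane: bool = False, n_missing: int = 0) -> SNPReport:
    """Full single-SNP block: HWE per group, genotype ORs vs the major-allele
    homozygote, and the allele OR."""
    if table.monomorphic:
        return SNPReport(table, None, None, monomorphic=True, n_missing=n_missing)
    rep = SNPReport(
        table,
        hwe_case=hwe_test(table.case_counts, "case"),
        hwe_control=hwe_test(table.control_counts, "control"),
        n_missing=n_missing,
    )
    ref_case, ref_control = table.case_counts[0], table.control_counts[0]
    for k in (1, 2):
        t = Contingency2x2(table.case_counts[k], table.control_counts[k],
                           ref_case, ref_control)
        label = f"{table.genotype_labels[k]} vs {table.genotype_labels[0]}"
        rep.genotype_results.append(odds_ratio_ci(t, haldane=haldane, label=label))
    major, minor = table.alleles
    rep.allele_result = odds_ratio_ci(alleles_from_genotypes(table), haldane=haldane,
                                      label=f"{minor} vs {major}")
    return rep


def build_table1(records: pd.DataFrame, haldane: bool = False) -> list[SNPReport]:
    """Association table from per-sample genotype records.

    ``records`` needs columns ``sample_id``, ``group`` (case|control) and one
    column per SNP holding a diploid genotype such as "CT" (order-free).
    Missing calls (NaN/empty) are excluded pairwise per SNP with a logged
    count.  Inconsistent allele labels raise a validation error that lists
    the offending records.
    """
    required = {"sample_id", "group"}
    if not required <= set(records.columns):
        raise AssociationError(f"records must contain columns {sorted(required)}")
    groups = set(records["group"].astype(str))
    if not groups <= {"case", "control"}:
        raise AssociationError(f"unknown group labels {sorted(groups - {'case', 'control'})}")
    reports = []
    snp_cols = [c for c in records.columns if c not in required]
    for snp in snp_cols:
        col = records[snp]
        present = col.notna() & (col.astype(str).str.strip() != "")
        n_missing = int((~present).sum())
        if n_missing:
            logger.info("%s: excluded %d samples with missing genotype", snp, n_missing)
        sub = records.loc[present, ["group", snp]]
        if sub.empty:
            continue
        geno = sub[snp].astype(str).str.strip().str.upper()
        bad = sub.loc[~geno.str.fullmatch(r"[ACGT]{2}"), :]
        if not bad.empty:
            ids = records.loc[bad.index, "sample_id"].tolist()
            raise AssociationError(f"{snp}: invalid genotype records for samples {ids}")
        norm = geno.map(lambda g: "".join(sorted(g)))
        alleles = sorted({a for g in norm for a in g})
        if len(alleles) > 2:
            offenders = records.loc[sub.index[norm.map(lambda g: any(a not in alleles[:2] for a in g))],
                                    "sample_id"].tolist()
            raise AssociationError(
                f"{snp}: more than two alleles {alleles}; offending samples include {offenders[:10]}")
        counts: dict[str, tuple[int, int]] = {}
        for g in sorted(norm.unique()):
            mask = norm == g
            counts[g] = (int((sub.loc[mask.index[mask], "group"] == "case").sum()),
                         int((sub.loc[mask.index[mask], "group"] == "control").sum()))
        table = _order_genotypes(counts, snp)
        reports.append(analyze_snp(table, haldane=haldane, n_missing=n_missing))
    return reports


def tables_from_counts(counts: pd.DataFrame) -> list[GenotypeTable]:
    """GenotypeTables from a pre-aggregated counts frame
    (columns snp_id, genotype, case_n, control_n)."""
    out = []
    for snp, grp in counts.groupby("snp_id", sort=False):
        by_geno = {str(r.genotype).upper(): (int(r.case_n), int(r.control_n))
                   for r in grp.itertuples()}
        if len({a for g in by_geno for a in g}) == 1:
            al = next(iter(by_geno))[0]
            other = "T" if al != "T" else "C"
            case_n, control_n = by_geno[al + al]
            out.append(GenotypeTable(snp, (al + al, "".join(sorted(al + other)), other + other),
                                     (case_n, 0, 0), (control_n, 0, 0)))
        else:
            out.append(_order_genotypes(by_geno, snp))
    return out


def reports_to_frame(reports: list[SNPReport]) -> pd.DataFrame:
    """Flatten SNP reports into a table mirroring the classic layout:
    one row per genotype and per allele with n (%), OR, 95% CI and p."""
    rows = []
    for rep in reports:
        t = rep.table
        nca, nco = t.n_cases, t.n_controls
        def fmt(res: AssociationResult | None):
            if res is None or res.odds_ratio is None:
                return (None, None, None, None)
            return (round_half_up(res.odds_ratio),
                    round_half_up(res.ci_low),
                    round_half_up(res.ci_high),
                    res.p_chisq)
        if rep.monomorphic:
            g = t.genotype_labels[0]
            rows.append({"snp_id": t.snp_id, "row": g,
                         "case_n": t.case_counts[0],
                         "case_pct": 100.0,
                         "control_n": t.control_counts[0], "control_pct": 100.0,
                         "odds_ratio": None, "ci_low": None, "ci_high": None,
                         "p_chisq": None, "p_fisher": None})
            continue
        blocks = [(t.genotype_labels[0], t.case_counts[0], t.control_counts[0], None)]
        for k, res in zip((1, 2), rep.genotype_results):
            blocks.append((t.genotype_labels[k], t.case_counts[k], t.control_counts[k], res))
        major, minor = t.alleles
        allele_case = alleles_from_genotypes(t)
        blocks.append((major, allele_case.c, allele_case.d, None))
        blocks.append((minor, allele_case.a, allele_case.b, rep.allele_result))
        for label, cn, con, res in blocks:
            denom_case = nca if len(label) == 2 else 2 * nca
            denom_control = nco if len(label) == 2 else 2 * nco
            orr, lo, hi, pc = fmt(res)
            rows.append({"snp_id": t.snp_id, "row": label,
                         "case_n": cn, "case_pct": round(100 * cn / denom_case, 1),
                         "control_n": con, "control_pct": round(100 * con / denom_control, 1),
                         "odds_ratio": orr, "ci_low": lo, "ci_high": hi,
                         "p_chisq": pc,
                         "p_fisher": res.p_fisher if res else None})
    return pd.DataFrame(rows)
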