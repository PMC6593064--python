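# seedshift — methods

## Scope and model overview

`seedshift` analyses a biallelic SNP located in (or near) a miRNA seed
site of a 3′-UTR, through four coupled layers: case–control association,
seed-site identification, a three-state thermodynamic binding model, and
qPCR expression contrasts. All layers run on synthetic inputs produced by
the package's own generators, so the full pipeline is testable end to end
without external data.

## Association statistics

For one biallelic SNP with genotype counts (major hom, het, minor hom) per
group:

* **Hardy–Weinberg** — allele frequency p̂ estimated from the counts;
  expected (p̂²n, 2p̂q̂n, q̂²n); χ² goodness of fit with df = 1. A
  monomorphic sample is flagged inapplicable rather than reported as 0/0.
  The test is computed for cases and controls separately; the usual
  quality-control reading applies to controls (cases may legitimately
  depart under a genotypic risk model, and a heterozygote deficit in cases
  is exactly what a recessive-leaning risk allele produces).
* **Odds ratios** — every 2×2 comparison (each non-reference genotype vs
  the major-allele homozygote; minor vs major allele) uses
  OR = ad/bc with the Woolf interval exp(ln OR ± z·SE),
  SE = √(1/a+1/b+1/c+1/d), z = 1.959964. A zero cell leaves the OR/CI
  undefined unless the Haldane–Anscombe +0.5 correction is explicitly
  requested — silent corrections hide data problems. Display rounding is
  half-up to 3 decimals.
* **p-values** — the Pearson χ² (optionally Yates-corrected,
  N(|ad−bc|−N/2)²/…) and the two-sided Fisher exact p (sum of
  hypergeometric point probabilities ≤ the observed one, relative
  tolerance 1e-7) are always reported side by side: published tables are
  frequently ambiguous about which one a statistics package printed, and
  at these sample sizes they straddle α = 0.05.
* Missing genotype calls are excluded pairwise per SNP with a logged
  count; inconsistent allele labels abort with the offending sample ids.

## Seed-site model

Seed classes follow the canonical hierarchy 8mer > 7mer-m8 > 7mer-A1 >
6mer. The 6mer core is miRNA positions 2–7; m8 adds a Watson–Crick match
to position 8 on the 5′ flank of the target site; A1 requires an adenosine
on the target opposite position 1 regardless of the miRNA base. Matching
is strict Watson–Crick by default (`allow_wobble=True` admits G·U).
Coordinates are 0-based half-open on the supplied window. Overlapping
candidate sites collapse to the strongest class (ties to the 5′-most);
disjoint sites are all reported.

SNP effect classification scans both allelic windows and compares the
best site overlapping the SNP. When the SNP sits on the m8/A1 flank, the
weaker allele's (shorter-class) interval may not contain the SNP position
itself; a same-locus fallback (best site overlapping the other allele's
interval) prevents spuriously calling such cases `site_created`.

## Three-state thermodynamics

States of the target window (energies in kcal/mol at 37 °C):

* **E_target** — minimum-free-energy secondary structure of the window
  (open chain = 0).
* **E_intermediate** — MFE under a hard constraint that every nucleotide
  of the binding site is unpaired. This is the transition state of site
  opening; by construction E_intermediate ≥ E_target and it is monotone
  in the width of the opened interval.
* **E_complex** — E_intermediate plus the intermolecular duplex energy of
  miRNA and site (two-step accessibility decomposition). Published
  analyses of this kind often compute the dimer energy with a cofolding
  algorithm instead; the two-step decomposition was chosen because it
  makes the diagram identity ΔE_b = ΔE_a + E_duplex exact by
  construction, at the cost of ignoring intermolecular pairing outside
  the declared site. Absolute energies are therefore not comparable with
  cofolding outputs; allele *differences* are the quantity of interest.

Derived: ΔE_a = E_intermediate − E_target (activation/opening cost) and
ΔE_b = E_complex − E_target (binding energy; more negative = stronger
repression). The allele comparison runs the diagram per allele through
each allele's own best seed site (sites overlapping the SNP preferred; an
allele with no site contributes ΔE_b = 0, "no binding") and reports
ΔΔE_b = ΔE_b(alt) − ΔE_b(ref) and the favored allele (ties reported
explicitly as `tie`).

The default window is 60 nt centered on the SNP (the generator's
default); off-center placement is simply a different input window.

### Energy function

Nearest-neighbor model with Watson–Crick and G·U pairs:

* stack table: Turner-2004-style ΔG°37 values (21 unique entries
  symmetrized by helix rotation into the 6×6 matrix);
* hairpin (size ≥ 3), bulge and internal loop initiation penalties
  tabulated, extended beyond the tabulated sizes by the Jacobson–Stockmayer
  form ΔG(s) = ΔG(s_max) + 1.75·RT·ln(s/s_max), RT = 0.6163 kcal/mol;
* multibranch loops: affine penalty a + b·(branches incl. the closing
  helix) + c·(unpaired), defaults a = 3.4, b = 0.4, c = 0 kcal/mol;
* duplex initiation 4.09 kcal/mol; 0.5 kcal/mol per AU/GU duplex helix
  end; no dangles, terminal mismatches or coaxial stacking.

Parameters live in an editable TSV (`EnergyModel.from_tsv` /
`.to_tsv`, rows `kind<TAB>key<TAB>value`). The defaults are a standard
literature-derived set, not a fit to any particular program's output, so
absolute energies differ from ViennaRNA's; all tests are comparative or
oracle-based for this reason.

### Numerical conventions

* All energies are integer centi-kcal/mol internally; DP and structure
  scoring are exact and float round-off cannot reorder optima.
* The DP value packs `energy*64 + n_pairs` into one int64, so the search
  minimizes (energy, number of pairs) lexicographically: among
  iso-energetic optima the structure with fewest pairs wins, and any
  remaining ties are resolved by a fixed traceback option order. (A
  dot-bracket-lexicographic tie-break was considered and rejected: a
  lexicographic objective does not compose across DP concatenation.)
* Bulge and interior loops in the fold DP are capped at 30 total unpaired
  nucleotides (the scorer itself accepts any size); a size-1 bulge is
  charged its size penalty only, with no stacking continuation across the
  bulge — this keeps the loop cost a pure function of loop size, which the
  vectorized inner minimization and the DP/scorer equivalence rely on.
* The duplex DP allows interior loops up to 4 unpaired bases per side; a
  hybridization is reported only if its total energy is below zero,
  otherwise the result is "no binding" (energy 0, empty trace).
* Degenerate inputs: windows shorter than 5 nt fold to the open chain;
  an empty site interval gives ΔE_a = ΔE_b = 0; a comparison where
  neither allele has any site is flagged non-informative.

The folding DP is validated against exhaustive enumeration of all legal
structures (energies scored by the explicit loop-decomposition scorer) for
hundreds of random sequences up to length 20, where the interior-loop cap
cannot bind; the duplex DP against enumeration of all pair chains.

## Expression

Relative expression is 2^−ΔCt with ΔCt = Ct_target − Ct_reference per
sample (no calibrator ΔΔCt step; the reference assay is the calibrator),
log10-transformed before any statistics. Valid T range (0, 45]. Group
contrasts default to Welch's t-test (robustness to unequal variances; a
flag restores Student's) or one-way ANOVA for k > 2 groups; regression is
ordinary least squares with the two-sided slope p. Reference
normalization is per sample and per cell type.

## Synthetic generators: what they emulate

* **Cohorts** (`gen_genotypes`): controls drawn from HWE at the control
  risk-allele frequency (default 0.357); cases from HWE weights
  multiplied by OR^(risk-allele count) and renormalized — the
  multiplicative (logistic-equivalent) model implied whenever a single
  allele OR is reported (default 1.8; default sizes 66 cases / 42
  controls).
* **Expression** (`gen_expression`): per-sample log10 level = base +
  shift·(#risk alleles) + Gaussian noise, defaults base −1.5, shift −0.3,
  SD 0.3. The study this emulates reports no numeric group means, only a
  significant downward trend per risk allele; −0.3 (one noise SD per
  allele) makes that trend detectable at the default sample sizes without
  being trivial, and base −1.5 puts target Ct values near 25 against a
  reference at 20, typical for a moderately expressed transcript. miRNA
  levels share the target's within-genotype residual with loading
  −√R² (default R² = 0.255), giving the intended negative correlation
  inside a genotype class; Ct pairs are back-computed so 2^−ΔCt
  reproduces the generated levels exactly (to 1e-9).
* **Sequence windows** (`gen_snp_window`): a random background (default
  60 nt, GC 0.5) with a perfect 8mer site for a freshly drawn 22-nt miRNA
  embedded at the center; the ref allele replaces one seed-heptamer
  position (default offset 3) with a base that can form neither a
  Watson–Crick nor a wobble pair, so the site exists only on the alt
  allele and the windows differ at exactly one position. Backgrounds with
  spurious surviving matches at the locus are redrawn (bounded retries).

What a green test on synthetic data does **not** establish: real UTR
windows have non-random base composition, conserved structure and
multiple competing miRNA sites; real cohorts have relatedness,
stratification and genotyping error; real qPCR has efficiency and
pipetting variation. The generators model none of these — they verify the
*estimators*, not the biology.

## Known limitations

* No partition function or base-pair probabilities; single optimal
  structures only. No pseudoknots.
* Duplex energies exclude 3′-supplementary pairing and any pairing
  outside the declared site; no conservation or context scoring of sites.
* Association supports no covariates, stratification control, haplotypes
  or multiple-testing correction (deliberately out of scope).
* The report's schema validation uses a pydantic model rather than a JSON
  Schema document; the contract (validate on every run) is the same.
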