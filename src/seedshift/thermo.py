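"""Three-state thermodynamic model of miRNA-target binding.

The binding process is described by three states of the target window:

* free target: minimum-free-energy structure, energy ``E_target``;
* transition state: the binding site forced open (constrained fold),
  energy ``E_intermediate``;
* miRNA-bound complex: opened target plus the intermolecular duplex,
  ``E_complex = E_intermediate + E_duplex`` (two-step accessibility
  decomposition).

Derived quantities: the activation energy ``dE_a = E_intermediate -
E_target`` (cost of opening the site, always >= 0) and the binding energy
``dE_b = E_complex - E_target`` (net gain of binding; more negative =
stronger repression).  By construction ``dE_b = dE_a + E_duplex`` exactly.
Comparing the two alleles of a 3'-UTR SNP through their own best seed sites
quantifies how the variant shifts miRNA-mediated repression.
"""

from __future__ import annotations

from dataclasses import dataclass

from .duplex import DuplexResult, duplex_energy
from .energy_params import EnergyModel, default_model
from .fold import SecondaryStructure, constrained_mfe, mfe_fold
from .seed_scan import SeedSite, SNPVariant, best_site_at, scan_seed_sites
from .sequences import NucSequence


@dataclass(frozen=True)
class EnergyDiagram:
    """The three state energies and the two derived deltas (kcal/mol)."""

    E_target: float
    E_intermediate: float
    E_complex: float
    target_structure: SecondaryStructure | None = None
    intermediate_structure: SecondaryStructure | None = None
    duplex: DuplexResult | None = None

    @property
    def dE_a(self) -> float:
        """Activation energy: cost of opening the binding site."""
        return round(self.E_intermediate - self.E_target, 9)

    @property
    def dE_b(self) -> float:
        """Binding energy: net energy change of complex formation."""
        return round(self.E_complex - self.E_target, 9)

    def as_dict(self) -> dict:
        return {"E_target": self.E_target, "E_intermediate": self.E_intermediate,
                "E_complex": self.E_complex, "dE_a": self.dE_a, "dE_b": self.dE_b}


@dataclass(frozen=True)
class AlleleComparison:
    """Per-allele energy diagrams for one SNP and their difference."""

    snp_id: str
    ref_allele: str
    alt_allele: str
    ref: EnergyDiagram
    alt: EnergyDiagram
    ref_site: SeedSite | None
    alt_site: SeedSite | None
    informative: bool = True

    @property
    def delta_binding(self) -> float:
        """dE_b(alt) - dE_b(ref); negative favors the alt allele."""
        return round(self.alt.dE_b - self.ref.dE_b, 9)

    @property
    def favored_allele(self) -> str:
        """Allele with the lower (more negative) binding energy."""
        d = self.delta_binding
        if d < 0:
            return self.alt_allele
        if d > 0:
            return self.ref_allele
        return "tie"


def energy_diagram(window: NucSequence, site_interval: tuple[int, int],
                   mirna: NucSequence,
                   model: EnergyModel | None = None) -> EnergyDiagram:
    """Compute the three-state diagram for one window and site interval."""
    model = model or default_model()
    start, end = site_interval
    if not (0 <= start <= end <= len(window)):
        raise ValueError(f"site interval {site_interval} outside window of length {len(window)}")
    target = mfe_fold(window, model)
    intermediate = constrained_mfe(window, site_interval, model)
    if end > start:
        dup = duplex_energy(mirna, window.subseq(start, end), model)
    else:
        dup = DuplexResult(0.0)
    return EnergyDiagram(
        E_target=target.energy,
        E_intermediate=intermediate.energy,
        E_complex=round(intermediate.energy + dup.energy, 9),
        target_structure=target,
        intermediate_structure=intermediate,
        duplex=dup,
    )


def _no_binding_diagram(window: NucSequence, model: EnergyModel) -> EnergyDiagram:
    """Diagram for an allele without a usable site: no opening, no duplex."""
    target = mfe_fold(window, model)
    return EnergyDiagram(target.energy, target.energy, target.energy,
                         target_structure=target, intermediate_structure=target,
                         duplex=DuplexResult(0.0))


def compare_alleles(window_ref: NucSequence, snp: SNPVariant, mirna: NucSequence,
                    model: EnergyModel | None = None,
                    allow_wobble: bool = False) -> AlleleComparison:
    """Per-allele energy diagrams through each allele's own best seed site.

    Sites overlapping the SNP are preferred (the site may exist in only one
    allele); if neither allele has a site at the SNP locus, the strongest
    site anywhere in the window is used for each allele.  An allele without
    any site contributes dE_b = 0 (no binding).  The comparison is flagged
    non-informative when neither allele has a site.
    """
    model = model or default_model()
    snp.check_window(window_ref)
    window_alt = window_ref.with_substitution(
        snp.position, snp.alt_allele, id=f"{window_ref.id}|{snp.snp_id}:{snp.alt_allele}")

    sites_ref = scan_seed_sites(window_ref, mirna, allow_wobble)
    sites_alt = scan_seed_sites(window_alt, mirna, allow_wobble)
    at_snp_ref = best_site_at(sites_ref, snp.position)
    at_snp_alt = best_site_at(sites_alt, snp.position)
    if at_snp_ref is not None or at_snp_alt is not None:
        site_ref, site_alt = at_snp_ref, at_snp_alt
    else:
        def _best(sites):
            return max(sites, key=lambda s: (s.rank, -s.target_interval[0])) if sites else None
        site_ref, site_alt = _best(sites_ref), _best(sites_alt)

    diag_ref = (energy_diagram(window_ref, site_ref.target_interval, mirna, model)
                if site_ref else _no_binding_diagram(window_ref, model))
    diag_alt = (energy_diagram(window_alt, site_alt.target_interval, mirna, model)
                if site_alt else _no_binding_diagram(window_alt, model))
    return AlleleComparison(
        snp_id=snp.snp_id,
        ref_allele=snp.ref_allele,
        alt_allele=snp.alt_allele,
        ref=diag_ref,
        alt=diag_alt,
        ref_site=site_ref,
        alt_site=site_alt,
        informative=site_ref is not None or site_alt is not None,
    )
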