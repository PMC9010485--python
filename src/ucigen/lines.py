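"""Default locus registry and founder genotypes used throughout.

Founder assignments: 511L = Ga2-S/Ga2-S; W22, B104, Zheng58, Chang7-2 and
ZYM1 = ga2/ga2; Mo17 = Ga2-M/Ga2-M; SDGa25 = Ga1-S/Ga1-S.  ZYM1 is the
purple-kernel tester, everything else is yellow.  Transgene loci are
modeled as unlinked UCI loci with specificity "Ga2": the F transgene
allele is the (hypothetical in nature) Fonly haplotype, the P transgene
allele is an M haplotype; the transgene construct also confers herbicide
resistance, so resistance == carrying a transgene allele.
"""

from __future__ import annotations

from .cross_engine import COLOR_LOCUS, PURPLE, YELLOW, GeneticMap
from .genetic_model import (
    AuxLocus,
    Genotype,
    Haplotype,
    LocusArchitecture,
    LocusRegistry,
)

GA2 = "Ga2"
GA1 = "Ga1"
TG_F = "ZmGa2F-tg"
TG_P = "ZmGa2P-tg"


def default_registry() -> LocusRegistry:
    reg = LocusRegistry()
    reg.add(LocusArchitecture(GA2, chromosome="5", position_cM=0.68))
    reg.add(LocusArchitecture(GA1, chromosome="4", position_cM=0.0))
    reg.add(LocusArchitecture(TG_F, chromosome="tgF", position_cM=0.0, specificity=GA2))
    reg.add(LocusArchitecture(TG_P, chromosome="tgP", position_cM=0.0, specificity=GA2))
    reg.add_aux(AuxLocus(COLOR_LOCUS, chromosome="9", position_cM=0.0, null_allele=YELLOW))
    return reg


def default_map(registry: LocusRegistry | None = None) -> GeneticMap:
    return GeneticMap.from_registry(registry or default_registry())


def _hap(locus: str, label: str) -> Haplotype:
    return {
        "S": Haplotype(locus, True, True),
        "M": Haplotype(locus, True, False),
        "Fonly": Haplotype(locus, False, True),
        "wt": Haplotype(locus, False, False),
    }[label]


def uci_pair(locus: str, a: str, b: str) -> tuple[Haplotype, Haplotype]:
    return (_hap(locus, a), _hap(locus, b))


def founders() -> dict[str, Genotype]:
    """Named founder genotypes (loci missing from a genotype are filled
    with wildtype/null alleles automatically when crossed)."""
    yellow = {COLOR_LOCUS: (YELLOW, YELLOW)}
    purple = {COLOR_LOCUS: (PURPLE, PURPLE)}
    f = {
        "511L": Genotype.make({GA2: uci_pair(GA2, "S", "S")}, yellow),
        "W22": Genotype.make({GA2: uci_pair(GA2, "wt", "wt")}, yellow),
        "B104": Genotype.make({GA2: uci_pair(GA2, "wt", "wt")}, yellow),
        "Zheng58": Genotype.make({GA2: uci_pair(GA2, "wt", "wt")}, yellow),
        "Chang7-2": Genotype.make({GA2: uci_pair(GA2, "wt", "wt")}, yellow),
        "ZYM1": Genotype.make({GA2: uci_pair(GA2, "wt", "wt")}, purple),
        "Mo17": Genotype.make({GA2: uci_pair(GA2, "M", "M")}, yellow),
        "SDGa25": Genotype.make(
            {GA1: uci_pair(GA1, "S", "S"), GA2: uci_pair(GA2, "wt", "wt")}, yellow
        ),
    }
    # near-isogenic S-haplotype conversions and their hybrid
    f["Zheng58-Ga2S"] = f["Zheng58"].with_locus(GA2, uci_pair(GA2, "S", "S"))
    f["Chang7-2-Ga2S"] = f["Chang7-2"].with_locus(GA2, uci_pair(GA2, "S", "S"))
    f["NILhybrid-Ga2S"] = f["Zheng58-Ga2S"]  # Zheng58^Ga2S/Chang7-2^Ga2S, S/S
    f["NILhybrid-ga2"] = f["Zheng58"]  # ga2/ga2 near-isogenic hybrid
    # pyramided line, homozygous S at both Ga1 and Ga2
    f["Ga1Ga2"] = Genotype.make(
        {GA1: uci_pair(GA1, "S", "S"), GA2: uci_pair(GA2, "S", "S")}, yellow
    )
    # transgenic lines in the B104 (ga2/ga2) background
    f["CS-hom"] = f["B104"].with_locus(TG_F, uci_pair(TG_F, "Fonly", "Fonly"))
    f["CS-hemi"] = f["B104"].with_locus(TG_F, uci_pair(TG_F, "Fonly", "wt"))
    f["MP-hemi"] = f["B104"].with_locus(TG_P, uci_pair(TG_P, "M", "wt"))
    return f


def carries_transgene(g: Genotype, locus: str = TG_F) -> bool:
    """Herbicide-resistance readout: does the plant carry a transgene allele?"""
    pair = g.uci.get(locus)
    return pair is not None and any(h.P or h.F for h in pair)
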