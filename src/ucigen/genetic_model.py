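"""Core domain types and pollen-silk compatibility rules for UCI loci.

A unilateral cross-incompatibility (UCI) locus is modeled as a pair of
determinant flags per allele: ``P`` (male determinant, pollen-expressed)
and ``F`` (female determinant, silk-expressed).  The three naturally
observed allele classes are

* **S** — carries both determinants (``P & F``),
* **M** — male determinant only (``P & ~F``),
* **wildtype** — neither determinant,

plus the hypothetical **Fonly** class (``~P & F``), which is representable
(it is exactly what an F-determinant transgene introduces) but flagged
because such a line would be self-incompatible and has never been found
in nature.

The compatibility rule is:

* the silk barrier is *sporophytic*: a locus blocks foreign pollen iff the
  diploid silk genotype carries at least ``female_dose_threshold`` F-bearing
  alleles at that locus (default 2, i.e. the barrier is recessive);
* the male determinant acts *gametophytically*: each pollen grain is judged
  by its own haploid content.  A grain passes an active barrier iff it
  carries ``P`` at some locus whose *specificity* matches the barrier.

``specificity`` exists so that a transgene locus (physically unlinked) can
raise or pass a barrier belonging to another locus: an F transgene cloned
from Ga2 erects a Ga2-type barrier, which native Ga2-P pollen overcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "GameteType",
    "Genotype",
    "Haplotype",
    "LocusArchitecture",
    "AuxLocus",
    "LocusRegistry",
    "UnknownLocusError",
    "classify_haplotype",
    "silk_barrier",
    "pollen_compatible",
    "active_barrier_specs",
]

GAMETOPHYTIC = "gametophytic"
SPOROPHYTIC = "sporophytic"

_LABEL_RANK = {"S": 0, "M": 1, "Fonly": 2, "wt": 3}


class UnknownLocusError(KeyError):
    """Raised when a genotype references a locus absent from the registry."""


@dataclass(frozen=True)
class LocusArchitecture:
    """Transmission-genetic architecture of one UCI locus.

    Parameters
    ----------
    locus_id:
        Identifier, e.g. ``"Ga2"`` or ``"ZmGa2F-tg"``.
    male_mode:
        ``"gametophytic"`` (default; each pollen grain judged by its haploid
        content) or ``"sporophytic"`` (pollen judged by the diploid donor
        plant) — the latter exists only for architecture-comparison runs.
    female_mode:
        ``"sporophytic"`` (default; barrier from the diploid silk genotype)
        or ``"gametophytic"`` (barrier per maternal gamete; hypothesis
        variant).
    female_dose_threshold:
        Number of F-bearing alleles required at this locus for an active
        silk barrier.  Default 2 reproduces the recessive behaviour of the
        heterozygote and of a hemizygous transgene with a single rule.
    specificity:
        Identifier of the barrier system this locus participates in.
        Defaults to ``locus_id``; a transgene locus cloned from Ga2 sets
        ``specificity="Ga2"``.
    """

    locus_id: str
    male_mode: str = GAMETOPHYTIC
    female_mode: str = SPOROPHYTIC
    female_dose_threshold: int = 2
    chromosome: str = "0"
    position_cM: float = 0.0
    specificity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.male_mode not in (GAMETOPHYTIC, SPOROPHYTIC):
            raise ValueError(f"invalid male_mode {self.male_mode!r}")
        if self.female_mode not in (SPOROPHYTIC, GAMETOPHYTIC):
            raise ValueError(f"invalid female_mode {self.female_mode!r}")
        if self.female_dose_threshold not in (1, 2):
            raise ValueError("female_dose_threshold must be 1 or 2")
        if self.position_cM < 0:
            raise ValueError("position_cM must be >= 0")
        if self.specificity is None:
            object.__setattr__(self, "specificity", self.locus_id)


@dataclass(frozen=True)
class AuxLocus:
    """A neutral auxiliary locus (DNA marker, kernel colour, resistance tag).

    ``null_allele`` is the allele assumed when a genotype is silently
    extended to cover this locus (e.g. ``"yellow"`` for the recessive
    kernel-colour allele).
    """

    locus_id: str
    chromosome: str = "0"
    position_cM: float = 0.0
    null_allele: str = "-"


@dataclass(frozen=True, order=True)
class Haplotype:
    """One allele at a UCI locus: a (P, F) determinant-flag pair."""

    locus_id: str
    P: bool = False
    F: bool = False

    @property
    def label(self) -> str:
        return classify_haplotype(self)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.locus_id}:{self.label}"


def classify_haplotype(h: Haplotype) -> str:
    """Classify a haplotype into S / M / wt / Fonly.

    Total and exhaustive over the four flag combinations.  ``Fonly`` is the
    hypothetical female-determinant-only class, never observed in nature
    but needed to model F transgenes.
    """
    if h.P and h.F:
        return "S"
    if h.P:
        return "M"
    if h.F:
        return "Fonly"
    return "wt"


def _sorted_hap_pair(pair: Iterable[Haplotype]) -> tuple[Haplotype, Haplotype]:
    a, b = tuple(pair)
    if a.locus_id != b.locus_id:
        raise ValueError("both haplotypes of a pair must share locus_id")
    lo, hi = sorted((a, b), key=lambda h: (_LABEL_RANK[h.label], h.locus_id))
    return lo, hi


@dataclass(frozen=True)
class Genotype:
    """Diploid multi-locus individual: UCI loci plus auxiliary loci.

    Allele pairs are unordered (no parent-of-origin tracking); internally
    they are stored sorted so genotypes hash and compare canonically.
    """

    uci_loci: tuple[tuple[str, tuple[Haplotype, Haplotype]], ...]
    aux_loci: tuple[tuple[str, tuple[str, str]], ...] = ()

    @classmethod
    def make(
        cls,
        uci: Mapping[str, Iterable[Haplotype]],
        aux: Mapping[str, Iterable[str]] | None = None,
    ) -> "Genotype":
        uci_t = tuple(
            sorted((lid, _sorted_hap_pair(pair)) for lid, pair in uci.items())
        )
        aux_t = ()
        if aux:
            aux_t = tuple(
                sorted((lid, tuple(sorted(pair))) for lid, pair in aux.items())
            )
            for lid, pair in aux_t:
                if len(pair) != 2:
                    raise ValueError(f"aux locus {lid} needs exactly two alleles")
        return cls(uci_t, aux_t)

    @property
    def uci(self) -> dict[str, tuple[Haplotype, Haplotype]]:
        return dict(self.uci_loci)

    @property
    def aux(self) -> dict[str, tuple[str, str]]:
        return dict(self.aux_loci)

    def locus_ids(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.uci_loci) + tuple(l for l, _ in self.aux_loci)

    def with_locus(
        self,
        locus_id: str,
        alleles: Iterable[Haplotype] | Iterable[str],
        aux: bool = False,
    ) -> "Genotype":
        """Return a copy with one locus added or replaced."""
        u, a = self.uci, self.aux
        if aux:
            a = {**a, locus_id: tuple(alleles)}  # type: ignore[arg-type]
        else:
            u = {**u, locus_id: tuple(alleles)}  # type: ignore[dict-item]
        return Genotype.make(u, a)

    def label(self) -> str:
        """Human-readable genotype string, e.g. ``"Ga2:S/wt"``."""
        parts = [f"{lid}:{p[0].label}/{p[1].label}" for lid, p in self.uci_loci]
        parts += [f"{lid}:{p[0]}/{p[1]}" for lid, p in self.aux_loci]
        return ";".join(parts)

    def locus_label(self, locus_id: str) -> str:
        """Genotype label restricted to one locus, e.g. ``"S/wt"``."""
        u = self.uci
        if locus_id in u:
            a, b = u[locus_id]
            return f"{a.label}/{b.label}"
        a, b = self.aux[locus_id]
        return f"{a}/{b}"


@dataclass
class GameteType:
    """A haploid gamete class: one allele per locus plus a probability mass.

    ``alleles`` maps UCI locus ids to :class:`Haplotype` and auxiliary
    locus ids to allele strings.
    """

    alleles: dict[str, object]
    weight: float

    def key(self) -> tuple:
        return tuple(sorted(self.alleles.items(), key=lambda kv: kv[0]))


@dataclass
class LocusRegistry:
    """Registry of locus architectures consulted by every compatibility call."""

    uci: dict[str, LocusArchitecture] = field(default_factory=dict)
    aux: dict[str, AuxLocus] = field(default_factory=dict)

    def add(self, arch: LocusArchitecture) -> None:
        self.uci[arch.locus_id] = arch

    def add_aux(self, aux: AuxLocus) -> None:
        self.aux[aux.locus_id] = aux

    def arch(self, locus_id: str) -> LocusArchitecture:
        try:
            return self.uci[locus_id]
        except KeyError:
            raise UnknownLocusError(
                f"locus {locus_id!r} has no registered architecture"
            ) from None

    def override(self, locus_id: str, **fields) -> "LocusRegistry":
        """Copy of the registry with one architecture's fields replaced."""
        new = LocusRegistry(dict(self.uci), dict(self.aux))
        new.uci[locus_id] = replace(self.arch(locus_id), **fields)
        return new


def silk_barrier(g: Genotype, locus: str, registry: LocusRegistry) -> bool:
    """Is the silk barrier of ``locus`` active in diploid genotype ``g``?

    Sporophytic contract: the answer depends only on the silk genotype,
    never on the pollen.  The barrier is active iff the number of F-bearing
    alleles at ``locus`` reaches the architecture's dose threshold.
    """
    arch = registry.arch(locus)
    pair = g.uci.get(locus)
    if pair is None:
        return False
    dose = sum(1 for h in pair if h.F)
    if arch.female_mode == GAMETOPHYTIC:
        # Hypothesis variant: the diploid silk as a whole never blocks;
        # per-gamete action is applied inside the cross engine.
        return False
    return dose >= arch.female_dose_threshold


def active_barrier_specs(silk: Genotype, registry: LocusRegistry) -> set[str]:
    """Specificities of all active barriers expressed by ``silk``."""
    specs: set[str] = set()
    for lid in silk.uci:
        if silk_barrier(silk, lid, registry):
            specs.add(registry.arch(lid).specificity)  # type: ignore[arg-type]
    return specs


def _passes_spec(
    spec: str,
    gam: GameteType,
    registry: LocusRegistry,
    donor: Optional[Genotype],
) -> bool:
    for lid, allele in gam.alleles.items():
        if not isinstance(allele, Haplotype):
            continue
        arch = registry.arch(lid)
        if arch.specificity != spec:
            continue
        if arch.male_mode == GAMETOPHYTIC:
            if allele.P:
                return True
        else:  # sporophytic-male variant: judged by the diploid donor plant
            if donor is not None and any(h.P for h in donor.uci.get(lid, ())):
                return True
    return False


def pollen_compatible(
    gam: GameteType,
    silk: Genotype,
    registry: LocusRegistry,
    donor: Optional[Genotype] = None,
) -> bool:
    """Can this pollen grain fertilize this silk?

    True iff for every active barrier specificity expressed by the silk the
    gamete carries a passing male determinant.  Loci without an active
    barrier impose no constraint, so with all barriers inactive every
    gamete is compatible (the Mendelian limit).

    ``donor`` (the diploid pollen parent) is consulted only when some
    architecture uses the sporophytic-male variant.
    """
    for spec in active_barrier_specs(silk, registry):
        if not _passes_spec(spec, gam, registry, donor):
            return False
    return True
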