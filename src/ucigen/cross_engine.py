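"""Exact enumeration of gamete and offspring distributions under pollen
selection, plus seed-set and kernel-colour phenotype prediction.

Meiosis is modeled without chiasma interference: within a chromosome the
gamete follows a Markov chain along the ordered loci, with switch
probability equal to the pairwise recombination fraction between adjacent
loci (Haldane by default, Kosambi optional).  Chromosomes assort
independently.

Seed set uses a pollen-excess saturation model: a silk pollinated with a
pool containing *any* compatible fraction sets a full ear; a fully
incompatible pool gives a barren ear (a value, not an exception), modified
only by a stray-compatible-pollen contamination rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genetic_model import (
    GameteType,
    Genotype,
    Haplotype,
    LocusRegistry,
    UnknownLocusError,
    pollen_compatible,
    silk_barrier,
)

__all__ = [
    "GeneticMap",
    "PollenPool",
    "PoolComponent",
    "OffspringDistribution",
    "SeedSetOutcome",
    "recomb_fraction",
    "gamete_distribution",
    "select_pollen",
    "cross",
    "compatible_fraction",
    "seed_set",
    "ear_composition",
    "kernel_color",
]

SEED_THRESHOLD = 5  # "<5 seeds" field convention for the low-seed class

HALDANE = "haldane"
KOSAMBI = "kosambi"


def recomb_fraction(d: float, map_function: str = HALDANE) -> float:
    """Recombination fraction for a map distance ``d`` in centimorgans.

    Haldane: ``r = (1 - exp(-2 d / 100)) / 2``;
    Kosambi: ``r = tanh(2 d / 100) / 2``.  Both satisfy ``r(0) = 0`` and
    ``r -> 0.5`` as ``d -> inf``.
    """
    if d < 0:
        raise ValueError("map distance must be >= 0")
    m = d / 100.0
    if map_function == HALDANE:
        return 0.5 * (1.0 - math.exp(-2.0 * m))
    if map_function == KOSAMBI:
        return 0.5 * math.tanh(2.0 * m)
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass
class GeneticMap:
    """Per-chromosome ordered locus positions plus a map function."""

    chromosomes: dict[str, list[tuple[str, float]]]
    map_function: str = HALDANE

    def __post_init__(self) -> None:
        self._pos: dict[str, tuple[str, float]] = {}
        for chrom, loci in self.chromosomes.items():
            last = -math.inf
            for lid, pos in loci:
                if pos < last:
                    raise ValueError(
                        f"positions on chromosome {chrom} must be non-decreasing"
                    )
                last = pos
                self._pos[lid] = (chrom, pos)

    def position(self, locus_id: str) -> tuple[str, float]:
        try:
            return self._pos[locus_id]
        except KeyError:
            raise UnknownLocusError(f"locus {locus_id!r} is not on the map") from None

    def r(self, a: str, b: str) -> float:
        """Pairwise recombination fraction; 0.5 for unlinked loci."""
        ca, pa = self.position(a)
        cb, pb = self.position(b)
        if ca != cb:
            return 0.5
        return recomb_fraction(abs(pa - pb), self.map_function)

    @classmethod
    def from_registry(cls, registry: LocusRegistry, map_function: str = HALDANE):
        chroms: dict[str, list[tuple[str, float]]] = {}
        for arch in registry.uci.values():
            chroms.setdefault(arch.chromosome, []).append(
                (arch.locus_id, arch.position_cM)
            )
        for aux in registry.aux.values():
            chroms.setdefault(aux.chromosome, []).append(
                (aux.locus_id, aux.position_cM)
            )
        for loci in chroms.values():
            loci.sort(key=lambda lp: lp[1])
        return cls(chroms, map_function)


@dataclass
class PoolComponent:
    donor: Genotype
    proportion: float = 1.0


@dataclass
class PollenPool:
    """A pollen source: one or more donor genotypes with proportions.

    ``application="mixed"`` pools the gametes before selection;
    ``"sequential"`` selects per component first and then mixes surviving
    components by ``sequential_weights`` (default equal), mirroring
    first-one-pollen-then-the-other field procedures.
    """

    components: list[PoolComponent]
    application: str = "mixed"
    sequential_weights: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("pollen pool needs at least one component")
        total = sum(c.proportion for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            for c in self.components:
                c.proportion /= total
        if self.application not in ("mixed", "sequential"):
            raise ValueError(f"unknown application {self.application!r}")
        if self.application == "sequential" and self.sequential_weights is None:
            k = len(self.components)
            self.sequential_weights = [1.0 / k] * k

    @classmethod
    def single(cls, donor: Genotype) -> "PollenPool":
        return cls([PoolComponent(donor, 1.0)])


@dataclass
class OffspringDistribution:
    """Exact probability mass over offspring genotypes after pollen selection."""

    mass: dict[Genotype, float] = field(default_factory=dict)
    rejected_pollen_fraction: float = 0.0

    @property
    def barren(self) -> bool:
        return not self.mass

    def marginal(self, locus_id: str) -> dict[str, float]:
        """Genotype-class probabilities at one locus."""
        out: dict[str, float] = {}
        for g, w in self.mass.items():
            lab = g.locus_label(locus_id)
            out[lab] = out.get(lab, 0.0) + w
        return out


@dataclass
class SeedSetOutcome:
    compatible_fraction: float
    expected_seeds: float
    klass: str  # "full" | "low"


# ---------------------------------------------------------------------------
# gamete enumeration


def _align(genotypes: Sequence[Genotype], registry: LocusRegistry) -> list[Genotype]:
    """Extend genotypes to a common locus set, filling UCI loci with
    wildtype haplotypes and aux loci with their null allele."""
    loci: set[str] = set()
    for g in genotypes:
        loci.update(g.locus_ids())
    out = []
    for g in genotypes:
        u, a = g.uci, g.aux
        for lid in loci:
            if lid in u or lid in a:
                continue
            if lid in registry.uci:
                wt = Haplotype(lid, False, False)
                u = {**u, lid: (wt, wt)}
            else:
                null = registry.aux[lid].null_allele if lid in registry.aux else "-"
                a = {**a, lid: (null, null)}
        out.append(Genotype.make(u, a))
    return out


def gamete_distribution(g: Genotype, gmap: GeneticMap) -> list[GameteType]:
    """Enumerate the exact gamete distribution of a genotype.

    Loci on the same chromosome recombine per the map; loci on different
    chromosomes assort independently.  Weights sum to 1.
    """
    # group this genotype's loci by chromosome, ordered by position
    alleles: dict[str, tuple] = {**g.uci, **g.aux}
    by_chrom: dict[str, list[tuple[float, str]]] = {}
    for lid in alleles:
        chrom, pos = gmap.position(lid)
        by_chrom.setdefault(chrom, []).append((pos, lid))
    per_chrom: list[list[tuple[dict, float]]] = []
    for chrom, loci in by_chrom.items():
        loci.sort()
        ordered = [lid for _, lid in loci]
        rs = [gmap.r(ordered[i], ordered[i + 1]) for i in range(len(ordered) - 1)]
        outcomes: dict[tuple, tuple[dict, float]] = {}
        for mask in range(2 ** len(ordered)):
            picks = [(mask >> i) & 1 for i in range(len(ordered))]
            w = 0.5
            for i in range(1, len(ordered)):
                w *= rs[i - 1] if picks[i] != picks[i - 1] else 1.0 - rs[i - 1]
            chosen = {lid: alleles[lid][picks[i]] for i, lid in enumerate(ordered)}
            key = tuple(sorted((k, repr(v)) for k, v in chosen.items()))
            if key in outcomes:
                outcomes[key] = (chosen, outcomes[key][1] + w)
            else:
                outcomes[key] = (chosen, w)
        per_chrom.append(list(outcomes.values()))
    # cartesian product across chromosomes
    combos: list[tuple[dict, float]] = [({}, 1.0)]
    for outcomes in per_chrom:
        combos = [
            ({**acc, **chosen}, wa * w)
            for acc, wa in combos
            for chosen, w in outcomes
        ]
    merged: dict[tuple, GameteType] = {}
    for chosen, w in combos:
        gam = GameteType(chosen, w)
        k = gam.key()
        if k in merged:
            merged[k].weight += w
        else:
            merged[k] = gam
    return list(merged.values())


def select_pollen(
    gametes: Iterable[GameteType],
    silk: Genotype,
    registry: LocusRegistry,
    donor: Optional[Genotype] = None,
) -> tuple[list[GameteType], float]:
    """Remove incompatible gametes and renormalize the survivors.

    Returns ``(survivors, rejected_fraction)``.  Total incompatibility is a
    valid outcome: an empty list with rejected fraction 1.  The operation
    is idempotent.
    """
    gametes = list(gametes)
    total = sum(g.weight for g in gametes)
    kept = [g for g in gametes if pollen_compatible(g, silk, registry, donor)]
    kept_mass = sum(g.weight for g in kept)
    if total <= 0 or kept_mass <= 0:
        return [], 1.0 if total > 0 else 0.0
    survivors = [GameteType(dict(g.alleles), g.weight / kept_mass) for g in kept]
    return survivors, 1.0 - kept_mass / total


def _pool_gametes(
    pool: PollenPool,
    silk: Genotype,
    registry: LocusRegistry,
    gmap: GeneticMap,
    aligned_donors: list[Genotype],
) -> tuple[list[GameteType], float]:
    """Selected, renormalized paternal gamete distribution for a pool."""
    if pool.application == "mixed":
        raw: list[tuple[GameteType, Genotype]] = []
        for comp, donor in zip(pool.components, aligned_donors):
            for gam in gamete_distribution(donor, gmap):
                raw.append(
                    (GameteType(gam.alleles, gam.weight * comp.proportion), donor)
                )
        kept = [
            GameteType(dict(g.alleles), g.weight)
            for g, donor in raw
            if pollen_compatible(g, silk, registry, donor)
        ]
        kept_mass = sum(g.weight for g in kept)
        if kept_mass <= 0:
            return [], 1.0
        for g in kept:
            g.weight /= kept_mass
        return kept, 1.0 - kept_mass
    # sequential: per-component selection, then weighted mixing of the
    # components that retained any compatible mass
    weights = pool.sequential_weights or []
    surviving: list[tuple[list[GameteType], float]] = []
    rejected_mass = 0.0
    for comp, donor, w in zip(pool.components, aligned_donors, weights):
        gams = gamete_distribution(donor, gmap)
        sel, rej = select_pollen(gams, silk, registry, donor)
        rejected_mass += comp.proportion * rej
        if sel:
            surviving.append((sel, w))
    if not surviving:
        return [], 1.0
    wsum = sum(w for _, w in surviving)
    merged: dict[tuple, GameteType] = {}
    for sel, w in surviving:
        for g in sel:
            gg = GameteType(dict(g.alleles), g.weight * w / wsum)
            k = gg.key()
            if k in merged:
                merged[k].weight += gg.weight
            else:
                merged[k] = gg
    return list(merged.values()), rejected_mass


def cross(
    mother: Genotype,
    pool: PollenPool | Genotype,
    gmap: Optional[GeneticMap] = None,
    registry: Optional[LocusRegistry] = None,
) -> OffspringDistribution:
    """Exact offspring distribution of ``mother`` x ``pool``.

    Maternal gametes are unselected; paternal gametes pass
    :func:`select_pollen` against the maternal silk.  A fully incompatible
    pool yields an empty distribution with ``rejected_pollen_fraction=1``
    (a barren ear, not an exception).
    """
    if registry is None:
        raise ValueError("cross() requires a locus registry")
    if isinstance(pool, Genotype):
        pool = PollenPool.single(pool)
    if gmap is None:
        gmap = GeneticMap.from_registry(registry)
    donors = [c.donor for c in pool.components]
    aligned = _align([mother] + donors, registry)
    mother_a, donors_a = aligned[0], aligned[1:]

    paternal, rejected = _pool_gametes(pool, mother_a, registry, gmap, donors_a)
    if not paternal:
        return OffspringDistribution({}, 1.0)
    maternal = gamete_distribution(mother_a, gmap)

    # gametophytic-female variant: barriers expressed per maternal gamete
    gameto_female = [
        lid
        for lid in mother_a.uci
        if registry.arch(lid).female_mode == "gametophytic"
        and any(h.F for h in mother_a.uci[lid])
    ]

    mass: dict[Genotype, float] = {}
    pair_total = 0.0
    pair_rejected = 0.0
    for mg in maternal:
        for pg in paternal:
            w = mg.weight * pg.weight
            pair_total += w
            if gameto_female and not _egg_accepts(mg, pg, gameto_female, registry):
                pair_rejected += w
                continue
            child = _fuse(mg, pg)
            mass[child] = mass.get(child, 0.0) + w
    if not mass:
        return OffspringDistribution({}, 1.0)
    kept = sum(mass.values())
    mass = {g: w / kept for g, w in mass.items()}
    rejected = rejected + (1.0 - rejected) * (pair_rejected / pair_total)
    return OffspringDistribution(mass, rejected)


def _egg_accepts(
    mg: GameteType, pg: GameteType, loci: list[str], registry: LocusRegistry
) -> bool:
    for lid in loci:
        hap = mg.alleles.get(lid)
        if isinstance(hap, Haplotype) and hap.F:
            spec = registry.arch(lid).specificity
            ok = any(
                isinstance(a, Haplotype)
                and registry.arch(l).specificity == spec
                and a.P
                for l, a in pg.alleles.items()
                if l in registry.uci
            )
            if not ok:
                return False
    return True


def _fuse(mg: GameteType, pg: GameteType) -> Genotype:
    uci: dict[str, tuple[Haplotype, Haplotype]] = {}
    aux: dict[str, tuple[str, str]] = {}
    for lid, a in mg.alleles.items():
        b = pg.alleles[lid]
        if isinstance(a, Haplotype):
            uci[lid] = (a, b)  # type: ignore[assignment]
        else:
            aux[lid] = (a, b)  # type: ignore[assignment]
    return Genotype.make(uci, aux)


def compatible_fraction(
    silk: Genotype,
    pool: PollenPool | Genotype,
    registry: LocusRegistry,
    gmap: Optional[GeneticMap] = None,
) -> float:
    """Fraction of the pool's pollen mass passing the silk's barriers."""
    if isinstance(pool, Genotype):
        pool = PollenPool.single(pool)
    if gmap is None:
        gmap = GeneticMap.from_registry(registry)
    donors = [c.donor for c in pool.components]
    aligned = _align([silk] + donors, registry)
    silk_a, donors_a = aligned[0], aligned[1:]
    frac = 0.0
    for comp, donor in zip(pool.components, donors_a):
        gams = gamete_distribution(donor, gmap)
        frac += comp.proportion * sum(
            g.weight
            for g in gams
            if pollen_compatible(g, silk_a, registry, donor)
        )
    return frac


def seed_set(
    silk: Genotype,
    pool: PollenPool | Genotype,
    registry: LocusRegistry,
    ovules: int = 300,
    contamination: float = 0.0,
    gmap: Optional[GeneticMap] = None,
    seed_threshold: int = SEED_THRESHOLD,
) -> SeedSetOutcome:
    """Binary field seed-set phenotype under the pollen-excess model.

    Any nonzero compatible fraction saturates the ear (``expected_seeds =
    ovules``); a fully incompatible pool yields only the contamination
    leak ``ovules * contamination``.  ``klass`` is ``"low"`` iff expected
    seeds fall at or below the ``<5 seeds`` threshold.
    """
    if ovules < 1:
        raise ValueError("ovules must be >= 1")
    if not 0.0 <= contamination < 1.0:
        raise ValueError("contamination must be in [0, 1)")
    cf = compatible_fraction(silk, pool, registry, gmap)
    if cf > 0:
        expected = float(ovules)
    else:
        expected = ovules * contamination
    cf_total = cf + (1.0 - cf) * contamination
    klass = "low" if expected <= seed_threshold else "full"
    return SeedSetOutcome(cf_total, expected, klass)


COLOR_LOCUS = "kernel_color"
PURPLE = "purple"
YELLOW = "yellow"


def kernel_color(g: Genotype) -> str:
    """Kernel colour readout: purple dominant over yellow."""
    pair = g.aux.get(COLOR_LOCUS, (YELLOW, YELLOW))
    return PURPLE if PURPLE in pair else YELLOW


def ear_composition(
    mother: Genotype,
    pool: PollenPool | Genotype,
    registry: LocusRegistry,
    gmap: Optional[GeneticMap] = None,
    classifier=kernel_color,
) -> dict[str, float]:
    """Kernel-class fractions on one ear (``{"none": 1.0}`` when barren)."""
    dist = cross(mother, pool, gmap, registry)
    if dist.barren:
        return {"none": 1.0}
    out: dict[str, float] = {}
    for g, w in dist.mass.items():
        k = classifier(g)
        out[k] = out.get(k, 0.0) + w
    return out
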