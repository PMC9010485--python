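import itertools
import math
import random

import pytest

from ucigen.cross_engine import (
    GeneticMap,
    PollenPool,
    PoolComponent,
    cross,
    ear_composition,
    gamete_distribution,
    recomb_fraction,
    seed_set,
    select_pollen,
)
from ucigen.genetic_model import (
    Genotype,
    Haplotype,
    LocusRegistry,
    UnknownLocusError,
)
from ucigen.lines import GA1, GA2, uci_pair


class TestRecombFraction:
    def test_zero_distance(self):
        assert recomb_fraction(0.0) == 0.0
        assert recomb_fraction(0.0, "kosambi") == 0.0

    def test_asymptote(self):
        assert recomb_fraction(1e6) == pytest.approx(0.5)
        assert recomb_fraction(1e6, "kosambi") == pytest.approx(0.5)

    def test_haldane_closed_form(self):
        # 0.5 * (1 - exp(-2*1.21/100)) evaluated independently
        assert recomb_fraction(1.21) == pytest.approx(0.011955, abs=1e-6)

    def test_kosambi_closed_form(self):
        assert recomb_fraction(1.21, "kosambi") == pytest.approx(
            0.5 * math.tanh(2 * 1.21 / 100), abs=1e-12
        )

    def test_negative_distance_errors(self):
        with pytest.raises(ValueError):
            recomb_fraction(-0.1)


class TestGameteDistribution:
    def test_single_locus_heterozygote(self, gmap):
        het = Genotype.make({GA2: uci_pair(GA2, "S", "wt")})
        gams = gamete_distribution(het, gmap)
        assert len(gams) == 2
        assert all(g.weight == pytest.approx(0.5) for g in gams)

    def test_homozygote_single_gamete(self, gmap, founders):
        gams = gamete_distribution(founders["511L"], gmap)
        assert len(gams) == 1
        assert gams[0].weight == pytest.approx(1.0)

    def test_linked_pair_in_coupling(self):
        # two linked loci at r=0.1: parentals 0.45 each, recombinants 0.05
        reg = LocusRegistry()
        gmap = GeneticMap({"1": [("A", 0.0), ("B", 11.157)]})  # r(11.157cM)~0.1
        r = gmap.r("A", "B")
        assert r == pytest.approx(0.1, abs=1e-3)
        g = Genotype.make({}, {"A": ("a1", "a2"), "B": ("b1", "b2")})
        gams = gamete_distribution(g, gmap)
        w = {tuple(sorted(x.alleles.values())): x.weight for x in gams}
        assert w[("a1", "b1")] == pytest.approx((1 - r) / 2)
        assert w[("a1", "b2")] == pytest.approx(r / 2)

    def test_weights_sum_to_one(self, gmap, founders):
        for name in ("511L", "Mo17", "Ga1Ga2", "CS-hemi"):
            gams = gamete_distribution(founders[name], gmap)
            assert sum(g.weight for g in gams) == pytest.approx(1.0)

    def test_unmapped_locus_errors(self, registry):
        gmap = GeneticMap({"1": [("A", 0.0)]})
        g = Genotype.make({GA2: uci_pair(GA2, "S", "wt")})
        with pytest.raises(UnknownLocusError):
            gamete_distribution(g, gmap)


class TestSelectPollen:
    def test_f1_pollen_on_S_silk(self, registry, gmap, founders):
        f1 = Genotype.make({GA2: uci_pair(GA2, "S", "wt")})
        gams = gamete_distribution(f1, gmap)
        kept, rejected = select_pollen(gams, founders["511L"], registry)
        assert rejected == pytest.approx(0.5)
        assert len(kept) == 1 and kept[0].weight == pytest.approx(1.0)
        assert kept[0].alleles[GA2].P

    def test_total_incompatibility(self, registry, gmap, founders):
        gams = gamete_distribution(founders["W22"], gmap)
        kept, rejected = select_pollen(gams, founders["511L"], registry)
        assert kept == [] and rejected == 1.0

    def test_no_barrier_no_selection(self, registry, gmap, founders):
        gams = gamete_distribution(founders["511L"], gmap)
        kept, rejected = select_pollen(gams, founders["W22"], registry)
        assert rejected == 0.0
        assert sum(g.weight for g in kept) == pytest.approx(1.0)

    def test_idempotence(self, registry, gmap, founders):
        f1 = Genotype.make({GA2: uci_pair(GA2, "S", "wt")})
        gams = gamete_distribution(f1, gmap)
        once, _ = select_pollen(gams, founders["511L"], registry)
        twice, rej2 = select_pollen(once, founders["511L"], registry)
        assert rej2 == pytest.approx(0.0)
        assert {g.key(): g.weight for g in twice} == pytest.approx(
            {g.key(): g.weight for g in once}
        )


class TestCross:
    def test_selected_backcross_single_genotype(self, registry, gmap, founders):
        f1 = Genotype.make(
            {GA2: uci_pair(GA2, "S", "wt")}, {"kernel_color": ("yellow", "yellow")}
        )
        dist = cross(founders["511L"], f1, gmap, registry)
        assert dist.rejected_pollen_fraction == pytest.approx(0.5)
        marg = dist.marginal(GA2)
        assert marg == pytest.approx({"S/S": 1.0})

    def test_unselected_backcross_one_to_one(self, registry, gmap, founders):
        f1 = Genotype.make(
            {GA2: uci_pair(GA2, "S", "wt")}, {"kernel_color": ("yellow", "yellow")}
        )
        dist = cross(founders["W22"], f1, gmap, registry)
        marg = dist.marginal(GA2)
        assert marg == pytest.approx({"S/wt": 0.5, "wt/wt": 0.5})

    def test_mendelian_f2(self, registry, gmap):
        het = Genotype.make({}, {"kernel_color": ("purple", "yellow")})
        dist = cross(het, het, gmap, registry)
        marg = dist.marginal("kernel_color")
        assert marg == pytest.approx(
            {"purple/purple": 0.25, "purple/yellow": 0.5, "yellow/yellow": 0.25}
        )

    def test_barren_ear_is_a_value(self, registry, gmap, founders):
        dist = cross(founders["511L"], founders["W22"], gmap, registry)
        assert dist.barren
        assert dist.rejected_pollen_fraction == 1.0

    def test_mixed_pool_component_order_invariant(self, registry, gmap, founders):
        pool_ab = PollenPool(
            [PoolComponent(founders["ZYM1"], 0.5), PoolComponent(founders["Mo17"], 0.5)]
        )
        pool_ba = PollenPool(
            [PoolComponent(founders["Mo17"], 0.5), PoolComponent(founders["ZYM1"], 0.5)]
        )
        da = cross(founders["W22"], pool_ab, gmap, registry)
        db = cross(founders["W22"], pool_ba, gmap, registry)
        assert da.mass == pytest.approx(db.mass)


# --- brute-force oracle ---------------------------------------------------


def _oracle_gametes(pairs, gmap):
    """Independent enumeration: explicit per-chromosome phase weights."""
    loci = sorted(pairs)
    by_chrom = {}
    for lid in loci:
        chrom, pos = gmap.position(lid)
        by_chrom.setdefault(chrom, []).append((pos, lid))
    out = {}
    for picks in itertools.product([0, 1], repeat=len(loci)):
        pick = dict(zip(loci, picks))
        w = 1.0
        for chrom, plist in by_chrom.items():
            plist = sorted(plist)
            w *= 0.5
            for (p0, l0), (p1, l1) in zip(plist, plist[1:]):
                r = 0.5 * (1 - math.exp(-2 * (p1 - p0) / 100))
                w *= r if pick[l0] != pick[l1] else 1 - r
        alleles = tuple((lid, pairs[lid][pick[lid]]) for lid in loci)
        out[alleles] = out.get(alleles, 0.0) + w
    return out


def _oracle_compatible(pat_alleles, silk_pairs, registry):
    pat = dict(pat_alleles)
    for lid, pair in silk_pairs.items():
        arch = registry.uci.get(lid)
        if arch is None:
            continue
        if sum(1 for h in pair if h.F) >= arch.female_dose_threshold:
            spec = arch.specificity
            if not any(
                isinstance(a, Haplotype)
                and registry.uci[l].specificity == spec
                and a.P
                for l, a in pat.items()
                if l in registry.uci
            ):
                return False
    return True


def _oracle_cross(mother, father, registry, gmap):
    mg = _oracle_gametes({**mother.uci, **mother.aux}, gmap)
    fg = _oracle_gametes({**father.uci, **father.aux}, gmap)
    mass = {}
    total = 0.0
    for ma, mw in mg.items():
        for fa, fw in fg.items():
            if not _oracle_compatible(fa, mother.uci, registry):
                continue
            uci, aux = {}, {}
            for (lid, a), (_, b) in zip(ma, fa):
                if isinstance(a, Haplotype):
                    uci[lid] = (a, b)
                else:
                    aux[lid] = (a, b)
            child = Genotype.make(uci, aux)
            mass[child] = mass.get(child, 0.0) + mw * fw
            total += mw * fw
    return {g: w / total for g, w in mass.items()} if total else {}


LABELS = ["S", "M", "wt", "Fonly"]


def _random_genotype(rng, loci):
    return Genotype.make(
        {lid: uci_pair(lid, rng.choice(LABELS), rng.choice(LABELS)) for lid in loci}
    )


@pytest.mark.parametrize("n_loci", [1, 2, 3])
def test_cross_equals_bruteforce_oracle(n_loci, registry):
    """Engine output equals exhaustive gamete-pair enumeration (<=3 loci)."""
    reg = LocusRegistry(dict(registry.uci), {})
    # put a third locus partially linked to Ga2 to exercise recombination
    gmap = GeneticMap({"5": [(GA2, 0.0), ("LNK", 7.5)], "4": [(GA1, 0.0)]})
    if n_loci == 3:
        from ucigen.genetic_model import LocusArchitecture

        reg.add(LocusArchitecture("LNK", chromosome="5", position_cM=7.5))
    loci = [GA2, GA1, "LNK"][:n_loci]
    rng = random.Random(20240917)
    for _ in range(25):
        mother = _random_genotype(rng, loci)
        father = _random_genotype(rng, loci)
        expected = _oracle_cross(mother, father, reg, gmap)
        dist = cross(mother, father, gmap, reg)
        assert set(dist.mass) == set(expected)
        for g, w in expected.items():
            assert dist.mass[g] == pytest.approx(w, abs=1e-12)


class TestSeedSet:
    def test_compatible_donor_full(self, registry, founders):
        f1 = Genotype.make({GA2: uci_pair(GA2, "S", "wt")})
        out = seed_set(founders["511L"], f1, registry, ovules=300)
        assert out.klass == "full" and out.expected_seeds == 300

    def test_incompatible_barren(self, registry, founders):
        out = seed_set(founders["511L"], founders["W22"], registry, ovules=300)
        assert out.klass == "low" and out.expected_seeds == 0

    def test_contamination_threshold_arithmetic(self, registry, founders):
        out = seed_set(
            founders["511L"], founders["W22"], registry, ovules=300, contamination=0.01
        )
        assert out.expected_seeds == pytest.approx(3.0)
        assert out.klass == "low"

    def test_validation(self, registry, founders):
        with pytest.raises(ValueError):
            seed_set(founders["511L"], founders["W22"], registry, ovules=0)
        with pytest.raises(ValueError):
            seed_set(founders["511L"], founders["W22"], registry, contamination=1.0)


class TestEarComposition:
    def _pool(self, founders, application):
        return PollenPool(
            [PoolComponent(founders["ZYM1"], 0.5), PoolComponent(founders["Mo17"], 0.5)],
            application=application,
        )

    def test_homozygous_transgene_yellow_only(self, registry, founders):
        comp = ear_composition(
            founders["CS-hom"], self._pool(founders, "sequential"), registry
        )
        assert comp == pytest.approx({"yellow": 1.0})

    def test_hemizygous_transgene_mixed(self, registry, founders):
        comp = ear_composition(
            founders["CS-hemi"], self._pool(founders, "sequential"), registry
        )
        assert comp["purple"] > 0 and comp["yellow"] > 0

    def test_barrier_free_mixed_pool_half_half(self, registry, founders):
        comp = ear_composition(founders["W22"], self._pool(founders, "mixed"), registry)
        assert comp == pytest.approx({"purple": 0.5, "yellow": 0.5})

    def test_barren_ear(self, registry, founders):
        comp = ear_composition(
            founders["511L"], PollenPool.single(founders["ZYM1"]), registry
        )
        assert comp == {"none": 1.0}
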