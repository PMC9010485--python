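"""Executable catalog of the named experimental designs.

Each design is data (a YAML fixture entry): a pedigree of cross/self steps
building named populations from founder genotypes, plus a readout that
reduces a population or a single cross to an expected class distribution.
``predict`` runs the exact enumeration through the cross engine — no
sampling anywhere — and ``compare_architectures`` re-runs a design under
alternative locus architectures (sporophytic-male, dose-threshold-1,
gametophytic-female) to show which variants the data can discriminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Optional

import yaml

from . import lines
from .cross_engine import (
    GeneticMap,
    OffspringDistribution,
    PollenPool,
    PoolComponent,
    compatible_fraction,
    cross,
    ear_composition,
    recomb_fraction,
)
from .genetic_model import Genotype, LocusRegistry

__all__ = [
    "ExperimentDesign",
    "ExpectedOutcome",
    "catalog",
    "get_design",
    "predict",
    "compare_architectures",
    "ratio_string",
]


@dataclass(frozen=True)
class ExperimentDesign:
    design_id: str
    description: str
    pedigree: tuple[dict, ...]
    readout: dict
    n_reported: Optional[int] = None
    reported_ratio: Optional[str] = None


@dataclass
class ExpectedOutcome:
    """Predicted class distribution for a named design."""

    classes: tuple[str, ...]
    probabilities: tuple[float, ...]
    ratio_string: str
    details: dict = field(default_factory=dict)

    def prob(self, klass: str) -> float:
        return dict(zip(self.classes, self.probabilities)).get(klass, 0.0)


def ratio_string(probabilities) -> str:
    """Canonical reduced ratio, e.g. (0.875, 0.125) -> "7:1".

    Falls back to formatted probabilities when no small-integer ratio
    matches within 1e-9.
    """
    fracs = [Fraction(p).limit_denominator(10_000) for p in probabilities]
    if any(abs(float(f) - p) > 1e-9 for f, p in zip(fracs, probabilities)):
        return ":".join(f"{p:.6g}" for p in probabilities)
    denom = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
    ints = [int(f * denom) for f in fracs]
    g = math.gcd(*ints) if any(ints) else 1
    ints = [i // g for i in ints]
    if max(ints, default=0) > 10_000:
        return ":".join(f"{p:.6g}" for p in probabilities)
    return ":".join(str(i) for i in ints)


def _load_fixture() -> list[dict]:
    text = resources.files("ucigen").joinpath("data/designs.yaml").read_text()
    return yaml.safe_load(text)["designs"]


def catalog() -> list[ExperimentDesign]:
    """All bundled designs, each executable by :func:`predict`."""
    out = []
    for entry in _load_fixture():
        out.append(
            ExperimentDesign(
                design_id=entry["id"],
                description=entry["description"],
                pedigree=tuple(entry.get("pedigree") or ()),
                readout=entry["readout"],
                n_reported=entry.get("n_reported"),
                reported_ratio=entry.get("reported_ratio"),
            )
        )
    return out


def get_design(design_id: str) -> ExperimentDesign:
    for d in catalog():
        if d.design_id == design_id:
            return d
    raise KeyError(f"unknown design {design_id!r}")


# ---------------------------------------------------------------------------
# pedigree interpreter

Population = dict[Genotype, float]


def _resolve(
    name: str, env: dict[str, Population], founder_map: dict[str, Genotype]
) -> Population:
    if name in env:
        return env[name]
    if name in founder_map:
        return {founder_map[name]: 1.0}
    raise KeyError(f"pedigree references undefined genotype/population {name!r}")


def _cross_populations(
    mothers: Population,
    fathers: Population,
    registry: LocusRegistry,
    gmap: GeneticMap,
) -> Population:
    """Pool offspring over all mother/father genotype pairs.

    Each non-barren mating contributes in proportion to the parental
    genotype frequencies (equal seeds per ear); barren matings contribute
    nothing and the rest renormalizes.
    """
    out: dict[Genotype, float] = {}
    total = 0.0
    for m, wm in mothers.items():
        for f, wf in fathers.items():
            dist = cross(m, f, gmap, registry)
            if dist.barren:
                continue
            w = wm * wf
            total += w
            for g, p in dist.mass.items():
                out[g] = out.get(g, 0.0) + w * p
    if total <= 0:
        return {}
    return {g: p / total for g, p in out.items()}


def _self_population(
    pop: Population, registry: LocusRegistry, gmap: GeneticMap
) -> Population:
    out: dict[Genotype, float] = {}
    total = 0.0
    for g, w in pop.items():
        dist = cross(g, g, gmap, registry)
        if dist.barren:
            continue
        total += w
        for c, p in dist.mass.items():
            out[c] = out.get(c, 0.0) + w * p
    if total <= 0:
        return {}
    return {g: p / total for g, p in out.items()}


def _run_pedigree(
    design: ExperimentDesign,
    registry: LocusRegistry,
    gmap: GeneticMap,
    founder_map: dict[str, Genotype],
) -> dict[str, Population]:
    env: dict[str, Population] = {}
    for step in design.pedigree:
        name = step["name"]
        if "cross" in step:
            spec = step["cross"]
            mothers = _resolve(spec["mother"], env, founder_map)
            fathers = _resolve(spec["father"], env, founder_map)
            env[name] = _cross_populations(mothers, fathers, registry, gmap)
        elif "self" in step:
            env[name] = _self_population(
                _resolve(step["self"], env, founder_map), registry, gmap
            )
        else:  # pragma: no cover - fixture validation
            raise ValueError(f"ill-formed pedigree step {step!r}")
    return env


def _build_pool(
    spec: dict, env: dict[str, Population], founder_map: dict[str, Genotype]
) -> PollenPool:
    comps = []
    for c in spec["components"]:
        pop = _resolve(c["donor"], env, founder_map)
        if len(pop) != 1:
            raise ValueError("pool components must be single genotypes")
        comps.append(PoolComponent(next(iter(pop)), c.get("proportion", 1.0)))
    return PollenPool(
        comps,
        application=spec.get("application", "mixed"),
        sequential_weights=spec.get("sequential_weights"),
    )


# ---------------------------------------------------------------------------
# prediction


def predict(
    design: ExperimentDesign | str,
    registry: Optional[LocusRegistry] = None,
    overrides: Optional[dict[str, dict]] = None,
    gmap: Optional[GeneticMap] = None,
) -> ExpectedOutcome:
    """Exact model prediction for a design, optionally under architecture
    overrides (``{"Ga2": {"female_dose_threshold": 1}}`` etc.)."""
    if isinstance(design, str):
        design = get_design(design)
    registry = registry or lines.default_registry()
    if overrides:
        for locus, fields in overrides.items():
            registry = registry.override(locus, **fields)
    gmap = gmap or GeneticMap.from_registry(registry)
    founder_map = lines.founders()
    env = _run_pedigree(design, registry, gmap, founder_map)
    ro = design.readout
    kind = ro["kind"]

    if kind == "donor_seedset":
        pop = _resolve(ro["population"], env, founder_map)
        tester = founder_map[ro["tester"]]
        full = sum(
            w
            for g, w in pop.items()
            if compatible_fraction(tester, g, registry, gmap) > 0
        )
        probs = (full, 1.0 - full)
    elif kind == "silk_seedset":
        pop = _resolve(ro["population"], env, founder_map)
        tester = founder_map[ro["tester"]]
        full = sum(
            w
            for g, w in pop.items()
            if compatible_fraction(g, tester, registry, gmap) > 0
        )
        probs = (full, 1.0 - full)
    elif kind == "genotype_ratio":
        pop = _resolve(ro["population"], env, founder_map)
        marg: dict[str, float] = {}
        for g, w in pop.items():
            lab = g.locus_label(ro["locus"])
            marg[lab] = marg.get(lab, 0.0) + w
        probs = tuple(marg.get(c, 0.0) for c in ro["classes"])
    elif kind == "marker_transmission":
        # probability a surviving paternal gamete carries the donor allele
        # at every listed flanking marker: prod(1 - r_i)
        from .mapping_sim import default_panel

        panel = default_panel()
        p_all = 1.0
        for m in ro["markers"]:
            d = abs(panel.position_cM(m) - panel.determinant_cM)
            p_all *= 1.0 - recomb_fraction(d, gmap.map_function)
        probs = (p_all, 1.0 - p_all)
    elif kind == "ear_composition":
        mother = founder_map[ro["mother"]]
        pool = _build_pool(ro["pool"], env, founder_map)
        comp = ear_composition(mother, pool, registry, gmap)
        classes = tuple(ro["classes"]) if "none" not in comp else ("none",)
        probs = tuple(comp.get(c, 0.0) for c in classes)
        return ExpectedOutcome(classes, probs, ratio_string(probs), {"raw": comp})
    elif kind == "progeny_fraction":
        mother = founder_map[ro["mother"]]
        pool = _build_pool(ro["pool"], env, founder_map)
        dist = cross(mother, pool, gmap, registry)
        if ro["classifier"] != "transgene":  # pragma: no cover
            raise ValueError(f"unknown classifier {ro['classifier']!r}")
        carrier = sum(
            w for g, w in dist.mass.items() if lines.carries_transgene(g)
        )
        probs = (carrier, 1.0 - carrier)
    elif kind == "compatibility_matrix":
        cells: dict[str, float] = {}
        for fname in ro["females"]:
            female = founder_map[fname]
            for dspec in ro["donors"]:
                if isinstance(dspec, dict) and "mix" in dspec:
                    comps = [
                        PoolComponent(founder_map[n], 1.0 / len(dspec["mix"]))
                        for n in dspec["mix"]
                    ]
                    pool = PollenPool(comps)
                    label = "+".join(dspec["mix"])
                else:
                    pool = PollenPool.single(founder_map[dspec])
                    label = dspec
                cells[f"{fname}|{label}"] = compatible_fraction(
                    female, pool, registry, gmap
                )
        classes = tuple(
            f"{k}:{'compatible' if v > 0 else 'barren'}" for k, v in cells.items()
        )
        n = len(classes)
        return ExpectedOutcome(
            classes, tuple([1.0 / n] * n), "matrix", {"matrix": cells}
        )
    else:  # pragma: no cover - fixture validation
        raise ValueError(f"unknown readout kind {kind!r}")

    classes = tuple(ro["classes"])
    return ExpectedOutcome(classes, probs, ratio_string(probs))


def compare_architectures(
    design: ExperimentDesign | str,
    variants: list[tuple[str, dict[str, dict]]],
    registry: Optional[LocusRegistry] = None,
) -> list[tuple[str, ExpectedOutcome]]:
    """Prediction table under alternative architectures.

    ``variants`` is a list of ``(label, overrides)`` pairs; the default
    architecture is always included first under the label ``"default"``.
    """
    rows = [("default", predict(design, registry))]
    for label, overrides in variants:
        rows.append((label, predict(design, registry, overrides=overrides)))
    return rows
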