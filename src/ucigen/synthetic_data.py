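"""Finite-sample data generators with the statistical structure the
analysis assumes: multinomial sampling of predicted class probabilities,
field misclassification of ear phenotypes, stray-pollen contamination, and
per-marker genotyping error.  One global seed with per-operation substream
derivation makes every output replayable byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import designs as _designs
from . import lines
from .cross_engine import GeneticMap, PollenPool, PoolComponent, ear_composition
from .mapping_sim import MarkerPanel, default_panel, simulate_female_screen, simulate_screen
from .segstats import CountData

__all__ = ["NoiseModel", "gen_counts", "gen_marker_table", "gen_ear_dataset", "substream"]


@dataclass(frozen=True)
class NoiseModel:
    """Field-realism noise knobs; all rates live in [0, 0.5)."""

    misclassification_eps: float = 0.0
    contamination_c: float = 0.0
    genotyping_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("misclassification_eps", "contamination_c", "genotyping_error"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Deterministic child RNG derived from the global seed and a tag path."""
    keys = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng([seed & 0xFFFFFFFF, *keys])


def gen_counts(
    design_id: str,
    n: int,
    noise: Optional[NoiseModel] = None,
) -> CountData:
    """Multinomial draw of class counts from a design's exact prediction,
    then per-individual misclassification flips with probability eps."""
    if n <= 0:
        raise ValueError("n must be positive")
    noise = noise or NoiseModel()
    outcome = _designs.predict(design_id)
    rng = substream(noise.seed, "gen_counts", design_id, str(n))
    counts = rng.multinomial(n, outcome.probabilities)
    eps = noise.misclassification_eps
    k = len(counts)
    if eps > 0 and k > 1:
        flipped = np.zeros(k, dtype=int)
        for i, c in enumerate(counts):
            stay = rng.binomial(c, 1.0 - eps)
            flipped[i] += stay
            stray = c - stay
            if stray:
                others = [j for j in range(k) if j != i]
                flipped[others] += rng.multinomial(stray, [1.0 / (k - 1)] * (k - 1))
        counts = flipped
    return CountData(design_id, outcome.classes, tuple(int(c) for c in counts))


def gen_marker_table(
    population: str,
    n: int,
    panel: Optional[MarkerPanel] = None,
    noise: Optional[NoiseModel] = None,
) -> pd.DataFrame:
    """Per-plant marker-call table for a named screen population.

    ``population`` is ``"male_screen"`` (gametic selection; the
    511L x (W22 x 511L) backcross) or ``"female_screen"`` (segregating
    (W22 x 511L) x W22-context screen).  Genotype calls per marker are
    "donor" (homozygous 511L) or "het"; genotyping error flips calls with
    the configured probability.  Columns: individual, marker, call.
    """
    noise = noise or NoiseModel()
    panel = panel or default_panel()
    rng = substream(noise.seed, "gen_marker_table", population, str(n))
    if population == "male_screen":
        sr = simulate_screen(n, panel, selection=True, rng=rng)
    elif population == "female_screen":
        sr = simulate_female_screen(n, panel, rng=rng)
    else:
        raise KeyError(f"unknown screen population {population!r}")
    calls = np.where(sr.gametes == 0, "donor", "het")
    if noise.genotyping_error > 0:
        flip = rng.random(calls.shape) < noise.genotyping_error
        calls = np.where(flip, np.where(calls == "donor", "het", "donor"), calls)
    records = [
        {"individual": f"P{i+1:05d}", "marker": m, "call": calls[i, j]}
        for i in range(n)
        for j, m in enumerate(panel.markers)
    ]
    df = pd.DataFrame.from_records(records)
    df.attrs["meta"] = {
        "population": population,
        "n": n,
        "seed": noise.seed,
        "genotyping_error": noise.genotyping_error,
    }
    return df


def gen_ear_dataset(
    mother: str,
    pool_donors: list[str],
    n_ears: int,
    ovules: int = 300,
    noise: Optional[NoiseModel] = None,
    application: str = "mixed",
) -> pd.DataFrame:
    """Per-ear kernel-class counts around the exact ear-composition
    expectation, with stray compatible pollen at rate ``contamination_c``
    drawn from the unselected pool."""
    noise = noise or NoiseModel()
    founders = lines.founders()
    registry = lines.default_registry()
    gmap = GeneticMap.from_registry(registry)
    mother_g = founders[mother]
    comps = [
        PoolComponent(founders[d], 1.0 / len(pool_donors)) for d in pool_donors
    ]
    pool = PollenPool(comps, application=application)
    comp = ear_composition(mother_g, pool, registry, gmap)
    c = noise.contamination_c
    if c > 0:
        # contamination: a fraction c of kernels drawn from the unselected pool
        from .cross_engine import kernel_color

        unsel: dict[str, float] = {}
        for pc in comps:
            col = kernel_color(pc.donor)
            unsel[col] = unsel.get(col, 0.0) + pc.proportion
        if "none" in comp:
            comp = dict(unsel)
            scale = c
        else:
            comp = {
                k: (1 - c) * comp.get(k, 0.0) + c * unsel.get(k, 0.0)
                for k in set(comp) | set(unsel)
            }
            scale = 1.0
    else:
        scale = 0.0 if "none" in comp else 1.0
    classes = sorted(k for k in comp if k != "none")
    rng = substream(noise.seed, "gen_ear_dataset", mother, *pool_donors)
    rows = []
    for e in range(n_ears):
        n_kernels = rng.binomial(ovules, scale) if scale < 1.0 else ovules
        if classes and n_kernels > 0:
            probs = np.array([comp[k] for k in classes], dtype=float)
            probs = probs / probs.sum()
            counts = rng.multinomial(n_kernels, probs)
        else:
            counts = np.zeros(len(classes), dtype=int)
        row = {"ear": f"E{e+1:03d}"}
        row.update({k: int(v) for k, v in zip(classes, counts)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["meta"] = {
        "mother": mother,
        "pool": "+".join(pool_donors),
        "n_ears": n_ears,
        "ovules": ovules,
        "contamination_c": c,
        "seed": noise.seed,
    }
    return df
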