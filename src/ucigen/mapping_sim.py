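"""Simulation and expectation calculus for the two fine-mapping screens.

* The **male** screen exploits complete gametophytic selection: in the
  donor-female x heterozygote-male backcross only determinant-carrying
  pollen fertilizes, so every survivor is homozygous for the donor
  determinant and phenotyping is unnecessary.  Among survivors, the
  frequency of the non-donor allele at a flanking marker equals the
  marker-determinant recombination fraction.
* The **female** screen genotypes a segregating backcross and phenotypes
  every plant by test pollination; recombinants appear as
  genotype-phenotype discordances.

Meioses are simulated as Markov chains along the marker ladder (Haldane,
no interference); breakpoints therefore fall uniformly within marker
intervals.  Allele coding: 0 = donor (511L), 1 = recurrent (W22).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .cross_engine import HALDANE, recomb_fraction

__all__ = [
    "MarkerPanel",
    "ScreenResult",
    "default_panel",
    "expected_recombinants",
    "simulate_screen",
    "simulate_female_screen",
    "localize",
    "backcross_program",
]

DONOR, RECURRENT = 0, 1


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker ladder spanning the determinant.

    Positions are physical (Mb) and converted to cM with a configurable
    local rate; logic never hardcodes marker names or positions.
    """

    markers: tuple[str, ...]
    positions_Mb: tuple[float, ...]
    determinant_Mb: float
    rate_cM_per_Mb: float = 0.2

    def __post_init__(self) -> None:
        if list(self.positions_Mb) != sorted(set(self.positions_Mb)):
            raise ValueError("marker positions must be strictly increasing")
        if not self.positions_Mb[0] < self.determinant_Mb < self.positions_Mb[-1]:
            raise ValueError("determinant must lie inside the panel")

    def position_cM(self, marker: str) -> float:
        return self.positions_Mb[self.markers.index(marker)] * self.rate_cM_per_Mb

    @property
    def determinant_cM(self) -> float:
        return self.determinant_Mb * self.rate_cM_per_Mb

    def r_to_determinant(self, marker: str) -> float:
        return recomb_fraction(
            abs(self.position_cM(marker) - self.determinant_cM), HALDANE
        )


def default_panel(
    rate_cM_per_Mb: Optional[float] = None, determinant_Mb: Optional[float] = None
) -> MarkerPanel:
    text = resources.files("ucigen").joinpath("data/marker_panel.yaml").read_text()
    cfg = yaml.safe_load(text)
    return MarkerPanel(
        markers=tuple(m["name"] for m in cfg["markers"]),
        positions_Mb=tuple(float(m["Mb"]) for m in cfg["markers"]),
        determinant_Mb=float(
            determinant_Mb if determinant_Mb is not None else cfg["determinant_Mb"]
        ),
        rate_cM_per_Mb=float(
            rate_cM_per_Mb if rate_cM_per_Mb is not None else cfg["rate_cM_per_Mb"]
        ),
    )


def expected_recombinants(n: int, d: float, map_function: str = HALDANE) -> float:
    """Expected recombinant count among n meioses across distance d (cM)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * recomb_fraction(d, map_function)


@dataclass
class ScreenResult:
    """Outcome of a simulated recombinant screen.

    ``gametes`` holds the informative (segregating) gamete per individual,
    one row per plant, one column per panel marker (0 donor / 1 recurrent).
    """

    n_screened: int
    panel: MarkerPanel
    gametes: np.ndarray
    determinant_alleles: np.ndarray
    phenotypes: Optional[np.ndarray] = None  # True = cross-compatible call
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def recombinant_mask(self) -> np.ndarray:
        return np.any(self.gametes != self.determinant_alleles[:, None], axis=1)

    @property
    def n_recombinants(self) -> int:
        return int(self.recombinant_mask.sum())

    def marker_donor_frequency(self) -> np.ndarray:
        return 1.0 - self.gametes.mean(axis=0)


def _simulate_gametes(
    n: int, panel: MarkerPanel, rng: np.random.Generator, condition_donor: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate n heterozygote gametes over the panel + determinant.

    When ``condition_donor`` the determinant allele is fixed to donor and
    the chain is extended outward from it (exact conditioning, not
    rejection sampling).
    """
    pos = [panel.position_cM(m) for m in panel.markers]
    det = panel.determinant_cM
    all_pos = sorted(set(pos) | {det})
    det_idx = all_pos.index(det)
    k = len(all_pos)
    rs = [
        recomb_fraction(all_pos[i + 1] - all_pos[i], HALDANE) for i in range(k - 1)
    ]
    alleles = np.empty((n, k), dtype=np.int8)
    if condition_donor:
        alleles[:, det_idx] = DONOR
    else:
        alleles[:, det_idx] = rng.integers(0, 2, size=n, dtype=np.int8)
    for i in range(det_idx + 1, k):  # rightward chain
        switch = rng.random(n) < rs[i - 1]
        alleles[:, i] = np.where(switch, 1 - alleles[:, i - 1], alleles[:, i - 1])
    for i in range(det_idx - 1, -1, -1):  # leftward chain
        switch = rng.random(n) < rs[i]
        alleles[:, i] = np.where(switch, 1 - alleles[:, i + 1], alleles[:, i + 1])
    marker_cols = [all_pos.index(p) for p in pos]
    det_alleles = alleles[:, det_idx].copy()
    return alleles[:, marker_cols], det_alleles


def simulate_screen(
    n: int,
    panel: Optional[MarkerPanel] = None,
    selection: bool = True,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ScreenResult:
    """Simulate the homogeneous-population (male-determinant) screen.

    Each individual receives one gamete from the heterozygous pollen
    parent.  With ``selection=True`` only determinant-carrying gametes
    fertilize, so the determinant allele is fixed at donor in every
    survivor — exactly, not approximately.
    """
    panel = panel or default_panel()
    if rng is None:
        rng = np.random.default_rng(seed)
    gametes, det = _simulate_gametes(n, panel, rng, condition_donor=selection)
    return ScreenResult(n, panel, gametes, det, seed=seed, meta={"selection": selection})


def simulate_female_screen(
    n: int,
    panel: Optional[MarkerPanel] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ScreenResult:
    """Simulate the genotype+phenotype (female-determinant) screen.

    Population: heterozygote-female x donor-male backcross, so the
    paternal gamete is uniformly donor and the maternal gamete segregates.
    Plants homozygous donor at the determinant express the silk barrier
    and set no seed on recurrent-parent test pollination (phenotype
    ``False`` = cross-incompatible); heterozygotes set full seed.
    """
    panel = panel or default_panel()
    if rng is None:
        rng = np.random.default_rng(seed)
    gametes, det = _simulate_gametes(n, panel, rng, condition_donor=False)
    phenotypes = det != DONOR  # compatible (full seed) iff heterozygous
    return ScreenResult(
        n, panel, gametes, det, phenotypes=phenotypes, seed=seed,
        meta={"screen": "female"},
    )


def localize(
    panel: MarkerPanel,
    recombinant_gametes: np.ndarray | Sequence[Sequence[int]],
    determinant_alleles: Sequence[int],
    recombinant_ids: Optional[Sequence[str]] = None,
) -> tuple[str, str]:
    """Narrow the determinant interval from recombinant marker vectors.

    Each recombinant's inferred determinant allele (from its compatibility
    phenotype) constrains the determinant to marker intervals adjacent to
    a marker sharing that allele — a compatible recombinant places the
    determinant on its donor-allele side.  The refined interval is the
    intersection of all constraints; an empty intersection signals
    genotyping or phenotyping error and raises, naming the conflict.
    """
    gams = np.asarray(recombinant_gametes, dtype=np.int8)
    dets = np.asarray(determinant_alleles, dtype=np.int8)
    k = len(panel.markers)
    if gams.size == 0:
        return panel.markers[0], panel.markers[-1]
    if gams.shape[1] != k:
        raise ValueError("marker vectors do not match panel size")
    ids = list(recombinant_ids or [f"R{i+1}" for i in range(len(gams))])
    allowed = np.ones(k - 1, dtype=bool)  # slot j = interval (M_j, M_j+1)
    constraining: list[str] = []
    for rid, v, d in zip(ids, gams, dets):
        slots = (v[:-1] == d) | (v[1:] == d)
        if not slots.all():
            constraining.append(rid)
        allowed &= slots
        if not allowed.any():
            raise ValueError(
                "contradictory recombinants: no interval satisfies "
                + ", ".join(constraining)
            )
    idx = np.flatnonzero(allowed)
    return panel.markers[idx[0]], panel.markers[idx[-1] + 1]


def fixture_recombinants(screen: str = "male") -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Bundled recombinant scenarios (R1-R3) for the default panel.

    Three single-crossover recombinants, each carrying the donor
    determinant allele (cross-compatible call), whose constraint
    intersection reproduces the published interval outputs: (M5, M8) for
    the male screen and (M3, M8) for the female screen.
    Returns (marker vectors, inferred determinant alleles, ids).
    """
    if screen == "male":
        gams = [
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0],  # breakpoint in (M5, M6)
            [0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1],  # breakpoint in (M7, M8)
            [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0],  # breakpoint in (M4, M5)
        ]
    elif screen == "female":
        gams = [
            [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],  # breakpoint in (M3, M4)
            [0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1],  # breakpoint in (M7, M8)
            [1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # breakpoint in (M2, M3)
        ]
    else:
        raise ValueError(f"unknown screen {screen!r}")
    arr = np.asarray(gams, dtype=np.int8)
    dets = np.zeros(len(gams), dtype=np.int8)  # all carry the donor determinant
    return arr, dets, [f"R{i+1}" for i in range(len(gams))]


def localize_screen(sr: ScreenResult) -> tuple[str, str]:
    """Convenience wrapper: localize using a ScreenResult's recombinants."""
    mask = sr.recombinant_mask
    return localize(sr.panel, sr.gametes[mask], sr.determinant_alleles[mask])


def backcross_program(
    generations: int = 8,
    n_background: int = 200,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[dict]:
    """Marker-assisted backcross toward a near-isogenic line.

    Single-seed descent with foreground selection: the donor segment is
    held heterozygous every generation while the unlinked background
    halves, giving an expected donor background fraction of (1/2)^(g+1)
    after g backcrosses.  A final selfing fixes the foreground (probability
    1/4 per selfed seed of homozygosity).  Returns one record per
    generation plus the selfed NIL.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # background locus state: 0 = recurrent homozygous, 1 = heterozygous
    het = np.ones(n_background, dtype=bool)
    records = []
    for g in range(1, generations + 1):
        keep = rng.random(n_background) < 0.5
        het &= keep
        records.append(
            {
                "generation": f"BC{g}",
                "expected_donor_fraction": 0.5 ** (g + 1),
                "simulated_donor_fraction": float(het.mean()) / 2.0,
                "foreground": "heterozygous",
            }
        )
    records.append(
        {
            "generation": f"BC{generations}F2",
            "expected_donor_fraction": 0.5 ** (generations + 1),
            "simulated_donor_fraction": float(het.mean()) / 2.0,
            "foreground": "homozygous (selected among selfed seed, P=1/4 each)",
        }
    )
    return records
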