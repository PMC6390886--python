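"""Autotetraploid meiosis and F1 population simulation.

Simulates a 2n=4x bi-parental F1 (modelled on a potato cross) with tetrasomic
inheritance.  Each meiosis forms either two bivalents (the four homologues
paired uniformly at random into one of the 3 possible pairings, each bivalent
transmitting one recombinant chromatid) or, with a configurable probability, a
quadrivalent in which the transmitted chromatids may descend from any
homologue and may be double-reduction products — a gamete carrying two
chromatid copies of the same homologue segment.  Crossovers follow a Poisson
process along the cM axis (no interference), so recombination fractions obey
Haldane's map function.

The simulator produces the true inherited homologue labels per individual and
grid position, from which gamete-class probability tables (with a tunable
informativeness emulating probabilistic haplotype reconstruction), marker
dosages, and phenotypes with a planted QTL plus polygenic / year / block /
residual variance structure are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .ibd import (
    BIVALENT_CLASSES,
    GAMETE_CLASSES,
    GameteClassProbabilities,
)

__all__ = [
    "MeiosisConfig",
    "PlantedQTL",
    "TrueInheritance",
    "simulate_gamete",
    "simulate_population",
    "inheritance_to_probabilities",
    "simulate_phenotypes",
]

_CROSSOVER_RATE = 0.01  # expected crossovers per cM (Haldane / no interference)
_DR_SWITCH_RATE = 0.02  # per-cM total switching rate of the DR state process

# sorted homologue pair -> index into GAMETE_CLASSES
_PAIR_TO_CLASS = np.full((4, 4), -1, dtype=np.int8)
for _k, _cls in enumerate(GAMETE_CLASSES):
    _a, _b = int(_cls[0]) - 1, int(_cls[1]) - 1
    _PAIR_TO_CLASS[_a, _b] = _k
    _PAIR_TO_CLASS[_b, _a] = _k

_BIVALENT_PAIRINGS = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)


@dataclass(frozen=True)
class MeiosisConfig:
    """Meiotic behaviour of one parent.

    Parameters
    ----------
    quadrivalent_rate
        Probability per meiosis per chromosome that the four homologues form
        a quadrivalent instead of two bivalents. In [0, 1].
    double_reduction_rate
        Probability that a quadrivalent-derived gamete is a double-reduction
        product at a given locus. In [0, 0.25] (the theoretical maximum at
        full equational segregation).
    """

    quadrivalent_rate: float = 0.0
    double_reduction_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.quadrivalent_rate <= 1.0:
            raise ValueError("quadrivalent_rate must be in [0, 1]")
        if not 0.0 <= self.double_reduction_rate <= 0.25:
            raise ValueError("double_reduction_rate must be in [0, 0.25]")


@dataclass
class PlantedQTL:
    """A known QTL planted in the simulated population.

    ``homologue_effects`` holds the additive effect (trait units per copy) of
    each of the 8 parental homologues (1-4 from parent 1, 5-8 from parent 2).
    ``dominance_effect`` is added once for carriers of at least one copy of a
    Q-labelled homologue; ``q_homologues`` defaults to the homologues with a
    non-zero additive effect.
    """

    chromosome: str
    position: float
    homologue_effects: np.ndarray
    dominance_effect: float = 0.0
    mu: float = 0.93
    q_homologues: tuple | None = None

    def __post_init__(self):
        eff = np.asarray(self.homologue_effects, dtype=float)
        if eff.shape != (8,) or not np.all(np.isfinite(eff)):
            raise ValueError("homologue_effects must be 8 finite values")
        self.homologue_effects = eff
        if self.q_homologues is None:
            self.q_homologues = tuple(int(h + 1) for h in np.flatnonzero(eff))


@dataclass
class TrueInheritance:
    """True inherited homologue labels for an F1 population.

    ``labels`` has shape ``(n_individuals, n_positions, 4)``: columns 0-1 are
    the sorted pair of parent-1 homologue labels (1..4) carried, columns 2-3
    the sorted pair of parent-2 labels (5..8).  A label may repeat within a
    pair only under double reduction.
    """

    labels: np.ndarray
    positions: pd.DataFrame
    individuals: np.ndarray
    dr_enabled: tuple = (False, False)

    @property
    def n_individuals(self) -> int:
        return self.labels.shape[0]

    @property
    def n_positions(self) -> int:
        return self.labels.shape[1]

    def locate(self, chromosome: str, position: float) -> int:
        mask = (self.positions["chromosome"] == str(chromosome)).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown chromosome {chromosome!r}")
        idx = np.flatnonzero(mask)
        pos = self.positions["position"].to_numpy()[idx]
        return int(idx[np.argmin(np.abs(pos - position))])

    def homologue_copies(self, position_index: int) -> np.ndarray:
        """(n_individuals, 8) true copy counts of each homologue."""
        lab = self.labels[:, position_index, :]
        copies = np.zeros((lab.shape[0], 8))
        for h in range(1, 9):
            copies[:, h - 1] = (lab == h).sum(axis=1)
        return copies


def _breakpoints(rng: np.random.Generator, length: float) -> np.ndarray:
    k = rng.poisson(_CROSSOVER_RATE * length)
    return np.sort(rng.uniform(0.0, length, k))


def _two_state_chain(rng, length, grid, states) -> np.ndarray:
    """Transmitted chromatid of one bivalent: flips partner at each crossover."""
    bps = _breakpoints(rng, length)
    start = rng.integers(2)
    seg = np.searchsorted(bps, grid, side="right")
    return np.asarray(states)[(start + seg) % 2]

def _jump_chain(rng, length, grid, n_states) -> np.ndarray:
    """Piecewise-constant chain that jumps to a uniform *other* state."""
    bps = _breakpoints(rng, length)
    states = np.empty(len(bps) + 1, dtype=np.int8)
    states[0] = rng.integers(n_states)
    for i in range(len(bps)):
        step = 1 + rng.integers(n_states - 1)
        states[i + 1] = (states[i] + step) % n_states
    seg = np.searchsorted(bps, grid, side="right")
    return states[seg]


def _dr_indicator(rng, length, grid, p) -> np.ndarray:
    """Two-state process with stationary double-reduction probability p.

    Continuous-time chain with entry rate rho*p and exit rate rho*(1-p) so
    the locus-wise DR probability equals p while DR tracts stay contiguous.
    """
    if p <= 0.0:
        return np.zeros(len(grid), dtype=bool)
    state = bool(rng.random() < p)
    bounds, states = [], [state]
    x = 0.0
    while True:
        rate = _DR_SWITCH_RATE * (p if not state else (1.0 - p))
        if rate <= 0.0:
            break
        x += rng.exponential(1.0 / rate)
        if x >= length:
            break
        state = not state
        bounds.append(x)
        states.append(state)
    seg = np.searchsorted(np.asarray(bounds), grid, side="right")
    return np.asarray(states, dtype=bool)[seg]


def simulate_gamete(
    gmap: GeneticMap,
    chromosome: str,
    config: MeiosisConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one gamete for one chromosome.

    Returns an ``(2, n_grid)`` array of homologue labels in 1..4 (sorted per
    position).  In bivalent mode the two labels are always distinct; in
    quadrivalent mode a repeated label marks a double-reduction locus.
    """
    length = gmap.length(chromosome)
    grid = gmap.chrom_grid(chromosome)
    if rng.random() < config.quadrivalent_rate:
        a = _jump_chain(rng, length, grid, 4)
        c = _jump_chain(rng, length, grid, 3)
        dr = _dr_indicator(rng, length, grid, config.double_reduction_rate)
        # c indexes the three homologues != a (sorted), giving the partner
        others = np.array(
            [[h for h in range(4) if h != s] for s in range(4)], dtype=np.int8
        )
        b = others[a, c]
        b = np.where(dr, a, b)
    else:
        pairing = _BIVALENT_PAIRINGS[rng.integers(3)]
        a = _two_state_chain(rng, length, grid, pairing[0])
        b = _two_state_chain(rng, length, grid, pairing[1])
    out = np.sort(np.stack([a, b]), axis=0).astype(np.int8) + 1
    return out


def simulate_population(
    n: int,
    gmap: GeneticMap,
    config_p1: MeiosisConfig,
    config_p2: MeiosisConfig,
    seed: int,
) -> TrueInheritance:
    """Simulate true inheritance for an F1 population of ``n`` individuals."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    positions = gmap.positions
    labels = np.empty((n, len(positions), 4), dtype=np.int8)
    for i in range(n):
        offset = 0
        for chrom in gmap.names:
            g1 = simulate_gamete(gmap, chrom, config_p1, rng)
            g2 = simulate_gamete(gmap, chrom, config_p2, rng) + 4
            width = g1.shape[1]
            labels[i, offset : offset + width, 0:2] = g1.T
            labels[i, offset : offset + width, 2:4] = g2.T
            offset += width
    individuals = np.array([f"F1_{i + 1:04d}" for i in range(n)])
    return TrueInheritance(
        labels=labels,
        positions=positions,
        individuals=individuals,
        dr_enabled=(
            config_p1.quadrivalent_rate > 0,
            config_p2.quadrivalent_rate > 0,
        ),
    )


def inheritance_to_probabilities(
    truth: TrueInheritance, informativeness: float = 1.0
) -> GameteClassProbabilities:
    """Gamete-class probability tables emulating haplotype reconstruction.

    The per-parent posterior is the mixture
    ``lam * one-hot(true class) + (1 - lam) * uniform`` over the admissible
    classes (6 bivalent classes, plus the 4 double-reduction classes when
    the parent's meiosis allows quadrivalents).  ``informativeness = 1``
    reproduces the truth exactly; ``0`` is completely uninformative (uniform,
    so every derived dosage is 0.5).
    """
    lam = float(informativeness)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("informativeness must be in [0, 1]")
    n, npos = truth.n_individuals, truth.n_positions
    probs = np.zeros((n, npos, 2, 10))
    for parent in (0, 1):
        pair = truth.labels[:, :, 2 * parent : 2 * parent + 2].astype(int)
        if parent == 1:
            pair = pair - 4
        cls = _PAIR_TO_CLASS[pair[:, :, 0] - 1, pair[:, :, 1] - 1]
        n_classes = 10 if truth.dr_enabled[parent] else len(BIVALENT_CLASSES)
        fill = (1.0 - lam) / n_classes
        probs[:, :, parent, :n_classes] = fill
        np.put_along_axis(
            probs[:, :, parent, :], cls[:, :, None], lam + fill, axis=2
        )
    return GameteClassProbabilities(
        probs=probs, positions=truth.positions, individuals=truth.individuals
    )


def simulate_phenotypes(
    truth: TrueInheritance,
    qtl: PlantedQTL | None,
    years: int = 1,
    blocks_per_year: int = 2,
    var_G_polygenic: float = 0.042,
    var_GxY: float = 0.001,
    var_E: float = 0.062,
    var_year: float = 0.001,
    var_block: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a multi-year, blocked field trial for the population.

    The record for clone i, year k, block j is::

        y_ijk = mu + sum_h alpha_h * copies_h(i) + d * 1[Q carrier]
                + G_i + Y_k + GY_ik + B_jk + e_ijk

    with independent Normal polygenic (``var_G_polygenic``), year
    (``var_year``), clone-by-year (``var_GxY``), block-within-year
    (``var_block``) and residual (``var_E``) effects.  Default variance
    magnitudes follow a potato protein-content trial (genetic 0.042,
    interaction 0.001, residual 0.062 trait-squared units).

    Columns: clone, year, block, dry_matter, pfj_protein, protein_content.
    The raw-measurement columns assume a constant tuber dry matter of 22.5%
    so the trait round-trips through the moisture-correction formula.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_individuals
    if qtl is not None:
        idx = truth.locate(qtl.chromosome, qtl.position)
        copies = truth.homologue_copies(idx)
        genetic = copies @ qtl.homologue_effects
        if qtl.dominance_effect:
            q_idx = [h - 1 for h in qtl.q_homologues]
            carrier = copies[:, q_idx].sum(axis=1) > 0
            genetic = genetic + qtl.dominance_effect * carrier
        mu = qtl.mu
    else:
        genetic = np.zeros(n)
        mu = 0.93
    polygenic = rng.normal(0.0, np.sqrt(var_G_polygenic), n)
    year_eff = rng.normal(0.0, np.sqrt(var_year), years)
    gxy = rng.normal(0.0, np.sqrt(var_GxY), (n, years))
    block_eff = rng.normal(0.0, np.sqrt(var_block), (years, blocks_per_year))
    records = []
    dry_matter = 22.5
    moisture = 100.0 - dry_matter
    for k in range(years):
        for j in range(blocks_per_year):
            y = (
                mu
                + genetic
                + polygenic
                + year_eff[k]
                + gxy[:, k]
                + block_eff[k, j]
                + rng.normal(0.0, np.sqrt(var_E), n)
            )
            records.append(
                pd.DataFrame(
                    {
                        "clone": truth.individuals,
                        "year": 2013 + k,
                        "block": j + 1,
                        "dry_matter": dry_matter,
                        "pfj_protein": y * 100.0 / moisture,
                        "protein_content": y,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
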