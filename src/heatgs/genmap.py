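"""Genetic map functions and the genetic-map container.

A map function links genetic map distance d (Morgans) to the recombination
fraction r between two loci.  The Kosambi function, r = tanh(2d)/2, allows
for partial crossover interference; the Haldane function, r = (1 - e^(-2d))/2,
assumes none.  Both are monotone bijections from [0, inf) onto [0, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def kosambi(d_cM):
    """Recombination fraction for a map distance in centiMorgans.

    r = 0.5 * tanh(2 d) with d in Morgans.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any distance is negative.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return r.item() if np.isscalar(d_cM) else r


def kosambi_inverse(r):
    """Map distance in centiMorgans for a recombination fraction.

    d = 0.25 * ln((1 + 2r) / (1 - 2r)) Morgans.

    Raises
    ------
    ValueError
        If any r is outside [0, 0.5).
    """
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * rr) / (1.0 - 2.0 * rr))
    return d.item() if np.isscalar(r) else d


def haldane(d_cM):
    """Haldane map function: r = 0.5 * (1 - exp(-2d)), d in Morgans."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r.item() if np.isscalar(d_cM) else r


def haldane_inverse(r):
    """Inverse Haldane function: d = -0.5 * ln(1 - 2r) Morgans, in cM."""
    rr = np.asarray(r, dtype=float)
    if np.any((rr < 0) | (rr >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * rr)
    return d.item() if np.isscalar(r) else d


MAP_FUNCTIONS = {
    "kosambi": (kosambi, kosambi_inverse),
    "haldane": (haldane, haldane_inverse),
}


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) per chromosome plus the map function.

    ``chromosomes`` maps chromosome id -> numpy array of positions in cM,
    non-decreasing within each chromosome.
    """

    chromosomes: dict = field(default_factory=dict)
    map_function: str = "kosambi"

    def __post_init__(self):
        if self.map_function not in MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")
        for chrom, pos in self.chromosomes.items():
            pos = np.asarray(pos, dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions on {chrom} are not sorted")
            self.chromosomes[chrom] = pos

    def recomb_fraction(self, d_cM):
        """r for a distance in cM under this map's function."""
        return MAP_FUNCTIONS[self.map_function][0](d_cM)

    def distance(self, r):
        """cM distance for a recombination fraction under this map's function."""
        return MAP_FUNCTIONS[self.map_function][1](r)

    def adjacent_recomb(self, chrom):
        """Recombination fractions between adjacent markers on a chromosome."""
        pos = self.chromosomes[chrom]
        return self.recomb_fraction(np.diff(pos))

    @property
    def total_length(self) -> float:
        return float(sum(p[-1] - p[0] for p in self.chromosomes.values() if len(p) > 1))
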