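"""Synthetic biparental single-seed-descent (SSD) populations.

Simulates the data-generating process the downstream analysis assumes: a
cross of two inbred founders advanced by selfing from F2 onward with one
seed per line per generation (no selection), GBS-like per-marker
missingness, and quantitative traits controlled by planted additive QTL
with configurable narrow-sense heritability and a genetic correlation
between trait pairs.

Meiosis places crossovers as a Poisson process on the centiMorgan scale
(no interference); residual heterozygosity therefore halves each selfing
generation: E[het] = (1/2)^(t-1) at F(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .variantio import GenotypeMatrix

GENERATION_ORDER = ("F2", "F3", "F4", "F5", "F6")

_PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of a synthetic SSD study population.

    Defaults mirror a tomato-scale desk design: 12 chromosomes of 120 cM,
    3000 GBS markers, 100 lines, two negatively correlated traits (yield
    per plant YP in kg, soluble solid content SSC in degrees Brix) with
    heritability 0.6 and genetic correlation -0.33.
    """

    n_chrom: int = 12
    chrom_length_cM: float = 120.0
    n_markers: int = 3000
    n_lines: int = 100
    generations: tuple = GENERATION_ORDER
    traits: tuple = ("YP", "SSC")
    trait_means: dict = field(default_factory=lambda: {"YP": 8.0, "SSC": 4.4})
    trait_sds: dict = field(default_factory=lambda: {"YP": 3.0, "SSC": 0.8})
    h2: dict = field(default_factory=lambda: {"YP": 0.6, "SSC": 0.6})
    rho_g: float = -0.33
    qtl_per_trait: int = 20
    ordinal_traits: tuple = ()  # scored 1-5 by thresholding a latent Gaussian
    missing_beta_a: float = 2.0  # per-marker missing rate ~ Beta(a, b)
    missing_beta_b: float = 8.0
    rare_marker_frac: float = 0.05  # markers replaced by a low-MAF spectrum tail
    maf_floor: float = 0.0
    bp_per_cM: float = 10_000.0
    transition_prob: float = 0.55  # substitution spectrum; Ts/Tv ~ p/(1-p)
    dominance: float = 0.0  # optional dominance coefficient at het loci
    seed: int = 0

    def __post_init__(self):
        if self.n_markers <= 0 or self.n_lines <= 0 or self.n_chrom <= 0:
            raise SimConfigError("n_markers, n_lines and n_chrom must be positive")
        for t in self.traits:
            if not 0.0 <= self.h2.get(t, 0.5) <= 1.0:
                raise SimConfigError(f"h2[{t}] outside [0, 1]")
        if not -1.0 <= self.rho_g <= 1.0:
            raise SimConfigError("rho_g outside [-1, 1]")
        if not 0.0 <= self.maf_floor <= 0.05:
            raise SimConfigError("maf_floor must lie in [0, 0.05]")
        unknown = [g for g in self.generations if g not in GENERATION_ORDER]
        if unknown:
            raise SimConfigError(f"unknown generations {unknown}")


@dataclass
class TruthRecord:
    """Ground truth of a simulated population, for oracle checks.

    ``qtl`` holds one row per (trait, QTL) with map position and the raw
    (unscaled) additive effect; ``effects`` holds the trait-scaled effect
    vectors actually used for phenotypes (fixed at the first generation a
    trait is phenotyped, so the architecture is constant across
    generations); ``genetic_values`` and ``realized_h2`` are keyed by
    (generation, trait).
    """

    qtl: pd.DataFrame
    map: GeneticMap
    effects: dict = field(default_factory=dict)
    unit_effects: dict = field(default_factory=dict)
    intercepts: dict = field(default_factory=dict)
    genetic_values: dict = field(default_factory=dict)
    realized_h2: dict = field(default_factory=dict)


def _chrom_name(i: int) -> str:
    return f"Chr{i + 1:02d}"


def _build_map(cfg: SimConfig, rng: np.random.Generator) -> GeneticMap:
    per = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per[: cfg.n_markers % cfg.n_chrom] += 1
    chroms = {}
    for i in range(cfg.n_chrom):
        pos = np.sort(rng.uniform(0.0, cfg.chrom_length_cM, size=per[i]))
        chroms[_chrom_name(i)] = pos
    return GeneticMap(chromosomes=chroms, map_function="kosambi")


def _marker_table(cfg: SimConfig, gmap: GeneticMap, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, pos_cM in gmap.chromosomes.items():
        bp = np.maximum(1, np.round(pos_cM * cfg.bp_per_cM).astype(int))
        # enforce strictly increasing physical positions
        for k in range(1, len(bp)):
            if bp[k] <= bp[k - 1]:
                bp[k] = bp[k - 1] + 1
        for p_bp, p_cM in zip(bp, pos_cM):
            ref = "ACGT"[rng.integers(4)]
            if rng.random() < cfg.transition_prob:
                alt = _PURINE_PARTNER[ref]
            else:
                alt = _TRANSVERSIONS[ref][rng.integers(2)]
            rows.append((chrom, int(p_bp), f"{chrom}_{p_bp}", ref, alt, p_cM))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "cM"])


def _meiosis(haps: np.ndarray, pos_cM: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per line from a (n_lines, 2, n_mark) haplotype block.

    Crossovers are Poisson with rate 1 per Morgan, placed uniformly; the
    starting haplotype is fair-coin.  With all markers at one position the
    gamete is a single parental haplotype.
    """
    n_lines, _, n_mark = haps.shape
    length_M = (pos_cM[-1] - pos_cM[0]) / 100.0 if n_mark > 1 else 0.0
    out = np.empty((n_lines, n_mark), dtype=haps.dtype)
    for i in range(n_lines):
        n_xo = rng.poisson(length_M)
        start = rng.integers(2)
        if n_xo == 0:
            which = np.full(n_mark, start)
        else:
            xo = np.sort(rng.uniform(pos_cM[0], pos_cM[-1], size=n_xo))
            which = (start + np.searchsorted(xo, pos_cM, side="left")) % 2
        out[i] = haps[i, which, np.arange(n_mark)]
    return out


def _self_generation(haps: np.ndarray, gmap: GeneticMap,
                     rng: np.random.Generator) -> np.ndarray:
    """Self every line once (single seed): two independent gametes per line."""
    new = np.empty_like(haps)
    start = 0
    for chrom, pos in gmap.chromosomes.items():
        n = len(pos)
        block = haps[:, :, start : start + n]
        g1 = _meiosis(block, pos, rng)
        g2 = _meiosis(block, pos, rng)
        new[:, 0, start : start + n] = g1
        new[:, 1, start : start + n] = g2
        start += n
    return new


def simulate_ssd_population(cfg: SimConfig):
    """Simulate an SSD population; returns (dict generation -> GenotypeMatrix, TruthRecord).

    F2 lines are independent selfed seeds of the F1; each later generation
    advances every line by one selfed seed of the same line (no selection).
    Dosage coding: -1 homozygous founder-A allele (VCF ref), 0 het, +1
    homozygous founder-B allele (VCF alt).
    """
    rng_map = np.random.default_rng([cfg.seed, 1])
    rng_gen = np.random.default_rng([cfg.seed, 2])
    rng_qtl = np.random.default_rng([cfg.seed, 3])
    rng_rare = np.random.default_rng([cfg.seed, 4])

    gmap = _build_map(cfg, rng_map)
    markers = _marker_table(cfg, gmap, rng_map)
    n_mark = len(markers)

    # F1 is heterozygous everywhere: haplotype 0 all founder-A, haplotype 1 all founder-B
    f1 = np.zeros((cfg.n_lines, 2, n_mark), dtype=np.int8)
    f1[:, 1, :] = 1

    haps = f1
    per_gen = {}
    for gen in GENERATION_ORDER:
        haps = _self_generation(haps, gmap, rng_gen)
        if gen in cfg.generations:
            per_gen[gen] = haps.copy()
        if all(g in per_gen for g in cfg.generations):
            break

    # spectrum tail: replace a fraction of markers with low-MAF columns so
    # the MAF < 0.05 filter has something to remove (GBS artifact mimic)
    n_rare = int(round(cfg.rare_marker_frac * n_mark))
    rare_idx = (
        np.sort(rng_rare.choice(n_mark, size=n_rare, replace=False)) if n_rare else np.array([], int)
    )
    rare_freq = rng_rare.uniform(cfg.maf_floor, 0.05, size=n_rare)

    line_ids = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    matrices = {}
    for gen, h in per_gen.items():
        dosage = (h.sum(axis=1) - 1).astype(float)
        for j, f in zip(rare_idx, rare_freq):
            carriers = rng_rare.random(cfg.n_lines) < f
            col = np.where(carriers, 1.0, -1.0)
            dosage[:, j] = col
        matrices[gen] = GenotypeMatrix(
            list(line_ids), markers[["chrom", "pos", "id", "ref", "alt"]].copy(), dosage
        )

    # planted QTL: shared positions across the trait pair, effects drawn from a
    # bivariate standard normal with correlation rho_g
    eligible = np.setdiff1d(np.arange(n_mark), rare_idx)
    n_qtl = min(cfg.qtl_per_trait, len(eligible))
    qtl_idx = np.sort(rng_qtl.choice(eligible, size=n_qtl, replace=False))
    all_traits = tuple(cfg.traits) + tuple(cfg.ordinal_traits)
    n_tr = len(all_traits)
    if n_tr:
        cov = np.full((n_tr, n_tr), cfg.rho_g, dtype=float)
        np.fill_diagonal(cov, 1.0)
        effects = rng_qtl.multivariate_normal(
            np.zeros(n_tr), cov, size=n_qtl, method="cholesky"
        )
    rows = []
    for t, trait in enumerate(all_traits):
        for k, j in enumerate(qtl_idx):
            rows.append(
                (trait, markers["chrom"].iloc[j], markers["cM"].iloc[j],
                 markers["id"].iloc[j], int(j), effects[k, t])
            )
    qtl = pd.DataFrame(rows, columns=["trait", "chrom", "cM", "marker_id", "marker_index", "effect"])
    truth = TruthRecord(qtl=qtl, map=gmap)
    return matrices, truth


def simulate_phenotypes(gm: GenotypeMatrix, truth: TruthRecord, cfg: SimConfig,
                        generation: str = "F4") -> pd.DataFrame:
    """Phenotypes y = g + e on the trait scale, targeting the configured h2.

    The additive effects are rescaled once per trait (at the first
    generation phenotyped) so the genetic variance is h2 * sd^2 on the
    trait scale; the residual variance is (1 - h2) * sd^2.  Ordinal traits
    are produced by cutting the latent phenotype into five equal-probability
    score bins.
    """
    rng = np.random.default_rng([cfg.seed, 5, GENERATION_ORDER.index(generation)])
    out = {}
    for trait in tuple(cfg.traits) + tuple(cfg.ordinal_traits):
        h2 = float(cfg.h2.get(trait, 0.5))
        mean = float(cfg.trait_means.get(trait, 0.0))
        sd = float(cfg.trait_sds.get(trait, 1.0))
        if sd <= 0 and h2 == 0:
            raise SimConfigError(f"trait {trait}: h2 = 0 with zero residual variance")
        sub = truth.qtl[truth.qtl["trait"] == trait]
        idx = sub["marker_index"].to_numpy()
        X = gm.dosage[:, idx]
        if np.isnan(X).any():
            raise ValueError("phenotypes must be simulated before missingness is applied")
        if cfg.dominance != 0.0:
            X = X + cfg.dominance * (X == 0)
        if trait not in truth.effects:
            a_raw = sub["effect"].to_numpy()
            g_raw = X @ a_raw
            s = g_raw.std(ddof=1)
            if h2 == 0 or s == 0:
                truth.effects[trait] = a_raw * 0.0
            else:
                u = a_raw / s  # unit genetic variance at this generation
                # plant the genetic correlation with the lead trait exactly:
                # Gram-Schmidt in genetic-value space (linear in effects)
                lead = cfg.traits[0] if cfg.traits else None
                u_lead = truth.unit_effects.get(lead)
                if u_lead is not None and trait != lead and abs(cfg.rho_g) < 1:
                    g1 = X @ u_lead
                    g2 = X @ u
                    g1c = g1 - g1.mean()
                    b = float((g2 - g2.mean()) @ g1c / (g1c @ g1c))
                    a_perp = u - b * u_lead
                    sp = (X @ a_perp).std(ddof=1)
                    if sp > 0:
                        u = cfg.rho_g * u_lead + np.sqrt(1 - cfg.rho_g**2) * a_perp / sp
                truth.unit_effects[trait] = u
                truth.effects[trait] = u * sd * np.sqrt(h2)
            truth.intercepts[trait] = mean - (X @ truth.effects[trait]).mean()
        a = truth.effects[trait]
        g = truth.intercepts[trait] + X @ a
        e = rng.normal(0.0, sd * np.sqrt(max(0.0, 1.0 - h2)), size=gm.n_lines)
        y = g + e
        vy = y.var(ddof=1)
        truth.genetic_values[(generation, trait)] = g
        truth.realized_h2[(generation, trait)] = (
            float(g.var(ddof=1) / vy) if vy > 0 else float("nan")
        )
        if trait in cfg.ordinal_traits:
            cuts = np.quantile(y, [0.2, 0.4, 0.6, 0.8])
            y = (np.searchsorted(cuts, y, side="right") + 1).astype(float)
        out[trait] = y
    return pd.DataFrame(out, index=pd.Index(gm.line_ids, name="line_id"))


def apply_gbs_missingness(gm: GenotypeMatrix, cfg: SimConfig, salt: int = 0) -> GenotypeMatrix:
    """Mask entries with per-marker missing rates drawn from Beta(a, b).

    The per-marker rate is a property of the marker (it mimics restriction
    -site coverage), so it depends only on the config seed: two generations
    masked with different ``salt`` values share the same rate profile and
    their call-rate-filtered marker sets overlap heavily, as in real GBS
    data.  Observed entries are unchanged; a degenerate Beta (a or b = 0,
    treated as a point mass) is honored so rate 0 returns the input
    untouched.
    """
    rate_rng = np.random.default_rng([cfg.seed, 6])
    mask_rng = np.random.default_rng([cfg.seed, 7, salt])
    a, b = cfg.missing_beta_a, cfg.missing_beta_b
    if a <= 0 and b <= 0:
        raise SimConfigError("missing rate Beta parameters must not both be <= 0")
    if a <= 0:
        rates = np.zeros(gm.n_markers)
    elif b <= 0:
        rates = np.ones(gm.n_markers)
    else:
        rates = rate_rng.beta(a, b, size=gm.n_markers)
    mask = mask_rng.random(gm.dosage.shape) < rates[None, :]
    out = gm.copy()
    out.dosage[mask] = np.nan
    return out
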