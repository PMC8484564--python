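"""QTL mapping in selfed biparental populations (F2-coded).

Pipeline: estimate a genetic map from two-locus recombination counts,
compute QTL genotype probabilities along a cM grid with a hidden Markov
model, then scan the genome by simple interval mapping (SIM) or composite
interval mapping (CIM).  At each grid position a three-component normal
mixture over the QTL genotypes (AA/AB/BB) is fitted by EM, giving

    LOD = (LL_full - LL_null) / ln(10),

which at a fully observed marker reduces to the marker-regression LOD
(n/2) log10(RSS0/RSS1).  Genome-wide significance comes from a permutation
test on the trait vector; the variance explained by a QTL follows the
sample-size formula h2 = 1 - 10^(-2 LOD / n); localization uncertainty is
summarized by a Bayes credible interval on the normalized 10^LOD curve.

Lines from later selfing generations are coded and modeled as an F2 cross
(AA/AB/BB genotypes); their reduced heterozygosity enters through the data,
not the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genmap import MAP_FUNCTIONS, GeneticMap

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)


@dataclass
class ScanConfig:
    """Genome-scan settings."""

    step_cM: float = 1.0
    window_cM: float = 15.0
    n_marcovar: int = 4
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    map_function: str = "kosambi"
    error_prob: float = 1e-4
    em_tol: float = 1e-6
    em_max_iter: int = 1000

    def __post_init__(self):
        if self.step_cM <= 0 or self.window_cM < 0 or self.n_marcovar < 0:
            raise ValueError("invalid scan configuration")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LodCurve:
    """LOD scores on a genome grid, with the permutation threshold if set."""

    table: pd.DataFrame  # columns chrom, cM, lod, is_marker
    n: int               # sample size used in the scan
    threshold: float = float("nan")

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self):
        row = self.table.loc[self.table["lod"].idxmax()]
        return str(row["chrom"]), float(row["cM"]), float(row["lod"])


@dataclass
class QTLResult:
    chrom: str
    peak_cM: float
    peak_lod: float
    h2_explained: float
    interval: tuple  # (lo_cM, hi_cM)
    flanking_markers: tuple


# ---------------------------------------------------------------------------
# Map estimation
# ---------------------------------------------------------------------------

def _f2_two_locus_probs(r: float) -> np.ndarray:
    """3x3 genotype probabilities at two loci for an F2 in coupling phase."""
    gam = np.array([[(1 - r) / 2, r / 2], [r / 2, (1 - r) / 2]])  # hap x (a1, a2)
    P = np.zeros((3, 3))
    for h1 in range(2):      # gamete 1 founder at locus 1
        for a1 in range(2):  # gamete 1 founder at locus 2
            for h2 in range(2):
                for a2 in range(2):
                    p = gam[h1, a1] * gam[h2, a2]
                    P[h1 + h2, a1 + a2] += p
    return P


def _estimate_r(counts: np.ndarray) -> float:
    """ML recombination fraction from a 3x3 two-locus genotype count table."""
    if counts.sum() == 0:
        return 0.4999

    def nll(r):
        P = _f2_two_locus_probs(r)
        return -(counts * np.log(P + 1e-300)).sum()

    res = optimize.minimize_scalar(nll, bounds=(1e-6, 0.4999), method="bounded",
                                   options={"xatol": 1e-8})
    r = float(res.x)
    if nll(1e-9) <= res.fun:  # boundary: identical columns
        r = 0.0
    return min(r, 0.4999)


def estimate_map(gm, map_function: str = "kosambi") -> GeneticMap:
    """Genetic map from adjacent-marker recombination fractions.

    Markers must be ordered by physical position within chromosomes (the
    GenotypeMatrix invariant).  Adjacent r is estimated by maximum
    likelihood from the 3x3 two-locus genotype counts, capped at 0.4999,
    and converted to cM by the inverse map function, accumulated from 0.
    A chromosome with fewer than 2 markers gets a zero-length map.
    """
    inv = MAP_FUNCTIONS[map_function][1]
    dosage = gm.dosage
    chroms = {}
    for chrom, sub in gm.markers.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            logger.warning("chromosome %s has < 2 markers: zero-length map", chrom)
            chroms[chrom] = np.zeros(len(idx))
            continue
        pos = np.zeros(len(idx))
        for k in range(len(idx) - 1):
            a = dosage[:, idx[k]]
            b = dosage[:, idx[k + 1]]
            ok = ~(np.isnan(a) | np.isnan(b))
            counts = np.zeros((3, 3))
            for ga, gb in zip(a[ok], b[ok]):
                counts[int(ga) + 1, int(gb) + 1] += 1
            r = min(_estimate_r(counts), 0.4999)
            pos[k + 1] = pos[k] + inv(min(r, 0.49989))
        chroms[chrom] = pos
    return GeneticMap(chromosomes=chroms, map_function=map_function)


# ---------------------------------------------------------------------------
# Genotype probabilities along the grid (F2 HMM)
# ---------------------------------------------------------------------------

def _f2_transition(r: float) -> np.ndarray:
    """3x3 genotype transition matrix between loci with recombination r."""
    return np.array([
        [(1 - r) ** 2, 2 * r * (1 - r), r**2],
        [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
        [r**2, 2 * r * (1 - r), (1 - r) ** 2],
    ])


_F2_INIT = np.array([0.25, 0.5, 0.25])


def _emission(dos_col: np.ndarray, error_prob: float = 1e-4) -> np.ndarray:
    """(n, 3) emission probabilities; missing genotypes are uninformative.

    A small genotyping-error probability keeps apparent double recombinants
    (real in data from extra selfing generations, impossible under a tight
    F2 chain) from zeroing the forward probabilities.
    """
    n = len(dos_col)
    E = np.ones((n, 3))
    obs = ~np.isnan(dos_col)
    E[obs] = error_prob / 2.0
    E[obs, (dos_col[obs] + 1).astype(int)] = 1.0 - error_prob
    return E


def _norm_rows(a: np.ndarray) -> np.ndarray:
    s = a.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(s) | (s <= 0)
    if bad.any():
        a = np.where(bad, 1.0, a)
        s = np.where(bad, a.shape[1], s)
    return a / s


def genotype_probabilities(dosage: np.ndarray, marker_cM: np.ndarray,
                           grid_cM: np.ndarray, map_function: str = "kosambi",
                           error_prob: float = 1e-4):
    """P(QTL genotype | marker data) at each grid position, per line.

    ``dosage`` is (n_lines, n_markers) for one chromosome, markers ordered
    by cM.  Returns (n_lines, n_grid, 3).  Computed by forward-backward
    over the F2 genotype Markov chain with missing markers marginalized and
    an ``error_prob`` genotyping-error emission.
    """
    fwd_fun = MAP_FUNCTIONS[map_function][0]
    n, m = dosage.shape
    E = np.stack([_emission(dosage[:, k], error_prob) for k in range(m)], axis=1)

    r_adj = fwd_fun(np.diff(marker_cM)) if m > 1 else np.array([])
    T = [None] + [_f2_transition(r) for r in r_adj]

    F = np.empty((n, m, 3))
    F[:, 0] = _norm_rows(_F2_INIT[None, :] * E[:, 0])
    for k in range(1, m):
        F[:, k] = _norm_rows((F[:, k - 1] @ T[k]) * E[:, k])

    B = np.empty((n, m, 3))
    B[:, m - 1] = 1.0
    for k in range(m - 2, -1, -1):
        B[:, k] = _norm_rows((E[:, k + 1] * B[:, k + 1]) @ T[k + 1].T)

    W = np.empty((n, len(grid_cM), 3))
    left = np.searchsorted(marker_cM, grid_cM, side="right") - 1
    for g, pos in enumerate(grid_cM):
        k = left[g]
        if k < 0:  # before first marker
            T2 = _f2_transition(fwd_fun(marker_cM[0] - pos))
            w = _F2_INIT[None, :] * ((E[:, 0] * B[:, 0]) @ T2.T)
        elif k >= m - 1:  # at/after last marker
            if abs(pos - marker_cM[m - 1]) < 1e-12:
                w = F[:, m - 1] * B[:, m - 1]
            else:
                T1 = _f2_transition(fwd_fun(pos - marker_cM[m - 1]))
                w = F[:, m - 1] @ T1
        elif abs(pos - marker_cM[k]) < 1e-12:
            w = F[:, k] * B[:, k]
        else:
            T1 = _f2_transition(fwd_fun(pos - marker_cM[k]))
            T2 = _f2_transition(fwd_fun(marker_cM[k + 1] - pos))
            w = (F[:, k] @ T1) * ((E[:, k + 1] * B[:, k + 1]) @ T2.T)
        W[:, g] = _norm_rows(w)
    return W


def _scan_grid(marker_cM: np.ndarray, step: float) -> np.ndarray:
    lo, hi = marker_cM[0], marker_cM[-1]
    grid = np.arange(lo, hi + 1e-9, step)
    return np.unique(np.round(np.concatenate([grid, marker_cM]), 9))


# ---------------------------------------------------------------------------
# EM mixture fits
# ---------------------------------------------------------------------------

def _normal_loglik(y: np.ndarray) -> np.ndarray:
    """ML log-likelihood of a plain normal model, per row of y (q, n)."""
    n = y.shape[-1]
    s2 = y.var(axis=-1)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _em_sim(Y: np.ndarray, W: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Vectorized EM over traits x positions for the no-covariate model.

    Y: (q, n) trait vectors; W: (npos, n, 3) genotype weights.  Returns LOD
    (q, npos).  Each (trait, position) cell iterates until its own
    log-likelihood change drops below ``tol``; converged cells leave the
    active set, which keeps genome-scan permutations cheap.
    """
    q, n = Y.shape
    npos = W.shape[0]
    gmean = Y.mean(axis=1)
    # init: prior-weighted class means (Haley-Knott start)
    wsum = np.maximum(W.sum(axis=1), 1e-12)  # (npos, 3)
    mu = np.einsum("pnk,qn->qpk", W, Y) / wsum[None, :, :]
    resid0 = Y[:, None, :, None] - mu[:, :, None, :]
    sigma2 = np.maximum(np.einsum("pnk,qpnk->qp", W, resid0**2) / n, 1e-12)

    ll = np.full((q, npos), -np.inf)
    qa, pa = np.unravel_index(np.arange(q * npos), (q, npos))
    for _ in range(max_iter):
        Wa = W[pa]                     # (A, n, 3)
        Ya = Y[qa]                     # (A, n)
        mua = mu[qa, pa]               # (A, 3)
        s2a = sigma2[qa, pa][:, None, None]
        dens = np.exp(-0.5 * (Ya[:, :, None] - mua[:, None, :]) ** 2 / s2a)
        dens /= np.sqrt(2 * np.pi * s2a)
        mix = np.maximum(np.einsum("ank,ank->an", Wa, dens), 1e-300)
        ll_new = np.log(mix).sum(axis=1)
        post = Wa * dens / mix[..., None]
        tot = post.sum(axis=1)         # (A, 3)
        mu_new = np.einsum("ank,an->ak", post, Ya) / np.maximum(tot, 1e-12)
        empty = tot < 1e-8
        mu_new[empty] = np.broadcast_to(gmean[qa][:, None], mu_new.shape)[empty]
        resid = Ya[:, :, None] - mu_new[:, None, :]
        s2_new = np.maximum(np.einsum("ank,ank->a", post, resid**2) / n, 1e-12)
        conv = np.abs(ll_new - ll[qa, pa]) < tol
        mu[qa, pa] = mu_new
        sigma2[qa, pa] = s2_new
        ll[qa, pa] = ll_new
        if conv.all():
            break
        keep = ~conv
        qa, pa = qa[keep], pa[keep]
    ll0 = _normal_loglik(Y)  # (q,)
    return np.maximum((ll - ll0[:, None]) / _LN10, 0.0)


def _em_covar(y: np.ndarray, X: np.ndarray, W_pos: np.ndarray,
              tol: float, max_iter: int) -> float:
    """EM log-likelihood gain at one position with fixed covariates.

    Model: y = X beta + mu_g + e.  Returns the LOD against the
    covariates-only null.
    """
    n = len(y)
    Xd = np.hstack([np.ones((n, 1)), X]) if X is not None and X.shape[1] else np.ones((n, 1))
    # null model
    beta0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    r0 = y - Xd @ beta0
    s20 = (r0**2).mean()
    ll0 = -0.5 * n * (np.log(2 * np.pi * s20) + 1.0)

    # full model design: covariates (no intercept) + 3 genotype means
    C = Xd[:, 1:]
    c = C.shape[1]
    P = W_pos.copy()  # (n, 3) start from prior weights
    ll_old = -np.inf
    ll = ll_old
    for _ in range(max_iter):
        # M-step: WLS on expanded data
        A = np.zeros((c + 3, c + 3))
        rhs = np.zeros(c + 3)
        tot = P.sum(axis=0)
        if c:
            A[:c, :c] = C.T @ C
            A[:c, c:] = C.T @ P
            A[c:, :c] = A[:c, c:].T
            rhs[:c] = C.T @ y
        A[c:, c:] = np.diag(np.maximum(tot, 1e-10))
        rhs[c:] = P.T @ y
        theta = np.linalg.solve(A + 1e-10 * np.eye(c + 3), rhs)
        beta, mu = theta[:c], theta[c:]
        fitted = (C @ beta if c else 0.0)
        resid = y[:, None] - (np.atleast_1d(fitted)[:, None] if c else 0.0) - mu[None, :]
        s2 = max(float((P * resid**2).sum() / n), 1e-12)
        # E-step
        dens = np.exp(-0.5 * resid**2 / s2) / np.sqrt(2 * np.pi * s2)
        mix = np.maximum((W_pos * dens).sum(axis=1), 1e-300)
        ll = float(np.log(mix).sum())
        P = W_pos * dens / mix[:, None]
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return max((ll - ll0) / _LN10, 0.0)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def _prepare(gm, y, gmap: GeneticMap):
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype vector contains missing values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    chrom_blocks = []
    for chrom, sub in gm.markers.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        if chrom not in gmap.chromosomes:
            raise ValueError(f"map does not cover chromosome {chrom}")
        pos = np.asarray(gmap.chromosomes[chrom], dtype=float)
        if len(pos) != len(idx):
            raise ValueError(f"map/marker count mismatch on {chrom}")
        chrom_blocks.append((chrom, idx, pos))
    return y, chrom_blocks


def _chrom_weights(gm, chrom_blocks, cfg: ScanConfig):
    out = []
    for chrom, idx, pos in chrom_blocks:
        grid = _scan_grid(pos, cfg.step_cM)
        W = genotype_probabilities(gm.dosage[:, idx], pos, grid, cfg.map_function,
                                   error_prob=cfg.error_prob)
        is_marker = np.isin(np.round(grid, 9), np.round(pos, 9))
        out.append((chrom, grid, np.ascontiguousarray(W.transpose(1, 0, 2)), is_marker))
    return out  # list of (chrom, grid, W (npos, n, 3), is_marker)


def sim_scan(gm, y, gmap: GeneticMap, cfg: ScanConfig | None = None) -> LodCurve:
    """Simple interval mapping scan over the whole genome."""
    cfg = cfg or ScanConfig()
    y, blocks = _prepare(gm, y, gmap)
    weights = _chrom_weights(gm, blocks, cfg)
    rows = []
    Y = y[None, :]
    for chrom, grid, W, is_marker in weights:
        lod = _em_sim(Y, W, cfg.em_tol, cfg.em_max_iter)[0]
        for p, l, m in zip(grid, lod, is_marker):
            rows.append((chrom, p, l, bool(m)))
    return LodCurve(pd.DataFrame(rows, columns=["chrom", "cM", "lod", "is_marker"]),
                    n=len(y))


def forward_select_covariates(gm, y, n_marcovar: int):
    """Greedy forward selection of background marker covariates.

    Markers (mean-filled) are added one at a time by largest squared
    partial correlation with the trait given those already chosen.
    Returns (X (n, c), marker indices, marker chrom/cM positions DataFrame).
    """
    D = gm.dosage.copy()
    mu = np.nanmean(D, axis=0)
    miss = np.isnan(D)
    D[miss] = np.take(mu, np.where(miss)[1])
    n = D.shape[0]
    chosen: list = []
    resid = y - y.mean()
    Dc = D - D.mean(axis=0)
    for _ in range(min(n_marcovar, max(0, n - 4))):
        ss = (Dc * resid[:, None]).sum(axis=0) ** 2 / np.maximum((Dc**2).sum(axis=0), 1e-12)
        ss[chosen] = -np.inf
        j = int(np.argmax(ss))
        if not np.isfinite(ss[j]) or ss[j] <= 0:
            break
        chosen.append(j)
        x = Dc[:, j]
        # residualize trait and remaining markers on the chosen marker
        denom = (x**2).sum()
        resid = resid - x * (x @ resid) / denom
        Dc = Dc - x[:, None] * (x @ Dc)[None, :] / denom
    X = D[:, chosen] if chosen else np.empty((n, 0))
    return X, chosen


def cim_scan(gm, y, gmap: GeneticMap, cfg: ScanConfig | None = None) -> LodCurve:
    """Composite interval mapping: SIM plus background marker covariates.

    Covariates within ``window_cM`` of the scan position (on the same
    chromosome) are dropped at that position.  With ``n_marcovar = 0`` the
    scan is identical to :func:`sim_scan`.
    """
    cfg = cfg or ScanConfig()
    y, blocks = _prepare(gm, y, gmap)
    if cfg.n_marcovar >= len(y) - 3:
        raise ValueError("n_marcovar too large for the sample size (model saturation)")
    if cfg.n_marcovar == 0:
        return sim_scan(gm, y, gmap, cfg)

    X, chosen = forward_select_covariates(gm, y, cfg.n_marcovar)
    cov_pos = []
    for j in chosen:
        chrom = gm.markers["chrom"].iloc[j]
        for c, idx, pos in blocks:
            if c == chrom:
                cov_pos.append((chrom, pos[np.searchsorted(idx, j)]))
                break
    weights = _chrom_weights(gm, blocks, cfg)
    rows = []
    for chrom, grid, W, is_marker in weights:
        for g, posn in enumerate(grid):
            keep = [k for k, (cc, cp) in enumerate(cov_pos)
                    if not (cc == chrom and abs(cp - posn) <= cfg.window_cM)]
            lod = _em_covar(y, X[:, keep], W[g], cfg.em_tol, cfg.em_max_iter)
            rows.append((chrom, posn, lod, bool(is_marker[g])))
    return LodCurve(pd.DataFrame(rows, columns=["chrom", "cM", "lod", "is_marker"]),
                    n=len(y))


def permutation_threshold(gm, y, gmap: GeneticMap, cfg: ScanConfig | None = None,
                          method: str = "sim") -> float:
    """Genome-wide LOD threshold: (1 - alpha) quantile of max LOD under
    ``n_perm`` random permutations of the trait vector (fixed seed)."""
    cfg = cfg or ScanConfig()
    y, blocks = _prepare(gm, y, gmap)
    rng = np.random.default_rng(cfg.seed)
    perms = np.stack([rng.permutation(y) for _ in range(cfg.n_perm)])
    if method == "sim":
        weights = _chrom_weights(gm, blocks, cfg)
        maxlod = np.zeros(cfg.n_perm)
        chunk = max(1, int(6e6 // (sum(len(g) for _, g, _, _ in weights) * len(y) * 3)))
        for s in range(0, cfg.n_perm, chunk):
            Y = perms[s : s + chunk]
            best = np.zeros(Y.shape[0])
            for chrom, grid, W, _ in weights:
                lod = _em_sim(Y, W, cfg.em_tol, cfg.em_max_iter)
                best = np.maximum(best, lod.max(axis=1))
            maxlod[s : s + chunk] = best
    elif method == "cim":
        maxlod = np.array([
            cim_scan(gm, perms[i], gmap, cfg).max_lod() for i in range(cfg.n_perm)
        ])
    else:
        raise ValueError(f"unknown scan method {method!r}")
    return float(np.quantile(maxlod, 1.0 - cfg.alpha))


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def variance_explained(lod, n: int):
    """Fraction of phenotypic variance explained: h2 = 1 - 10^(-2 LOD / n)."""
    lod = np.asarray(lod, dtype=float)
    if np.any(lod < 0):
        raise ValueError("LOD must be non-negative")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    out = 1.0 - 10.0 ** (-2.0 * lod / n)
    return out.item() if out.ndim == 0 else out


def bayes_interval(curve: LodCurve, chrom: str, prob: float = 0.95):
    """Bayes credible interval for a QTL on one chromosome.

    The 10^LOD profile is normalized to a posterior over grid positions;
    the smallest contiguous run of positions around the peak reaching
    ``prob`` is returned, expanded outward to the nearest flanking markers.
    A flat curve yields the whole chromosome (with a warning).
    """
    sub = curve.table[curve.table["chrom"] == chrom].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no scan positions on chromosome {chrom}")
    lod = sub["lod"].to_numpy()
    pos = sub["cM"].to_numpy()
    post = 10.0 ** (lod - lod.max())
    post /= post.sum()
    if np.ptp(lod) == 0:
        logger.warning("flat LOD curve on %s: interval spans the chromosome", chrom)
        return float(pos[0]), float(pos[-1])
    k = int(np.argmax(lod))
    lo = hi = k
    mass = post[k]
    while mass < prob and (lo > 0 or hi < len(pos) - 1):
        left = post[lo - 1] if lo > 0 else -1.0
        right = post[hi + 1] if hi < len(pos) - 1 else -1.0
        if left >= right:
            lo -= 1
            mass += post[lo]
        else:
            hi += 1
            mass += post[hi]
    markers = sub["is_marker"].to_numpy()
    lo_m = np.flatnonzero(markers[: lo + 1])
    hi_m = np.flatnonzero(markers[hi:])
    lo_pos = pos[lo_m[-1]] if len(lo_m) else pos[0]
    hi_pos = pos[hi + hi_m[0]] if len(hi_m) else pos[-1]
    return float(lo_pos), float(hi_pos)


def summarize_qtl(curve: LodCurve, prob: float = 0.95, threshold: float | None = None):
    """Per-chromosome QTL calls above the LOD threshold."""
    thr = curve.threshold if threshold is None else threshold
    out = []
    for chrom, sub in curve.table.groupby("chrom", sort=True):
        i = sub["lod"].idxmax()
        peak_lod = float(sub.loc[i, "lod"])
        if not np.isfinite(thr) or peak_lod <= thr:
            continue
        lo, hi = bayes_interval(curve, chrom, prob)
        mk = sub[sub["is_marker"]]
        peak_cM = float(sub.loc[i, "cM"])
        left = mk[mk["cM"] <= peak_cM]["cM"]
        right = mk[mk["cM"] >= peak_cM]["cM"]
        flank = (float(left.max()) if len(left) else float(mk["cM"].min()),
                 float(right.min()) if len(right) else float(mk["cM"].max()))
        out.append(QTLResult(str(chrom), peak_cM, peak_lod,
                             float(variance_explained(peak_lod, curve.n)),
                             (lo, hi), flank))
    return out
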