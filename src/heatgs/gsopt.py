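"""Training-protocol optimization and cross-generation selection.

Implements the study design used to tune a genomic-selection model on a
single biparental training population:

* a grid over test-set size (training-set composition) and marker
  call-rate stringency (PEMV level), each cell evaluated by repeated
  random hold-out validation with RR-BLUP refit per draw;
* intersection of marker sets between two genotyped generations (with
  allele-flip reconciliation) so a model trained on one generation can
  score the next;
* threshold selection of candidate lines by GEBV against a reference
  genotype, and validation of the selections against offspring phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import impute_matrix
from .rrblup import PredictionResult, accuracy, fit_kernel
from .variantio import FilterConfig, GenotypeMatrix, filter_markers

logger = logging.getLogger(__name__)


@dataclass
class GridConfig:
    """Hold-out grid settings (test-set sizes x PEMV levels x iterations)."""

    trait: str
    tst_sizes: tuple = (15, 20, 25, 30, 35)
    pemv_levels: tuple = (70, 75, 80, 85, 90)
    n_iter: int = 1000
    maf_min: float = 0.05
    impute_method: str = "em"
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class GridResult:
    """Per-cell accuracy distributions of the hold-out grid.

    ``accuracies`` has shape (len(tst_sizes), len(pemv_levels), n_iter);
    ``mean_accuracy`` is the cell-mean table (rows tst_size, cols pemv).
    """

    config: GridConfig
    accuracies: np.ndarray
    marker_counts: dict
    mean_accuracy: pd.DataFrame = field(init=False)
    best_cell: tuple = field(init=False)

    def __post_init__(self):
        means = np.nanmean(self.accuracies, axis=2)
        self.mean_accuracy = pd.DataFrame(
            means, index=list(self.config.tst_sizes), columns=list(self.config.pemv_levels)
        )
        # best mean accuracy; ties broken toward larger TRS (smaller TST),
        # then higher PEMV
        best, best_key = None, None
        for i, t in enumerate(self.config.tst_sizes):
            for j, p in enumerate(self.config.pemv_levels):
                key = (means[i, j], -t, p)
                if best_key is None or key > best_key:
                    best_key, best = key, (t, p)
        self.best_cell = best


def _aligned(geno: GenotypeMatrix, pheno: pd.DataFrame, trait: str):
    y_all = pheno[trait]
    shared = [lid for lid in geno.line_ids if lid in y_all.index and np.isfinite(y_all[lid])]
    if not shared:
        raise ValueError(f"no lines shared between genotypes and phenotypes for {trait}")
    idx = [geno.line_ids.index(lid) for lid in shared]
    return geno.subset_lines(idx), y_all.loc[shared].to_numpy(dtype=float)


def holdout_grid(geno: GenotypeMatrix, pheno: pd.DataFrame, cfg: GridConfig) -> GridResult:
    """Run the tst-size x PEMV hold-out grid for one trait.

    Marker filtering (MAF then call rate) and imputation happen once per
    PEMV level on the full training population; each iteration then draws a
    test set uniformly without replacement, refits RR-BLUP (REML) on the
    remaining lines and records the Pearson accuracy on the held-out lines.
    """
    geno, y = _aligned(geno, pheno, cfg.trait)
    n = len(y)
    if n < max(cfg.tst_sizes) + 3:
        raise ValueError(f"{n} phenotyped lines cannot support TST of {max(cfg.tst_sizes)}")

    kernels = {}
    marker_counts = {}
    for pemv in cfg.pemv_levels:
        sub = filter_markers(geno, FilterConfig(maf_min=cfg.maf_min, pemv_level=pemv))
        marker_counts[pemv] = sub.n_markers
        if sub.n_markers == 0:
            kernels[pemv] = None
            logger.warning("PEMV %s leaves no markers", pemv)
            continue
        imputed, _ = impute_matrix(sub, method=cfg.impute_method)
        Z = imputed.dosage
        kernels[pemv] = Z @ Z.T

    acc = np.full((len(cfg.tst_sizes), len(cfg.pemv_levels), cfg.n_iter), np.nan)
    for i, tst_size in enumerate(cfg.tst_sizes):
        for j, pemv in enumerate(cfg.pemv_levels):
            K = kernels[pemv]
            if K is None:
                continue
            rng = np.random.default_rng([cfg.seed, tst_size, int(pemv)])
            for it in range(cfg.n_iter):
                tst = rng.choice(n, size=tst_size, replace=False)
                trs = np.setdiff1d(np.arange(n), tst)
                kf = fit_kernel(K[np.ix_(trs, trs)], y[trs])
                gebv = K[np.ix_(tst, trs)] @ kf.alpha
                acc[i, j, it] = accuracy(gebv, y[tst])
    return GridResult(cfg, acc, marker_counts)


def intersect_markers(a: GenotypeMatrix, b: GenotypeMatrix):
    """Restrict two matrices to their common markers, in identical order.

    Markers are matched on (chrom, pos); allele pairs must agree either
    directly or with ref/alt swapped, in which case the second matrix's
    dosages are sign-flipped.  Raises when the intersection is empty.
    """
    ma = a.markers.reset_index().rename(columns={"index": "ia"})
    mb = b.markers.reset_index().rename(columns={"index": "ib"})
    merged = ma.merge(mb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    same = (merged["ref_a"] == merged["ref_b"]) & (merged["alt_a"] == merged["alt_b"])
    flipped = (merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])
    merged = merged[same | flipped]
    if merged.empty:
        raise ValueError("no common markers between the two matrices")
    merged = merged.sort_values(["chrom", "pos"], kind="stable")
    ia = merged["ia"].to_numpy()
    ib = merged["ib"].to_numpy()
    flip = ((merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])).to_numpy()
    out_a = a.subset_markers(ia)
    out_b = b.subset_markers(ib)
    out_b.dosage[:, flip] *= -1.0
    # after flipping, marker metadata of b is reported on a's allele convention
    out_b.markers = out_a.markers.copy()
    return out_a, out_b


def select_candidates(pred: PredictionResult, reference_gebv: float,
                      scale: str = "absolute") -> pd.DataFrame:
    """Label lines best/worst against a reference GEBV (strict inequality).

    Returns a table with line_id, gebv, label; the table's ``attrs`` carry
    the percentage of best and worst lines (summing to 100).
    """
    g = pred.gebv_absolute if scale == "absolute" else pred.gebv
    label = np.where(g > reference_gebv, "best", "worst")
    table = pd.DataFrame({"line_id": pred.line_ids, "gebv": g, "label": label})
    n = len(table)
    table.attrs["pct_best"] = 100.0 * (label == "best").sum() / n
    table.attrs["pct_worst"] = 100.0 * (label == "worst").sum() / n
    table.attrs["reference_gebv"] = reference_gebv
    return table


def validate_offspring(sel: pd.DataFrame, offspring_pheno: pd.Series,
                       reference_pheno: float) -> pd.DataFrame:
    """Confirm predicted-best lines against offspring phenotypes.

    A selection is confirmed when the line was predicted best and its
    offspring phenotype strictly exceeds the reference phenotype.  The
    returned table's ``attrs`` include the Pearson correlation between
    GEBVs and offspring phenotypes.
    """
    missing = [lid for lid in sel["line_id"] if lid not in offspring_pheno.index]
    if missing:
        raise ValueError(f"offspring phenotypes missing for lines: {missing[:10]}")
    out = sel.copy()
    out["offspring_phenotype"] = offspring_pheno.loc[out["line_id"]].to_numpy(dtype=float)
    out["offspring_best"] = out["offspring_phenotype"] > reference_pheno
    out["confirmed"] = (out["label"] == "best") & out["offspring_best"]
    out.attrs.update(sel.attrs)
    out.attrs["prediction_offspring_r"] = accuracy(
        out["gebv"].to_numpy(), out["offspring_phenotype"].to_numpy()
    )
    return out
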