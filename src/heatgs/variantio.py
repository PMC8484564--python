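"""Genotype and phenotype I/O, marker QC filters and diversity summaries.

The central container is :class:`GenotypeMatrix`: a lines x markers dosage
matrix for biallelic SNPs coded -1 (homozygous reference), 0 (heterozygous),
+1 (homozygous alternate), with NaN marking missing calls.  This matches the
AA/AB/BB/NA coding used for selfed biparental populations, mapped onto a
numeric scale that ridge-regression models consume directly.

Filters implement the two marker-quality rules of GBS pipelines:

* MAF filter: markers with minor allele frequency strictly below the cutoff
  (default 0.05) are removed; a marker exactly at the cutoff is kept.
* PEMV filter ("percentage of eliminated missing values"): a marker is kept
  when it is genotyped in at least ``pemv_level`` percent of the lines, i.e.
  a call-rate threshold in the style of vcftools' ``--max-missing``.  Higher
  PEMV therefore retains fewer markers.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
_NUCLEOTIDES = {"A", "C", "G", "T"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with marker metadata.

    Parameters
    ----------
    line_ids : list of str
        Sample names, one per matrix row.
    markers : pandas.DataFrame
        One row per marker with columns chrom, pos (1-based), id, ref, alt,
        sorted by (chrom, pos).
    dosage : ndarray of float, shape (n_lines, n_markers)
        Values in {-1, 0, +1} or NaN for missing.
    """

    line_ids: list
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosage) | ((self.dosage >= -1.0) & (self.dosage <= 1.0))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"dosage values outside [-1, 1] or NaN: {bad[:5]}")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def is_trinary(self) -> bool:
        """True when every call is exactly -1, 0, +1 or missing (no imputed fractions)."""
        return bool(np.all(np.isnan(self.dosage) | np.isin(self.dosage, (-1.0, 0.0, 1.0))))

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.line_ids), self.markers.copy(), self.dosage.copy())

    def subset_markers(self, index) -> "GenotypeMatrix":
        """New matrix keeping the markers selected by a boolean mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.line_ids),
            self.markers.iloc[index].reset_index(drop=True),
            self.dosage[:, index],
        )

    def subset_lines(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.line_ids[i] for i in index], self.markers.copy(), self.dosage[index, :]
        )

    # -- per-marker statistics ------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency p_alt per marker from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return (np.nanmean(self.dosage, axis=0) + 1.0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker; NaN where no calls exist."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def het_fraction(self) -> np.ndarray:
        """Observed heterozygosity per marker (het calls / non-missing calls)."""
        obs = ~np.isnan(self.dosage)
        with np.errstate(invalid="ignore"):
            return (self.dosage == 0).sum(axis=0) / obs.sum(axis=0)


@dataclass
class FilterConfig:
    """Marker-retention thresholds for :func:`filter_markers`."""

    maf_min: float = 0.05
    pemv_level: float = 0.0  # required call-rate percentage; 0 disables
    min_depth: int | None = None  # applied at VCF read time when DP is present

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.pemv_level <= 100.0:
            raise ValueError("pemv_level must be in (0, 100]")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, min_depth: int | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are used; multi-allelic and non-SNP records
    are skipped and counted in a log message.  Genotypes come from the GT
    field; when ``min_depth`` is given and a FORMAT/DP field exists, calls
    below that depth are set missing.

    Raises
    ------
    VcfParseError
        On malformed records (with the offending line number) or when no
        usable record remains.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from None

    line_ids = list(vcf.samples)
    chroms, poss, ids, refs, alts = [], [], [], [], []
    rows = []
    skipped = 0
    # header line count so parse errors can name a line number
    n_header = 0
    with open(path, "rt") as fh:
        for ln in fh:
            if ln.startswith("#"):
                n_header += 1
            else:
                break

    for i, var in enumerate(vcf):
        lineno = n_header + i + 1
        if len(var.ALT) != 1 or var.REF not in _NUCLEOTIDES or var.ALT[0] not in _NUCLEOTIDES:
            skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
        if gt.shape[0] != len(line_ids):
            raise VcfParseError(f"{path}: record at line {lineno} has wrong sample count")
        dos = gt - 1.0
        dos[gt == 3] = np.nan
        if min_depth is not None:
            dp = var.format("DP")
            if dp is not None:
                dos[np.asarray(dp, dtype=float).ravel() < min_depth] = np.nan
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)

    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise VcfParseError(f"{path}: no usable biallelic SNP records")

    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "id": ids, "ref": refs, "alt": alts}
    )
    dosage = np.column_stack(rows)  # (lines, markers) in file order
    order = markers.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    markers = markers.iloc[order].reset_index(drop=True)
    dosage = dosage[:, order]
    gm = GenotypeMatrix(line_ids, markers, dosage)
    gm.n_skipped = skipped
    return gm


_GT_CODE = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as minimal VCF v4.2 (GT only, unphased)."""
    if not gm.is_trinary:
        raise ValueError("cannot write fractional (imputed) dosages as VCF genotypes")
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in pd.unique(gm.markers["chrom"]):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(str(s) for s in gm.line_ids) + "\n")
    for j, rec in enumerate(gm.markers.itertuples(index=False)):
        gts = "\t".join(
            "./." if np.isnan(d) else _GT_CODE[d] for d in gm.dosage[:, j]
        )
        buf.write(
            f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\t.\t.\tGT\t{gts}\n"
        )
    with open(path, "wt") as fh:
        fh.write(buf.getvalue())


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-separated phenotype table (line_id + trait columns, NA missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index(df.columns[0])


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", na_rep="NA", index_label="line_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_markers(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Apply MAF and call-rate (PEMV) filters; line set and marker order preserved.

    Markers with MAF strictly below ``maf_min`` are removed (a marker at the
    threshold survives), as are markers genotyped in fewer than
    ``pemv_level`` percent of lines.  Returns an empty matrix (with a logged
    warning) rather than raising when nothing survives.
    """
    maf = gm.maf()
    with np.errstate(invalid="ignore"):
        # strict "less than" removal, with float-noise guard at the boundary
        keep = ~(maf < cfg.maf_min - 1e-9)
    keep &= ~np.isnan(maf)
    if cfg.pemv_level > 0:
        keep &= gm.call_rate() >= cfg.pemv_level / 100.0
    if not keep.any():
        logger.warning("filter_markers: all %d markers removed", gm.n_markers)
    return gm.subset_markers(keep)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def tstv(gm: GenotypeMatrix):
    """Transition / transversion counts and ratio over the marker set.

    Transitions are A<->G and C<->T; every other SNP substitution is a
    transversion.  When no transversion exists the ratio is ``inf``.
    """
    pairs = list(zip(gm.markers["ref"], gm.markers["alt"]))
    ts = sum(p in _TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    ratio = float("inf") if tv == 0 else ts / tv
    return ts, tv, ratio


def pic_biallelic(p) -> np.ndarray:
    """Polymorphism information content for a biallelic locus (Botstein form).

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, maximal at 0.375 when p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def marker_diversity(gm: GenotypeMatrix) -> dict:
    """Per-marker and per-chromosome diversity summary.

    Returns a dict with a per-marker DataFrame (p, maf, H observed
    heterozygosity, PIC, call rate), a per-chromosome mean table, per-sample
    het/hom ratios, and genome-wide Ts/Tv counts.
    """
    p = gm.alt_freq()
    per_marker = pd.DataFrame(
        {
            "chrom": gm.markers["chrom"],
            "pos": gm.markers["pos"],
            "id": gm.markers["id"],
            "p_alt": p,
            "maf": gm.maf(),
            "H": gm.het_fraction(),
            "PIC": pic_biallelic(p),
            "call_rate": gm.call_rate(),
        }
    )
    per_chrom = (
        per_marker.groupby("chrom", sort=True)[["maf", "H", "PIC", "call_rate"]]
        .mean()
        .join(per_marker.groupby("chrom", sort=True).size().rename("n_snps"))
    )
    het = (gm.dosage == 0).sum(axis=1).astype(float)
    hom = (np.abs(gm.dosage) == 1).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        het_hom = np.where(hom > 0, het / hom, np.nan)
    ts, tv, ratio = tstv(gm)
    return {
        "per_marker": per_marker,
        "per_chrom": per_chrom,
        "per_sample": pd.DataFrame(
            {"line_id": gm.line_ids, "n_het": het, "n_hom": hom, "het_hom_ratio": het_hom}
        ),
        "tstv": {"ts": ts, "tv": tv, "ratio": ratio},
    }


def density_windows(gm: GenotypeMatrix, window_bp: int) -> pd.DataFrame:
    """SNP counts per half-open genomic window [start, start + window_bp).

    Windows start at position 1 (VCF is 1-based); counts per chromosome sum
    to that chromosome's marker total.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out = []
    for chrom, sub in gm.markers.groupby("chrom", sort=True):
        idx = (sub["pos"].to_numpy() - 1) // window_bp
        n_win = int(idx.max()) + 1 if len(idx) else 0
        counts = np.bincount(idx, minlength=n_win)
        for w, c in enumerate(counts):
            out.append((chrom, w * window_bp + 1, (w + 1) * window_bp + 1, int(c)))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_snps"])


def phenotype_summary(pheno: pd.DataFrame) -> dict:
    """Trait means/ranges and pairwise Pearson correlations.

    Correlations use pairwise-complete observations; p-values are
    Bonferroni-adjusted by the number of trait pairs tested.  A pair with a
    constant trait or fewer than 3 complete observations is reported NaN.
    """
    traits = list(pheno.columns)
    desc = pd.DataFrame(
        {"mean": pheno.mean(), "min": pheno.min(), "max": pheno.max(), "n": pheno.count()}
    )
    n_pairs = len(traits) * (len(traits) - 1) // 2
    rows = []
    for a, b in combinations(traits, 2):
        sub = pheno[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append((a, b, np.nan, np.nan, len(sub)))
            continue
        r, pval = stats.pearsonr(sub[a], sub[b])
        rows.append((a, b, r, min(1.0, pval * n_pairs), len(sub)))
    corr = pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p_bonferroni", "n"])
    return {"traits": desc, "correlations": corr}
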