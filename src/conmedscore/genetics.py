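"""Per-SNP association scans, ancestry PCs, MAF filtering, and the
paired-model bootstrap comparison of a SNP's effect size.

Genotypes are held as an additive dosage matrix (subjects × SNPs,
values in [0, 2], missing allowed) read from a plain TSV or a VCF.
Ancestry is summarized by principal components of the column-
standardized dosage matrix; rare variants (minor allele frequency
below 3% by default) are removed before analysis.  The confounding
check refits two nested models — with and without the co-medication
score — on the same subject resamples and compares the SNP
coefficient's bootstrap distributions by 95% percentile-CI overlap and
a two-sample t-test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import RankDeficientError, fit_linear

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive dosages (subjects × SNPs) plus SNP metadata."""

    dosages: pd.DataFrame  # index subject_id, columns snp ids; NaN = missing
    snp_info: pd.DataFrame  # columns: snp, chrom, pos

    def __post_init__(self) -> None:
        vals = self.dosages.values
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        missing = set(self.snp_info["snp"]) ^ set(self.dosages.columns)
        if missing:
            raise ValueError(f"snp_info and dosage columns disagree: {sorted(missing)[:5]}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def maf(self) -> pd.Series:
        """Folded minor allele frequency per SNP (missing excluded)."""
        freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        return pd.Series(np.minimum(freq, 1 - freq), index=self.dosages.columns, name="maf")

    def restrict_region(self, region: str) -> "GenotypeMatrix":
        """Subset SNPs to a ``chrom:start-end`` region string."""
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", region)
        if not m:
            raise ValueError(f"bad region string: {region!r} (expected chrom:start-end)")
        chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        info = self.snp_info
        keep = info.loc[
            (info["chrom"].astype(str) == chrom) & (info["pos"] >= start) & (info["pos"] <= end),
            "snp",
        ].tolist()
        return GenotypeMatrix(self.dosages[keep], info.loc[info["snp"].isin(keep)].reset_index(drop=True))


def read_dosage_tsv(path: str | Path, snp_info: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a subjects × SNPs dosage TSV (first column = subject_id).

    When no metadata table is supplied, chromosome/position default to
    unknowns so positional filtering is unavailable but scans still run.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}).set_index("subject_id")
    if snp_info is None:
        snp_info = pd.DataFrame({"snp": df.columns, "chrom": "NA", "pos": range(len(df.columns))})
    return GenotypeMatrix(df.astype(float), snp_info)


def read_vcf(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read dosages from a VCF (DS field when present, else GT sum)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snps, chroms, poss, rows = [], [], [], []
    it = vcf(region) if region else vcf
    for var in it:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 dosage-coded; 2 = unknown
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        snps.append(snp)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(ds)
    dos = pd.DataFrame(np.column_stack(rows) if rows else np.empty((len(subjects), 0)),
                       index=pd.Index(subjects, name="subject_id"), columns=snps)
    info = pd.DataFrame({"snp": snps, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(dos, info)


def maf_filter(G: GenotypeMatrix, threshold: float = 0.03) -> GenotypeMatrix:
    """Remove SNPs with minor allele frequency below ``threshold``."""
    keep = G.maf() >= threshold
    kept = [s for s in G.snp_ids if keep[s]]
    return GenotypeMatrix(G.dosages[kept], G.snp_info.loc[G.snp_info["snp"].isin(kept)].reset_index(drop=True))


def genotype_pca(G: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed; columns are centred and scaled to
    unit variance (monomorphic SNPs contribute zeros).  PCs are ordered
    by decreasing variance explained with the sign fixed so each
    component's largest-magnitude SNP loading is positive.
    """
    X = G.dosages.values.astype(float).copy()
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_subjects, n_snps)={min(n, m)}")
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(col_mean, idx[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X /= sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=G.dosages.index, columns=[f"PC{i+1}" for i in range(k)])


def snp_scan(
    y: pd.Series, covariates: pd.DataFrame, G: GenotypeMatrix
) -> pd.DataFrame:
    """Association scan: OLS of response on covariates + each SNP dosage.

    Subjects with a missing dosage are dropped per SNP; SNPs whose
    design is rank deficient (e.g. monomorphic in the analysis set)
    yield an NA row with a warning.  Returns snp, chrom, pos, beta, se,
    p, n.
    """
    ids = y.index.intersection(covariates.index).intersection(G.dosages.index)
    yv = y.loc[ids]
    cov = covariates.loc[ids]
    info = G.snp_info.set_index("snp")
    rows = []
    for snp in G.snp_ids:
        dose = G.dosages.loc[ids, snp]
        ok = dose.notna()
        X = cov.loc[ok].copy()
        X["__snp__"] = dose.loc[ok]
        try:
            fit = fit_linear(yv.loc[ok], X)
            coef = fit.coefficients.set_index("name").loc["__snp__"]
            rows.append((snp, info.loc[snp, "chrom"], info.loc[snp, "pos"],
                         coef["beta"], coef["se"], coef["p"], fit.n))
        except (RankDeficientError, ValueError) as exc:
            logger.warning("snp %s not testable: %s", snp, exc)
            rows.append((snp, info.loc[snp, "chrom"], info.loc[snp, "pos"],
                         np.nan, np.nan, np.nan, int(ok.sum())))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "beta", "se", "p", "n"])


@dataclass
class BootstrapComparison:
    snp_id: str
    beta_with: float
    beta_without: float
    boot_with: np.ndarray
    boot_without: np.ndarray
    ci_with: tuple[float, float]
    ci_without: tuple[float, float]
    overlap: bool
    t_stat: float
    t_p: float


def _ols_beta(A: np.ndarray, y: np.ndarray, col: int) -> float:
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise RankDeficientError("rank-deficient resample")
    return float(coef[col])


def bootstrap_compare(
    y: pd.Series,
    model_with: pd.DataFrame,
    model_without: pd.DataFrame,
    snp: str,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    max_retries: int = 10,
) -> BootstrapComparison:
    """Paired bootstrap of a SNP coefficient under two covariate sets.

    Subjects are resampled with replacement; both models are refit on
    the same resample and the SNP coefficient recorded, giving two
    B-length distributions compared by 95% percentile-CI overlap and a
    two-sample t-test.  A resample with a rank-deficient design is
    redrawn (up to ``max_retries`` times).  Deterministic given the
    seed.
    """
    if B < 100:
        raise ValueError("B too small; need at least 100 bootstrap iterations")
    if snp not in model_with.columns or snp not in model_without.columns:
        raise ValueError(f"both models must contain the SNP column {snp!r}")
    ids = y.index
    if not (model_with.index.equals(ids) and model_without.index.equals(ids)):
        raise ValueError("models and response must share the same subject set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yv = y.values.astype(float)
    n = len(yv)

    def _design(tab: pd.DataFrame) -> tuple[np.ndarray, int]:
        A = np.column_stack([np.ones(n), tab.values.astype(float)])
        return A, 1 + list(tab.columns).index(snp)

    A_w, c_w = _design(model_with)
    A_o, c_o = _design(model_without)
    beta_with = _ols_beta(A_w, yv, c_w)
    beta_without = _ols_beta(A_o, yv, c_o)
    boot_w = np.empty(B)
    boot_o = np.empty(B)
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            try:
                boot_w[b] = _ols_beta(A_w[idx], yv[idx], c_w)
                boot_o[b] = _ols_beta(A_o[idx], yv[idx], c_o)
                break
            except RankDeficientError:
                logger.info("rank-deficient resample redrawn (iteration %d)", b)
        else:
            raise RankDeficientError(f"resample rank deficient after {max_retries} retries")
    ci_w = tuple(np.percentile(boot_w, [2.5, 97.5]))
    ci_o = tuple(np.percentile(boot_o, [2.5, 97.5]))
    overlap = (ci_w[0] <= ci_o[1]) and (ci_o[0] <= ci_w[1])
    if np.allclose(boot_w, boot_o):
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_ind(boot_w, boot_o)
    return BootstrapComparison(
        snp_id=snp,
        beta_with=beta_with,
        beta_without=beta_without,
        boot_with=boot_w,
        boot_without=boot_o,
        ci_with=(float(ci_w[0]), float(ci_w[1])),
        ci_without=(float(ci_o[0]), float(ci_o[1])),
        overlap=bool(overlap),
        t_stat=float(t_stat),
        t_p=float(t_p),
    )
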