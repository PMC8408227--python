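"""Gene-dosage analysis: per-chromosome mean expression vs. mean copy number.

For each chromosome, every sample contributes one point: its mean
log2(x+1)-transformed expression over the chromosome's genes (x axis is the
sample's average chromosomal copy number). A Pearson correlation across
samples quantifies how faithfully transcription tracks DNA dosage; the
contrast of interest is a strong correlation on recurrently altered
chromosomes against no correlation on copy-neutral ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DosageCorrelation", "chromosome_mean_expression",
           "dosage_correlation"]

log = logging.getLogger(__name__)


@dataclass
class DosageCorrelation:
    chrom: str
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    slope_se: float
    undefined: bool = False

    def confidence_band(self, x: np.ndarray, level: float = 0.95):
        """(lower, upper) of the mean-response CI of the fitted line at x."""
        if self.undefined:
            raise ValueError("correlation undefined; no fitted line")
        x = np.asarray(x, dtype=float)
        xm, sx = self._x_stats
        yhat = self.intercept + self.slope * x
        se = self._resid_sd * np.sqrt(1.0 / self.n + (x - xm) ** 2 / sx)
        tq = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return yhat - tq * se, yhat + tq * se


def _validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return expr


def chromosome_mean_expression(expr: pd.DataFrame, gene_map: pd.DataFrame,
                               chrom: str, transform: str = "log") -> pd.Series:
    """Per-sample mean expression over one chromosome's genes.

    ``expr`` is genes x samples; ``gene_map`` maps gene -> chromosome
    (columns gene, chrom). Genes with zero counts in every sample are
    dropped before averaging (they carry no dosage signal). ``transform``
    is ``"log"`` (log2(x+1), default) or ``"raw"``.
    """
    _validate_expression(expr)
    genes = gene_map.loc[gene_map["chrom"] == chrom, "gene"]
    genes = genes[genes.isin(expr.index)]
    if len(genes) == 0:
        raise ValueError(f"no mapped genes on chromosome {chrom!r}")
    sub = expr.loc[genes]
    expressed = (sub.sum(axis=1) > 0)
    if (~expressed).any():
        log.info("chromosome %s: dropping %d unexpressed genes", chrom,
                 int((~expressed).sum()))
    sub = sub[expressed]
    if len(sub) == 0:
        raise ValueError(f"no expressed genes on chromosome {chrom!r}")
    if transform == "log":
        sub = np.log2(sub + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    return sub.mean(axis=0)


def dosage_correlation(mean_expr: pd.Series, mean_cn: pd.Series,
                       chrom: str = "") -> DosageCorrelation:
    """Pearson correlation (and fitted line) of expression vs. copy number.

    Vectors are aligned on their sample index and must pair over >= 3
    samples. A zero-variance axis yields a flagged ``undefined`` result
    rather than NaN propagation.
    """
    x = pd.Series(mean_cn)
    y = pd.Series(mean_expr)
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(common)}")
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    n = len(common)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return DosageCorrelation(chrom=chrom, r=np.nan, p=np.nan, n=n,
                                 slope=np.nan, intercept=np.nan,
                                 slope_se=np.nan, undefined=True)
    r, p = stats.pearsonr(xv, yv)
    fit = stats.linregress(xv, yv)
    res = DosageCorrelation(chrom=chrom, r=float(r), p=float(p), n=n,
                            slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            slope_se=float(fit.stderr))
    res._x_stats = (float(xv.mean()), float(np.sum((xv - xv.mean()) ** 2)))
    resid = yv - (fit.intercept + fit.slope * xv)
    res._resid_sd = float(np.sqrt(np.sum(resid ** 2) / (n - 2))) if n > 2 else np.nan
    return res
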