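"""Conditional-FDR machinery: stratified Q-Q curves, inflation-corrected
fold enrichment, the empirical cFDR / conjunction cFDR estimators,
significance calling, novelty filtering and Manhattan-plot data.

The cFDR of SNP i for a principal trait (p-values ``p1``) given a
conditional trait (``p2``) is estimated empirically as

    cfdr_i = min(1, p1_i * N2_i / N12_i)

where ``N2_i`` counts SNPs with ``p2 <= p2_i`` and ``N12_i`` counts SNPs
with both ``p1 <= p1_i`` and ``p2 <= p2_i`` (ties inclusive; the SNP
counts itself, so ``N12 >= 1``).  This is the pointwise empirical-Bayes
estimate of the probability that a random SNP is null for the principal
phenotype given both observed p-values; conditioning on a genuinely
associated second trait concentrates small ``p1`` inside small ``p2``,
raising ``N12`` and shrinking the estimate — the power gain pleiotropy
buys.  The conjunction cFDR is the per-SNP maximum over the two trait
orderings, small only when the SNP is non-null for both traits.

No monotonicity (running-minimum) enforcement is applied: raw pointwise
values are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld_prune import GenotypePanel, pairwise_r2
from .sumstats_io import MergedPanel

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

#: -log10(0.05): the Manhattan-plot reference line for calls at 5%.
SIG_LINE = -np.log10(0.05)

DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)


@dataclass(frozen=True)
class StratumSpec:
    """Nested conditional-trait strata: p2 <= each threshold.

    The default (1, 0.1, 0.01, 0.001) corresponds to -log10(p2) > 0,1,2,3;
    the first stratum is the full SNP set.
    """

    thresholds: tuple[float, ...] = DEFAULT_STRATA

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t or t[0] != 1.0:
            raise ValueError("first stratum must be the full set (threshold 1.0)")
        if any(b >= a for a, b in zip(t, t[1:])):
            raise ValueError("strata thresholds must be strictly decreasing")

    def labels(self) -> list[str]:
        return [f"-log10(p2)>{abs(-np.log10(t)):g}" for t in self.thresholds]


@dataclass
class QQCurve:
    """Per-stratum conditional Q-Q data.

    ``strata[label]`` is a DataFrame with columns ``nominal`` and
    ``empirical`` (both on the -log10 scale) sorted by ascending p1;
    ``sizes[label]`` is the stratum size.
    """

    strata: dict[str, pd.DataFrame]
    sizes: dict[str, int]

    def deflection(self, at_empirical: float = 2.0) -> dict[str, float]:
        """Nominal -log10 p1 at a fixed empirical quantile, per stratum.

        Enrichment shows as this value increasing for stricter strata.
        """
        out = {}
        for label, df in self.strata.items():
            emp = df["empirical"].to_numpy()[::-1]
            nom = df["nominal"].to_numpy()[::-1]
            out[label] = float(np.interp(at_empirical, emp, nom))
        return out


@dataclass
class EnrichmentCurve:
    """Fold enrichment over a nominal -log10 p grid, per stratum."""

    grid_neglog10: np.ndarray
    strata: dict[str, np.ndarray]
    lambda_gc: float


def genomic_lambda(pvals: np.ndarray) -> float:
    """Genomic-control inflation factor.

    Median of the squared two-sided normal quantiles of the p-values,
    divided by the median of the 1-df chi-square (~0.4549).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_lambda: empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(p / 2)
    return float(np.median(z * z) / CHI2_1_MEDIAN)


def _gc_correct_p(p1: np.ndarray, lam: float) -> np.ndarray:
    """Rescale chi-square statistics by lambda (floored at 1) and return
    the corrected tail p-values."""
    lam = max(lam, 1.0)
    chi = stats.chi2.isf(p1, 1)
    return stats.chi2.sf(chi / lam, 1)


def conditional_qq(panel: MergedPanel, strata: StratumSpec | None = None) -> QQCurve:
    """Stratified Q-Q curves of the principal trait's p-values within
    nested conditional-trait strata."""
    strata = strata or StratumSpec()
    if len(panel) == 0:
        raise ValueError("conditional_qq: empty panel")
    p1 = panel.df["p1"].to_numpy()
    p2 = panel.df["p2"].to_numpy()
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for thr, label in zip(strata.thresholds, strata.labels()):
        sel = p2 <= thr
        n = int(sel.sum())
        if n == 0:
            logger.warning("conditional_qq: stratum %s empty; omitted", label)
            continue
        ps = np.sort(p1[sel])
        ranks = np.arange(1, n + 1)
        curves[label] = pd.DataFrame(
            {
                "nominal": -np.log10(ps),
                "empirical": -np.log10(ranks / (n + 1)),
            }
        )
        sizes[label] = n
    return QQCurve(curves, sizes)


def fold_enrichment(
    panel: MergedPanel,
    strata: StratumSpec | None = None,
    gc_correct: bool = True,
    n_grid: int = 200,
) -> EnrichmentCurve:
    """Fold-enrichment of each stratum over the full set along a nominal
    p-value grid; the principal trait's p-values are inflation-corrected
    via lambda rescaling when ``gc_correct``."""
    strata = strata or StratumSpec()
    if len(panel) == 0:
        raise ValueError("fold_enrichment: empty panel")
    p1 = panel.df["p1"].to_numpy()
    p2 = panel.df["p2"].to_numpy()
    lam = genomic_lambda(p1)
    if gc_correct:
        p1 = _gc_correct_p(p1, lam)
    grid = np.logspace(0, -8, n_grid)
    n_total = p1.size
    base = np.array([(p1 <= g).sum() for g in grid], dtype=float)
    curves: dict[str, np.ndarray] = {}
    for thr, label in zip(strata.thresholds, strata.labels()):
        sel = p2 <= thr
        n_s = int(sel.sum())
        if n_s == 0:
            logger.warning("fold_enrichment: stratum %s empty; omitted", label)
            continue
        num = np.array([(p1[sel] <= g).sum() for g in grid], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            fe = (num / n_s) / (base / n_total)
        fe[base == 0] = np.nan  # grid point omitted: no SNP that extreme
        curves[label] = fe
    return EnrichmentCurve(-np.log10(grid), curves, lam)


# ---------------------------------------------------------------------------
# Empirical cFDR
# ---------------------------------------------------------------------------


class _Fenwick:
    """Binary indexed tree over 1..n for prefix counts."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def empirical_cfdr(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-SNP empirical cFDR of trait 1 conditional on trait 2.

    O(N log N): sweep SNPs in ascending-p2 order (inserting whole tie
    groups before querying, so ``<=`` comparisons are inclusive) and count
    joint dominances with a Fenwick tree over p1 ranks.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p1 and p2 length mismatch")
    n = p1.size
    if n == 0:
        raise ValueError("empirical_cfdr: empty input")

    # dense ranks of p1 (ties share a rank)
    uniq, r1 = np.unique(p1, return_inverse=True)
    r1 = r1 + 1  # 1-based for the tree
    tree = _Fenwick(len(uniq))

    order = np.argsort(p2, kind="stable")
    cfdr = np.empty(n)
    i = 0
    inserted = 0
    while i < n:
        j = i
        while j < n and p2[order[j]] == p2[order[i]]:
            j += 1
        for k in order[i:j]:  # insert the tie group, then query its members
            tree.add(int(r1[k]))
        inserted += j - i
        for k in order[i:j]:
            n12 = tree.prefix(int(r1[k]))
            cfdr[k] = p1[k] * inserted / n12
        i = j
    return np.minimum(cfdr, 1.0)


def conjunction_cfdr(c12: np.ndarray, c21: np.ndarray) -> np.ndarray:
    """Element-wise maximum of the two cFDR orderings."""
    c12 = np.asarray(c12, dtype=float)
    c21 = np.asarray(c21, dtype=float)
    if c12.shape != c21.shape:
        raise ValueError("cfdr vectors length mismatch")
    return np.maximum(c12, c21)


def call_significant(values: np.ndarray, alpha: float) -> np.ndarray:
    """Inclusive thresholding: value <= alpha."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return np.asarray(values, dtype=float) <= alpha


@dataclass
class CFDRResult:
    """Per-SNP cFDR in both orderings, conjunction cFDR and calls.

    ``df`` columns: snp_id, chrom, pos, p1, p2, cfdr_12, cfdr_21, ccfdr,
    sig05, sig01, pleio05, pleio01, novel.  ``cfdr_12`` conditions trait 1
    (principal) on trait 2.  Values are raw pointwise estimates (no
    running-minimum smoothing), recorded in ``meta``.
    """

    trait1: str
    trait2: str
    df: pd.DataFrame
    meta: dict = field(default_factory=lambda: {"estimator": "pointwise-empirical"})

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def compute_cfdr(panel: MergedPanel, alphas: tuple[float, float] = (0.05, 0.01)) -> CFDRResult:
    """Both cFDR orderings, the conjunction cFDR, and significance calls."""
    p1 = panel.df["p1"].to_numpy()
    p2 = panel.df["p2"].to_numpy()
    c12 = empirical_cfdr(p1, p2)
    c21 = empirical_cfdr(p2, p1)
    cc = conjunction_cfdr(c12, c21)
    a_loose, a_tight = max(alphas), min(alphas)
    df = panel.df[["snp_id", "chrom", "pos", "p1", "p2"]].copy()
    df["cfdr_12"] = c12
    df["cfdr_21"] = c21
    df["ccfdr"] = cc
    df["sig05"] = call_significant(c12, a_loose)
    df["sig01"] = call_significant(c12, a_tight)
    df["pleio05"] = call_significant(cc, a_loose)
    df["pleio01"] = call_significant(cc, a_tight)
    df["novel"] = True
    return CFDRResult(panel.trait1, panel.trait2, df)


def exclude_known(
    result: CFDRResult,
    known_ids: set[str] | list[str],
    panel: GenotypePanel | None = None,
    r2_link: float = 0.2,
) -> CFDRResult:
    """Flag novelty: a SNP is novel iff it is not a known id and (when a
    genotype panel is supplied) not in LD (r² >= ``r2_link``) with any
    known SNP on the same chromosome."""
    known = set(known_ids)
    novel = ~result.df["snp_id"].isin(known)
    if panel is not None and known:
        col = {s: k for k, s in enumerate(panel.snp_ids)}
        known_in_panel = [s for s in known if s in col]
        for idx in np.flatnonzero(novel.to_numpy()):
            s = result.df["snp_id"].iloc[idx]
            if s not in col:
                continue
            for ks in known_in_panel:
                if panel.chrom[col[ks]] != panel.chrom[col[s]]:
                    continue
                v = pairwise_r2(panel.dosages[:, col[s]], panel.dosages[:, col[ks]])
                if not np.isnan(v) and v >= r2_link:
                    novel.iloc[idx] = False
                    break
    out = result.df.copy()
    out["novel"] = novel.to_numpy()
    return CFDRResult(result.trait1, result.trait2, out, dict(result.meta))


def manhattan_data(result: CFDRResult, value: str = "cfdr_12") -> pd.DataFrame:
    """Plot-ready table: chromosome, cumulative position, -log10 of the
    chosen cFDR column, and its significance flag.

    The returned frame carries ``attrs['sig_line'] = -log10(0.05)``.
    Cumulative positions offset each chromosome by the running total of
    preceding chromosome lengths, so a single-chromosome input keeps raw
    coordinates.
    """
    flag = {"cfdr_12": "sig05", "cfdr_21": "sig05", "ccfdr": "pleio05"}[value]
    df = result.df[["snp_id", "chrom", "pos", value, flag]].copy()
    df = df.rename(columns={value: "value", flag: "significant"})
    df["neglog10"] = -np.log10(df["value"].to_numpy())
    offset = 0
    cum = np.empty(len(df), dtype=float)
    for chrom in pd.unique(df["chrom"]):
        sel = (df["chrom"] == chrom).to_numpy()
        cum[sel] = df.loc[sel, "pos"].to_numpy() + offset
        offset += int(df.loc[sel, "pos"].max())
    df["cum_pos"] = cum
    df.attrs["sig_line"] = float(SIG_LINE)
    return df
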