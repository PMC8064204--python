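"""Two-sample Mendelian randomization: instrument selection, allele
harmonization, and the five summary-data estimators (IVW, MR-Egger,
weighted median, simple and weighted mode), run bi-directionally.

Conventions (chosen to match the standard two-sample MR toolchain):

* IVW is weighted least squares of outcome betas on exposure betas without
  intercept, weights 1/se_O²; the reported SE is the fixed-effect SE
  inflated by the residual scale when it exceeds 1 (multiplicative random
  effects floored at fixed-effect).  p-values are normal.
* MR-Egger adds a free intercept after orienting exposure betas
  non-negative; SEs get the same residual-scale floor; p-values use
  t(n-2).  The intercept tests directional pleiotropy.
* The weighted median interpolates the inverse-variance-weighted median of
  per-SNP Wald ratios; mode estimators maximise a weighted Gaussian kernel
  density of the ratios.  Both get parametric-bootstrap SEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .ld_prune import GenotypePanel, clump_by_pvalue
from .sumstats_io import (
    AMBIGUITY_BAND,
    COMPLEMENT,
    SumstatTable,
    _is_palindromic,
)

logger = logging.getLogger(__name__)

GWAS_SIG = 5e-8
CLUMP_R2 = 0.001

MR_COLUMNS = ["method", "nsnp", "b", "se", "pval", "or", "or_lci95", "or_uci95"]


@dataclass
class MRInput:
    """Harmonized instrument effects for one exposure->outcome direction.

    ``df`` columns: snp_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf_exposure, eaf_outcome.  Alleles are already aligned to
    the exposure's effect allele.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) and not (
            (self.df["se_exposure"] > 0).all() and (self.df["se_outcome"] > 0).all()
        ):
            raise ValueError("instrument standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.df
        return (
            d["beta_exposure"].to_numpy(float),
            d["se_exposure"].to_numpy(float),
            d["beta_outcome"].to_numpy(float),
            d["se_outcome"].to_numpy(float),
        )


@dataclass
class MREstimate:
    method: str
    n_snp: int
    b: float
    se: float
    pval: float

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.b))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.b - 1.96 * self.se)), float(np.exp(self.b + 1.96 * self.se)))

    def as_row(self) -> dict:
        lci, uci = self.ci95
        return {
            "method": self.method,
            "nsnp": self.n_snp,
            "b": self.b,
            "se": self.se,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_lci95": lci,
            "or_uci95": uci,
        }


@dataclass
class EggerIntercept:
    intercept: float
    se: float
    pval: float


def load_packaged_instruments() -> MRInput:
    """The birth-weight -> T2D instrument table shipped with the package
    (columns beta.E/se.E/beta.O/se.O/eaf.E/eaf.O per SNP), harmonized with
    the default palindromic-ambiguity rule."""
    with resources.files("cpgcfdr.data").joinpath("bw_t2d_instruments.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    return harmonize_table(raw)


def harmonize_table(raw: pd.DataFrame, action: int = 2) -> MRInput:
    """Harmonize a Table-3-style instrument frame (ea_E/oa_E/ea_O/oa_O,
    beta.E/beta.O, eaf.E/eaf.O, se.E/se.O) to an :class:`MRInput`."""
    exp = pd.DataFrame(
        {
            "snp_id": raw["SNP"],
            "effect_allele": raw["ea_E"],
            "other_allele": raw["oa_E"],
            "beta": raw["beta.E"],
            "se": raw["se.E"],
            "eaf": raw["eaf.E"],
        }
    )
    out = pd.DataFrame(
        {
            "snp_id": raw["SNP"],
            "effect_allele": raw["ea_O"],
            "other_allele": raw["oa_O"],
            "beta": raw["beta.O"],
            "se": raw["se.O"],
            "eaf": raw["eaf.O"],
        }
    )
    exposure = str(raw["exposure"].iloc[0]) if "exposure" in raw else "exposure"
    outcome = str(raw["outcome"].iloc[0]) if "outcome" in raw else "outcome"
    return harmonize(exp, out, action=action, exposure_label=exposure, outcome_label=outcome)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    action: int = 2,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> MRInput:
    """Align outcome effects to the exposure's effect allele.

    Rows join on ``snp_id``.  A swapped coding flips the outcome beta and
    complements its frequency; strand complements are accepted.  Palindromic
    SNPs: ``action=1`` assumes same strand; ``action=2`` (default) drops
    those with ambiguous frequency (either study inside the 0.42-0.58
    band) and frequency-orients the rest; ``action=3`` drops all.
    Irreconcilable allele sets are dropped and logged.
    """
    if action not in (1, 2, 3):
        raise ValueError("action must be 1, 2 or 3")
    m = exposure.merge(outcome, on="snp_id", suffixes=("_e", "_o"))
    rows = []
    n_bad = n_pal = 0
    for r in m.itertuples(index=False):
        ea_e, oa_e = r.effect_allele_e, r.other_allele_e
        ea_o, oa_o = r.effect_allele_o, r.other_allele_o
        beta_o, eaf_o = r.beta_o, r.eaf_o
        pal = _is_palindromic(ea_e, oa_e)
        if pal:
            if {ea_o, oa_o} != {ea_e, oa_e}:
                n_bad += 1
                logger.info("harmonize: %s irreconcilable alleles; dropped", r.snp_id)
                continue
            if action == 3:
                n_pal += 1
                continue
            if ea_o != ea_e:  # label swap; frequency refers to the other allele
                beta_o, eaf_o = -beta_o, 1 - eaf_o
            if action == 2:
                lo, hi = AMBIGUITY_BAND
                if lo <= r.eaf_e <= hi or lo <= eaf_o <= hi:
                    n_pal += 1
                    logger.info("harmonize: %s palindromic-ambiguous; dropped", r.snp_id)
                    continue
                if (r.eaf_e - 0.5) * (eaf_o - 0.5) < 0:  # opposite strand coding
                    beta_o, eaf_o = -beta_o, 1 - eaf_o
        else:
            cea, coa = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
            if (ea_o, oa_o) == (ea_e, oa_e) or (cea, coa) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e) or (cea, coa) == (oa_e, ea_e):
                beta_o, eaf_o = -beta_o, 1 - eaf_o
            else:
                n_bad += 1
                logger.info("harmonize: %s irreconcilable alleles; dropped", r.snp_id)
                continue
        rows.append(
            {
                "snp_id": r.snp_id,
                "beta_exposure": r.beta_e,
                "se_exposure": r.se_e,
                "beta_outcome": beta_o,
                "se_outcome": r.se_o,
                "eaf_exposure": r.eaf_e,
                "eaf_outcome": eaf_o,
            }
        )
    if n_bad or n_pal:
        logger.info("harmonize: dropped %d irreconcilable, %d palindromic rows", n_bad, n_pal)
    df = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_exposure",
            "eaf_outcome",
        ],
    )
    return MRInput(exposure_label, outcome_label, df)


def select_instruments(
    exposure: SumstatTable,
    panel: GenotypePanel,
    p_threshold: float = GWAS_SIG,
    r2_max: float = CLUMP_R2,
) -> list[str]:
    """Genome-wide significant (p < threshold) SNPs clumped to approximate
    independence (pairwise r² < ``r2_max``)."""
    hits = exposure.df[exposure.df["pval"] < p_threshold]
    if hits.empty:
        logger.warning("select_instruments: no SNP passes p < %g", p_threshold)
        return []
    return clump_by_pvalue(
        hits["snp_id"].tolist(), hits["pval"].to_numpy(), panel, r2_max=r2_max
    )


def wald_ratios(inp: MRInput) -> pd.DataFrame:
    """Per-SNP causal ratios beta_O/beta_E with first-order SEs
    se_O/|beta_E|; SNPs with a zero exposure beta are excluded."""
    be, _, bo, so = inp.arrays()
    ok = be != 0
    if (~ok).any():
        logger.info("wald_ratios: excluded %d SNPs with beta_exposure = 0", int((~ok).sum()))
    return pd.DataFrame(
        {
            "snp_id": inp.df["snp_id"].to_numpy()[ok],
            "ratio": bo[ok] / be[ok],
            "ratio_se": so[ok] / np.abs(be[ok]),
        }
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares; returns (coef, cov_unit, dof, sigma2) where
    cov_unit is the covariance at unit residual variance."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ y)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float((w * resid**2).sum() / dof) if dof > 0 else np.nan
    return coef, xtwx_inv, dof, sigma2


def ivw(inp: MRInput) -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects
    floored at fixed effect); degenerates to the Wald ratio at one SNP."""
    if inp.n_snp == 0:
        raise ValueError("ivw: no instruments")
    be, _, bo, so = inp.arrays()
    if inp.n_snp == 1:
        b = float(bo[0] / be[0])
        se = float(so[0] / abs(be[0]))
        p = float(2 * stats.norm.sf(abs(b / se)))
        return MREstimate("Inverse variance weighted", 1, b, se, p)
    w = 1.0 / so**2
    coef, cov_unit, dof, sigma2 = _wls(be, bo, w, intercept=False)
    b = float(coef[0])
    se = float(np.sqrt(cov_unit[0, 0] * max(1.0, sigma2)))
    p = float(2 * stats.norm.sf(abs(b / se)))
    return MREstimate("Inverse variance weighted", inp.n_snp, b, se, p)


def egger(inp: MRInput) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression; the intercept is the directional-pleiotropy
    test.  Exposure betas are oriented non-negative first."""
    if inp.n_snp < 3:
        raise ValueError(
            f"egger: needs >= 3 instruments for positive degrees of freedom, got {inp.n_snp}"
        )
    be, _, bo, so = inp.arrays()
    sgn = np.where(be < 0, -1.0, 1.0)
    be, bo = be * sgn, bo * sgn
    w = 1.0 / so**2
    coef, cov_unit, dof, sigma2 = _wls(be, bo, w, intercept=True)
    scale = max(1.0, sigma2)
    se_int = float(np.sqrt(cov_unit[0, 0] * scale))
    se_slope = float(np.sqrt(cov_unit[1, 1] * scale))
    slope = float(coef[1])
    inter = float(coef[0])
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), dof))
    p_int = float(2 * stats.t.sf(abs(inter / se_int), dof))
    return (
        MREstimate("MR Egger", inp.n_snp, slope, se_slope, p_slope),
        EggerIntercept(inter, se_int, p_int),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, r))


def _bootstrap_se(inp: MRInput, point_fn, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample each beta from its normal and
    recompute the point estimate."""
    rng = np.random.default_rng(seed)
    be, se_e, bo, so = inp.arrays()
    ests = np.empty(n_boot)
    for k in range(n_boot):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(bo, so)
        ests[k] = point_fn(be_s, bo_s, so)
    return float(ests.std(ddof=1))


def weighted_median(inp: MRInput, n_boot: int = 1000, seed: int = 20210404) -> MREstimate:
    """Interpolated inverse-variance-weighted median of Wald ratios."""
    if inp.n_snp < 3:
        raise ValueError("weighted_median: needs >= 3 instruments")

    def point(be, bo, so):
        ok = be != 0
        r = bo[ok] / be[ok]
        w = (np.abs(be[ok]) / so[ok]) ** 2
        return _weighted_median(r, w)

    be, _, bo, so = inp.arrays()
    b = point(be, bo, so)
    se = _bootstrap_se(inp, point, n_boot, seed)
    p = float(2 * stats.norm.sf(abs(b / se)))
    return MREstimate("Weighted median", inp.n_snp, b, se, p)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of the weighted Gaussian KDE of the ratios.

    Bandwidth: phi * 0.9 * min(SD, 1.4826*MAD) * n^(-1/5), evaluated on a
    512-point grid extended 3 bandwidths past the data range.
    """
    n = ratios.size
    sd = float(np.std(ratios, ddof=1))
    mad = float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))
    s = 0.9 * min(sd, mad if mad > 0 else sd) * n ** (-0.2)
    h = max(1e-8, phi * s)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    w = weights / weights.sum()
    dens = (w[:, None] * stats.norm.pdf(grid[None, :], ratios[:, None], h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    inp: MRInput,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 20210404,
) -> MREstimate:
    """Mode-based estimate: the dominant cluster of Wald ratios."""
    if inp.n_snp < 3:
        raise ValueError("mode_estimate: needs >= 3 instruments")

    def point(be, bo, so):
        ok = be != 0
        r = bo[ok] / be[ok]
        rse = so[ok] / np.abs(be[ok])
        w = 1.0 / rse**2 if weighted else np.ones_like(r)
        return _mode_point(r, w, phi)

    be, _, bo, so = inp.arrays()
    b = point(be, bo, so)
    se = _bootstrap_se(inp, point, n_boot, seed)
    p = float(2 * stats.norm.sf(abs(b / se)))
    return MREstimate("Weighted mode" if weighted else "Simple mode", inp.n_snp, b, se, p)


def run_all_estimators(inp: MRInput, n_boot: int = 1000, seed: int = 20210404) -> pd.DataFrame:
    """The five-estimator suite as a tidy frame (plus the Egger intercept
    recorded in ``attrs``)."""
    rows = []
    if inp.n_snp >= 3:
        est, intercept = egger(inp)
        rows.append(est.as_row())
        rows.append(weighted_median(inp, n_boot=n_boot, seed=seed).as_row())
    else:
        intercept = None
    if inp.n_snp >= 1:
        rows.append(ivw(inp).as_row())
    if inp.n_snp >= 3:
        rows.append(mode_estimate(inp, weighted=False, n_boot=n_boot, seed=seed).as_row())
        rows.append(mode_estimate(inp, weighted=True, n_boot=n_boot, seed=seed).as_row())
    out = pd.DataFrame(rows, columns=MR_COLUMNS)
    out.attrs["egger_intercept"] = intercept
    out.attrs["bootstrap_seed"] = seed
    return out


def run_bidirectional(
    t_exposure: SumstatTable,
    t_outcome: SumstatTable,
    panel: GenotypePanel,
    p_threshold: float = GWAS_SIG,
    r2_max: float = CLUMP_R2,
    action: int = 2,
    n_boot: int = 1000,
    seed: int = 20210404,
) -> pd.DataFrame:
    """Full bi-directional MR: select instruments from each trait in turn,
    extract the other trait's effects, harmonize and run all estimators.

    Directions with no instruments get a single ``not-estimable`` row.
    """
    frames = []
    for exp, out in ((t_exposure, t_outcome), (t_outcome, t_exposure)):
        ids = select_instruments(exp, panel, p_threshold=p_threshold, r2_max=r2_max)
        label = {"exposure": exp.trait_label, "outcome": out.trait_label}
        sub_e = exp.df[exp.df["snp_id"].isin(ids)]
        sub_o = out.df[out.df["snp_id"].isin(ids)]
        inp = harmonize(
            sub_e,
            sub_o,
            action=action,
            exposure_label=exp.trait_label,
            outcome_label=out.trait_label,
        )
        if inp.n_snp == 0:
            res = pd.DataFrame(
                [{"method": "not-estimable", "nsnp": 0, "b": np.nan, "se": np.nan,
                  "pval": np.nan, "or": np.nan, "or_lci95": np.nan, "or_uci95": np.nan}]
            )
        else:
            res = run_all_estimators(inp, n_boot=n_boot, seed=seed)
        res.insert(0, "outcome", label["outcome"])
        res.insert(1, "exposure", label["exposure"])
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
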