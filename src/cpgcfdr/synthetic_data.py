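"""Synthetic GWAS summary statistics with a known pleiotropic architecture.

A four-component mixture assigns each SNP a latent class — null for both
traits (00), associated with trait 1 only (10), trait 2 only (01), or both
(11, pleiotropic).  Observed z-scores are the sum of unit null noise and a
Gaussian signal component of SD sigma1/sigma2 for associated classes; for
pleiotropic SNPs the two signal components share correlation rho.  Betas
are reconstructed from z via the standard GWAS standard-error
approximation se = 1/sqrt(2 n eaf (1-eaf)).  CpG flags are Bernoulli,
independent of class by default.  A companion reference genotype panel is
simulated with block-diagonal AR(1) linkage disequilibrium.

Everything is seeded and reproducible; the per-SNP truth (latent class,
signal means, CpG flag) is recorded for parameter-recovery and FDR tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ld_prune import GenotypePanel
from .sumstats_io import SnpContext, CpGCatalog, SumstatTable, build_cpg_catalog
from scipy import stats

BASES = np.array(list("ACGT"))


@dataclass
class MixtureSpec:
    """Study-condition parameters of the synthetic trait pair.

    Defaults encode a sparse polygenic architecture with mild pleiotropy:
    2% of SNPs associated with each trait alone and 2% with both, signal
    SD 3 on the z scale (well-powered loci at consortium sample sizes),
    signal correlation 0.5 among pleiotropic SNPs, and moderately strong
    local LD (AR(1) r = 0.8 in 10-SNP blocks).
    """

    pi00: float = 0.94
    pi10: float = 0.02
    pi01: float = 0.02
    pi11: float = 0.02
    sigma1: float = 3.0
    sigma2: float = 3.0
    rho: float = 0.5
    n_snps: int = 10_000
    f_cpg: float = 0.3
    ld_block: int = 10
    r_ld: float = 0.8
    n_samples_trait1: int = 150_000
    n_samples_trait2: int = 150_000
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        pis = (self.pi00, self.pi10, self.pi01, self.pi11)
        if any(p < 0 for p in pis):
            raise ValueError("mixture proportions must be non-negative")
        if abs(sum(pis) - 1.0) > 1e-12:
            raise ValueError("mixture proportions must sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("signal SDs must be positive")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
        if self.n_snps < 1 or self.ld_block < 1:
            raise ValueError("n_snps and ld_block must be positive")
        if not 0 <= self.r_ld < 1:
            raise ValueError("r_ld must lie in [0, 1)")


CLASS_LABELS = np.array(["00", "10", "01", "11"])


@dataclass
class SyntheticTruth:
    """Per-SNP latent class, true z-score means and CpG flag."""

    df: pd.DataFrame  # snp_id, chrom, pos, latent_class, mu1, mu2, cpg_flag

    def class_of(self) -> pd.Series:
        return self.df.set_index("snp_id")["latent_class"]


def _positions(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SNP ids and coordinates spread over spec.n_chromosomes."""
    ids = np.array([f"rs{100000 + i}" for i in range(spec.n_snps)])
    per = int(np.ceil(spec.n_snps / spec.n_chromosomes))
    chrom = np.array([str(1 + i // per) for i in range(spec.n_snps)])
    pos = np.array([10_000 + 5_000 * (i % per) for i in range(spec.n_snps)])
    return ids, chrom, pos


def simulate_reference_panel(spec: MixtureSpec, n_samples: int = 200) -> GenotypePanel:
    """Block-diagonal LD genotype panel aligned to the simulated SNPs.

    LD follows a first-order haplotype-copying chain: within each
    ``ld_block``-SNP block the block's MAF is drawn from U(0.05, 0.5) and,
    per haplotype, each SNP copies its left neighbour's allele with
    probability ``r_ld`` (resampling a fresh Bernoulli(MAF) allele
    otherwise), so the correlation between adjacent dosages is ``r_ld``
    and decays geometrically with distance.  Dosages are the sum of two
    independent haplotypes.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20 for a usable LD reference")
    rng = np.random.default_rng(spec.seed + 1)
    ids, chrom, pos = _positions(spec)
    n = spec.n_snps
    dosages = np.zeros((n_samples, n))
    r = spec.r_ld
    for start in range(0, n, spec.ld_block):
        end = min(start + spec.ld_block, n)
        width = end - start
        maf = rng.uniform(0.05, 0.5)
        for _hap in range(2):
            alleles = np.empty((n_samples, width))
            alleles[:, 0] = rng.random(n_samples) < maf
            for j in range(1, width):
                copy = rng.random(n_samples) < r
                fresh = rng.random(n_samples) < maf
                alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
            dosages[:, start:end] += alleles
    return GenotypePanel(dosages, list(ids), chrom, pos)


def _random_contexts(
    rng: np.random.Generator, ids: np.ndarray, cpg: np.ndarray
) -> list[SnpContext]:
    """Flanking-base contexts consistent with each SNP's CpG flag.

    CpG-SNPs get a C on the left with a G/A allele pair (G completes the
    CG, A does not); non-CpG SNPs get neutral flanks and a non-C/G pair.
    """
    ctxs = []
    for i, s in enumerate(ids):
        if cpg[i]:
            ctxs.append(SnpContext(str(s), "C", str(rng.choice(("A", "T"))), "G", "A"))
        else:
            ctxs.append(SnpContext(str(s), "A", "T", "A", str(rng.choice(("T", "G")))))
    return ctxs


def simulate_sumstats_pair(
    spec: MixtureSpec,
) -> tuple[SumstatTable, SumstatTable, SyntheticTruth, CpGCatalog]:
    """Draw the paired summary statistics, the latent truth and the CpG
    catalog implied by the simulated flanking contexts."""
    rng = np.random.default_rng(spec.seed)
    ids, chrom, pos = _positions(spec)
    n = spec.n_snps
    classes = rng.choice(4, size=n, p=[spec.pi00, spec.pi10, spec.pi01, spec.pi11])

    mu1 = np.zeros(n)
    mu2 = np.zeros(n)
    mu1[classes == 1] = rng.normal(0, spec.sigma1, size=int((classes == 1).sum()))
    mu2[classes == 2] = rng.normal(0, spec.sigma2, size=int((classes == 2).sum()))
    n11 = int((classes == 3).sum())
    if n11:
        # shared + independent components give the target correlation and
        # stay well-defined at |rho| = 1
        u = rng.standard_normal(n11)
        v = rng.standard_normal(n11)
        mu1[classes == 3] = spec.sigma1 * u
        mu2[classes == 3] = spec.sigma2 * (spec.rho * u + np.sqrt(1 - spec.rho**2) * v)

    z1 = mu1 + rng.standard_normal(n)
    z2 = mu2 + rng.standard_normal(n)
    p1 = 2 * stats.norm.sf(np.abs(z1))
    p2 = 2 * stats.norm.sf(np.abs(z2))
    tiny = np.nextafter(0.0, 1.0)
    p1 = np.clip(p1, tiny, 1.0)
    p2 = np.clip(p2, tiny, 1.0)

    eaf = rng.uniform(0.05, 0.95, size=n)
    se1 = 1.0 / np.sqrt(2 * spec.n_samples_trait1 * eaf * (1 - eaf))
    se2 = 1.0 / np.sqrt(2 * spec.n_samples_trait2 * eaf * (1 - eaf))

    cpg = rng.random(n) < spec.f_cpg
    contexts = _random_contexts(rng, ids, cpg)
    catalog = build_cpg_catalog(contexts)

    # non-palindromic allele pair so the merged panel keeps every SNP
    allele_pairs = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])
    pick = rng.integers(0, len(allele_pairs), size=n)
    ea = allele_pairs[pick, 0]
    oa = allele_pairs[pick, 1]

    def table(label, z, se, p, n_samples):
        return SumstatTable(
            trait_label=label,
            df=pd.DataFrame(
                {
                    "snp_id": ids,
                    "chrom": chrom,
                    "pos": pos,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf,
                    "beta": z * se,
                    "se": se,
                    "pval": p,
                }
            ),
            n_samples=n_samples,
        )

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": chrom,
                "pos": pos,
                "latent_class": CLASS_LABELS[classes],
                "mu1": mu1,
                "mu2": mu2,
                "cpg_flag": cpg,
            }
        )
    )
    t1 = table("trait1", z1, se1, p1, spec.n_samples_trait1)
    t2 = table("trait2", z2, se2, p2, spec.n_samples_trait2)
    return t1, t2, truth, catalog


@dataclass
class MRTruth:
    true_slope: float
    alphas: np.ndarray = field(default_factory=lambda: np.zeros(0))


def simulate_mr_instruments(
    n_snp: int,
    true_slope: float,
    pleiotropy_sd: float = 0.0,
    pleiotropy_mean: float = 0.0,
    se_exposure: float = 0.003,
    se_outcome: float = 0.03,
    noise: bool = True,
    seed: int = 0,
):
    """Instrument table with known causal slope.

    beta_E = |N(0, 0.05^2)| + 0.02 (bounded away from zero);
    beta_O = slope*beta_E + alpha_i + noise, alpha_i ~ N(mean, sd^2)
    (directional pleiotropy off by default).  With ``noise=False`` the
    measurement errors vanish and every estimator is exact.
    """
    if n_snp < 2:
        raise ValueError("n_snp must be >= 2")
    rng = np.random.default_rng(seed)
    be_true = np.abs(rng.normal(0, 0.05, size=n_snp)) + 0.02
    alphas = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_snp) if (
        pleiotropy_sd > 0 or pleiotropy_mean != 0
    ) else np.zeros(n_snp)
    bo_true = true_slope * be_true + alphas
    if noise:
        be = rng.normal(be_true, se_exposure)
        bo = rng.normal(bo_true, se_outcome)
    else:
        be, bo = be_true, bo_true
    from .mr import MRInput

    df = pd.DataFrame(
        {
            "snp_id": [f"iv{i}" for i in range(n_snp)],
            "beta_exposure": be,
            "se_exposure": se_exposure,
            "beta_outcome": bo,
            "se_outcome": se_outcome,
            "eaf_exposure": 0.3,
            "eaf_outcome": 0.3,
        }
    )
    return MRInput("exposure", "outcome", df), MRTruth(true_slope, alphas)


def write_fixture_bundle(outdir: str | Path, spec: MixtureSpec, n_ref_samples: int = 200) -> dict:
    """Emit the complete synthetic study: two sumstats TSVs, a genotype
    reference TSV, the CpG catalog, the truth table and a YAML manifest.

    Returns the manifest (paths + spec + seed).  Re-running with the same
    spec reproduces every file byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t1, t2, truth, catalog = simulate_sumstats_pair(spec)
    panel = simulate_reference_panel(spec, n_samples=n_ref_samples)

    paths = {
        "sumstats_trait1": outdir / "sumstats_trait1.tsv",
        "sumstats_trait2": outdir / "sumstats_trait2.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "cpg_catalog": outdir / "cpg_catalog.tsv",
        "truth": outdir / "truth.tsv",
    }
    t1.df.to_csv(paths["sumstats_trait1"], sep="\t", index=False)
    t2.df.to_csv(paths["sumstats_trait2"], sep="\t", index=False)
    panel.to_tsv(paths["genotypes"])
    pd.DataFrame({"snp_id": sorted(catalog.membership)}).to_csv(
        paths["cpg_catalog"], sep="\t", index=False
    )
    truth.df.to_csv(paths["truth"], sep="\t", index=False)

    manifest = {
        "spec": asdict(spec),
        "n_ref_samples": n_ref_samples,
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
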