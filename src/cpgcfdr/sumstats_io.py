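"""Reading, validation, merging and CpG-filtering of GWAS summary statistics.

Summary statistics are carried as pandas DataFrames with the canonical
columns ``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
pval`` wrapped in a light :class:`SumstatTable`.  Effect sizes are on the
trait scale (log odds ratios for binary traits).  Coordinates are 1-based.

Rows violating the per-record invariants (non-ACGT or identical alleles,
``se <= 0``, ``pval`` outside ``(0, 1]``, ``eaf`` outside ``[0, 1]``) are
dropped at read time and counted; p-values of exactly zero are clamped to
the smallest positive float and logged rather than dropped.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Palindromic SNPs whose effect-allele frequency falls inside this closed
#: band cannot be strand-resolved from frequency and are dropped.
AMBIGUITY_BAND = (0.42, 0.58)

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
]

#: smallest positive double; zero p-values are clamped here before -log10.
TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class SumstatTable:
    """One trait's per-SNP association summary records.

    ``df`` holds the canonical columns sorted by ``(chrom, pos)`` with
    unique ``snp_id``.
    """

    trait_label: str
    df: pd.DataFrame
    n_samples: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SumstatTable missing columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate snp_id in table: {dups.iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.df)


def _chrom_rank(chrom: pd.Series) -> pd.Series:
    """Numeric ordering for chromosome labels (1..22 < X < Y < MT < other)."""
    special = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}

    def rank(c: str) -> int:
        c = str(c).removeprefix("chr")
        if c.isdigit():
            return int(c)
        return special.get(c.upper(), 99)

    return chrom.map(rank)


def sort_genomic(df: pd.DataFrame) -> pd.DataFrame:
    key = _chrom_rank(df["chrom"])
    return (
        df.assign(_ck=key)
        .sort_values(["_ck", "pos"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sumstats(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    trait_label: str | None = None,
    n_samples: int | None = None,
    or_column: str | None = None,
) -> SumstatTable:
    """Read a tab-separated summary-statistics file into a validated table.

    Parameters
    ----------
    path
        TSV file with a header row; transparently gunzipped if ``.gz``.
    dialect
        Mapping from canonical column names to the file's column names,
        e.g. ``{"snp_id": "MarkerName", "pval": "P"}``.  Unmapped canonical
        names are looked up verbatim.
    or_column
        Name of an odds-ratio column to convert to ``beta`` via the natural
        log (mutually exclusive with a mapped ``beta`` column).
    """
    dialect = dict(dialect or {})
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep="\t", dtype={0: str})
    colmap: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        if canon == "beta" and or_column is not None:
            continue
        src = dialect.get(canon, canon)
        if src not in raw.columns:
            raise ValueError(f"mandatory column {src!r} (for {canon!r}) missing in {path}")
        colmap[src] = canon
    df = raw.rename(columns=colmap)[
        [c for c in CANONICAL_COLUMNS if c != "beta" or or_column is None]
    ].copy()
    if or_column is not None:
        if or_column not in raw.columns:
            raise ValueError(f"odds-ratio column {or_column!r} missing in {path}")
        df["beta"] = np.log(raw[or_column].astype(float).to_numpy())
    df = df[CANONICAL_COLUMNS]

    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    n_zero_p = int((df["pval"] == 0).sum())
    if n_zero_p:
        logger.warning("%d p-values of exactly 0 clamped to %g", n_zero_p, TINY_P)
        df.loc[df["pval"] == 0, "pval"] = TINY_P

    ok = (
        df["effect_allele"].isin(VALID_BASES)
        & df["other_allele"].isin(VALID_BASES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["eaf"] >= 0)
        & (df["eaf"] <= 1)
        & df["beta"].notna()
        & df["pos"].notna()
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_dropped)
    df = df[ok]
    if df.empty:
        raise ValueError(f"no valid summary-statistic rows in {path}")
    df["pos"] = df["pos"].astype(int)
    df = sort_genomic(df)
    return SumstatTable(
        trait_label=trait_label or Path(path).stem,
        df=df,
        n_samples=n_samples,
        n_dropped=n_dropped,
    )


def write_sumstats(table: SumstatTable, path: str | Path) -> None:
    """Write the canonical TSV dialect (deterministic column/row order)."""
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CpG-SNP classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpContext:
    """Immediate flanking reference bases and the two alleles of a SNP."""

    snp_id: str
    left_base: str
    right_base: str
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        for b in (self.left_base, self.right_base, self.allele_a, self.allele_b):
            if b not in VALID_BASES:
                raise ValueError(f"invalid nucleotide {b!r} in context for {self.snp_id}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"alleles identical for {self.snp_id}")


def _cpg_sites(left: str, allele: str, right: str) -> frozenset[tuple[int, int]]:
    """CG dinucleotides overlapping the variant position, as offset pairs.

    CpG is strand-symmetric (CG reverse-complements to CG), so scanning the
    plus strand suffices.
    """
    sites = set()
    if left == "C" and allele == "G":
        sites.add((-1, 0))
    if allele == "C" and right == "G":
        sites.add((0, 1))
    return frozenset(sites)


def classify_cpg_snp(ctx: SnpContext) -> bool:
    """True iff the two alleles differ in the CpG sites they form.

    A SNP is a CpG-SNP when one allele introduces or disrupts a CG
    dinucleotide relative to the other, i.e. the allele changes whether (or
    where) the position participates in a potential methylation target.
    """
    a = _cpg_sites(ctx.left_base, ctx.allele_a, ctx.right_base)
    b = _cpg_sites(ctx.left_base, ctx.allele_b, ctx.right_base)
    return a != b


@dataclass
class CpGCatalog:
    """Set of snp_ids classified as CpG-SNPs."""

    membership: frozenset[str] = field(default_factory=frozenset)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.membership

    def __len__(self) -> int:
        return len(self.membership)


def build_cpg_catalog(contexts: list[SnpContext]) -> CpGCatalog:
    seen: set[str] = set()
    members: set[str] = set()
    for ctx in contexts:
        if ctx.snp_id in seen:
            raise ValueError(f"duplicate snp_id in contexts: {ctx.snp_id!r}")
        seen.add(ctx.snp_id)
        if classify_cpg_snp(ctx):
            members.add(ctx.snp_id)
    return CpGCatalog(frozenset(members))


def read_contexts(path: str | Path) -> list[SnpContext]:
    """Read a (snp_id, left_base, right_base, allele_a, allele_b) TSV."""
    df = pd.read_csv(path, sep="\t")
    return [
        SnpContext(r.snp_id, r.left_base, r.right_base, r.allele_a, r.allele_b)
        for r in df.itertuples(index=False)
    ]


def read_catalog(path: str | Path) -> CpGCatalog:
    """Read a catalog as either an id list or a context TSV."""
    with _open_text(path) as fh:
        header = fh.readline().strip().split("\t")
    if len(header) >= 5:
        return build_cpg_catalog(read_contexts(path))
    ids = pd.read_csv(path, sep="\t")
    return CpGCatalog(frozenset(ids.iloc[:, 0].astype(str)))


def write_catalog(catalog: CpGCatalog, path: str | Path) -> None:
    pd.DataFrame({"snp_id": sorted(catalog.membership)}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-trait merging
# ---------------------------------------------------------------------------


@dataclass
class MergedPanel:
    """SNP-aligned joint (p1, p2, z1, z2, CpG flag) table for a trait pair.

    ``df`` columns: snp_id, chrom, pos, p1, p2, z1, z2, cpg_flag.
    Trait 1 is the principal trait of the ``p1``/``z1`` columns.
    """

    trait1: str
    trait2: str
    df: pd.DataFrame
    n_dropped_alleles: int = 0
    n_dropped_palindromic: int = 0

    def __len__(self) -> int:
        return len(self.df)


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in PALINDROMIC_PAIRS


def merge_traits(t1: SumstatTable, t2: SumstatTable) -> MergedPanel:
    """Inner-join two traits on snp_id with allele harmonization.

    Alleles of trait 2 are aligned to trait 1's effect allele: a swapped
    coding flips the sign of beta2 and complements eaf2; a strand flip
    (base complement) is accepted as-is; swap-plus-complement flips sign.
    Palindromic SNPs (A/T or C/G) whose frequency in either study falls in
    the ambiguity band around 0.5 are dropped; irreconcilable allele sets
    are dropped and counted.
    """
    m = t1.df.merge(t2.df, on="snp_id", suffixes=("_1", "_2"))
    if m.empty:
        return MergedPanel(t1.trait_label, t2.trait_label, _empty_panel())

    ea1, oa1 = m["effect_allele_1"], m["other_allele_1"]
    ea2, oa2 = m["effect_allele_2"], m["other_allele_2"]
    cea2 = ea2.map(COMPLEMENT)
    coa2 = oa2.map(COMPLEMENT)

    same = (ea2 == ea1) & (oa2 == oa1)
    swap = (ea2 == oa1) & (oa2 == ea1)
    comp = (cea2 == ea1) & (coa2 == oa1)
    comp_swap = (cea2 == oa1) & (coa2 == ea1)
    reconcilable = same | swap | comp | comp_swap
    n_bad_alleles = int((~reconcilable).sum())

    palin = [
        _is_palindromic(e, o) for e, o in zip(ea1, oa1)
    ]
    palin = pd.Series(palin, index=m.index)
    lo, hi = AMBIGUITY_BAND
    ambiguous = palin & (
        m["eaf_1"].between(lo, hi) | m["eaf_2"].between(lo, hi)
    )
    n_palindromic = int((reconcilable & ambiguous).sum())

    keep = reconcilable & ~ambiguous
    m = m[keep].copy()
    if n_bad_alleles:
        logger.info("merge_traits: dropped %d rows with irreconcilable alleles", n_bad_alleles)
    if n_palindromic:
        logger.info("merge_traits: dropped %d ambiguous palindromic rows", n_palindromic)

    # For palindromic SNPs the swap and complement configurations coincide,
    # so allele labels cannot orient the effect; frequency discordance
    # (minor allele on opposite sides of 0.5) decides the flip instead.
    label_flip = (swap | comp_swap)[keep].to_numpy()
    palin_kept = palin[keep].to_numpy()
    freq_discord = (
        (m["eaf_1"].to_numpy() - 0.5) * (m["eaf_2"].to_numpy() - 0.5) < 0
    )
    flip = np.where(palin_kept, freq_discord, label_flip)

    beta2 = np.where(flip, -m["beta_2"].to_numpy(), m["beta_2"].to_numpy())
    out = pd.DataFrame(
        {
            "snp_id": m["snp_id"].to_numpy(),
            "chrom": m["chrom_1"].to_numpy(),
            "pos": m["pos_1"].to_numpy(),
            "p1": m["pval_1"].to_numpy(),
            "p2": m["pval_2"].to_numpy(),
            "z1": m["beta_1"].to_numpy() / m["se_1"].to_numpy(),
            "z2": beta2 / m["se_2"].to_numpy(),
            "cpg_flag": False,
        }
    )
    out = sort_genomic(out)
    return MergedPanel(
        t1.trait_label,
        t2.trait_label,
        out,
        n_dropped_alleles=n_bad_alleles,
        n_dropped_palindromic=n_palindromic,
    )


def _empty_panel() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "p1", "p2", "z1", "z2", "cpg_flag"]
    )


def filter_cpg(panel: MergedPanel, catalog: CpGCatalog) -> MergedPanel:
    """Restrict the panel to catalog members, preserving order."""
    mask = panel.df["snp_id"].isin(catalog.membership)
    out = panel.df[mask].copy()
    if out.empty:
        raise ValueError(
            "CpG filter removed every SNP: the catalog does not overlap the panel "
            "(check snp_id conventions)"
        )
    out["cpg_flag"] = True
    return MergedPanel(panel.trait1, panel.trait2, out.reset_index(drop=True))
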