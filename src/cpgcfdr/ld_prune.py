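"""Pairwise genotype r², windowed LD pruning, and greedy p-value clumping.

The pruning scheme mirrors the classic ``indep-pairwise`` procedure: slide
a window of ``window_snps`` SNPs along each chromosome in steps of
``step_snps``; within a window, while any retained pair has r² above the
ceiling, remove one SNP of the pair; repeat full passes until stable.
Which SNP of a violating pair is removed is made deterministic here: the
one with the larger principal-trait p-value, falling back to the later
positional SNP when no p-values are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """Reference genotypes: ``dosages`` is samples x SNPs in {0,1,2}.

    Missing dosages are NaN.  SNP columns are sorted by (chrom, pos).
    """

    dosages: np.ndarray
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match snp id count")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp ids in genotype panel")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def subset(self, ids: list[str]) -> "GenotypePanel":
        idx = [self.snp_ids.index(i) for i in ids]
        return GenotypePanel(
            self.dosages[:, idx],
            [self.snp_ids[i] for i in idx],
            self.chrom[idx],
            self.pos[idx],
            self.sample_ids,
        )

    @classmethod
    def from_tsv(cls, geno_path: str | Path, variant_map: pd.DataFrame) -> "GenotypePanel":
        """Load a samples-as-rows dosage TSV plus a (snp_id, chrom, pos) map.

        The genotype file's first column is the sample id; remaining column
        headers are snp ids.  SNPs absent from the map are dropped.
        """
        raw = pd.read_csv(geno_path, sep="\t")
        sample_ids = raw.iloc[:, 0].astype(str).tolist()
        geno = raw.iloc[:, 1:]
        vm = variant_map.set_index("snp_id")
        keep = [c for c in geno.columns if c in vm.index]
        geno = geno[keep]
        order = np.lexsort(
            (vm.loc[keep, "pos"].to_numpy(), vm.loc[keep, "chrom"].astype(str).to_numpy())
        )
        ids = [keep[i] for i in order]
        return cls(
            geno[ids].to_numpy(dtype=float),
            ids,
            vm.loc[ids, "chrom"].astype(str).to_numpy(),
            vm.loc[ids, "pos"].to_numpy(),
            sample_ids,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PruneResult:
    kept: list[str]
    removed: list[str]
    trigger: dict[str, str] = field(default_factory=dict)  # removed id -> partner

    def __post_init__(self) -> None:
        if set(self.kept) & set(self.removed):
            raise ValueError("kept and removed sets overlap")


def pairwise_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing values are removed pairwise-complete.  Returns NaN when fewer
    than two complete pairs remain or either vector has zero variance
    (callers treat NaN as "no LD evidence", i.e. r² = 0).
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = ~(np.isnan(g_i) | np.isnan(g_j))
    x, y = g_i[ok], g_j[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """All-pairs r² with pairwise-complete missing handling."""
    n = dosages.shape[1]
    out = np.empty((n, n))
    if not np.isnan(dosages).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(dosages, rowvar=False)
        out = c * c
        np.fill_diagonal(out, 1.0)
        return out
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_r2(dosages[:, i], dosages[:, j])
    return out


def indep_pairwise(
    panel: GenotypePanel,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
    pvals: dict[str, float] | None = None,
) -> PruneResult:
    """Windowed LD pruning; chromosomes are processed independently.

    ``pvals`` (snp_id -> principal-trait p) breaks removal ties: within a
    violating pair the larger-p SNP is removed; without p-values the later
    positional SNP goes.
    """
    if window_snps <= 1:
        raise ValueError("window_snps must be > 1")
    kept_all: list[str] = []
    removed_all: list[str] = []
    trigger: dict[str, str] = {}

    for chrom in pd.unique(pd.Series(panel.chrom, dtype=object)):
        idx = np.flatnonzero(panel.chrom == chrom)
        idx = idx[np.argsort(panel.pos[idx], kind="stable")]
        doses = panel.dosages[:, idx]
        ids = [panel.snp_ids[i] for i in idx]
        n = len(ids)
        r2 = _r2_matrix(doses)
        r2 = np.nan_to_num(r2, nan=0.0)
        alive = np.ones(n, dtype=bool)

        def remove_of_pair(i: int, j: int) -> int:
            if pvals is not None:
                pi = pvals.get(ids[i], np.nan)
                pj = pvals.get(ids[j], np.nan)
                if not (np.isnan(pi) or np.isnan(pj)) and pi != pj:
                    return i if pi > pj else j
            return j  # later positional SNP

        # windows slide over the SNPs surviving at the start of each pass;
        # passes repeat until a full sweep removes nothing, so no window
        # over the final kept list contains a violating pair
        changed = True
        while changed:
            changed = False
            survivors = [k for k in range(n) if alive[k]]
            for start in range(0, max(len(survivors) - 1, 1), step_snps):
                win = [k for k in survivors[start : start + window_snps] if alive[k]]
                while True:
                    worst = None
                    worst_r2 = r2_max
                    for a in range(len(win)):
                        for b in range(a + 1, len(win)):
                            v = r2[win[a], win[b]]
                            if v > worst_r2:
                                worst_r2 = v
                                worst = (win[a], win[b])
                    if worst is None:
                        break
                    i, j = worst
                    drop = remove_of_pair(i, j)
                    other = i if drop == j else j
                    alive[drop] = False
                    trigger[ids[drop]] = ids[other]
                    win.remove(drop)
                    changed = True
        kept_all.extend([ids[k] for k in range(n) if alive[k]])
        removed_all.extend([ids[k] for k in range(n) if not alive[k]])

    return PruneResult(kept_all, removed_all, trigger)


def clump_by_pvalue(
    ids: list[str],
    pvals: np.ndarray,
    panel: GenotypePanel,
    r2_max: float = 0.001,
) -> list[str]:
    """Greedy p-value clumping: accept SNPs in ascending-p order when their
    r² with every previously accepted SNP on the same chromosome stays
    below ``r2_max``."""
    pvals = np.asarray(pvals, dtype=float)
    if len(ids) != pvals.size:
        raise ValueError("ids and pvals length mismatch")
    col = {s: k for k, s in enumerate(panel.snp_ids)}
    chrom_of = {s: panel.chrom[k] for s, k in col.items()}
    order = np.lexsort((np.asarray(ids, dtype=object), pvals))
    accepted: list[str] = []
    for o in order:
        s = ids[o]
        if s not in col:
            logger.warning("clump: %s absent from genotype panel; skipped", s)
            continue
        ok = True
        for a in accepted:
            if chrom_of[a] != chrom_of[s]:
                continue
            v = pairwise_r2(panel.dosages[:, col[s]], panel.dosages[:, col[a]])
            if not np.isnan(v) and v >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(s)
    return accepted
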