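"""Nonparametric group statistics for longitudinal phase comparisons.

Per-feature active-phase (AP) vs remission-phase (RP) differences are
tested with the Mann-Whitney U test and adjusted across features with the
Benjamini-Hochberg step-up rule at FDR < 0.05; feature-vs-severity
relationships use Spearman rank correlation with the joint |rho| > 0.5 and
p < 0.01 threshold.  Exact p-values are used where enumeration is cheap
(tie-free Mann-Whitney with n1+n2 <= 12; tie-free Spearman with n <= 9),
otherwise the usual large-sample approximations with tie and continuity
corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # {"exact", "asymptotic", "degenerate"}

    def __iter__(self):
        return iter((self.u, self.p))


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided",
                   method: str = "auto") -> MannWhitneyResult:
    """Mann-Whitney U with mid-ranks.

    method "auto" selects exact enumeration for tie-free samples with
    n_x + n_y <= 12, else the normal approximation with tie and continuity
    corrections.  Two identical constant groups yield p = 1 flagged
    degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=len(x) * len(y) / 2, p=1.0, method="degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        use_exact = not has_ties and len(pooled) <= EXACT_MW_MAX_N
    elif method == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney requires tie-free data")
        use_exact = True
    elif method == "asymptotic":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if use_exact else "asymptotic",
                           use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             method="exact" if use_exact else "asymptotic")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@lru_cache(maxsize=8)
def _exact_spearman_distribution(n: int) -> np.ndarray:
    """Sorted |rho| over all n! permutations of tie-free ranks."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1)
    rhos = []
    for perm in itertools.permutations(range(n)):
        d2 = float(np.sum((base - base[list(perm)]) ** 2))
        rhos.append(abs(1.0 - 6.0 * d2 / denom))
    return np.sort(np.array(rhos))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    method: str

    def __iter__(self):
        return iter((self.rho, self.p))


def spearman_rho(x: Sequence[float], y: Sequence[float],
                 method: str = "auto") -> SpearmanResult:
    """Spearman rank correlation (mid-ranks on ties).

    Tie-free samples with n <= 9 get an exact two-sided p from the full
    permutation distribution; otherwise the t-approximation with n - 2
    degrees of freedom.  A constant input yields rho = nan flagged
    "not-available".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("spearman_rho requires equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=float("nan"), p=float("nan"),
                              method="not-available")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tie_free = (len(np.unique(x)) == n) and (len(np.unique(y)) == n)
    if method == "auto":
        use_exact = tie_free and n <= EXACT_SPEARMAN_MAX_N
    elif method == "exact":
        if not tie_free:
            raise ValueError("exact Spearman requires tie-free data")
        use_exact = True
    elif method == "approx":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")
    if use_exact:
        dist = _exact_spearman_distribution(n)
        p = float(np.mean(dist >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p=p, method="exact")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho=rho, p=0.0, method="approx")
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p=min(p, 1.0), method="approx")


def _phase_groups(meta: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    ap = meta.index[meta["phase"] == "AP"]
    rp = meta.index[meta["phase"] == "RP"]
    if len(ap) < 2 or len(rp) < 2:
        raise ValueError(
            f"each phase needs >= 2 samples (AP={len(ap)}, RP={len(rp)})")
    return ap, rp


def compare_phase_groups(table: pd.DataFrame, meta: pd.DataFrame,
                         fdr: float = 0.05) -> pd.DataFrame:
    """Per-feature AP vs RP Mann-Whitney with BH adjustment.

    table is samples x features; meta must carry a "phase" column over the
    same samples.  Features zero in every sample are excluded before
    adjustment (counted in attrs["n_excluded"]).  direction is "up_RP" when
    the RP median exceeds the AP median.
    """
    missing = [s for s in table.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[table.index]
    ap, rp = _phase_groups(meta)
    nonzero = table.columns[(table != 0).any(axis=0)]
    rows = []
    for feat in nonzero:
        xa = table.loc[ap, feat].to_numpy()
        xr = table.loc[rp, feat].to_numpy()
        res = mann_whitney_u(xa, xr)
        med_ap, med_rp = float(np.median(xa)), float(np.median(xr))
        rows.append(dict(feature=feat, u=res.u, p=res.p,
                         median_ap=med_ap, median_rp=med_rp,
                         mean_ap=float(np.mean(xa)), mean_rp=float(np.mean(xr)),
                         direction="up_RP" if med_rp > med_ap else "down_RP",
                         method=res.method))
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
        out = out.sort_values("q", kind="mergesort").reset_index(drop=True)
    out.attrs["n_excluded"] = len(table.columns) - len(nonzero)
    return out


def easi_correlation(table: pd.DataFrame, meta: pd.DataFrame,
                     rho_cut: float = 0.5, p_cut: float = 0.01) -> pd.DataFrame:
    """Per-feature Spearman correlation against the EASI severity score.

    passes_threshold requires |rho| > rho_cut and p < p_cut.  Results are
    sorted by |rho| descending.  A constant EASI vector leaves every result
    not-available.
    """
    missing = [s for s in table.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    easi = meta.loc[table.index, "easi"].to_numpy(dtype=float)
    rows = []
    for feat in table.columns:
        res = spearman_rho(table[feat].to_numpy(), easi)
        ok = (not math.isnan(res.rho) and abs(res.rho) > rho_cut
              and res.p < p_cut)
        rows.append(dict(feature=feat, rho=res.rho, p=res.p,
                         passes_threshold=ok, method=res.method))
    out = pd.DataFrame(rows)
    out["abs_rho"] = out["rho"].abs()
    out = (out.sort_values("abs_rho", ascending=False, kind="mergesort")
           .drop(columns="abs_rho").reset_index(drop=True))
    return out


def fld_adjacency_filter(genes: pd.DataFrame,
                         pair: tuple[str, str] = ("fldB", "fldC")
                         ) -> pd.DataFrame:
    """Retain fldB/fldC homolog pairs that are adjacent on one contig.

    genes needs columns gene_id, contig, gene_index (ordinal position on
    the contig), family.  A pair is retained iff both members sit on the
    same contig with |ordinal difference| == 1; all other hits drop.
    """
    a, b = pair
    rows = []
    for contig, grp in genes.groupby("contig"):
        ga = grp[grp["family"] == a]
        gb = grp[grp["family"] == b]
        for ra in ga.itertuples(index=False):
            for rb in gb.itertuples(index=False):
                if abs(int(ra.gene_index) - int(rb.gene_index)) == 1:
                    rows.append(dict(contig=contig,
                                     **{f"{a}_gene": ra.gene_id,
                                        f"{b}_gene": rb.gene_id}))
    return pd.DataFrame(rows, columns=["contig", f"{a}_gene", f"{b}_gene"])


def increment_analysis(table_t1: pd.DataFrame, table_t2: pd.DataFrame,
                       groups: Mapping[str, str]) -> pd.DataFrame:
    """Two-timepoint increment comparison across subject groups.

    table_t1/table_t2 are subjects x feature-classes at the two timepoints.
    Per feature class: per-subject increment t2 - t1; a between-group
    Mann-Whitney on the increments; and within each group both an unpaired
    Mann-Whitney of t2 vs t1 values and a paired Wilcoxon signed-rank
    (labeled columns — the choice is left to the reader).
    """
    unmatched = set(table_t1.index) ^ set(table_t2.index)
    if unmatched:
        raise ValueError(f"subject(s) not matched across timepoints: "
                         f"{sorted(unmatched)[:5]}")
    missing = [s for s in table_t1.index if s not in groups]
    if missing:
        raise ValueError(f"subject(s) without group label: {missing[:5]}")
    subjects = list(table_t1.index)
    table_t2 = table_t2.loc[subjects]
    labels = sorted(set(groups[s] for s in subjects))
    if len(labels) != 2:
        raise ValueError(f"increment_analysis needs exactly 2 groups, got {labels}")
    g1, g2 = labels
    idx1 = [s for s in subjects if groups[s] == g1]
    idx2 = [s for s in subjects if groups[s] == g2]
    rows = []
    for feat in table_t1.columns:
        inc = table_t2[feat] - table_t1[feat]
        between = mann_whitney_u(inc.loc[idx1], inc.loc[idx2])
        row = dict(feature=feat,
                   **{f"mean_increment_{g1}": float(inc.loc[idx1].mean()),
                      f"mean_increment_{g2}": float(inc.loc[idx2].mean())},
                   between_u=between.u, between_p=between.p,
                   direction=(f"higher_{g1}" if inc.loc[idx1].median()
                              > inc.loc[idx2].median() else f"higher_{g2}"))
        for label, idx in ((g1, idx1), (g2, idx2)):
            within = mann_whitney_u(table_t1.loc[idx, feat],
                                    table_t2.loc[idx, feat])
            row[f"within_{label}_unpaired_p"] = within.p
            diffs = inc.loc[idx].to_numpy()
            if np.all(diffs == 0):
                row[f"within_{label}_paired_p"] = 1.0
            else:
                row[f"within_{label}_paired_p"] = float(
                    sps.wilcoxon(diffs, zero_method="wilcox").pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
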