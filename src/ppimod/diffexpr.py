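"""From a counts matrix to a seed gene set.

The stage mirrors how nonparametric RNA-seq group comparisons are run on a
small paired donor design: median-of-ratios size-factor normalization,
averaging of technical replicates within each (donor, phenotype, treatment,
timepoint) cell, per-gene linear fold change with a pseudocount, exact
Mann-Whitney U (unpaired) or Wilcoxon matched-pairs signed-rank (paired)
p-values on log2 values, and threshold filtering into a seed set.  The
2^-ddCT relative-expression computation used for qPCR validation lives here
as well.

Exact test p-values are computed from the full permutation distribution
(rank-sum counting for Mann-Whitney, a sign-flip generating function for
Wilcoxon) whenever the design is small enough; larger designs fall back to
the normal approximation with midrank tie correction and continuity
correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

META_COLUMNS = ("donor", "phenotype", "treatment", "timepoint", "replicate")

DEFAULT_PSEUDOCOUNT = 0.5
MANN_WHITNEY_EXACT_LIMIT = 12  # exact when n + m <= limit and no ties
WILCOXON_EXACT_LIMIT = 15  # exact when nonzero pairs <= limit


class DiffExprError(ValueError):
    """Raised for invalid expression input or degenerate designs."""


# ---------------------------------------------------------------------------
# normalization and replicate handling
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample j the factor is the median over reference genes (genes with
    positive counts in every sample) of counts[g, j] / geomean_g(counts).

    Parameters
    ----------
    counts
        Genes x samples non-negative matrix.
    """
    arr = counts.to_numpy(dtype=float)
    zero_samples = counts.columns[(arr.sum(axis=0) == 0)]
    if len(zero_samples):
        raise DiffExprError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise DiffExprError("no reference genes (no gene expressed in all samples)")
    log_geomean = np.log(arr[ref]).mean(axis=1, keepdims=True)
    ratios = arr[ref] / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def average_replicates(
    counts: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average replicate columns within each (donor, phenotype, treatment, timepoint).

    Returns the averaged matrix plus the collapsed metadata (one row per
    group, ``replicate`` fixed at 1).  The input is typically normalized
    first; averaging identical replicates is a no-op.
    """
    _check_meta(counts, meta)
    keys = ["donor", "phenotype", "treatment", "timepoint"]
    group_of = meta[keys].astype(str).agg(":".join, axis=1)
    out_cols: dict[str, np.ndarray] = {}
    out_meta: list[dict] = []
    for gid in group_of.unique():
        members = group_of.index[group_of == gid]
        out_cols[gid] = counts[members].mean(axis=1).to_numpy()
        row = meta.loc[members[0], list(keys)].to_dict()
        row["replicate"] = 1
        out_meta.append(row)
    avg = pd.DataFrame(out_cols, index=counts.index)
    avg_meta = pd.DataFrame(out_meta, index=list(out_cols))
    avg_meta.index.name = "sample_id"
    return avg, avg_meta


def _check_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    if meta.index.has_duplicates:
        raise DiffExprError("duplicate sample_ids in metadata")
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise DiffExprError(f"samples without metadata: {missing}")
    if counts.index.has_duplicates:
        raise DiffExprError("duplicate gene ids in counts matrix")


# ---------------------------------------------------------------------------
# exact nonparametric tests
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _mw_u_pmf(n: int, m: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic for group sizes n, m (no ties).

    Built by the standard rank-sum counting recursion; entry u is
    P(U = u), u = 0 .. n*m.
    """
    # C(i, j, u): interleavings of i x's and j y's with U = u.  The largest
    # pooled rank is either a y (C(i, j-1, u)) or an x beating all j y's
    # (C(i-1, j, u-j)).
    size = n * m + 1
    prev = np.zeros((m + 1, size))  # i = 0
    prev[:, 0] = 1.0
    for _i in range(1, n + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for j in range(1, m + 1):
            cur[j] = cur[j - 1]
            cur[j, j:] += prev[j, :-j]
        prev = cur
    counts = prev[m]
    return counts / counts.sum()


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = MANN_WHITNEY_EXACT_LIMIT,
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U, p).

    U counts pairs where x exceeds y (ties add 1/2).  Exact p from the full
    null distribution when n + m <= ``exact_limit`` and the pooled data are
    tie-free; otherwise the normal approximation with midrank tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DiffExprError("mann_whitney_u: empty group")
    if alternative not in {"two-sided", "greater", "less"}:
        raise DiffExprError(f"unknown alternative: {alternative!r}")
    n, m = x.size, y.size
    u_stat = float((x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum())

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= exact_limit and not has_ties:
        pmf = _mw_u_pmf(n, m)
        u = int(round(u_stat))
        if alternative == "greater":
            p = float(pmf[u:].sum())
        elif alternative == "less":
            p = float(pmf[: u + 1].sum())
        else:
            center = n * m / 2.0
            dev = abs(u - center)
            support = np.arange(pmf.size)
            p = float(pmf[np.abs(support - center) >= dev - 1e-12].sum())
        return u_stat, min(1.0, p)

    # normal approximation with tie correction
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1)))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return u_stat, 1.0
    mean = n * m / 2.0
    if alternative == "greater":
        z = (u_stat - mean - 0.5) / math.sqrt(var)
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u_stat - mean + 0.5) / math.sqrt(var)
        p = stats.norm.cdf(z)
    else:
        z = (abs(u_stat - mean) - 0.5) / math.sqrt(var)
        p = 2 * stats.norm.sf(max(z, 0.0))
    return u_stat, float(min(1.0, max(p, np.nextafter(0, 1))))


@lru_cache(maxsize=1024)
def _signed_rank_pmf(double_ranks: tuple[int, ...]) -> np.ndarray:
    """Null pmf of the positive rank sum over all sign assignments.

    Ranks are passed doubled so midranks stay integral; index w of the
    result is P(2 * W+ = w).
    """
    total = sum(double_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    alternative: str = "two-sided",
    exact_limit: int = WILCOXON_EXACT_LIMIT,
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test; returns (W, p).

    Differences x - y; zero differences are dropped.  W is the smaller of
    the positive/negative rank sums.  Exact p from the sign-flip
    distribution (conditional on the observed midranks) when the number of
    nonzero pairs <= ``exact_limit``; otherwise the normal approximation.
    """
    arr = np.asarray(pairs, dtype=float)
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    k = d.size
    if k == 0:
        raise DiffExprError("degenerate pairs: all differences zero")
    if alternative not in {"two-sided", "greater", "less"}:
        raise DiffExprError(f"unknown alternative: {alternative!r}")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w_stat = min(w_pos, w_neg)
    total = k * (k + 1) / 2.0

    if k <= exact_limit:
        dr = tuple(int(round(2 * r)) for r in ranks)
        pmf = _signed_rank_pmf(dr)
        support = np.arange(pmf.size)  # doubled W+ values
        obs = int(round(2 * w_pos))
        if alternative == "greater":
            p = float(pmf[support >= obs].sum())
        elif alternative == "less":
            p = float(pmf[support <= obs].sum())
        else:
            center = total  # doubled scale: 2 * total / 2
            dev = abs(obs - center)
            p = float(pmf[np.abs(support - center) >= dev - 1e-12].sum())
        return w_stat, min(1.0, p)

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = k * (k + 1) * (2 * k + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    mean = total / 2.0
    if var <= 0:
        return w_stat, 1.0
    if alternative == "greater":
        z = (w_pos - mean - 0.5) / math.sqrt(var)
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (w_pos - mean + 0.5) / math.sqrt(var)
        p = stats.norm.cdf(z)
    else:
        z = (abs(w_pos - mean) - 0.5) / math.sqrt(var)
        p = 2 * stats.norm.sf(max(z, 0.0))
    return w_stat, float(min(1.0, max(p, np.nextafter(0, 1))))


# ---------------------------------------------------------------------------
# differential expression and seed selection
# ---------------------------------------------------------------------------

def differential_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: Mapping[str, str],
    group_b: Mapping[str, str],
    paired: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalize: bool = True,
    average: bool = True,
) -> pd.DataFrame:
    """Per-gene fold change and nonparametric p-value for a two-group contrast.

    Groups are metadata selections, e.g. ``{"treatment": "compressed",
    "timepoint": "t3h"}`` vs the matching control.  Counts are size-factor
    normalized and replicates averaged first; fold change is
    (mean_a + pc) / (mean_b + pc) on the linear scale, p-values come from
    :func:`mann_whitney_u` on log2 values (unpaired) or
    :func:`wilcoxon_signed_rank` on donor-matched log2 differences (paired).

    Returns a DataFrame indexed by gene with columns fc, log2fc, p, direction.
    """
    _check_meta(counts, meta)
    if normalize:
        counts = normalize_counts(counts)
    if average:
        counts, meta = average_replicates(counts, meta)

    cols_a = _select_samples(meta, group_a, "group_a")
    cols_b = _select_samples(meta, group_b, "group_b")

    mat = counts.to_numpy(dtype=float)
    idx_a = [counts.columns.get_loc(c) for c in cols_a]
    idx_b = [counts.columns.get_loc(c) for c in cols_b]
    log_a = np.log2(mat[:, idx_a] + pseudocount)
    log_b = np.log2(mat[:, idx_b] + pseudocount)

    if paired:
        donors_a = meta.loc[cols_a, "donor"]
        donors_b = meta.loc[cols_b, "donor"]
        common = [d for d in donors_a if d in set(donors_b)]
        if not common:
            raise DiffExprError("paired contrast: no donors shared between groups")
        pos_a = {d: i for i, d in enumerate(donors_a)}
        pos_b = {d: i for i, d in enumerate(donors_b)}
        ia = [pos_a[d] for d in common]
        ib = [pos_b[d] for d in common]

    fc = (mat[:, idx_a].mean(axis=1) + pseudocount) / (mat[:, idx_b].mean(axis=1) + pseudocount)
    pvals = np.empty(mat.shape[0])
    for gi in range(mat.shape[0]):
        if paired:
            pair_vals = np.column_stack([log_a[gi, ia], log_b[gi, ib]])
            try:
                _, p = wilcoxon_signed_rank(pair_vals, "two-sided")
            except DiffExprError:  # all differences zero: no evidence
                p = 1.0
        else:
            _, p = mann_whitney_u(log_a[gi], log_b[gi], "two-sided")
        pvals[gi] = p

    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    de = pd.DataFrame(
        {"fc": fc, "log2fc": np.log2(fc), "p": pvals, "direction": direction},
        index=counts.index,
    )
    de.index.name = "gene"
    return de


def _select_samples(meta: pd.DataFrame, query: Mapping[str, str], name: str) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    for col, val in query.items():
        if col not in meta.columns:
            raise DiffExprError(f"{name}: unknown metadata column {col!r}")
        mask &= meta[col].astype(str) == str(val)
    cols = list(meta.index[mask])
    if not cols:
        raise DiffExprError(f"contrast group {name} matches zero samples: {dict(query)}")
    return cols


@dataclass(frozen=True)
class SeedSet:
    """Genes passing the fold-change and p-value cut-offs."""

    genes: frozenset[str]
    fc_cutoff: float
    p_cutoff: float
    direction_filter: str = "both"
    n_up: int = 0
    n_down: int = 0

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise DiffExprError("fc_cutoff must exceed 1")
        if not (0 < self.p_cutoff <= 1):
            raise DiffExprError("p_cutoff must be in (0, 1]")


def select_seeds(
    de: pd.DataFrame,
    fc_cutoff: float,
    p_cutoff: float = 0.05,
    direction_filter: str = "both",
) -> SeedSet:
    """Threshold a DE table into a seed set.

    A gene passes if p <= p_cutoff and its linear fold change is >= fc_cutoff
    (up) or <= 1/fc_cutoff (down), subject to the direction filter.  Cut-offs
    are symmetric on the linear scale.
    """
    if fc_cutoff <= 1:
        raise DiffExprError("fc_cutoff must exceed 1")
    if direction_filter not in {"both", "up_only", "down_only"}:
        raise DiffExprError(f"unknown direction_filter: {direction_filter!r}")
    sig = de["p"] <= p_cutoff
    up = sig & (de["fc"] >= fc_cutoff)
    down = sig & (de["fc"] <= 1.0 / fc_cutoff)
    if direction_filter == "up_only":
        chosen = up
    elif direction_filter == "down_only":
        chosen = down
    else:
        chosen = up | down
    genes = frozenset(de.index[chosen])
    n_up, n_down = int(up.sum()), int(down.sum())
    logger.info(
        "select_seeds(fc>=%.3g, p<=%.3g, %s): %d seeds (%d up, %d down)",
        fc_cutoff, p_cutoff, direction_filter, len(genes), n_up, n_down,
    )
    return SeedSet(genes, fc_cutoff, p_cutoff, direction_filter, n_up, n_down)


def ddct_relative_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    dCt = Ct(target) - Ct(housekeeping reference) within each condition;
    ddCt = dCt(treated) - dCt(control); returns 2**-ddCt.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise DiffExprError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts TSV: first column gene, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise DiffExprError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise DiffExprError(f"{path}: missing metadata columns {missing}")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """External DE table TSV (gene, fc, log2fc, p[, adj_p]); fc or log2fc may be derived."""
    de = pd.read_csv(path, sep="\t", index_col=0)
    if "fc" not in de.columns and "log2fc" in de.columns:
        de["fc"] = 2.0 ** de["log2fc"]
    if "log2fc" not in de.columns and "fc" in de.columns:
        de["log2fc"] = np.log2(de["fc"])
    for col in ("fc", "p"):
        if col not in de.columns:
            raise DiffExprError(f"{path}: missing DE column {col!r}")
    if "direction" not in de.columns:
        de["direction"] = np.where(de["fc"] > 1, "up", np.where(de["fc"] < 1, "down", "none"))
    return de


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene", float_format="%.6E")
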