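"""Hypothesis tests and trend analyses on developmental transcriptomes.

The central test asks whether the transcriptome index in the middle
(phylotypic) period differs from the early period: the hourglass model
predicts lowest divergence in middle development, early conservation
predicts conservation that is at least as strong early on.  The statistic
is Δe–m, the difference of mean index between early and middle stages
(pre-MZT stages are excluded — they reflect the maternal transcriptome;
late stages are excluded because late divergence is high under both
models).  The null distribution comes from permuting the gene-level
parameter across genes while holding expression fixed; besides the
empirical tail probability a normal approximation of the permutation
distribution is reported.

The direction of the one-sided test depends on the parameter: for ω₀,
phyletic age and paralog number a *lower* middle index supports the
hourglass (test for large Δe–m); for protein connectivity — where high
values mean strong constraint — the sign flips.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, StageTimeline, TissuePanel
from .indexes import compute_tei
from .preprocess import ExpressionCallMatrix

__all__ = [
    "PermutationResult",
    "PleiotropyResult",
    "delta_em",
    "permutation_test",
    "pleiotropy_flags",
    "pleiotropy_profile",
    "compare_param_by_group",
    "tau",
    "retrogene_trend",
    "connectivity_duplicability",
]

DIRECTIONS = ("middle_lower", "middle_higher")


@dataclass
class PermutationResult:
    parameter_name: str
    delta_observed: float
    null_mean: float
    null_sd: float
    p_normal: float
    p_empirical: float
    direction: str
    n_perm: int
    seed: int | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "delta_observed": self.delta_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_normal": self.p_normal,
            "p_empirical": self.p_empirical,
            "direction": self.direction,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


@dataclass
class PleiotropyResult:
    """Per-stage pleiotropic-gene proportions and a chi-square GOF test.

    The null hypothesis is a stage-constant pleiotropic fraction: expected
    pleiotropic counts are proportional to each stage's expressed-gene
    total, df = S − 1.
    """

    table: pd.DataFrame  # index stage; columns n_expressed, n_pleiotropic, proportion
    chi2_statistic: float
    df: int
    p_value: float
    breadth_threshold: float


def delta_em(tei: pd.Series, timeline: StageTimeline) -> float:
    """Mean index over early stages minus mean over middle stages.

    Pre-MZT and late stages do not enter either mean.
    """
    early = timeline.stages_in("early")
    middle = timeline.stages_in("middle")
    for period, stages in (("early", early), ("middle", middle)):
        missing = [s for s in stages if s not in tei.index]
        if not stages:
            raise ValueError(f"timeline has no {period} stages")
        if missing:
            raise ValueError(f"{period} stage(s) absent from index profile: {missing}")
    return float(tei.loc[early].mean() - tei.loc[middle].mean())


def permutation_test(
    m: ExpressionMatrix,
    param: pd.Series,
    timeline: StageTimeline,
    direction: str = "middle_lower",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """One-sided early-vs-middle permutation test of the index profile.

    Parameter values are shuffled across genes (expression fixed) and Δe–m
    recomputed for each of ``n_perm`` permutations.  ``p_normal``
    approximates the permutation distribution by a normal with the
    permuted values' mean and SD; ``p_empirical`` is the add-one-corrected
    tail count.  With ``direction="middle_lower"`` (ω₀, phyletic age,
    paralogs) the tested tail is Δ ≥ Δ_obs; with ``"middle_higher"``
    (connectivity) it is Δ ≤ Δ_obs.  A permutation-invariant input
    (constant parameter) yields a degenerate null and p = 1.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)

    param = param.dropna()
    genes = m.data.index.intersection(param.index)
    if len(genes) == 0:
        raise ValueError("no gene carries both expression and the parameter")
    sub = ExpressionMatrix(data=m.data.loc[genes], scale=m.scale)
    values = param.loc[genes].to_numpy(dtype=float)

    tei_obs = compute_tei(sub, param.loc[genes])
    delta_obs = delta_em(tei_obs, timeline)

    # Δe–m is linear in the permuted parameter vector: with V the
    # column-normalized weight matrix, Δ(perm) = E_perm · v where
    # v = rowmean(V[:, early]) − rowmean(V[:, middle]).
    weights = sub.data.to_numpy(dtype=float)
    denom = weights.sum(axis=0)
    V = weights / denom
    cols = {s: j for j, s in enumerate(sub.stage_ids)}
    early_idx = [cols[s] for s in timeline.stages_in("early")]
    middle_idx = [cols[s] for s in timeline.stages_in("middle")]
    v = V[:, early_idx].mean(axis=1) - V[:, middle_idx].mean(axis=1)

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7) // max(len(genes), 1)))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        block = np.tile(values, (stop - start, 1))
        block = rng.permuted(block, axis=1)
        deltas[start:stop] = block @ v

    null_mean = float(deltas.mean())
    null_sd = float(deltas.std(ddof=1))

    if null_sd == 0.0:
        return PermutationResult(
            parameter_name=param.name or "parameter",
            delta_observed=delta_obs,
            null_mean=null_mean,
            null_sd=0.0,
            p_normal=1.0,
            p_empirical=1.0,
            direction=direction,
            n_perm=n_perm,
            seed=seed,
            degenerate=True,
        )

    z = (delta_obs - null_mean) / null_sd
    if direction == "middle_lower":
        p_normal = float(stats.norm.sf(z))
        n_extreme = int((deltas >= delta_obs).sum())
    else:
        p_normal = float(stats.norm.cdf(z))
        n_extreme = int((deltas <= delta_obs).sum())
    p_empirical = (1 + n_extreme) / (n_perm + 1)

    return PermutationResult(
        parameter_name=param.name or "parameter",
        delta_observed=delta_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        p_normal=p_normal,
        p_empirical=p_empirical,
        direction=direction,
        n_perm=n_perm,
        seed=seed,
        degenerate=False,
    )


def pleiotropy_flags(
    calls: ExpressionCallMatrix,
    breadth_threshold: float = 0.5,
    timeline: StageTimeline | None = None,
    exclude_premzt: bool = False,
) -> pd.Series:
    """Flag temporally pleiotropic genes: expressed in > threshold of stages.

    Expression breadth across development proxies the number of traits a
    gene can affect.  The comparison is strict: a gene expressed in exactly
    half the stages is not flagged at threshold 0.5.  With
    ``exclude_premzt=True`` (requires a timeline) pre-MZT stages are left
    out of both numerator and denominator.
    """
    if not (0 < breadth_threshold < 1):
        raise ValueError("breadth_threshold must be in (0, 1)")
    table = calls.calls
    if exclude_premzt:
        if timeline is None:
            raise ValueError("exclude_premzt requires a timeline")
        keep = [s for s in table.columns if timeline.period_of.get(s) != "preMZT"]
        table = table[keep]
    if table.shape[1] == 0:
        raise ValueError("no stages left to compute expression breadth")
    breadth = table.sum(axis=1) / table.shape[1]
    return (breadth > breadth_threshold).rename("is_pleiotropic")


def pleiotropy_profile(
    calls: ExpressionCallMatrix, flags: pd.Series, breadth_threshold: float = 0.5
) -> PleiotropyResult:
    """Per-stage proportion of pleiotropic genes among expressed genes.

    At each stage the numerator counts pleiotropic genes called expressed
    there and the denominator all genes called expressed there.  The
    chi-square goodness-of-fit test compares observed per-stage pleiotropic
    counts to counts proportional to per-stage expressed totals (constant
    proportion under H0), df = S − 1.
    """
    flags = flags.reindex(calls.gene_ids).fillna(False).astype(bool)
    table = calls.calls
    n_expressed = table.sum(axis=0)
    if (n_expressed == 0).any():
        empty = list(n_expressed.index[n_expressed == 0])
        raise ValueError(f"stage(s) with zero expressed genes: {empty}")
    n_pleio = table.loc[flags.to_numpy()].sum(axis=0)
    if table.shape[1] < 2:
        raise ValueError("chi-square test needs at least 2 stages (df = S-1 >= 1)")
    observed = n_pleio.to_numpy(dtype=float)
    expected = n_expressed.to_numpy(dtype=float)
    expected = expected * observed.sum() / expected.sum()
    chi2, p = stats.chisquare(observed, f_exp=expected)
    out = pd.DataFrame(
        {
            "n_expressed": n_expressed,
            "n_pleiotropic": n_pleio,
            "proportion": n_pleio / n_expressed,
        }
    )
    # rename, don't mutate: the index object is shared with the call matrix
    out.index = out.index.rename("stage")
    return PleiotropyResult(
        table=out,
        chi2_statistic=float(chi2),
        df=table.shape[1] - 1,
        p_value=float(p),
        breadth_threshold=breadth_threshold,
    )


def compare_param_by_group(param: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a parameter between two gene groups.

    Typically used to ask whether pleiotropic genes have lower ω₀ than
    non-pleiotropic genes.  Exact enumeration is used for tie-free small
    samples (< 25 per group); otherwise the normal approximation with tie
    correction.  Returns the Mann–Whitney U of the True group and the p.
    """
    joined = pd.concat({"param": param, "group": groups}, axis=1).dropna()
    a = joined.loc[joined["group"].astype(bool), "param"].to_numpy(dtype=float)
    b = joined.loc[~joined["group"].astype(bool), "param"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) < 25 and len(b) < 25 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def tau(panel: TissuePanel) -> pd.DataFrame:
    """Tissue-specificity index per gene.

    Tau = Σ_i (1 − x̂_i) / (n − 1) with x̂_i = x_i / max_i(x_i), ranging
    from 0 (uniform expression) to 1 (single-tissue expression).  Negative
    (log-scale) values are floored at 0 before computing; genes not
    expressed in any tissue (max = 0) are removed.  A gene is testis
    specific when its highest expression is in testis and Tau ≥ 0.8.
    """
    x = panel.data.to_numpy(dtype=float).copy()
    x[x < 0] = 0.0
    n = x.shape[1]
    xmax = x.max(axis=1)
    keep = xmax > 0
    x = x[keep]
    xmax = xmax[keep]
    xhat = x / xmax[:, None]
    tau_values = (1.0 - xhat).sum(axis=1) / (n - 1)
    top = np.asarray(panel.tissue_ids)[x.argmax(axis=1)]
    out = pd.DataFrame(
        {
            "tau": tau_values,
            "top_tissue": top,
            "is_testis_specific": (top == panel.testis) & (tau_values >= 0.8),
        },
        index=panel.gene_ids[keep],
    )
    out.index.name = "gene_id"
    return out


def _exact_spearman_p(x_ranks: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all orderings of y (small S only)."""
    n = len(y)
    y_ranks = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(np.corrcoef(x_ranks, y_ranks[list(perm)])[0, 1])
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def retrogene_trend(
    m: ExpressionMatrix,
    retro_flags: pd.Series,
    exclude: set[str] | pd.Index | None = None,
) -> tuple[pd.Series, float, float]:
    """Median retrogene expression per stage and its Spearman trend over development.

    Retrogenes typically lack ancestral regulatory elements; rising median
    expression toward late development supports a permissive, testis-like
    role of late stages.  Genes in *exclude* (e.g. testis-specific genes,
    whose high testis expression would confound the trend) are removed
    first.  The correlation is between stage rank (1..S) and the medians;
    p is two-sided (t-approximation, or exact over S! orderings when
    S < 5).
    """
    if m.shape[1] < 3:
        raise ValueError("retrogene trend needs at least 3 stages")
    retro_flags = retro_flags.reindex(m.data.index).fillna(False).astype(bool)
    retro_genes = m.data.index[retro_flags.to_numpy()]
    if exclude is not None:
        retro_genes = retro_genes.difference(pd.Index(exclude))
    if len(retro_genes) == 0:
        raise ValueError("no retrogenes left after exclusion")
    medians = m.data.loc[retro_genes].median(axis=0)
    s = len(medians)
    stage_rank = np.arange(1, s + 1, dtype=float)
    rho, p = stats.spearmanr(stage_rank, medians.to_numpy())
    rho = float(rho)
    if np.isnan(rho):
        # constant medians: no trend, maximally nonsignificant
        return medians, 0.0, 1.0
    if s < 5:
        p = _exact_spearman_p(stage_rank, medians.to_numpy(), rho)
    return medians, rho, float(p)


def connectivity_duplicability(
    ann: pd.DataFrame, n_bins: int = 5
) -> tuple[float, float, pd.DataFrame, bool]:
    """Spearman relation between protein connectivity and duplicability.

    Dosage-balance arguments predict that highly connected proteins
    duplicate less.  Returns (rho, p, binned trend table, undefined flag).
    The table gives the mean paralog count per connectivity quantile bin
    (default 5 bins) to expose non-monotone (rise-then-fall) shapes that a
    single rank correlation would blur.  With all connectivity values tied
    the correlation is undefined and flagged rather than reported as a
    number.
    """
    sub = ann[["connectivity", "paralog_count"]].dropna()
    if len(sub) < 10:
        raise ValueError("need at least 10 genes with both connectivity and paralog_count")
    conn = sub["connectivity"].to_numpy(dtype=float)
    para = sub["paralog_count"].to_numpy(dtype=float)
    if np.unique(conn).size == 1:
        empty = pd.DataFrame(columns=["connectivity_mean", "paralog_mean", "n_genes"])
        return float("nan"), float("nan"), empty, True
    rho, p = stats.spearmanr(conn, para)
    bins = pd.qcut(sub["connectivity"].rank(method="average"), q=n_bins, duplicates="drop")
    grouped = sub.groupby(bins, observed=True)
    table = pd.DataFrame(
        {
            "connectivity_mean": grouped["connectivity"].mean(),
            "paralog_mean": grouped["paralog_count"].mean(),
            "n_genes": grouped.size(),
        }
    ).reset_index(drop=True)
    table.index.name = "connectivity_bin"
    return float(rho), float(p), table, False
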