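"""The differential-variability screen.

Core statistic: for each probe, the ratio of the unbiased sample
variances of the young (<15 y) and old (>=15 y) groups,

    F = s2_young / s2_old,

referred to an F distribution with (n_young - 1, n_old - 1) degrees of
freedom; the one-sided upper-tail p-value tests H0: the young-group
variance is not larger.  Before testing, probes are ranked by pooled
variance across *all* samples and only the top fraction (~5% in the
original design) is retained — this pre-filter concentrates power on
genuinely variable transcripts but, with unbalanced groups, shifts the
null of downstream summary statistics (see
:func:`permutation_null_proportion`).

Multiple-testing adjustment is reported two ways: step-up
Benjamini–Hochberg ("FDR") and Storey's q-values ("pFDR") with the null
proportion estimated on a lambda grid by a cubic smoother.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .matrix import ExpressionMatrix, SampleTable

#: thresholds from the screen's published configuration
DEFAULT_TOP_FRACTION = 0.05
DEFAULT_Q_CUTOFF = 0.25


# ---------------------------------------------------------------------------
# selection

def top_variance_subset(
    matrix: ExpressionMatrix, fraction: float = DEFAULT_TOP_FRACTION, k: int | None = None
) -> list[str]:
    """Ids of the ``k = round(fraction * n_probes)`` most variable probes.

    Variance is the unbiased sample variance across all samples,
    regardless of group.  Ties at the selection boundary are broken by
    probe-id lexicographic order so the subset is deterministic.  An
    explicit ``k`` overrides the fraction (for replicating a published
    probe count).
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples to rank by variance")
    if k is None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        k = int(round(fraction * matrix.n_probes))
    if not 0 < k <= matrix.n_probes:
        raise ValueError(f"k={k} out of range for {matrix.n_probes} probes")
    var = matrix.values.var(axis=1, ddof=1)
    if float(var.max()) == 0.0:
        raise ValueError("all probes are constant; no variance ranking possible")
    order = sorted(var.index, key=lambda p: (-var[p], p))
    return order[:k]


# ---------------------------------------------------------------------------
# the F-test

def variance_ratio_ftest(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    probes: list[str] | None = None,
) -> pd.DataFrame:
    """One-sided variance-ratio F-test per probe, young vs old.

    Returns a DataFrame indexed by probe with columns ``sd_young``,
    ``sd_old``, ``var_ratio`` (= F), ``F``, ``df_num``, ``df_den``,
    ``p_one_sided`` and ``degenerate`` (True where a group variance is
    exactly zero: p=0 if only the old group is degenerate, p=1 if both).
    """
    samples = samples.align_to(matrix)
    young_ids, old_ids = samples.group_sample_ids()
    if len(young_ids) < 2 or len(old_ids) < 2:
        raise ValueError(
            f"both age groups need >= 2 samples (young={len(young_ids)}, old={len(old_ids)})"
        )
    values = matrix.values if probes is None else matrix.values.loc[probes]
    y = values[young_ids].to_numpy(dtype=float)
    o = values[old_ids].to_numpy(dtype=float)
    s2y = y.var(axis=1, ddof=1)
    s2o = o.var(axis=1, ddof=1)
    dfn, dfd = len(young_ids) - 1, len(old_ids) - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        F = s2y / s2o
    p = np.empty_like(F)
    ok = s2o > 0
    p[ok] = stats.f.sf(F[ok], dfn, dfd)
    # degenerate conventions: zero old-group variance with signal in the
    # young group is maximal evidence (p=0); both zero carries none (p=1)
    both_zero = (~ok) & (s2y == 0)
    p[~ok] = 0.0
    p[both_zero] = 1.0
    F[both_zero] = np.nan

    return pd.DataFrame(
        {
            "sd_young": np.sqrt(s2y),
            "sd_old": np.sqrt(s2o),
            "var_ratio": F,
            "F": F,
            "df_num": dfn,
            "df_den": dfd,
            "p_one_sided": p,
            "degenerate": ~ok,
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# multiple testing

def _bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def estimate_pi0(p: np.ndarray, lambda_: float | None = None) -> float:
    """Storey's estimate of the null proportion pi0.

    With ``lambda_`` given, ``pi0 = #{p > lambda} / (m (1 - lambda))``.
    Otherwise pi0(lambda) is computed on the grid {0, 0.05, ..., 0.95},
    smoothed by a cubic spline and evaluated at the largest lambda.
    The result is clamped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if lambda_ is not None:
        pi0 = (p > lambda_).sum() / (m * (1.0 - lambda_))
        return float(min(max(pi0, 1.0 / m), 1.0))
    grid = np.arange(0.0, 0.951, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    spline = interpolate.UnivariateSpline(grid, pi0_l, k=3)
    pi0 = float(spline(grid[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def adjust_fdr(
    p_values, method: str = "bh", lambda_: float | None = None
) -> np.ndarray:
    """Multiple-testing adjustment: BH step-up or Storey q-values.

    ``bh`` is the Benjamini–Hochberg step-up rule with monotonicity
    enforcement; ``storey`` multiplies the BH quantities by the
    estimated null proportion pi0 (the positive-FDR flavour), so the
    two coincide when pi0 estimates to 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return _bh(p)
    if method == "storey":
        pi0 = estimate_pi0(p, lambda_=lambda_)
        return np.minimum(pi0 * _bh(p), 1.0)
    raise ValueError(f"unknown method {method!r}; use 'bh' or 'storey'")


# ---------------------------------------------------------------------------
# paired summaries over the selected probes

def signed_rank_paired_sd(
    sd_young, sd_old, alternative: str = "greater"
) -> float:
    """Wilcoxon signed-rank p-value for paired group SDs.

    Tests whether sd_young - sd_old is shifted above zero (default) or
    away from it.  Zero differences are dropped; tied absolute
    differences receive average ranks.  The exact null distribution is
    used for <= 25 nonzero untied pairs, otherwise the normal
    approximation with continuity and tie corrections.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    d = np.asarray(sd_young, dtype=float) - np.asarray(sd_old, dtype=float)
    if len(np.asarray(sd_young)) != len(np.asarray(sd_old)):
        raise ValueError("paired lists must have equal length")
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    alt = "greater" if alternative == "greater" else "two-sided"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=True, alternative=alt, method=method
    )
    return float(res.pvalue)


def proportion_sd_greater(sd_young, sd_old) -> float:
    """Fraction of probes with strictly larger SD in the young group."""
    y = np.asarray(sd_young, dtype=float)
    o = np.asarray(sd_old, dtype=float)
    if y.shape != o.shape or y.size == 0:
        raise ValueError("paired lists must be nonempty and equal length")
    return float(np.mean(y > o))


# ---------------------------------------------------------------------------
# whole screen

def run_variance_screen(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    fraction: float = DEFAULT_TOP_FRACTION,
    k: int | None = None,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """Select the most variable probes and test them for larger young-group variance.

    Returns one row per probe in the matrix with the F-test columns (all
    probes), ``selected_top_variance`` flags for the top-variance
    subset, ``q_bh`` / ``q_pfdr`` computed *within the selected subset*
    (NaN elsewhere, mirroring a design that only carries the selected
    probes forward), and ``significant`` = selected & q < ``q_cutoff``
    on the configured FDR flavour.
    """
    selected = top_variance_subset(matrix, fraction=fraction, k=k)
    res = variance_ratio_ftest(matrix, samples)
    res["selected_top_variance"] = res.index.isin(selected)
    res["q_bh"] = np.nan
    res["q_pfdr"] = np.nan
    sel_p = res.loc[selected, "p_one_sided"].to_numpy()
    res.loc[selected, "q_bh"] = adjust_fdr(sel_p, method="bh")
    res.loc[selected, "q_pfdr"] = adjust_fdr(sel_p, method="storey")
    q_col = "q_pfdr" if fdr_method == "storey" else "q_bh"
    res["significant"] = res["selected_top_variance"] & (res[q_col] < q_cutoff)
    return res


def screen_summary(result: pd.DataFrame, q_cutoff: float = DEFAULT_Q_CUTOFF) -> dict:
    """Headline numbers of a screen result (selected probes only)."""
    sel = result[result["selected_top_variance"]]
    return {
        "n_probes_tested": int(len(result)),
        "n_selected": int(len(sel)),
        "proportion_sd_greater": proportion_sd_greater(sel["sd_young"], sel["sd_old"]),
        "signed_rank_p": signed_rank_paired_sd(sel["sd_young"], sel["sd_old"]),
        "n_significant_pfdr": int((sel["q_pfdr"] < q_cutoff).sum()),
        "n_significant_bh_0.1": int((sel["q_bh"] < 0.1).sum()),
        "q_cutoff": q_cutoff,
    }


# ---------------------------------------------------------------------------
# selection-bias diagnostic

@dataclass(frozen=True)
class PermutationNull:
    """Null distribution of the proportion-greater statistic."""

    null_proportions: np.ndarray
    observed: float
    p_empirical: float


def permutation_null_proportion(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    fraction: float = DEFAULT_TOP_FRACTION,
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationNull:
    """Permutation null of the fraction of probes with larger young SD.

    Age-group labels are permuted across samples; per permutation the
    top-variance subset is (re)taken and the proportion of selected
    probes with sd_young > sd_old recorded.  Because pooled variance
    ignores labels, the selected subset is permutation-invariant and is
    computed once.  With unbalanced groups the pre-filter drags this
    null above 0.5 — the larger group dominates pooled variance, so
    top-variance probes tend to be the ones whose larger-group variance
    ran high.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    selected = top_variance_subset(matrix, fraction=fraction)
    X = matrix.values.loc[selected].to_numpy(dtype=float)
    groups = (samples.align_to(matrix).age_group == "young").to_numpy()
    n_young = int(groups.sum())
    obs_res = variance_ratio_ftest(matrix, samples, probes=selected)
    observed = proportion_sd_greater(obs_res["sd_young"], obs_res["sd_old"])

    null = np.empty(n_perm)
    n = X.shape[1]
    for b in range(n_perm):
        perm = rng.permutation(n)
        yc = perm[:n_young]
        oc = perm[n_young:]
        s2y = X[:, yc].var(axis=1, ddof=1)
        s2o = X[:, oc].var(axis=1, ddof=1)
        null[b] = np.mean(s2y > s2o)
    p_emp = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationNull(null_proportions=null, observed=observed, p_empirical=p_emp)
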