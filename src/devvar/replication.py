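"""Cross-dataset and cross-platform corroboration.

Three independent checks of a variance screen: (a) rerunning the screen
on an external, already-preprocessed study (postmortem rather than
surgical tissue, possibly a different array platform) and comparing the
significant-set overlap with chance; (b) Fisher's exact test on 2x2
classifications such as the mouse-phenotype under-representation; and
(c) correlating microarray log2 intensities with qPCR -dCt values gene
by gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, SampleTable
from .variance import (
    DEFAULT_Q_CUTOFF,
    DEFAULT_TOP_FRACTION,
    run_variance_screen,
    screen_summary,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    observed: int
    expected: float
    fold: float


def expected_overlap(set_a, set_b, universe_size: int) -> OverlapResult:
    """Observed |A ∩ B| against the chance expectation |A||B|/N."""
    a, b = set(set_a), set(set_b)
    if universe_size == 0:
        raise ValueError("universe_size must be positive")
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    observed = len(a & b)
    expected = len(a) * len(b) / universe_size
    fold = observed / expected if expected > 0 else float("nan")
    return OverlapResult(observed=observed, expected=expected, fold=fold)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows in/out of the focal set, columns with/without the property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table needs at least one positive margin")

    @classmethod
    def from_margins(
        cls, k_focal: int, n_focal: int, k_rest: int, n_rest: int
    ) -> "ContingencyTable2x2":
        """Build from 'k of n' phrasing for the focal and comparison groups."""
        return cls(a=k_focal, b=n_focal - k_focal, c=k_rest, d=n_rest - k_rest)


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float
    odds_ratio_defined: bool


def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: str = "two_sided"
) -> FisherResult:
    """Fisher's exact test with the point-probability two-sided rule.

    Two-sided p sums the probabilities of all tables (on the fixed
    margins) no more likely than the observed one.  The odds ratio is
    the sample ad/bc; with a zero cell it is 0 or infinite and flagged
    undefined when 0/0.
    """
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(
        alternative
    )
    if alt is None:
        raise ValueError("alternative must be two_sided, less or greater")
    arr = np.array([[table.a, table.b], [table.c, table.d]])
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return FisherResult(p=1.0, odds_ratio=float("nan"), odds_ratio_defined=False)
    _, p = stats.fisher_exact(arr, alternative=alt)
    num, den = table.a * table.d, table.b * table.c
    if den == 0:
        oratio = float("inf") if num > 0 else float("nan")
        return FisherResult(p=float(p), odds_ratio=oratio, odds_ratio_defined=False)
    return FisherResult(p=float(p), odds_ratio=num / den, odds_ratio_defined=True)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    significant: bool


def correlate_platforms(
    values_a, values_b, method: str = "spearman", alpha: float = 0.05
) -> CorrelationResult:
    """Correlate paired per-sample measurements from two platforms.

    Spearman rank correlation by default (qPCR -dCt against microarray
    log2 signal need only be monotone); Pearson available.  Significant
    when p < ``alpha`` (0.05 by convention).
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-d arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 paired samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return CorrelationResult(rho=float(rho), p=float(p), significant=bool(p < alpha))


def replicate_screen(
    external_matrix: ExpressionMatrix,
    external_samples: SampleTable,
    fraction: float = DEFAULT_TOP_FRACTION,
    k: int | None = None,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> dict:
    """Rerun the variance screen on an external, preprocessed study.

    The sex-adjustment step is skipped (external datasets often lack
    sex annotation); the matrix must already be on the log2 scale.
    Returns the summary dict plus the per-probe table under ``"table"``
    and the significant probe ids under ``"significant_probes"`` for
    intersection with the primary study.
    """
    if external_matrix.scale != "log2":
        raise ValueError("external matrix must be preprocessed to log2 scale")
    if external_samples.data["age_years"].isna().any():
        raise ValueError("external samples are missing age values")
    log.info("replication screen: sex adjustment step skipped")
    table = run_variance_screen(
        external_matrix, external_samples, fraction=fraction, k=k, q_cutoff=q_cutoff
    )
    summary = screen_summary(table, q_cutoff=q_cutoff)
    summary["sex_adjustment"] = "skipped"
    return {
        "summary": summary,
        "table": table,
        "significant_probes": list(table.index[table["significant"]]),
    }
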