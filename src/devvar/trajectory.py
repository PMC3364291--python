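"""Developmental-trajectory exclusion: quadratic age regression per probe.

A gene that merely follows a developmental trajectory (mean changing
with age) would also look more variable in a wide young age range; the
screen therefore refits each candidate with a quadratic age model,

    full:    y ~ 1 + age + age^2 + sex + delay
    reduced: y ~ 1 + sex + delay

and tests the two age terms jointly with a nested-model F-test,

    F = ((SSE_red - SSE_full) / 2) / (SSE_full / df_resid),

referred to F(2, df_resid).  Age is centered before squaring (the F is
invariant to affine re-coding of age either way; centering just keeps
the normal equations well-conditioned).  Candidates with small q-values
here are flagged as developmentally regulated rather than
differentially variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import SampleTable, ExpressionMatrix
from .variance import adjust_fdr

log = logging.getLogger(__name__)

_REL_TOL = 1e-12


def _design_matrices(samples: SampleTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full and reduced design matrices plus full-model column names.

    Nuisance covariates (sex, delay) that are constant in the study carry
    no information and are dropped from both models; a constant age is a
    hard error because the tested terms themselves vanish.
    """
    meta = samples.data
    n = len(meta)
    age = meta["age_years"].to_numpy(dtype=float)
    age_c = age - age.mean()
    if np.ptp(age) == 0:
        raise ValueError("design is rank deficient: column 'age' is constant")
    sex = (meta["sex"].astype(str) == "male").to_numpy(dtype=float)
    delay_raw = meta["dev_delay"]
    if delay_raw.isna().any():
        log.warning(
            "dev_delay missing for %d samples; imputing as False", int(delay_raw.isna().sum())
        )
    delay = delay_raw.fillna(False).astype(bool).to_numpy(dtype=float)

    nuisance, names = [], []
    if np.ptp(sex) > 0:
        nuisance.append(sex)
        names.append("sex")
    if np.ptp(delay) > 0:
        nuisance.append(delay)
        names.append("delay")
    reduced = np.column_stack([np.ones(n)] + nuisance)
    full = np.column_stack([np.ones(n), age_c, age_c**2] + nuisance)
    full_names = ["intercept", "age", "age2"] + names

    if np.linalg.matrix_rank(full) < full.shape[1]:
        # name the first column that adds no rank
        for j in range(1, full.shape[1]):
            if np.linalg.matrix_rank(full[:, : j + 1]) == np.linalg.matrix_rank(
                full[:, :j]
            ):
                raise ValueError(
                    f"design is rank deficient: column {full_names[j]!r} is collinear"
                )
    return full, reduced, full_names


@dataclass(frozen=True)
class TrajectoryResult:
    """Joint age F-test for one probe."""

    coefficients: dict[str, float]
    F: float
    df_num: int
    df_den: int
    p: float


def quadratic_age_ftest(expression, samples: SampleTable) -> TrajectoryResult:
    """Nested-model F-test of the joint age terms for one probe."""
    y = np.asarray(expression, dtype=float)
    n = len(samples.data)
    if len(y) != n:
        raise ValueError("expression length does not match sample table")
    if n < 6:
        raise ValueError("need at least 6 samples for the quadratic age model")
    full, reduced, names = _design_matrices(samples)
    table = _fit_many(y[None, :], full, reduced)
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    row = table.iloc[0]
    return TrajectoryResult(
        coefficients=dict(zip(names, beta)),
        F=float(row["F_age"]),
        df_num=int(row["df_num"]),
        df_den=int(row["df_den"]),
        p=float(row["p_age"]),
    )


def _residual_basis(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q


def _fit_many(Y: np.ndarray, full: np.ndarray, reduced: np.ndarray) -> pd.DataFrame:
    """Vectorized nested F-test for a probes x samples matrix."""
    n = Y.shape[1]
    qf = _residual_basis(full)
    qr = _residual_basis(reduced)
    res_f = Y - (Y @ qf) @ qf.T
    res_r = Y - (Y @ qr) @ qr.T
    sse_f = np.einsum("ij,ij->i", res_f, res_f)
    sse_r = np.einsum("ij,ij->i", res_r, res_r)
    df_num = full.shape[1] - reduced.shape[1]  # the two age terms
    df_den = n - full.shape[1]
    scale = np.maximum(1.0, np.einsum("ij,ij->i", Y, Y))
    num = np.maximum(sse_r - sse_f, 0.0) / df_num

    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / (sse_f / df_den)
    p = stats.f.sf(F, df_num, df_den)
    # degenerate conventions: a perfect reduced fit means no age signal
    # (p=1); a perfect full fit with reduced misfit is maximal evidence
    red_perfect = sse_r <= _REL_TOL * scale
    full_perfect = sse_f <= _REL_TOL * scale
    p = np.where(full_perfect & ~red_perfect, 0.0, p)
    F = np.where(full_perfect & ~red_perfect, np.inf, F)
    p = np.where(red_perfect, 1.0, p)
    F = np.where(red_perfect, 0.0, F)
    return pd.DataFrame(
        {"F_age": F, "df_num": df_num, "df_den": df_den, "p_age": p}
    )


def screen_age_regulated(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    probes: list[str] | None = None,
    q_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Quadratic age F-test over a probe list with pFDR flags.

    Returns a DataFrame indexed by probe with the joint-age F statistic,
    p-value, Storey q (``q_pfdr``), BH q (``q_bh``) and the boolean
    ``developmentally_regulated`` flag at ``q_pfdr < q_cutoff``.
    """
    samples = samples.align_to(matrix)
    if probes is None:
        probes = matrix.probe_ids
    if len(probes) == 0:
        return pd.DataFrame(
            columns=["F_age", "df_num", "df_den", "p_age", "q_pfdr", "q_bh",
                     "developmentally_regulated"]
        )
    missing = [p for p in probes if p not in matrix.values.index]
    if missing:
        raise KeyError(f"probes not in matrix: {missing[:5]}")
    full, reduced, _ = _design_matrices(samples)
    Y = matrix.values.loc[probes].to_numpy(dtype=float)
    table = _fit_many(Y, full, reduced)
    table.index = pd.Index(probes, name="probe_id")
    table["q_pfdr"] = adjust_fdr(table["p_age"], method="storey")
    table["q_bh"] = adjust_fdr(table["p_age"], method="bh")
    table["developmentally_regulated"] = table["q_pfdr"] < q_cutoff
    return table
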