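"""Preprocessing: raw intensities to the analysis-ready log2 matrix.

Pipeline order (enforced downstream, recorded in provenance):

1. :func:`filter_by_detection` — keep probes detected in enough unique
   subjects;
2. :func:`offset_and_log2` — global additive offset so the smallest
   intensity is exactly 1.0, then log2;
3. :func:`quantile_normalize` — force every column onto the common
   reference distribution (Bolstad row-mean-of-sorted procedure);
4. :func:`average_technical_replicates` — collapse duplicate arrays to
   one column per subject;
5. :func:`adjust_group_means` — subtract per-level means of a covariate
   (the sex adjustment) from every probe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleTable

log = logging.getLogger(__name__)


def filter_by_detection(
    matrix: ExpressionMatrix,
    p_threshold: float,
    min_individuals: int,
    samples: SampleTable,
    vote: str = "any",
) -> ExpressionMatrix:
    """Keep probes detected (p <= threshold) in enough unique subjects.

    A subject with replicate arrays counts as detected if *any* of its
    arrays is detected (``vote="any"``, the default) or only if *all*
    are (``vote="all"``).
    """
    if matrix.detection_p is None:
        raise ValueError(
            "matrix has no detection p-values; skip the detection-filter stage"
        )
    if vote not in ("any", "all"):
        raise ValueError("vote must be 'any' or 'all'")
    samples = samples.align_to(matrix)
    if min_individuals > samples.n_subjects:
        raise ValueError(
            f"min_individuals={min_individuals} exceeds the "
            f"{samples.n_subjects} unique subjects"
        )
    detected = matrix.detection_p.to_numpy() <= p_threshold
    subj = samples.data["subject_id"].to_numpy()
    per_subject = []
    for s in pd.unique(subj):
        cols = np.flatnonzero(subj == s)
        agg = detected[:, cols].any(axis=1) if vote == "any" else detected[:, cols].all(
            axis=1
        )
        per_subject.append(agg)
    n_detected = np.sum(per_subject, axis=0)
    keep = n_detected >= min_individuals
    log.info(
        "detection filter: %d of %d probes retained (p<=%g in >=%d subjects, %s-replicate rule)",
        int(keep.sum()),
        matrix.n_probes,
        p_threshold,
        min_individuals,
        vote,
    )
    return matrix.evolve(
        matrix.values.loc[keep],
        f"detection_filter(p<={p_threshold}, min_individuals={min_individuals}, vote={vote})",
        detection_p=matrix.detection_p.loc[keep],
    )


def offset_and_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Add a single global constant so the minimum equals 1.0, then log2.

    The constant is ``1 - min(values)`` over the whole matrix (it may be
    negative if the minimum exceeds 1).  The minimum of the output is
    exactly 0.
    """
    if matrix.scale != "raw":
        raise ValueError("offset_and_log2 expects a raw-scale matrix")
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    c = 1.0 - float(matrix.values.to_numpy().min())
    out = np.log2(matrix.values.to_numpy() + c)
    return matrix.evolve(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        f"offset_and_log2(c={c:g})",
        keep_detection=True,
        scale="log2",
    )


def _qn_column(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    # map sorted positions to reference quantiles, then average over ties
    srt = np.argsort(col, kind="stable")
    vals = np.empty_like(ref)
    vals[srt] = ref
    _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
    sums = np.bincount(inv, weights=vals)
    return (sums / counts)[inv]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization with the average-rank tie rule.

    The reference distribution is the vector of row means of the
    column-sorted matrix.  Each column is replaced by the reference
    values at its ranks; tied values within a column all receive the
    mean of the reference values at their tied ranks, so the map is a
    function of the value.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; imputation is out of scope")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.column_stack([_qn_column(X[:, j], ref) for j in range(X.shape[1])])
    return matrix.evolve(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "quantile_normalize",
        keep_detection=True,
    )


def average_technical_replicates(
    matrix: ExpressionMatrix, samples: SampleTable
) -> tuple[ExpressionMatrix, SampleTable]:
    """Collapse replicate arrays to one column per subject (arithmetic mean).

    Covariates must agree across a subject's replicates; the collapsed
    sample table is keyed by subject id.
    """
    samples = samples.align_to(matrix)
    meta = samples.data
    covars = ["age_years", "sex", "dev_delay", "region"]
    for subject, grp in meta.groupby("subject_id", sort=False):
        if len(grp) > 1 and (grp[covars].nunique() > 1).any():
            bad = grp[covars].columns[(grp[covars].nunique() > 1)].tolist()
            raise ValueError(
                f"subject {subject!r} has conflicting covariates across replicates: {bad}"
            )
    subj_order = list(pd.unique(meta["subject_id"]))
    collapsed = pd.DataFrame(
        {
            s: matrix.values.loc[:, meta.index[meta["subject_id"] == s]].mean(axis=1)
            for s in subj_order
        }
    )
    new_meta = (
        meta.drop_duplicates("subject_id").set_index("subject_id", drop=False).loc[
            subj_order
        ]
    )
    new_meta.index = pd.Index(subj_order, name="sample_id")
    out_matrix = matrix.evolve(collapsed, "average_technical_replicates")
    return out_matrix, SampleTable(new_meta, age_cutoff=samples.age_cutoff)


def adjust_group_means(
    matrix: ExpressionMatrix, samples: SampleTable, factor: str = "sex"
) -> ExpressionMatrix:
    """Center every probe within each level of ``factor``.

    For the sex adjustment this subtracts the male mean from male
    samples and the female mean from female samples, probe by probe;
    afterwards every level's per-probe mean is exactly 0.  A level of
    "unknown" is treated as its own level, so an all-unknown table
    degrades to overall-mean centering.
    """
    samples = samples.align_to(matrix)
    if factor not in samples.data.columns:
        raise ValueError(f"unknown covariate {factor!r}")
    levels = samples.data[factor]
    X = matrix.values.to_numpy(dtype=float).copy()
    for lev in pd.unique(levels):
        cols = np.flatnonzero((levels == lev).to_numpy())
        X[:, cols] -= X[:, cols].mean(axis=1, keepdims=True)
    return matrix.evolve(
        pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns),
        f"adjust_group_means(factor={factor})",
    )
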