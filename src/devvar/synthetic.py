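"""Synthetic expression studies with known ground truth.

The generator emulates the design of a two-age-group brain expression
study: 29 young (<15 y) and 8 old (>=15 y) subjects, three of them
arrayed in technical duplicate (40 arrays for 37 biological samples),
~20,000 detected probes, and planted gene classes:

``null``
    equal variance in both age groups, no age or sex structure;
``dv``
    differential variability — the young-group residual SD is
    ``sd_ratio`` times the old-group SD;
``dev``
    developmentally regulated — a quadratic trajectory of the mean with
    age;
``sex``
    an additive sex effect on the mean.

Per-probe log2 signal for subject *i*:

    x_gi = mu_g + beta_sex_g * male_i + gamma1_g * a_i + gamma2_g * a_i^2
           + eps_gi,        eps_gi ~ Normal(0, sigma_{g, group(i)})

Raw intensity is ``2**x`` plus a small half-normal background, so raw
values can dip below 1 and exercise the offset step of preprocessing.

All randomness flows through one :func:`numpy.random.default_rng` stream
with a fixed draw order (probe parameters, then subject covariates, then
noise, then technical replication, then detection p-values, then
background), so a seed fully determines the study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCollection
from .matrix import ExpressionMatrix, SampleTable


class DegenerateVarianceWarning(UserWarning):
    """Raised when simulated probes have zero variance across arrays."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic study.

    Defaults mirror the study design the screen was built for: 29 young
    and 8 old subjects, 3 subjects in technical duplicate, 5% of genes
    differentially variable with a young/old SD ratio of 3, small
    fractions of developmentally regulated and sex-affected genes, and
    a residual (adult) SD of 0.25 on the log2 scale.
    """

    n_probes: int = 20000
    n_young: int = 29
    n_old: int = 8
    n_duplicated_subjects: int = 3
    age_range_young: tuple[float, float] = (0.5, 14.5)
    age_range_old: tuple[float, float] = (15.0, 53.0)
    frac_dv: float = 0.05
    #: young/old residual SD ratio per DV gene; a scalar or a (lo, hi)
    #: interval sampled uniformly per gene.  Must be >= 1.
    sd_ratio: float | tuple[float, float] = 3.0
    frac_dev: float = 0.02
    frac_sex: float = 0.02
    base_sd: float = 0.25
    technical_sd: float = 0.10
    mu_mean: float = 7.0
    mu_sd: float = 2.0
    background_scale: float = 0.5
    #: fraction of probes that are unexpressed: their detection p-values
    #: are Uniform(0,1) instead of Uniform(0, detected_p_max).
    frac_undetected: float = 0.10
    detected_p_max: float = 0.05
    prob_male: float = 0.5
    prob_delay: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_young", "n_old"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_duplicated_subjects < 0:
            raise ValueError("n_duplicated_subjects must be >= 0")
        if self.n_duplicated_subjects > self.n_young + self.n_old:
            raise ValueError("cannot duplicate more subjects than exist")
        fracs = (self.frac_dv, self.frac_dev, self.frac_sex)
        if any(not 0 <= f <= 1 for f in fracs) or not 0 <= self.frac_undetected <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("class fractions must sum to at most 1")
        lo, hi = self._sd_ratio_interval()
        if lo < 1:
            raise ValueError("sd_ratio must be >= 1 (young at least as variable)")
        if hi < lo:
            raise ValueError("sd_ratio interval must be (lo, hi) with lo <= hi")
        for name in ("base_sd", "technical_sd", "background_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def _sd_ratio_interval(self) -> tuple[float, float]:
        if isinstance(self.sd_ratio, (tuple, list)):
            return float(self.sd_ratio[0]), float(self.sd_ratio[1])
        return float(self.sd_ratio), float(self.sd_ratio)


@dataclass(frozen=True)
class TruthTable:
    """Per-gene generative parameters; the oracle for recovery tests.

    ``data`` is indexed by probe id with columns ``gene_id``, ``label``
    (null/dv/dev/sex), ``mu``, ``sd_young``, ``sd_old``, ``beta_sex``,
    ``gamma1``, ``gamma2``, ``expressed``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        null = d["label"] == "null"
        if null.any():
            ratio = d.loc[null, "sd_young"] / d.loc[null, "sd_old"]
            if not np.allclose(ratio[np.isfinite(ratio)], 1.0):
                raise ValueError("null genes must have equal group SDs")
        nondev = ~d["label"].str.contains("dev")
        if (d.loc[nondev, ["gamma1", "gamma2"]].to_numpy() != 0).any():
            raise ValueError("age coefficients must be zero outside the dev class")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def probes_of_class(self, label: str) -> list[str]:
        return list(self.data.index[self.data["label"] == label])

    def genes_of_class(self, label: str) -> list[str]:
        return list(self.data.loc[self.data["label"] == label, "gene_id"])

    @property
    def probe_gene_map(self) -> pd.Series:
        return self.data["gene_id"]


def simulate_expression_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, TruthTable]:
    """Simulate a raw-intensity study bundle.

    Returns the raw probe × array expression matrix (with detection
    p-values), the per-array sample table, and the ground-truth table.
    Deterministic given ``config.seed``.
    """
    cfg = config
    if cfg.n_young == 0 or cfg.n_old == 0:
        raise ValueError("both age groups need at least one subject")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_probes

    # 1. probe parameters -------------------------------------------------
    mu = rng.normal(cfg.mu_mean, cfg.mu_sd, size=m)
    labels = np.array(["null"] * m, dtype=object)
    n_dv = int(round(cfg.frac_dv * m))
    n_dev = int(round(cfg.frac_dev * m))
    n_sex = int(round(cfg.frac_sex * m))
    order = rng.permutation(m)
    labels[order[:n_dv]] = "dv"
    labels[order[n_dv : n_dv + n_dev]] = "dev"
    labels[order[n_dv + n_dev : n_dv + n_dev + n_sex]] = "sex"

    lo, hi = cfg._sd_ratio_interval()
    ratios = np.ones(m)
    ratios[labels == "dv"] = rng.uniform(lo, hi, size=n_dv) if hi > lo else lo
    sd_old = np.full(m, cfg.base_sd)
    sd_young = sd_old * ratios

    beta_sex = np.zeros(m)
    beta_sex[labels == "sex"] = rng.uniform(0.3, 0.8, size=n_sex) * rng.choice(
        [-1.0, 1.0], size=n_sex
    )
    # quadratic trajectories with ~0.5-1.5 log2-unit amplitude over the
    # age range; sign random
    gamma1 = np.zeros(m)
    gamma2 = np.zeros(m)
    dev_idx = np.flatnonzero(labels == "dev")
    gamma1[dev_idx] = rng.uniform(-0.02, 0.02, size=n_dev)
    gamma2[dev_idx] = rng.uniform(0.0005, 0.0015, size=n_dev) * rng.choice(
        [-1.0, 1.0], size=n_dev
    )
    expressed = rng.random(m) >= cfg.frac_undetected

    # 2. subject covariates -----------------------------------------------
    n_subj = cfg.n_young + cfg.n_old
    subj_ids = [f"S{i + 1:03d}" for i in range(n_subj)]
    ages = np.concatenate(
        [
            rng.uniform(*cfg.age_range_young, size=cfg.n_young),
            rng.uniform(*cfg.age_range_old, size=cfg.n_old),
        ]
    )
    male = rng.random(n_subj) < cfg.prob_male
    delay = rng.random(n_subj) < cfg.prob_delay
    region = rng.choice(["temporal", "frontal"], size=n_subj, p=[0.85, 0.15])
    dup_subjects = set(
        rng.choice(n_subj, size=cfg.n_duplicated_subjects, replace=False).tolist()
    )

    # 3. subject-level biological signal ----------------------------------
    young_mask = np.arange(n_subj) < cfg.n_young
    sigma = np.where(
        young_mask[None, :], sd_young[:, None], sd_old[:, None]
    )  # m x n_subj
    eps = rng.normal(0.0, 1.0, size=(m, n_subj)) * sigma
    x_subj = (
        mu[:, None]
        + beta_sex[:, None] * male[None, :].astype(float)
        + gamma1[:, None] * ages[None, :]
        + gamma2[:, None] * ages[None, :] ** 2
        + eps
    )

    # 4. arrays: duplicated subjects contribute two columns, each with its
    # own technical noise draw
    array_subj: list[int] = []
    array_ids: list[str] = []
    for i, sid in enumerate(subj_ids):
        if i in dup_subjects:
            array_subj += [i, i]
            array_ids += [f"{sid}.1", f"{sid}.2"]
        else:
            array_subj.append(i)
            array_ids.append(sid)
    n_arrays = len(array_ids)
    tech = (
        rng.normal(0.0, cfg.technical_sd, size=(m, n_arrays))
        if cfg.technical_sd > 0
        else np.zeros((m, n_arrays))
    )
    x = x_subj[:, array_subj] + tech

    # 5. detection p-values ------------------------------------------------
    u = rng.random((m, n_arrays))
    detection = np.where(expressed[:, None], u * cfg.detected_p_max, u)

    # 6. raw intensity with half-normal background
    background = (
        np.abs(rng.normal(0.0, cfg.background_scale, size=(m, n_arrays)))
        if cfg.background_scale > 0
        else np.zeros((m, n_arrays))
    )
    raw = np.exp2(x) + background

    probe_ids = [f"P{i:05d}" for i in range(m)]
    gene_ids = [f"G{i:05d}" for i in range(m)]
    values = pd.DataFrame(raw, index=probe_ids, columns=array_ids)
    detection_df = pd.DataFrame(detection, index=probe_ids, columns=array_ids)
    if (values.std(axis=1, ddof=1) == 0).any():
        warnings.warn(
            "simulated matrix contains zero-variance probes",
            DegenerateVarianceWarning,
            stacklevel=2,
        )

    samples = SampleTable(
        pd.DataFrame(
            {
                "subject_id": [subj_ids[i] for i in array_subj],
                "age_years": ages[array_subj],
                "sex": np.where(male[array_subj], "male", "female"),
                "dev_delay": delay[array_subj],
                "region": region[array_subj],
            },
            index=pd.Index(array_ids, name="sample_id"),
        )
    )
    truth = TruthTable(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "label": labels,
                "mu": mu,
                "sd_young": sd_young,
                "sd_old": sd_old,
                "beta_sex": beta_sex,
                "gamma1": gamma1,
                "gamma2": gamma2,
                "expressed": expressed,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )
    matrix = ExpressionMatrix(
        values=values,
        detection_p=detection_df,
        scale="raw",
        provenance=(f"simulated(seed={cfg.seed})",),
    )
    return matrix, samples, truth


def simulate_gene_sets(
    truth: TruthTable,
    n_terms: int,
    planted_odds_ratio: float = 1.0,
    term_size: tuple[int, int] = (20, 100),
    seed: int = 0,
) -> GeneSetCollection:
    """Annotation terms over the truth-table genes, one enriched for DV.

    The first term ("planted") samples members without replacement with
    weight ``planted_odds_ratio`` on DV-class genes and 1 elsewhere, so
    at odds ratio 1 membership is independent of class.  Remaining terms
    sample uniformly.  Term sizes are uniform integers in ``term_size``.
    """
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    genes = np.array(truth.gene_ids)
    if n_terms == 0:
        return GeneSetCollection({})
    if len(genes) == 0:
        raise ValueError("truth table is empty")
    lo, hi = int(term_size[0]), int(term_size[1])
    if lo > len(genes):
        raise ValueError(
            f"term_size lower bound {lo} exceeds number of genes {len(genes)}"
        )
    hi = min(hi, len(genes))
    rng = np.random.default_rng(seed)
    is_dv = truth.data["label"].to_numpy() == "dv"
    weights = np.where(is_dv, float(planted_odds_ratio), 1.0)
    weights = weights / weights.sum()

    terms: dict[str, GeneSet] = {}
    for t in range(n_terms):
        k = int(rng.integers(lo, hi + 1))
        p = weights if t == 0 else None
        members = rng.choice(genes, size=k, replace=False, p=p)
        term_id = "T0000_planted" if t == 0 else f"T{t:04d}"
        name = "planted differential-variability term" if t == 0 else f"random term {t}"
        terms[term_id] = GeneSet(
            term_id=term_id, name=name, namespace="BP", genes=frozenset(members)
        )
    return GeneSetCollection(terms)


def simulate_qpcr_panel(
    matrix: ExpressionMatrix,
    genes: list[str],
    noise_sd: float = 0.5,
    seed: int = 0,
    intercept: float = -5.0,
    slope: float = 1.0,
) -> pd.DataFrame:
    """Per-sample qPCR −ΔCt values for a panel of genes.

    −ΔCt is defined as Ct_reference − Ct_target, so it increases with
    target expression; here it is an affine function of the log2
    microarray signal plus Normal(0, noise_sd) measurement noise:

        −ΔCt = intercept + slope * log2_expression + noise,   slope > 0

    Returns a gene × sample DataFrame.
    """
    if matrix.scale != "log2":
        raise ValueError("qPCR panel is simulated from a log2-scale matrix")
    if slope <= 0:
        raise ValueError("slope must be positive: −ΔCt rises with expression")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    rng = np.random.default_rng(seed)
    expr = matrix.values.loc[genes]
    noise = rng.normal(0.0, noise_sd, size=expr.shape) if noise_sd > 0 else 0.0
    return intercept + slope * expr + noise
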