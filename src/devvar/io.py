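"""File formats and study configuration.

Plain-text formats throughout: probes x samples expression and
detection-p matrices as TSV (first column probe id, header of sample
ids), sample metadata as TSV keyed by sample_id, gene sets as GMT,
probe-to-gene map as 2-column TSV, results as CSV/JSON.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import GeneSetCollection
from .matrix import ExpressionMatrix, SampleTable, ShapeMismatchError
from .synthetic import SimulationConfig, TruthTable


class NonNumericError(ValueError):
    """Expression cells that fail to parse as numbers."""


# ---------------------------------------------------------------------------
# matrices and metadata


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise NonNumericError(f"{path}: non-numeric cells in columns {bad[:5]}")
    return df


def read_expression_matrix(
    expression_path, detection_p_path=None, scale: str = "raw"
) -> ExpressionMatrix:
    values = read_matrix_tsv(expression_path)
    detection = None
    if detection_p_path is not None:
        detection = read_matrix_tsv(detection_p_path)
        if detection.shape != values.shape:
            raise ShapeMismatchError(
                f"detection matrix {detection.shape} does not match expression {values.shape}"
            )
        detection = detection.reindex(index=values.index, columns=values.columns)
    return ExpressionMatrix(values=values, detection_p=detection, scale=scale)


def write_metadata_tsv(samples: SampleTable, path) -> None:
    samples.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path, age_cutoff: float = 15.0) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "dev_delay" in df.columns:
        df["dev_delay"] = df["dev_delay"].astype(bool)
    return SampleTable(df, age_cutoff=age_cutoff)


def read_probe_gene_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: probe-gene map must have exactly 2 columns")
    s = pd.Series(df[1].to_numpy(), index=df[0].to_numpy(), name="gene_id")
    s.index.name = "probe_id"
    return s


def write_probe_gene_map(mapping: pd.Series, path) -> None:
    mapping.to_csv(path, sep="\t", header=False)


def write_study_bundle(
    out_dir,
    matrix: ExpressionMatrix,
    samples: SampleTable,
    truth: TruthTable | None = None,
    gene_sets: GeneSetCollection | None = None,
    probe_gene_map: pd.Series | None = None,
) -> dict[str, Path]:
    """Write the standard study bundle; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expression.tsv", "metadata": out / "metadata.tsv"}
    write_expression_tsv(matrix.values, paths["expression"])
    write_metadata_tsv(samples, paths["metadata"])
    if matrix.detection_p is not None:
        paths["detection_p"] = out / "detection_p.tsv"
        write_expression_tsv(matrix.detection_p, paths["detection_p"])
    if truth is not None:
        paths["truth"] = out / "truth.csv"
        truth.data.to_csv(paths["truth"], index_label="probe_id")
        paths["probe_gene_map"] = out / "probe_gene_map.tsv"
        write_probe_gene_map(truth.probe_gene_map, paths["probe_gene_map"])
    if probe_gene_map is not None:
        paths["probe_gene_map"] = out / "probe_gene_map.tsv"
        write_probe_gene_map(probe_gene_map, paths["probe_gene_map"])
    if gene_sets is not None:
        paths["gene_sets"] = out / "gene_sets.gmt"
        gene_sets.to_gmt(paths["gene_sets"])
    return paths


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run the pipeline end to end.

    Exactly one of ``expression_path`` and ``simulation`` must be set:
    the pipeline either loads a study bundle from disk or generates one.
    """

    # inputs (file mode)
    expression_path: str | None = None
    detection_p_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    probe_gene_map_path: str | None = None
    # inputs (simulation mode)
    simulation: SimulationConfig | None = None
    # stage parameters
    detection_p_threshold: float = 0.1
    min_individuals: int | None = None  # None -> floor(n_subjects / 2)
    detection_vote: str = "any"
    top_fraction: float = 0.05
    top_k: int | None = None
    age_cutoff: float = 15.0
    q_cutoff: float = 0.25
    enrichment_q_cutoff: float = 0.1
    fdr_method: str = "storey"
    correlation_method: str = "spearman"
    adjust_sex: bool = True
    # run control
    output_dir: str = "devvar_results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.expression_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of expression_path and simulation must be given"
            )
        if self.age_cutoff <= 0:
            raise ValueError("age_cutoff must be positive")
        for name in ("detection_p_threshold", "top_fraction", "q_cutoff",
                     "enrichment_q_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "sd_ratio" in sim and isinstance(sim["sd_ratio"], list):
                sim["sd_ratio"] = tuple(sim["sd_ratio"])
            for key in ("age_range_young", "age_range_old"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        if self.simulation is not None:
            raw["simulation"] = asdict(self.simulation)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def with_output_dir(self, output_dir) -> "StudyConfig":
        return replace(self, output_dir=str(output_dir))


def published_study_config(
    expression_path,
    detection_p_path,
    metadata_path,
    gmt_path=None,
    probe_gene_map_path=None,
    output_dir="devvar_results",
) -> StudyConfig:
    """The exact configuration of the original published screen.

    Detection p <= 0.1 in at least 16 unique subjects, an explicit
    top-k of 1095 probes, the 15-year age cutoff, and the pFDR < 0.25
    significance call.  Point the paths at a study bundle derived from
    the deposited raw data to attempt the published counts.
    """
    return StudyConfig(
        expression_path=str(expression_path),
        detection_p_path=str(detection_p_path),
        metadata_path=str(metadata_path),
        gmt_path=None if gmt_path is None else str(gmt_path),
        probe_gene_map_path=None
        if probe_gene_map_path is None
        else str(probe_gene_map_path),
        detection_p_threshold=0.1,
        min_individuals=16,
        top_k=1095,
        age_cutoff=15.0,
        q_cutoff=0.25,
        enrichment_q_cutoff=0.1,
        fdr_method="storey",
        output_dir=str(output_dir),
    )


def load_study(
    config: StudyConfig,
) -> tuple[ExpressionMatrix, SampleTable, GeneSetCollection | None, pd.Series | None]:
    """Load and align the study bundle named by a file-mode config."""
    if config.expression_path is None:
        raise ValueError("config is in simulation mode; nothing to load")
    if config.metadata_path is None:
        raise ValueError("metadata_path is required alongside expression_path")
    matrix = read_expression_matrix(
        config.expression_path, config.detection_p_path, scale="raw"
    )
    samples = read_metadata_tsv(config.metadata_path, age_cutoff=config.age_cutoff)
    samples = samples.align_to(matrix)  # raises naming any missing sample
    gene_sets = (
        GeneSetCollection.from_gmt(config.gmt_path) if config.gmt_path else None
    )
    mapping = (
        read_probe_gene_map(config.probe_gene_map_path)
        if config.probe_gene_map_path
        else None
    )
    return matrix, samples, gene_sets, mapping
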