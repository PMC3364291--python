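"""Over-representation analysis of the screened genes.

For a study set of n genes drawn from a universe of N, a term with K
member genes in the universe, and k of them in the study set, the
upper-tail hypergeometric probability P(X >= k) measures enrichment and
``expected = n * K / N`` is the count predicted by chance.  The report
is run against two universes: all genes present on the array, and the
top-variance subset only — the second asks whether the young-variable
genes stand out even among generally variable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variance import adjust_fdr

log = logging.getLogger(__name__)

DEFAULT_ENRICHMENT_Q = 0.1


class GmtParseError(ValueError):
    """Malformed GMT gene-set file."""


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: frozenset[str]
    namespace: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"term {self.term_id!r} has no member genes")


@dataclass(frozen=True)
class GeneSetCollection:
    """Flat mapping of term id to :class:`GeneSet` (no term hierarchy)."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Parse a GMT file: term, description, then member genes, tab-separated."""
        terms: dict[str, GeneSet] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise GmtParseError(
                        f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                    )
                term_id, desc = fields[0], fields[1]
                genes = frozenset(g for g in fields[2:] if g)
                if term_id in terms:
                    raise GmtParseError(f"{path}:{lineno}: duplicate term {term_id!r}")
                namespace = desc.split("|", 1)[0] if "|" in desc else ""
                terms[term_id] = GeneSet(
                    term_id=term_id, name=desc, genes=genes, namespace=namespace
                )
        return cls(terms)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for gs in self.terms.values():
                fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.genes)]) + "\n")


def hypergeometric_overrepresentation(
    study: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term against a custom universe.

    Genes outside the universe are dropped from terms (logged); terms
    with fewer than ``min_term_size`` universe genes are skipped.
    Returns a DataFrame indexed by term with ``observed``, ``expected``,
    ``K`` (term size in universe), ``p_hyper`` and ``q_pfdr``, sorted by
    p.
    """
    study = set(study)
    universe = set(universe)
    outside = study - universe
    if outside:
        raise ValueError(f"study genes outside the universe: {sorted(outside)[:5]}")
    N, n = len(universe), len(study)
    if N == 0:
        raise ValueError("empty universe")
    rows = []
    n_dropped = 0
    for gs in sets:
        members = gs.genes & universe
        n_dropped += len(gs.genes) - len(members)
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": gs.term_id,
                "name": gs.name,
                "namespace": gs.namespace,
                "K": K,
                "observed": k,
                "expected": n * K / N,
                "p_hyper": p,
            }
        )
    if n_dropped:
        log.info("dropped %d term-gene memberships outside the universe", n_dropped)
    if not rows:
        return pd.DataFrame(
            columns=["name", "namespace", "K", "observed", "expected", "p_hyper", "q_pfdr"]
        )
    table = pd.DataFrame(rows).set_index("term_id")
    table["q_pfdr"] = adjust_fdr(table["p_hyper"], method="storey")
    return table.sort_values("p_hyper")


@dataclass(frozen=True)
class EnrichmentReport:
    """Dual-universe enrichment tables plus expected-vs-observed plot data."""

    vs_all_present: pd.DataFrame      # full table, universe = all present genes
    vs_top_variance: pd.DataFrame     # full table, universe = top-variance genes
    significant_vs_all: pd.DataFrame
    significant_vs_top: pd.DataFrame
    q_report_cutoff: float

    def plot_data(self, universe: str = "all_present") -> pd.DataFrame:
        """(term, expected, observed, q) pairs, the Fig-style line data."""
        table = self.vs_all_present if universe == "all_present" else self.vs_top_variance
        out = table[["expected", "observed", "q_pfdr"]].copy()
        out["universe"] = universe
        return out.reset_index()


def _map_probes_to_genes(probes, probe_gene_map: pd.Series) -> set[str]:
    mapped = probe_gene_map.reindex(probes)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        log.info("dropping %d probes without a gene mapping", n_unmapped)
    return set(mapped.dropna())


def enrichment_report(
    screen: pd.DataFrame,
    sets: GeneSetCollection,
    probe_gene_map: pd.Series,
    q_report_cutoff: float = DEFAULT_ENRICHMENT_Q,
    min_term_size: int = 2,
) -> EnrichmentReport:
    """Dual-reference over-representation report for a variance screen.

    ``screen`` is the per-probe table from
    :func:`devvar.variance.run_variance_screen`; probes collapse to
    unique gene ids through ``probe_gene_map`` (a probe-indexed Series
    of gene ids), so duplicate probes of one gene count once.  The study
    set is the significant genes; the test runs against both the
    all-present-genes universe and the top-variance universe.
    """
    study = _map_probes_to_genes(screen.index[screen["significant"]], probe_gene_map)
    if not study:
        raise ValueError("study set is empty after probe-to-gene mapping")
    all_present = _map_probes_to_genes(screen.index, probe_gene_map)
    top_var = _map_probes_to_genes(
        screen.index[screen["selected_top_variance"]], probe_gene_map
    )
    vs_all = hypergeometric_overrepresentation(
        study, all_present, sets, min_term_size=min_term_size
    )
    vs_top = hypergeometric_overrepresentation(
        study, top_var, sets, min_term_size=min_term_size
    )
    return EnrichmentReport(
        vs_all_present=vs_all,
        vs_top_variance=vs_top,
        significant_vs_all=vs_all[vs_all["q_pfdr"] <= q_report_cutoff],
        significant_vs_top=vs_top[vs_top["q_pfdr"] <= q_report_cutoff],
        q_report_cutoff=q_report_cutoff,
    )
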