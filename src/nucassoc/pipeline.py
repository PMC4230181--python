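"""End-to-end analysis: score -> null -> exact test -> co-expression.

Produces one machine-readable report table joining, per probe pair, the
observed association frequency, the null expectation (published
reference constant or fresh simulation), the exact-test result, and —
when expression inputs are configured — per-segment mean expression and
a high/low co-expression label.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from . import coexpression as coex
from .errors import MissingReferenceError, NucAssocError
from .io import RunConfig, write_table_with_header
from .rsd import Relation, estimate_null, reference_null
from .scoring import association_frequency, read_scored_nuclei
from .stats import compare_to_null

__all__ = ["run_pipeline", "segment_pair_coexpression"]

log = logging.getLogger("nucassoc")


def segment_pair_coexpression(
    matrix: pd.DataFrame, genes_a, genes_b
) -> float:
    """Mean Spearman rs over all cross-segment gene pairs."""
    values = [
        coex.spearman_rs(matrix.loc[a].to_numpy(), matrix.loc[b].to_numpy())
        for a in genes_a
        for b in genes_b
        if a != b
    ]
    if not values:
        raise NucAssocError("no cross-segment gene pairs to correlate")
    return float(sum(values) / len(values))


def _null_percent(config: RunConfig, relation: Relation, ploidy: str) -> tuple[float, str]:
    if config.null_source == "reference":
        return reference_null(ploidy, relation), "reference"
    if config.null_source == "simulated":
        est = estimate_null(config.geometry, relation, config.n_trials, config.seed)
        return est.percent, f"simulated(n={config.n_trials})"
    raise NucAssocError(f"unknown null_source {config.null_source!r}")


def run_pipeline(config: RunConfig, nuclei=None) -> pd.DataFrame:
    """Run the full analysis described by ``config``.

    ``nuclei`` may be passed in-memory (table or ScoredNucleus list);
    otherwise ``config.nuclei_path`` is read.  Returns the report table;
    when ``config.out_path`` is set it is also written as TSV with a
    provenance header.  An empty input yields an empty report with a
    warning rather than an error.
    """
    if nuclei is None:
        if config.nuclei_path is None:
            raise NucAssocError("no nuclei input: set nuclei_path or pass nuclei")
        nuclei = read_scored_nuclei(config.nuclei_path)
    elif not isinstance(nuclei, list):
        nuclei = read_scored_nuclei(nuclei)

    expression = segment_map = None
    if config.expression_path:
        matrix = coex.read_expression_matrix(config.expression_path)
        expression = coex.mean_normalize(matrix)
        if config.segment_map_path:
            segment_map = pd.read_csv(config.segment_map_path, sep="\t")

    columns = [
        "probe_a",
        "probe_b",
        "relation",
        "k",
        "n",
        "percent",
        "percent_display",
        "null_percent",
        "null_source",
        "p_value",
        "stars",
        "mean_expr_a",
        "mean_expr_b",
        "cross_rs",
        "coexpression",
    ]
    if not nuclei:
        warnings.warn("empty nuclei table: producing an empty report")
        report = pd.DataFrame(columns=columns)
        if config.out_path:
            write_table_with_header(report, config.out_path, seed=config.seed, config=config)
        return report

    ploidies = {n.ploidy_label for n in nuclei}
    ploidy = ploidies.pop() if len(ploidies) == 1 else "2C"

    seg_expr = None
    if expression is not None and segment_map is not None and config.expression_sample:
        seg_expr = coex.segment_mean_expression(
            expression, segment_map, config.expression_sample
        )

    rows = []
    for probe_a, probe_b, relation_name in config.probe_pairs:
        try:
            relation = Relation.coerce(relation_name)
            summary = association_frequency(
                nuclei, probe_a, probe_b, relation, config.distance_threshold
            )
            null_pct, null_src = _null_percent(config, relation, ploidy)
            test = compare_to_null(summary, null_pct)
        except (NucAssocError, MissingReferenceError) as exc:
            raise type(exc)(
                f"pipeline stage failed for pair {probe_a}/{probe_b}: {exc}"
            ) from exc
        row = {
            "probe_a": probe_a,
            "probe_b": probe_b,
            "relation": relation.value,
            "k": summary.k,
            "n": summary.n,
            "percent": summary.percent,
            "percent_display": summary.percent_display,
            "null_percent": null_pct,
            "null_source": null_src,
            "p_value": test.p_value,
            "stars": test.stars,
            "mean_expr_a": None,
            "mean_expr_b": None,
            "cross_rs": None,
            "coexpression": None,
        }
        if seg_expr is not None:
            for side, probe in (("a", probe_a), ("b", probe_b)):
                if probe in seg_expr.index:
                    row[f"mean_expr_{side}"] = seg_expr.loc[probe, "mean_expression"]
            genes_a = segment_map.loc[segment_map["segment_id"] == probe_a, "gene_id"]
            genes_b = segment_map.loc[segment_map["segment_id"] == probe_b, "gene_id"]
            if len(genes_a) and len(genes_b):
                rs = segment_pair_coexpression(expression, genes_a, genes_b)
                row["cross_rs"] = rs
                label = coex.classify_coexpression(
                    pd.DataFrame({"rs": [rs]}),
                    config.high_threshold,
                    config.low_threshold,
                ).iloc[0]
                row["coexpression"] = label
        rows.append(row)

    report = pd.DataFrame(rows, columns=columns)
    if config.out_path:
        write_table_with_header(report, config.out_path, seed=config.seed, config=config)
    return report
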