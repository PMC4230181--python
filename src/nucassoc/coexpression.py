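"""Gene co-expression scoring for probed chromatin segments.

Works on microarray-style expression matrices (genes x samples,
positive intensities) held as pandas DataFrames with the gene identifier
as index.  Provides the normalisation, pairwise Spearman co-response
queries (single-gene sGQ and multiple-gene mGQ), high/low co-expression
classification and per-segment mean expression summaries used to relate
spatial association of euchromatin segments to the transcriptional
activity of the genes they carry.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats

from .errors import NucAssocError, UndefinedCorrelationError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "mean_normalize",
    "spearman_rs",
    "spearman_pvalue",
    "coresponse_query",
    "classify_coexpression",
    "segment_mean_expression",
    "EXACT_PERMUTATION_MAX_N",
]

#: Largest sample count for which the permutation null of rs is enumerated.
EXACT_PERMUTATION_MAX_N = 9


def read_expression_matrix(path) -> pd.DataFrame:
    """TSV with gene ids in the first column, sample ids in the header."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise NucAssocError(f"duplicate gene ids in expression matrix: {dups}")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def mean_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 mean-normalised intensities.

    Each intensity is divided by its gene's mean across samples and
    log2-transformed, so a value of +1 means 2-fold above that gene's
    average level.  Requires strictly positive input.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(values > 0):
        raise NucAssocError("mean_normalize requires strictly positive intensities")
    return np.log2(matrix.div(matrix.mean(axis=1), axis=0))


def spearman_rs(x, y) -> float:
    """Spearman's rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NucAssocError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise NucAssocError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "rank correlation undefined for a constant sequence"
        )
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    n = x.size
    if np.unique(rx).size == n and np.unique(ry).size == n:
        # untied ranks: the rank-difference form is exact (gives +/-1
        # exactly on monotone sequences, free of float round-off)
        d2 = float(((rx - ry) ** 2).sum())
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(scipy.stats.spearmanr(x, y).statistic)


@lru_cache(maxsize=8)
def _permutation_abs_rs(n: int) -> np.ndarray:
    """|rs| over all n! rank permutations against a fixed ranking (no ties)."""
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=np.int64)
    ranks = np.arange(1, n + 1, dtype=np.int64)
    d2 = ((perms - ranks) ** 2).sum(axis=1)
    rs = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.abs(rs)


def spearman_pvalue(rs: float, n: int) -> float:
    """Two-sided p-value for an observed rs at sample size n.

    For n <= 9 the exact permutation null of untied ranks is enumerated
    (p = share of permutations with |rs| at least as extreme); for larger
    n the t approximation t = rs*sqrt((n-2)/(1-rs^2)) on n-2 degrees of
    freedom is used, returning the smallest positive float at |rs| = 1.
    """
    if not (-1.0 <= rs <= 1.0):
        raise NucAssocError(f"rs {rs} outside [-1, 1]")
    if n < 4:
        raise NucAssocError("need n >= 4 for a p-value")
    if n <= EXACT_PERMUTATION_MAX_N:
        null = _permutation_abs_rs(n)
        # tolerance absorbs float error in the observed rs
        return float(np.mean(null >= abs(rs) - 1e-9))
    if abs(rs) >= 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    return float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))


def _pair_row(matrix: pd.DataFrame, a: str, b: str) -> dict:
    n = matrix.shape[1]
    rs = spearman_rs(matrix.loc[a].to_numpy(), matrix.loc[b].to_numpy())
    return {
        "gene_a": a,
        "gene_b": b,
        "rs": rs,
        "p_value": spearman_pvalue(rs, n),
        "n_samples": n,
    }


def coresponse_query(
    matrix: pd.DataFrame,
    reference_genes,
    candidate_genes,
    mode: str = "auto",
) -> pd.DataFrame:
    """Pairwise gene-to-gene co-response query.

    ``sGQ`` correlates one reference gene with every candidate; ``mGQ``
    forms all pairs among the union of references and candidates.  With
    ``mode="auto"`` a single reference selects sGQ.  Ids absent from the
    matrix are reported in the error, never silently dropped.  Rows are
    sorted by |rs| descending, ties broken by gene ids.
    """
    reference_genes = list(reference_genes)
    candidate_genes = list(candidate_genes)
    unknown = [
        g
        for g in dict.fromkeys(reference_genes + candidate_genes)
        if g not in matrix.index
    ]
    if unknown:
        raise LookupError(f"gene ids absent from the expression matrix: {unknown}")
    if mode == "auto":
        mode = "sGQ" if len(reference_genes) == 1 else "mGQ"
    if mode == "sGQ":
        if len(reference_genes) != 1:
            raise NucAssocError("sGQ requires exactly one reference gene")
        ref = reference_genes[0]
        pairs = [(ref, c) for c in candidate_genes if c != ref]
    elif mode == "mGQ":
        union = list(dict.fromkeys(reference_genes + candidate_genes))
        pairs = list(itertools.combinations(union, 2))
    else:
        raise NucAssocError(f"unknown query mode {mode!r}")
    rows = [_pair_row(matrix, a, b) for a, b in pairs]
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rs", "p_value", "n_samples"]
    )
    if len(df):
        df = df.sort_values(
            by=["rs", "gene_a", "gene_b"],
            key=lambda s: -s.abs() if s.name == "rs" else s,
        ).reset_index(drop=True)
    return df


def classify_coexpression(
    pairs: pd.DataFrame,
    high_threshold: float = 0.7,
    low_threshold: float = 0.3,
) -> pd.Series:
    """Label each pair high / low / intermediate by its rs.

    ``high`` when rs >= high_threshold, ``low`` when |rs| <=
    low_threshold, ``intermediate`` otherwise.  The thresholds are
    package conventions and should be tuned to the question at hand.
    """
    if not (0.0 <= low_threshold <= high_threshold <= 1.0):
        raise NucAssocError(
            f"need 0 <= low <= high <= 1, got low={low_threshold}, high={high_threshold}"
        )
    rs = pairs["rs"]
    labels = pd.Series("intermediate", index=pairs.index, name="coexpression")
    labels[rs >= high_threshold] = "high"
    labels[rs.abs() <= low_threshold] = "low"
    return labels


def segment_mean_expression(
    matrix: pd.DataFrame,
    segment_map: "pd.DataFrame | dict[str, str]",
    sample: str,
) -> pd.DataFrame:
    """Mean and SD of (normalised) expression per segment in one sample.

    ``segment_map`` maps gene id -> segment id (dict, or a DataFrame with
    ``gene_id`` / ``segment_id`` columns).  Single-gene segments report
    sd = 0 by convention.  Every mapped gene must be present in the
    matrix.
    """
    if isinstance(segment_map, pd.DataFrame):
        mapping = dict(zip(segment_map["gene_id"], segment_map["segment_id"]))
    else:
        mapping = dict(segment_map)
    if not mapping:
        raise NucAssocError("empty segment map")
    missing = [g for g in mapping if g not in matrix.index]
    if missing:
        raise LookupError(f"mapped genes absent from the matrix: {missing}")
    if sample not in matrix.columns:
        raise LookupError(f"sample {sample!r} absent from the matrix")
    rows = []
    segments: dict[str, list[str]] = {}
    for gene, seg in mapping.items():
        segments.setdefault(seg, []).append(gene)
    for seg in sorted(segments):
        genes = segments[seg]
        vals = matrix.loc[genes, sample].to_numpy(dtype=float)
        rows.append(
            {
                "segment_id": seg,
                "gene_count": len(genes),
                "mean_expression": float(vals.mean()),
                "sd_expression": float(vals.std(ddof=1)) if len(genes) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("segment_id")
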