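"""Differential-expression calling, ncRNA expression calling, and sample clustering.

The caller is deliberately simple: a per-gene Welch two-sample t-test on
log2-transformed abundances, Benjamini–Hochberg correction across the genes of
one contrast, and the study's strict thresholds (|log2FC| > 2, adjusted
p < 0.05).  It is not a replacement for a dispersion-shrinking count model; it
exists so the threshold logic, persistence bookkeeping, and signature algebra
downstream can be exercised and validated on data with known structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DEGTable",
    "Dendrogram",
    "test_differential_expression",
    "bh_adjust",
    "call_degs",
    "call_expressed_ncrna",
    "cluster_samples",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with a condition design.

    ``values`` has gene ids as the index and sample ids as columns;
    ``design`` maps each sample id to ``(condition_label, replicate_index)``.
    Values may be counts or FPKM — downstream code only assumes they are
    finite and non-negative.
    """

    values: pd.DataFrame
    design: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        missing = [s for s in cols if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if np.any(arr < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.design[s][0]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.design[s][0] == condition]
        if not out:
            raise KeyError(f"condition {condition!r} not present in design")
        return out

    def condition_means(self, condition: str) -> pd.Series:
        return self.values[self.samples_for(condition)].mean(axis=1)


@dataclass
class DEGTable:
    """Per-gene effect/significance records plus signed DEG calls for one contrast.

    ``records`` columns: gene_id, log2fc, p_raw, p_adj, call
    (call in {"up", "down", "not_de"}).
    """

    treatment: str
    control: str
    records: pd.DataFrame
    fc_threshold: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "p_adj", "call"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"DEGTable records missing columns: {sorted(missing)}")
        if self.records["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in DEG table")

    @property
    def contrast(self) -> str:
        return f"{self.treatment}_vs_{self.control}"

    @property
    def gene_ids(self) -> set[str]:
        return set(self.records["gene_id"])

    def ids_with_call(self, call: str) -> set[str]:
        return set(self.records.loc[self.records["call"] == call, "gene_id"])

    @property
    def up_ids(self) -> set[str]:
        return self.ids_with_call("up")

    @property
    def down_ids(self) -> set[str]:
        return self.ids_with_call("down")

    @property
    def de_ids(self) -> set[str]:
        return self.up_ids | self.down_ids

    def directions(self) -> dict[str, str]:
        """gene_id -> 'up'/'down' for called DEGs only."""
        de = self.records[self.records["call"] != "not_de"]
        return dict(zip(de["gene_id"], de["call"]))


def test_differential_expression(
    matrix: ExpressionMatrix,
    treatment: str,
    control: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene effect size and raw p-value for treatment vs control.

    log2fc is the difference of mean log2(value + pseudocount) between the
    two conditions; p_raw comes from a two-sided pooled-variance Student
    t-test on the same log-transformed replicate values.  With two or three
    replicates a group, pooling the variance (df = n1 + n2 - 2) matters: the
    Welch approximation collapses toward df = 2 whenever the two sample
    variances differ by chance, which at n = 3 is typical and costs most of
    the test's power at stringent FDR thresholds, while same-protocol
    replicate groups justify the equal-variance assumption.  Genes with zero
    variance in both
    groups get p_raw = 1 when the group means agree and p_raw = 0 (with a
    warning) when they differ.

    Returns a DataFrame with columns gene_id, log2fc, p_raw.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    t_samples = matrix.samples_for(treatment)
    c_samples = matrix.samples_for(control)
    for label, samples in ((treatment, t_samples), (control, c_samples)):
        if len(samples) < 2:
            raise ValueError(
                f"condition {label!r} has {len(samples)} replicate(s); "
                "need at least 2 for a location test"
            )
    log_t = np.log2(matrix.values[t_samples].to_numpy(dtype=float) + pseudocount)
    log_c = np.log2(matrix.values[c_samples].to_numpy(dtype=float) + pseudocount)
    log2fc = log_t.mean(axis=1) - log_c.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows are handled explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        _, p_raw = stats.ttest_ind(log_t, log_c, axis=1, equal_var=True)
    p_raw = np.asarray(p_raw, dtype=float)

    var_t = log_t.var(axis=1)
    var_c = log_c.var(axis=1)
    degenerate = (var_t == 0) & (var_c == 0)
    if degenerate.any():
        equal = degenerate & np.isclose(log2fc, 0.0)
        unequal = degenerate & ~np.isclose(log2fc, 0.0)
        p_raw[equal] = 1.0
        if unequal.any():
            warnings.warn(
                f"{int(unequal.sum())} gene(s) have zero variance in both groups "
                "with unequal means; assigning p_raw = 0",
                RuntimeWarning,
                stacklevel=2,
            )
            p_raw[unequal] = 0.0
    # one-group-degenerate rows: Welch handles them, but guard residual NaNs
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    return pd.DataFrame(
        {"gene_id": matrix.gene_ids, "log2fc": log2fc, "p_raw": p_raw}
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    stats_table: pd.DataFrame,
    treatment: str = "treatment",
    control: str = "control",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> DEGTable:
    """Adjust p-values across the contrast and apply strict DEG thresholds.

    A gene is called ``up`` iff log2fc > fc_threshold and p_adj < alpha,
    ``down`` iff log2fc < -fc_threshold and p_adj < alpha, else ``not_de``.
    Both inequalities are strict.
    """
    if len(stats_table) == 0:
        raise ValueError("empty statistics table")
    rec = stats_table.copy().reset_index(drop=True)
    rec["p_adj"] = bh_adjust(rec["p_raw"].to_numpy())
    sig = rec["p_adj"] < alpha
    call = np.where(
        sig & (rec["log2fc"] > fc_threshold),
        "up",
        np.where(sig & (rec["log2fc"] < -fc_threshold), "down", "not_de"),
    )
    rec["call"] = call
    return DEGTable(
        treatment=treatment,
        control=control,
        records=rec,
        fc_threshold=fc_threshold,
        alpha=alpha,
    )


def call_expressed_ncrna(
    matrix: ExpressionMatrix,
    ncrna_ids: Iterable[str],
    cutoff: float = 24.7,
) -> dict[str, set[str]]:
    """Per-condition sets of ncRNAs whose mean abundance reaches the cutoff.

    The default cutoff 24.7 FPKM is the minimum observed expression of the
    housekeeping gene pmp-3, used as the floor for calling an ncRNA expressed.
    Expression is summarized as the replicate mean per condition and the
    comparison is inclusive (mean >= cutoff).
    """
    ids = list(dict.fromkeys(ncrna_ids))
    unknown = [g for g in ids if g not in matrix.values.index]
    if unknown:
        raise KeyError(f"unknown ncRNA ids (not in matrix): {unknown[:10]}")
    out: dict[str, set[str]] = {}
    sub = matrix.values.loc[ids]
    for cond in matrix.conditions:
        means = sub[matrix.samples_for(cond)].mean(axis=1)
        out[cond] = set(means.index[means >= cutoff])
    return out


@dataclass
class Dendrogram:
    """Sample dendrogram: Ward linkage over log-transformed profiles."""

    labels: list[str]
    linkage: np.ndarray = field(repr=False)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.left, node.right
            parts = []
            for child in (left, right):
                bl = node.dist - child.dist
                parts.append(f"{rec(child)}:{bl:.10g}")
            return f"({','.join(parts)})"

        return rec(tree) + ";"

    def merge_order(self) -> list[tuple[frozenset[str], frozenset[str]]]:
        """Leaf-label sets joined at each merge, in merge order."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        order = []
        for i, (a, b, _, _) in enumerate(self.linkage):
            sa, sb = members[int(a)], members[int(b)]
            order.append((sa, sb))
            members[n + i] = sa | sb
        return order


def cluster_samples(
    matrix: ExpressionMatrix,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> Dendrogram:
    """Agglomerative clustering of sample profiles (Ward linkage, Euclidean)."""
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    X = matrix.values.to_numpy(dtype=float).T
    if log_transform:
        X = np.log2(X + pseudocount)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return Dendrogram(labels=matrix.sample_ids, linkage=Z)
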