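"""Expression-matrix processing and covariate-adjusted differential expression.

Operations mirror a standard microarray workflow: quantile normalization,
averaging of technical replicates, PCA and within-group correlation summaries
of sample structure, per-gene linear-model differential expression adjusted
for sample covariates (sex, disease status, twin/clone pairing), BH multiple
testing correction, and threshold-based DEG selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionStudy",
    "DGEResult",
    "PCASummary",
    "OverlapSummary",
    "quantile_normalize",
    "merge_technical_replicates",
    "pca_summary",
    "group_mean_correlation",
    "fit_dge",
    "bh_adjust",
    "select_degs",
    "overlap_summary",
    "marker_anova",
]

VALID_GROUPS = ("UD", "FD", "T", "FIB")


@dataclass
class ExpressionStudy:
    """A gene × sample log2-intensity matrix plus per-sample metadata.

    ``matrix`` columns must match the index of ``samples`` exactly.  The
    sample sheet carries the culture-condition group (UD/FD/T/FIB), cell
    type, donor, sex, disease status, twin id, technical-replicate group id,
    and passage where known.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.matrix.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate sample ids in expression matrix")
        if list(self.samples.index) != cols:
            raise ValueError("sample sheet index does not match matrix columns")
        if "group" not in self.samples.columns:
            raise ValueError("sample sheet must have a 'group' column")
        if self.samples["group"].isna().any():
            raise ValueError("missing group labels in sample sheet")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DGEResult:
    """Per-gene differential-expression table for one group contrast.

    ``table`` columns: gene (index), log2fc, p, adj_p, direction.
    """

    table: pd.DataFrame
    comparison: str

    def __post_init__(self) -> None:
        required = {"log2fc", "p", "adj_p", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DGE table missing columns: {sorted(missing)}")


@dataclass
class PCASummary:
    """Sample scores and variance-explained fractions for the top components."""

    scores: pd.DataFrame  # samples × PC1..PCk
    variance_fractions: np.ndarray  # length k, non-increasing, each in [0, 1]

    def __post_init__(self) -> None:
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        vf = self.variance_fractions
        if np.any(vf < -1e-12) or np.any(vf > 1 + 1e-12):
            raise ValueError("variance fractions must lie in [0, 1]")
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")


@dataclass
class OverlapSummary:
    """Set-overlap bookkeeping for DEG lists (|A|, |B|, |A∩B|, % of A)."""

    n_a: int
    n_b: int
    n_overlap: int
    percent_of_a: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap cannot exceed either set size")
        if self.n_a == 0:
            raise ValueError("percentage of empty set A is undefined")
        self.percent_of_a = round(100.0 * self.n_overlap / self.n_a, 1)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the identical distribution of per-rank means.

    Each column is replaced by the across-column mean of the k-th smallest
    values, assigned by within-column rank.  Tied values within a column
    receive the mean of the target values for the ranks they jointly occupy,
    so the operation is deterministic and idempotent.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one column")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")
    rank_targets = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = rank_targets
        # average target values within tie groups
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def merge_technical_replicates(study: ExpressionStudy) -> ExpressionStudy:
    """Average technical replicates into one column per biological sample.

    Columns sharing a ``tech_rep_group`` id are replaced by their arithmetic
    mean; all other metadata within a replicate group must agree.
    """
    if "tech_rep_group" not in study.samples.columns:
        raise ValueError("sample sheet has no 'tech_rep_group' column")
    meta_cols = [c for c in study.samples.columns if c != "tech_rep_group"]
    merged_cols: dict[str, np.ndarray] = {}
    merged_meta: list[pd.Series] = []
    order: list[str] = []
    for rep_id, sub in study.samples.groupby("tech_rep_group", sort=False):
        meta = sub[meta_cols].drop_duplicates()
        if len(meta) != 1:
            raise ValueError(
                f"technical replicate group {rep_id!r} has conflicting metadata"
            )
        merged_cols[str(rep_id)] = study.matrix[sub.index].mean(axis=1).to_numpy()
        row = meta.iloc[0].copy()
        row.name = str(rep_id)
        merged_meta.append(row)
        order.append(str(rep_id))
    matrix = pd.DataFrame(merged_cols, index=study.matrix.index)[order]
    samples = pd.DataFrame(merged_meta)
    samples["tech_rep_group"] = samples.index
    return ExpressionStudy(matrix=matrix, samples=samples)


def pca_summary(matrix: pd.DataFrame, k: int = 2) -> PCASummary:
    """PCA on samples: per-gene centering, no scaling, SVD-based.

    Variance fractions are singular-value energies over the total variance.
    Sign convention: within each component the largest-magnitude gene
    loading is made positive, so results are fully deterministic.
    """
    n_samples = matrix.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if k > min(matrix.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(matrix.shape)}")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    # columns are samples; scores live in sample space
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    fractions = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = (Vt[:k].T * s[:k])  # samples × k
    loadings = U[:, :k]
    for i in range(k):
        j = np.argmax(np.abs(loadings[:, i]))
        if loadings[j, i] < 0:
            scores[:, i] *= -1
            loadings[:, i] *= -1
    score_df = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCASummary(scores=score_df, variance_fractions=fractions)


def group_mean_correlation(
    matrix: pd.DataFrame, grouping: Mapping[str, str] | pd.Series
) -> pd.Series:
    """Mean pairwise Pearson correlation among samples of each group."""
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    out = {}
    for group, members in grouping.groupby(grouping).groups.items():
        cols = [c for c in members if c in matrix.columns]
        if len(cols) < 2:
            raise ValueError(f"group {group!r} has fewer than two samples")
        sub = matrix[cols].to_numpy(dtype=float)
        if np.any(sub.std(axis=0) == 0):
            raise ValueError(
                f"constant-valued sample vector in group {group!r}: correlation undefined"
            )
        corr = np.corrcoef(sub, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        out[group] = float(corr[iu].mean())
    return pd.Series(out, name="mean_correlation")


def _design_matrix(
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: Sequence[str],
) -> tuple[np.ndarray, list[str], pd.Index]:
    """Build intercept + group indicator + dummy-coded covariate design."""
    test_group, ref_group = contrast
    mask = samples["group"].isin([test_group, ref_group])
    sub = samples[mask]
    if (sub["group"] == test_group).sum() == 0 or (sub["group"] == ref_group).sum() == 0:
        raise ValueError(f"contrast groups {contrast} not both present in study")
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(sub)),
        f"group[{test_group}]": (sub["group"] == test_group).to_numpy(dtype=float),
    }
    for cov in covariates:
        if cov not in sub.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        values = sub[cov]
        if values.dtype.kind in "fiu" and values.nunique() > 2:
            cols[cov] = values.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(values.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the columns that do not add rank, for the error message
        bad: list[str] = []
        r = 0
        kept = np.empty((X.shape[0], 0))
        for i, name in enumerate(names):
            cand = np.column_stack([kept, X[:, i]])
            if np.linalg.matrix_rank(cand) > r:
                kept = cand
                r += 1
            else:
                bad.append(name)
        raise ValueError(f"confounded design: collinear columns {bad}")
    return X, names, sub.index


def fit_dge(
    study: ExpressionStudy,
    contrast: tuple[str, str],
    covariates: Sequence[str] = (),
    moderate: bool = False,
    prior_df: float = 4.0,
) -> DGEResult:
    """Per-gene linear model: log2 expression ~ group + covariates.

    The reported effect is the coefficient of the group indicator
    (log2 fold change of ``contrast[0]`` over ``contrast[1]``); p values come
    from two-sided t-tests on that coefficient.  With ``moderate=True``,
    per-gene residual variances are shrunk toward their global mean with
    ``prior_df`` prior degrees of freedom (a simple empirical-Bayes
    stabilization for small sample sizes); the default is plain OLS.

    Genes with zero residual variance are handled explicitly: a nonzero
    effect gets p = 0, a zero effect p = 1.
    """
    X, names, sample_idx = _design_matrix(study.samples, contrast, covariates)
    Y = study.matrix[sample_idx].to_numpy(dtype=float)  # genes × n
    n, p = X.shape
    if n <= p:
        raise ValueError(f"not enough samples ({n}) for {p} model parameters")
    coef_idx = names.index(f"group[{contrast[0]}]")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y.T  # p × genes
    resid = Y.T - X @ B
    dof = n - p
    s2 = (resid**2).sum(axis=0) / dof
    if moderate:
        s2_bar = s2.mean()
        s2 = (prior_df * s2_bar + dof * s2) / (prior_df + dof)
        dof = dof + prior_df
    lfc = B[coef_idx]
    se = np.sqrt(s2 * XtX_inv[coef_idx, coef_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    zero_var = se == 0
    pvals[zero_var & (np.abs(lfc) > 0)] = 0.0
    pvals[zero_var & (lfc == 0)] = 1.0
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": pvals,
            "adj_p": bh_adjust(pvals),
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=study.matrix.index,
    )
    return DGEResult(table=table, comparison=f"{contrast[0]}_vs_{contrast[1]}")


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, in the input order."""
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                   dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def select_degs(
    dge: DGEResult, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes with |log2FC| strictly above threshold and adjusted p below alpha."""
    t = dge.table
    mask = (t["log2fc"].abs() > lfc_threshold) & (t["adj_p"] < alpha)
    return t[mask].copy()


def overlap_summary(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapSummary:
    """Counts and percent-of-A for the intersection of two gene sets."""
    a, b = set(set_a), set(set_b)
    return OverlapSummary(n_a=len(a), n_b=len(b), n_overlap=len(a & b))


def marker_anova(
    matrix: pd.DataFrame,
    gene_panel: Sequence[str],
    grouping: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD per marker gene across sample groups.

    Intended for small marker panels (pluripotency core, germ-layer and
    fibroblast markers).  Genes absent from the matrix are reported with
    status ``missing`` rather than raising.  Returns a long table with one
    row per (gene, pairwise comparison) plus the per-gene ANOVA p.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    cols = [c for c in matrix.columns if c in grouping.index]
    labels = grouping[cols]
    if labels.nunique() < 2:
        raise ValueError("need at least two groups")
    if (labels.value_counts() < 2).any():
        raise ValueError("every group needs at least two samples")
    rows: list[dict] = []
    for gene in gene_panel:
        if gene not in matrix.index:
            rows.append({"gene": gene, "status": "missing", "anova_p": np.nan,
                         "pair": None, "tukey_p": np.nan})
            continue
        values = matrix.loc[gene, cols].to_numpy(dtype=float)
        by_group = [values[(labels == g).to_numpy()] for g in labels.unique()]
        if np.ptp(values) == 0:
            # identical values everywhere: no group effect distinguishable
            rows.append({"gene": gene, "status": "constant", "anova_p": 1.0,
                         "pair": None, "tukey_p": np.nan})
            continue
        f_p = stats.f_oneway(*by_group).pvalue
        tukey = pairwise_tukeyhsd(values, labels.to_numpy())
        res = tukey.summary().data[1:]
        for row in res:
            g1, g2 = str(row[0]), str(row[1])
            rows.append({
                "gene": gene,
                "status": "ok",
                "anova_p": float(f_p),
                "pair": f"{g1}-{g2}",
                "tukey_p": float(row[3]),
            })
    return pd.DataFrame(rows)
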