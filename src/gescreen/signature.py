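"""Minimal gene-expression-signature (GES) derivation.

The derivation pipeline discriminates treated from vehicle samples:

1. a per-gene two-sample pooled-variance t-test keeps genes with unadjusted
   p < 0.01;
2. genes are ranked by the signal-to-noise ratio (SNR) statistic
   ``(mu_treated - mu_vehicle) / (sd_treated + sd_vehicle)``;
3. forward stepwise selection under diagonal linear discriminant analysis
   (DLDA) grows the signature one gene at a time, maximizing leave-one-out
   cross-validated (LOOCV) accuracy, stopping at the first step with no
   strict improvement or at a hard cap of 7 genes (fewer than 8 predictors
   keeps joint estimation honest at 20 replicates per group);
4. an exhaustive divergence reduction searches subsets of the selected
   signature containing at least one up- and one down-regulated gene for the
   smallest subset that retains the selected model's LOOCV accuracy.

DLDA is the equal-prior Gaussian classifier with class-specific means and a
shared diagonal covariance: a sample is assigned to the class minimizing the
variance-scaled squared distance ``sum_j (x_j - mu_kj)^2 / s_j^2``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "NoDiscriminantGenesError",
    "DLDAModel",
    "de_filter",
    "snr",
    "dlda_fit",
    "dlda_predict",
    "loocv_accuracy",
    "forward_select",
    "divergence_reduce",
    "derive_signature",
]

TREATED = "treated"
VEHICLE = "vehicle"

#: relative variance floor applied to zero-variance genes in DLDA
VARIANCE_FLOOR_REL = 1e-8
#: absolute fallback when every gene in a model has zero pooled variance
VARIANCE_FLOOR_ABS = 1e-12
#: floor on the SNR denominator sd sum, keeps the statistic finite
SNR_EPS = 1e-12


class NoDiscriminantGenesError(ValueError):
    """No gene passed the differential-expression filter."""


def _two_groups(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Treated and vehicle genes x samples arrays, with size checks."""
    a = matrix.group_values(TREATED)
    b = matrix.group_values(VEHICLE)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return a, b


def de_filter(matrix: ExpressionMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene pooled-variance two-sample t-test.

    Returns a frame indexed by gene with columns ``t``, ``p``, ``sign``
    (sign of treated minus vehicle mean) and ``selected`` (p strictly below
    ``alpha``).  Genes with zero pooled variance get p = 1 when the group
    means agree and p = 0 when they differ (perfect separation).
    """
    a, b = _two_groups(matrix)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = ma - mb

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    zero_var = sp2 == 0
    equal_means = diff == 0
    inf_t = np.where(diff > 0, np.inf, -np.inf)
    t = np.where(zero_var, np.where(equal_means, 0.0, inf_t), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var, np.where(equal_means, 1.0, 0.0), p)

    return pd.DataFrame(
        {"t": t, "p": p, "sign": np.sign(diff), "selected": p < alpha},
        index=matrix.gene_ids)


def snr(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Golub signal-to-noise ratio per gene, ranked by |SNR| descending.

    ``SNR = (mu_treated - mu_vehicle) / (sd_treated + sd_vehicle)`` with the
    sd sum floored at a small epsilon; ties in |SNR| rank in gene-id order.
    """
    a, b = _two_groups(matrix)
    denom = np.maximum(a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1), SNR_EPS)
    values = (a.mean(axis=1) - b.mean(axis=1)) / denom
    table = pd.DataFrame({"snr": values, "abs_snr": np.abs(values)},
                         index=matrix.gene_ids)
    # stable sort on a gene-id-sorted frame gives the deterministic tie-break
    order = table.sort_index().sort_values("abs_snr", ascending=False,
                                           kind="stable")
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return table


@dataclass
class DLDAModel:
    """A fitted DLDA classifier on a fixed gene set."""

    genes: list[str]
    classes: tuple[str, str]
    #: genes x classes means
    class_means: pd.DataFrame
    #: per-gene pooled within-class variance (floored)
    pooled_var: pd.Series
    loocv_accuracy: float | None = None
    selection_trace: list[float] = field(default_factory=list)
    divergence_warning: bool = False

    @property
    def directions(self) -> pd.Series:
        """Sign of the treated-minus-vehicle mean difference per gene."""
        diff = self.class_means[self.classes[0]] - self.class_means[self.classes[1]]
        return np.sign(diff)


def dlda_fit(matrix: ExpressionMatrix, genes: list[str]) -> DLDAModel:
    """Fit DLDA on the given genes: per-class means and pooled variances.

    The pooled variance per gene is the within-class sum of squares over
    ``n - 2``, floored at ``1e-8`` times the mean pooled variance across the
    model's genes so constant genes stay usable.
    """
    if not genes:
        raise ValueError("empty gene list")
    sub = ExpressionMatrix(matrix.values.loc[list(genes)], matrix.design)
    a, b = _two_groups(sub)
    means, pooled = _fit_arrays(a, b)
    idx = pd.Index(list(genes), name="gene_id")
    return DLDAModel(
        genes=list(genes),
        classes=(TREATED, VEHICLE),
        class_means=pd.DataFrame({TREATED: means[0], VEHICLE: means[1]}, index=idx),
        pooled_var=pd.Series(pooled, index=idx),
    )


def _fit_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class means stacked (2, genes) and floored pooled variances."""
    n = a.shape[1] + b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    wss = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    pooled = wss / (n - 2)
    mean_pv = pooled.mean()
    floor = VARIANCE_FLOOR_REL * mean_pv if mean_pv > 0 else VARIANCE_FLOOR_ABS
    return np.stack([ma, mb]), np.maximum(pooled, floor)


def dlda_predict(model: DLDAModel, sample) -> str:
    """Classify one sample (mapping or Series of gene -> value).

    Assigns the class minimizing ``sum_j (x_j - mu_kj)^2 / s_j^2`` under
    equal priors; an exact tie goes to the vehicle class (conservative).
    """
    try:
        x = np.array([float(sample[g]) for g in model.genes])
    except KeyError as e:
        raise KeyError(f"sample is missing signature gene {e.args[0]!r}") from e
    mu = model.class_means.to_numpy().T  # (2, genes), treated first
    s2 = model.pooled_var.to_numpy()
    scores = ((x[None, :] - mu) ** 2 / s2).sum(axis=1)
    if scores[0] < scores[1]:
        return model.classes[0]
    return model.classes[1]


def _loocv_arrays(a: np.ndarray, b: np.ndarray) -> float:
    """LOOCV accuracy of DLDA from the two groups' genes x samples arrays."""
    na, nb = a.shape[1], b.shape[1]
    correct = 0
    for k in range(na + nb):
        if k < na:
            ta = np.delete(a, k, axis=1)
            tb = b
            x = a[:, k]
            true_first = True
        else:
            ta = a
            tb = np.delete(b, k - na, axis=1)
            x = b[:, k - na]
            true_first = False
        mu, s2 = _fit_arrays(ta, tb)
        d = ((x[None, :] - mu) ** 2 / s2).sum(axis=1)
        pred_first = d[0] < d[1]  # tie -> second (vehicle) class
        correct += pred_first == true_first
    return correct / (na + nb)


def loocv_accuracy(matrix: ExpressionMatrix, genes: list[str]) -> float:
    """Leave-one-out cross-validated DLDA accuracy on the given genes."""
    if not genes:
        raise ValueError("empty gene list")
    sub = matrix.values.loc[list(genes)]
    a = sub.loc[:, matrix.group_columns(TREATED)].to_numpy()
    b = sub.loc[:, matrix.group_columns(VEHICLE)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return _loocv_arrays(a, b)


def forward_select(matrix: ExpressionMatrix,
                   de: pd.DataFrame,
                   snr_table: pd.DataFrame,
                   cap: int = 7) -> DLDAModel:
    """Forward stepwise DLDA selection over the DE-passing genes.

    Starting from the empty set, each step adds the candidate gene whose
    augmented set maximizes LOOCV accuracy (ties broken by larger |SNR|,
    then gene-id order); selection stops when no addition strictly improves
    accuracy or when the signature reaches ``cap`` genes.
    """
    candidates = list(de.index[de["selected"]])
    if not candidates:
        raise NoDiscriminantGenesError(
            "no gene passed the differential-expression filter (p < 0.01)")
    # deterministic candidate order: |SNR| desc, then gene id
    candidates.sort(key=lambda g: (-snr_table.at[g, "abs_snr"], g))

    a_all = matrix.values.loc[candidates, matrix.group_columns(TREATED)].to_numpy()
    b_all = matrix.values.loc[candidates, matrix.group_columns(VEHICLE)].to_numpy()
    pos = {g: i for i, g in enumerate(candidates)}

    selected: list[str] = []
    trace: list[float] = []
    best_acc = -np.inf
    while len(selected) < cap:
        best_gene, best_gene_acc = None, -np.inf
        for g in candidates:
            if g in selected:
                continue
            rows = [pos[x] for x in selected] + [pos[g]]
            acc = _loocv_arrays(a_all[rows], b_all[rows])
            # candidate order already encodes the |SNR| / gene-id tie-break
            if acc > best_gene_acc:
                best_gene, best_gene_acc = g, acc
        if best_gene is None or best_gene_acc <= best_acc:
            break
        selected.append(best_gene)
        trace.append(best_gene_acc)
        best_acc = best_gene_acc

    model = dlda_fit(matrix, selected)
    model.loocv_accuracy = best_acc
    model.selection_trace = trace
    return model


def divergence_reduce(matrix: ExpressionMatrix,
                      model: DLDAModel,
                      tolerance: float = 0.0) -> DLDAModel:
    """Reduce a signature to its smallest accurate divergent subset.

    Searches all subsets of the signature containing at least one up- and
    one down-regulated gene (sign of the treated-minus-vehicle mean
    difference) and returns the smallest whose LOOCV accuracy is at least
    the input model's accuracy minus ``tolerance``.  Ties prefer the higher
    summed |SNR|, then the lexicographically first gene tuple.  If no subset
    is divergent (all genes move the same way) the input model is returned
    with ``divergence_warning`` set.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    base_acc = model.loocv_accuracy
    if base_acc is None:
        base_acc = loocv_accuracy(matrix, model.genes)
    directions = model.directions
    snr_table = snr(ExpressionMatrix(matrix.values.loc[model.genes],
                                     matrix.design))
    up = [g for g in model.genes if directions[g] > 0]
    down = [g for g in model.genes if directions[g] < 0]
    if not up or not down:
        model.divergence_warning = True
        return model

    genes_sorted = sorted(model.genes)
    for size in range(2, len(model.genes) + 1):
        feasible = []
        for combo in itertools.combinations(genes_sorted, size):
            has_up = any(g in up for g in combo)
            has_down = any(g in down for g in combo)
            if not (has_up and has_down):
                continue
            acc = loocv_accuracy(matrix, list(combo))
            if acc >= base_acc - tolerance:
                score = sum(snr_table.at[g, "abs_snr"] for g in combo)
                feasible.append((-score, combo, acc))
        if feasible:
            feasible.sort(key=lambda rec: (rec[0], rec[1]))
            _, combo, acc = feasible[0]
            reduced = dlda_fit(matrix, list(combo))
            reduced.loocv_accuracy = acc
            reduced.selection_trace = list(model.selection_trace)
            return reduced
    # unreachable when up and down are both non-empty: the full set qualifies
    model.divergence_warning = True
    return model


def derive_signature(matrix: ExpressionMatrix,
                     alpha: float = 0.01,
                     cap: int = 7,
                     tolerance: float = 0.0) -> DLDAModel:
    """Full derivation: DE filter, SNR ranking, stepwise DLDA, reduction."""
    de = de_filter(matrix, alpha=alpha)
    snr_table = snr(matrix)
    model = forward_select(matrix, de, snr_table, cap=cap)
    return divergence_reduce(matrix, model, tolerance=tolerance)
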