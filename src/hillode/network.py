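"""GRN extraction from trained parameters and edge-recovery evaluation.

The trained field encodes a regulatory network.  At the activation centre
``g = 0.5 * 1`` both activations vanish and have unit slope, so the
Jacobian of the learned field (excluding the universal self-decay term)
has the closed form

    D = diag(ReLU(upsilon)) @ ( U_sums @ W_sums
                                + U_prods @ diag(exp(b_prods)) @ W_prods )

with ``D[i, j]`` the estimated effect of regulator *j* on target *i*.
This needs only model coefficients — no sensitivity analysis.  |D| ranks
candidate edges; the evaluation half scores that ranking against a
reference network: ROC AUC for edge existence, Spearman correlation of
out-degrees, the accuracy-maximizing threshold C_max with its TPR/TNR and
the sparsity it induces, and sign recovery on signed references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .errors import ArgumentError, DimensionError
from .grn import GroundTruthGRN
from .model import PREEXP_CLAMP, ModelParameters

__all__ = ["DynamicsMatrix", "EdgeEvaluation", "extract_dynamics_matrix",
           "auc_edge_recovery", "out_degree_correlation", "compute_cmax",
           "sign_accuracy", "evaluate_network", "write_edge_ranking"]


@dataclass(frozen=True)
class DynamicsMatrix:
    """n x n effect matrix; rows = targets, columns = regulators.

    Includes the ReLU(upsilon) scaling and is not normalized per gene, so
    two models over the same genes can be compared directly.  The diagonal
    is retained (self-effects beyond the universal decay) but excluded
    from edge-recovery metrics.
    """

    gene_ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        n = len(self.gene_ids)
        if D.shape != (n, n):
            raise DimensionError(f"D must be {n}x{n}, got {D.shape}")
        if not np.all(np.isfinite(D)):
            raise ArgumentError("D contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class EdgeEvaluation:
    auc: float | None
    rho_out: float | None
    c_max: float
    tpr_max: float
    tnr_max: float
    sparsity: float
    sign_accuracy: float | None = None


def extract_dynamics_matrix(params: ModelParameters) -> DynamicsMatrix:
    """Closed-form Jacobian of the learned field at g = 0.5, self-decay
    excluded."""
    inside = (np.abs(params.b_prods) <= PREEXP_CLAMP).astype(float)
    prod_term = params.U_prods @ (np.exp(np.clip(params.b_prods, -PREEXP_CLAMP,
                                                 PREEXP_CLAMP))[:, None]
                                  * inside[:, None] * params.W_prods)
    core = params.U_sums @ params.W_sums + prod_term
    u = np.maximum(params.upsilon, 0.0)
    return DynamicsMatrix(params.gene_ids, u[:, None] * core)


def _aligned_truth(dyn: DynamicsMatrix, truth: GroundTruthGRN) -> np.ndarray:
    if tuple(dyn.gene_ids) != tuple(truth.gene_ids):
        raise ArgumentError("dynamics matrix and reference network use different gene orders")
    return truth.adjacency()


def _offdiag_scores_labels(dyn: DynamicsMatrix, truth: GroundTruthGRN):
    A = _aligned_truth(dyn, truth)
    mask = ~np.eye(dyn.n_genes, dtype=bool)
    return np.abs(dyn.D[mask]), (A[mask] != 0).astype(int)


def auc_edge_recovery(dyn: DynamicsMatrix, truth: GroundTruthGRN) -> float | None:
    """ROC AUC of |D| for edge existence over ordered off-diagonal pairs."""
    scores, labels = _offdiag_scores_labels(dyn, truth)
    if labels.sum() == 0 or labels.sum() == labels.size:
        warnings.warn("degenerate reference network; AUC undefined")
        return None
    return float(roc_auc_score(labels, scores))


def out_degree_correlation(dyn: DynamicsMatrix, truth: GroundTruthGRN) -> float | None:
    """Spearman correlation between true out-degrees and the continuous
    out-degree proxy (off-diagonal column sums of |D|)."""
    _aligned_truth(dyn, truth)
    deg = truth.out_degrees().astype(float)
    absD = np.abs(dyn.D.copy())
    np.fill_diagonal(absD, 0.0)
    proxy = absD.sum(axis=0)
    if np.all(deg == deg[0]) or np.all(proxy == proxy[0]):
        warnings.warn("constant out-degree vector; correlation undefined")
        return None
    return float(spearmanr(deg, proxy).statistic)


def compute_cmax(dyn: DynamicsMatrix, truth: GroundTruthGRN) -> dict:
    """Accuracy-maximizing |D| threshold and the rates it induces.

    Candidate thresholds are the sorted unique |D| values; the classifier
    is ``|D_ij| >= c``.  Balanced accuracy (TPR + TNR)/2 is maximized —
    raw accuracy would collapse to the empty network under the extreme
    class imbalance of sparse references.  Ties break toward the larger
    threshold (the sparser network).  ``sparsity`` is the fraction of
    pairs classified as non-edges.
    """
    scores, labels = _offdiag_scores_labels(dyn, truth)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ArgumentError("reference network has no edges or no non-edges")
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    uniq, first_idx = np.unique(s_sorted, return_index=True)
    # pos_below[k] / neg_below[k]: counts strictly below threshold uniq[k]
    cum_pos = np.concatenate([[0], np.cumsum(l_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(1 - l_sorted)])
    pos_below = cum_pos[first_idx]
    neg_below = cum_neg[first_idx]
    tpr = (n_pos - pos_below) / n_pos
    tnr = neg_below / n_neg
    bal = (tpr + tnr) / 2.0
    best = np.flatnonzero(bal == bal.max())[-1]   # ties -> larger threshold
    c_max = float(uniq[best])
    return {
        "c_max": c_max,
        "tpr_max": float(tpr[best]),
        "tnr_max": float(tnr[best]),
        "sparsity": float(np.mean(scores < c_max)),
    }


def sign_accuracy(dyn: DynamicsMatrix, truth: GroundTruthGRN) -> float:
    """Fraction of true edges whose sign matches sign(D); zeros mismatch."""
    A = _aligned_truth(dyn, truth)
    if truth.n_edges == 0:
        raise ArgumentError("reference network has no edges")
    tgt, src = np.nonzero(A)
    return float(np.mean(np.sign(dyn.D[tgt, src]) == A[tgt, src]))


def evaluate_network(dyn: DynamicsMatrix, truth: GroundTruthGRN,
                     signed: bool = True) -> EdgeEvaluation:
    cm = compute_cmax(dyn, truth)
    return EdgeEvaluation(
        auc=auc_edge_recovery(dyn, truth),
        rho_out=out_degree_correlation(dyn, truth),
        c_max=cm["c_max"], tpr_max=cm["tpr_max"], tnr_max=cm["tnr_max"],
        sparsity=cm["sparsity"],
        sign_accuracy=sign_accuracy(dyn, truth) if signed else None,
    )


def write_edge_ranking(dyn: DynamicsMatrix, path, top: int | None = None) -> None:
    """Write ranked off-diagonal edges as TSV (source, target, score, sign)."""
    n = dyn.n_genes
    mask = ~np.eye(n, dtype=bool)
    tgt, src = np.nonzero(mask)
    scores = np.abs(dyn.D[tgt, src])
    order = np.argsort(-scores, kind="stable")
    if top is not None:
        order = order[:top]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tscore\tsign\n")
        for k in order:
            i, j = tgt[k], src[k]
            fh.write(f"{dyn.gene_ids[j]}\t{dyn.gene_ids[i]}\t"
                     f"{abs(dyn.D[i, j]):.8g}\t{int(np.sign(dyn.D[i, j]))}\n")
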