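"""Multivariate phylogenetic signal: the K_mult statistic.

K_mult generalises Blomberg's K to multivariate data (e.g. shape-space
principal-component scores) by replacing univariate sums of squares with
Euclidean norms; under Brownian motion on the given tree its expectation
is 1, values below 1 indicate less resemblance among relatives than BM
predicts.  Significance comes from permuting trait rows across tips.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .trees import Tree, phylo_cov

__all__ = ["SignalResult", "kmult"]


@dataclasses.dataclass(frozen=True)
class SignalResult:
    """K_mult statistic with its permutation test."""

    kmult: float
    p_value: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _kmult_stat(Y: np.ndarray, cho, C: np.ndarray, denom: float) -> float:
    n = Y.shape[0]
    ones = np.ones(n)
    Ci1 = cho_solve(cho, ones)
    a = (Ci1 @ Y) / (ones @ Ci1)  # phylogenetic mean, 1 x p
    Yc = Y - a
    num = float(np.sum(Yc * Yc))
    if num == 0.0:  # constant traits carry no signal
        return 0.0
    den = float(np.sum(Yc * cho_solve(cho, Yc)))
    return (num / den) / denom


def kmult(
    scores: pd.DataFrame | np.ndarray,
    tree: Tree,
    n_perm: int = 999,
    seed: int | None = None,
    labels: list[str] | None = None,
) -> SignalResult:
    """K_mult phylogenetic signal of a specimens x traits score matrix.

    Rows are matched to tree tips by label (DataFrame index, or ``labels``).
    The permutation p-value counts the observed statistic among the
    permuted ones, so its floor is ``1/(n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(scores, pd.DataFrame):
        idx = list(scores.index)
        missing = [t for t in tree.tip_labels if t not in idx]
        extra = [t for t in idx if t not in tree.tip_labels]
        if missing or extra:
            raise ValueError(
                f"tip/trait label mismatch; missing from scores: {missing[:5]}, "
                f"not in tree: {extra[:5]}"
            )
        Y = scores.loc[list(tree.tip_labels)].to_numpy(dtype=float)
    else:
        Y = np.asarray(scores, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if labels is not None:
            order = [labels.index(t) for t in tree.tip_labels]
            Y = Y[order]
        if Y.shape[0] != tree.n_tips:
            raise ValueError(f"{Y.shape[0]} score rows for {tree.n_tips} tips")

    C = phylo_cov(tree).matrix
    n = C.shape[0]
    try:
        cho = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance") from exc
    ones = np.ones(n)
    Ci1 = cho_solve(cho, ones)
    denom = (float(np.trace(C)) - n / float(ones @ Ci1)) / (n - 1)

    obs = _kmult_stat(Y, cho, C, denom)
    rng = np.random.default_rng(seed)
    count = 1  # the observed statistic is a member of its own null set
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _kmult_stat(Y[perm], cho, C, denom) >= obs:
            count += 1
    return SignalResult(
        kmult=float(obs),
        p_value=count / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )
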