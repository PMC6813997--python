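"""Brownian-motion and multi-peak Ornstein-Uhlenbeck models on painted trees.

The centrepiece is a two-phase stepwise search for adaptive regimes in the
spirit of the SURFACE method: a *forward* phase greedily adds regime shifts
(each introducing a brand-new selective optimum) at the origin of whichever
branch most improves the small-sample-corrected Akaike criterion (AICc), and
a *backward* phase greedily collapses pairs of regimes into one shared
(convergent) regime while that keeps improving AICc.

Model conventions
-----------------
Traits are treated as evolving independently: each trait has its own rate of
adaptation ``alpha``, diffusion ``sigma^2`` and per-regime optima ``theta_r``;
the model AICc is the sum of per-trait AICc values.  For a lineage *i* the
expected tip value is a weighted average of the optima it evolved under,

    E[y_i] = sum_r W_ir theta_r,

where the weight of regime *r* accumulates ``exp(-a (T - t_end)) -
exp(-a (T - t_start))`` over the lineage's time segments spent in *r*, and
the residual root weight ``exp(-a T)`` is assigned to the root regime (the
root state is anchored at the root-regime optimum).  The tip covariance on
an ultrametric tree of depth ``T`` is

    V_ij = sigma^2 / (2 a) * exp(-a d_ij) * (1 - exp(-2 a s_ij)),

with ``d_ij`` the patristic distance and ``s_ij`` the shared path length.
``sigma^2`` and the optima are profiled out in closed form (GLS); only
``alpha`` needs a 1-D numerical search.
"""
from __future__ import annotations

import dataclasses
import math
import string
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .trees import Tree, phylo_cov, patristic

__all__ = [
    "RegimePainting",
    "HansenFit",
    "SurfaceResult",
    "ModelError",
    "aicc",
    "bm_fit",
    "hansen_loglik",
    "hansen_fit",
    "surface_forward",
    "surface_backward",
    "surface",
]

_ALPHA_FLOOR = 1e-8
LOG2PI = math.log(2.0 * math.pi)


class ModelError(ValueError):
    """Raised for degenerate data or invalid model configurations."""


# ----------------------------------------------------------------------
# regime paintings


@dataclasses.dataclass(frozen=True)
class RegimePainting:
    """Assignment of every branch of a tree to an adaptive regime.

    ``branch_regimes`` maps each non-root node id to the regime of the
    branch above it; ``root_regime`` is the regime of the (zero-length)
    root stem.  A *shift* is a branch whose regime differs from its
    parent's branch regime; shifts are where new regimes originate.
    """

    branch_regimes: Mapping[int, str]
    root_regime: str

    @staticmethod
    def from_shifts(
        tree: Tree, shifts: Mapping[int, str], root_regime: str = "a"
    ) -> "RegimePainting":
        """Paint a tree from a shift map (node id -> new regime label).

        Each shifted branch and all its descendants take the new regime
        until overridden by a more recent shift.  Shifts whose label equals
        the regime already flowing down the parent branch are vacuous and
        simply absorbed.
        """
        regimes: dict[int, str] = {}
        for v in tree.preorder():
            if v == tree.root:
                continue
            p = int(tree.parent[v])
            inherited = root_regime if p == tree.root else regimes[p]
            regimes[v] = shifts.get(v, inherited)
        return RegimePainting(branch_regimes=regimes, root_regime=root_regime)

    def shifts(self, tree: Tree) -> dict[int, str]:
        """Effective shift map: branches whose regime differs from the parent's."""
        out: dict[int, str] = {}
        for v in tree.preorder():
            if v == tree.root:
                continue
            p = int(tree.parent[v])
            parent_reg = (
                self.root_regime if p == tree.root else self.branch_regimes[p]
            )
            if self.branch_regimes[v] != parent_reg:
                out[v] = self.branch_regimes[v]
        return out

    def regime_labels(self) -> tuple[str, ...]:
        """Distinct regime labels, root regime first then by first use in pre-order."""
        seen = [self.root_regime]
        for v in sorted(self.branch_regimes):
            r = self.branch_regimes[v]
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    def validate(self, tree: Tree) -> None:
        missing = [v for v in tree.preorder() if v != tree.root and v not in self.branch_regimes]
        if missing:
            raise ModelError(f"unpainted branches: {missing[:5]}")

    def to_branch_table(self, tree: Tree) -> pd.DataFrame:
        """Branch table (child node id, tip label if any, regime) for serialisation."""
        rows = [
            {
                "node": v,
                "tip_label": tree.labels.get(v, ""),
                "regime": self.branch_regimes[v],
            }
            for v in sorted(self.branch_regimes)
        ]
        return pd.DataFrame(rows)

    def to_annotated_newick(self, tree: Tree) -> str:
        """Newick with the regime of each branch in a comment after its length."""

        def emit(v: int) -> str:
            if not tree.children[v]:
                base = tree.labels[v]
            else:
                base = "(" + ",".join(emit(c) for c in tree.children[v]) + ")"
            if v == tree.root:
                return base + f"[&regime={self.root_regime}]"
            return f"{base}:{tree.blen[v]:.17g}[&regime={self.branch_regimes[v]}]"

        return emit(tree.root) + ";"


def _regime_label(i: int) -> str:
    """0 -> 'a', 1 -> 'b', ..., 26 -> 'aa', ..."""
    letters = string.ascii_lowercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


# ----------------------------------------------------------------------
# information criterion


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``-2 logL + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if n <= k + 1:
        raise ModelError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ----------------------------------------------------------------------
# likelihood plumbing


class TreeLikelihoodContext:
    """Per-tree precomputation shared by all BM/OU likelihood evaluations."""

    def __init__(self, tree: Tree):
        self.tree = tree
        cov = phylo_cov(tree)
        self.S = cov.matrix
        self.T = cov.depth
        self.D = patristic(tree)
        self.n = tree.n_tips
        # edge table: (child node, start depth, end depth, tip rows below)
        self.edges: list[tuple[int, float, float, np.ndarray]] = []
        for v in tree.preorder():
            if v == tree.root:
                continue
            p = int(tree.parent[v])
            self.edges.append(
                (v, float(tree.depths[p]), float(tree.depths[v]), tree.subtree_tip_rows(v))
            )
        self._chol_S: tuple | None = None

    def chol_S(self):
        if self._chol_S is None:
            try:
                self._chol_S = cho_factor(self.S, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ModelError("singular phylogenetic covariance") from exc
        return self._chol_S

    def design_weights(self, painting_idx: np.ndarray, root_idx: int, n_regimes: int, alpha: float) -> np.ndarray:
        """OU design matrix W (tips x regimes); rows sum to 1."""
        a, T = alpha, self.T
        W = np.zeros((self.n, n_regimes))
        for (v, t0, t1, tips) in self.edges:
            w = math.exp(-a * (T - t1)) - math.exp(-a * (T - t0))
            W[tips, painting_idx[v]] += w
        W[:, root_idx] += math.exp(-a * T)
        return W

    def ou_cov_unit(self, alpha: float) -> np.ndarray:
        """OU tip covariance for sigma^2 = 1: exp(-a d)(1 - exp(-2 a s)) / (2a)."""
        a = alpha
        return np.exp(-a * self.D) * (-np.expm1(-2.0 * a * self.S)) / (2.0 * a)


def _gls_profile(y: np.ndarray, X: np.ndarray, V0_cho) -> tuple[float, float, np.ndarray]:
    """Profile GLS fit of y on design X under covariance sigma^2 * V0.

    Returns (logL at the ML sigma^2, sigma^2_hat, coefficient vector).
    """
    n = y.size
    Vi_y = cho_solve(V0_cho, y)
    Vi_X = cho_solve(V0_cho, X)
    A = X.T @ Vi_X
    try:
        beta = np.linalg.solve(A, X.T @ Vi_y)
    except np.linalg.LinAlgError as exc:
        raise ModelError("rank-deficient design (a regime has no weight)") from exc
    if not np.all(np.isfinite(beta)):
        # near-singular design can yield non-finite solutions without
        # LAPACK reporting failure
        raise ModelError("rank-deficient design (non-finite GLS solution)")
    r = y - X @ beta
    q = float(r @ cho_solve(V0_cho, r))
    if q <= 0.0 or not np.isfinite(q):
        raise ModelError("degenerate data: zero residual variance under the model")
    sigma2 = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(V0_cho[0]))))
    logL = -0.5 * n * LOG2PI - 0.5 * n * math.log(sigma2) - 0.5 * logdet - 0.5 * n
    return logL, sigma2, beta


# ----------------------------------------------------------------------
# Brownian motion


def bm_fit(trait: np.ndarray, tree: Tree, *, _ctx: TreeLikelihoodContext | None = None):
    """ML Brownian-motion fit of a single trait.

    Returns ``(root_estimate, sigma2, logL, AICc)`` with the root state the
    GLS phylogenetic mean and ``sigma2`` the ML estimator (divisor N).
    """
    ctx = _ctx or TreeLikelihoodContext(tree)
    y = np.asarray(trait, dtype=float)
    if y.size != ctx.n:
        raise ModelError(f"trait length {y.size} != {ctx.n} tips")
    ones = np.ones((ctx.n, 1))
    logL, sigma2, beta = _gls_profile(y, ones, ctx.chol_S())
    # AICc is undefined below n = 4 tips (k = 2); report NaN there
    ic = aicc(logL, 2, ctx.n) if ctx.n > 3 else math.nan
    return float(beta[0]), float(sigma2), float(logL), ic


# ----------------------------------------------------------------------
# Hansen (multi-peak OU) model


def _painting_arrays(tree: Tree, painting: RegimePainting) -> tuple[np.ndarray, int, tuple[str, ...]]:
    labels = painting.regime_labels()
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    idx = np.full(tree.n_nodes, -1, dtype=np.int64)
    for v, lab in painting.branch_regimes.items():
        idx[v] = lab_idx[lab]
    return idx, lab_idx[painting.root_regime], labels


def hansen_loglik(
    trait: np.ndarray,
    tree: Tree,
    painting: RegimePainting,
    alpha: float,
    *,
    _ctx: TreeLikelihoodContext | None = None,
    _arrays: tuple | None = None,
):
    """Profile log-likelihood of a single trait under a painted OU model.

    ``sigma^2`` and the regime optima are maximised analytically for the
    given ``alpha``.  Returns ``(logL, sigma2_hat, theta_hat)`` with
    ``theta_hat`` a dict regime label -> optimum.
    """
    ctx = _ctx or TreeLikelihoodContext(tree)
    if not tree.is_ultrametric():
        raise ModelError("OU covariance requires an ultrametric tree")
    if not (alpha > 0):
        raise ModelError("alpha must be positive")
    painting_idx, root_idx, labels = _arrays or _painting_arrays(tree, painting)
    y = np.asarray(trait, dtype=float)
    W = ctx.design_weights(painting_idx, root_idx, len(labels), alpha)
    col_tot = W.sum(axis=0)
    if np.any(col_tot <= 1e-12):
        bad = [labels[i] for i in np.flatnonzero(col_tot <= 1e-12)]
        raise ModelError(f"regime(s) with zero design weight: {bad}")
    V0 = ctx.ou_cov_unit(alpha)
    try:
        cho = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"OU covariance not positive definite at alpha={alpha}") from exc
    logL, sigma2, beta = _gls_profile(y, W, cho)
    theta = {lab: float(b) for lab, b in zip(labels, beta)}
    return float(logL), float(sigma2), theta


@dataclasses.dataclass
class HansenFit:
    """Fitted multi-peak OU model (independent traits).

    Per-trait arrays are indexed like ``trait_names``; ``theta`` is a
    DataFrame (regimes x traits).  ``half_life`` is ``ln 2 / alpha`` in the
    tree's time units.
    """

    trait_names: tuple[str, ...]
    regime_labels: tuple[str, ...]
    alpha: np.ndarray
    sigma2: np.ndarray
    theta: pd.DataFrame
    loglik: np.ndarray
    aicc_per_trait: np.ndarray
    aicc: float
    n_tips: int
    n_regimes: int

    @property
    def half_life(self) -> np.ndarray:
        return np.log(2.0) / self.alpha


def _fit_alpha_one_trait(y, ctx, painting_idx, root_idx, n_regimes, labels, grid_size=8):
    """Maximise the profile likelihood over alpha on a log scale."""
    lo, hi = math.log(_ALPHA_FLOOR), math.log(1e3 / ctx.T)

    BAD = 1e300  # finite penalty keeps the bounded minimiser well-behaved

    def neg(loga: float) -> float:
        a = math.exp(loga)
        W = ctx.design_weights(painting_idx, root_idx, n_regimes, a)
        if np.any(W.sum(axis=0) <= 1e-12):
            return BAD
        V0 = ctx.ou_cov_unit(a)
        try:
            cho = cho_factor(V0, lower=True)
            logL, _, _ = _gls_profile(y, W, cho)
        except (np.linalg.LinAlgError, ModelError):
            return BAD
        return -logL

    grid = np.linspace(lo, hi, grid_size)
    vals = np.array([neg(g) for g in grid])
    if not np.any(vals < BAD):
        raise ModelError("alpha search failed: likelihood undefined on the whole grid")
    best = int(np.argmin(vals))
    blo = grid[max(best - 1, 0)]
    bhi = grid[min(best + 1, grid_size - 1)]
    if blo == bhi:
        opt_loga = grid[best]
    else:
        res = minimize_scalar(neg, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-3})
        opt_loga = res.x if res.fun <= vals[best] else grid[best]
    return math.exp(float(opt_loga))


def hansen_fit(
    traits: np.ndarray | pd.DataFrame,
    tree: Tree,
    painting: RegimePainting,
    *,
    _ctx: TreeLikelihoodContext | None = None,
) -> HansenFit:
    """Fit the multi-peak OU model, one independent fit per trait column.

    Per trait, ``alpha`` is optimised by a bounded search on a log scale
    (coarse grid then Brent refinement); ``sigma^2`` and the optima are
    profiled analytically.  Per-trait parameter count is ``2 + R`` (alpha,
    sigma^2, one optimum per regime); the model AICc is the sum over traits.
    """
    ctx = _ctx or TreeLikelihoodContext(tree)
    Y, names = _as_matrix(traits, tree)
    painting_idx, root_idx, labels = _painting_arrays(tree, painting)
    R = len(labels)
    alphas, sigmas, logLs, aiccs = [], [], [], []
    theta_rows = []
    for j in range(Y.shape[1]):
        y = Y[:, j]
        a_hat = _fit_alpha_one_trait(y, ctx, painting_idx, root_idx, R, labels)
        logL, s2, theta = hansen_loglik(
            y, tree, painting, a_hat, _ctx=ctx, _arrays=(painting_idx, root_idx, labels)
        )
        alphas.append(a_hat)
        sigmas.append(s2)
        logLs.append(logL)
        aiccs.append(aicc(logL, 2 + R, ctx.n))
        theta_rows.append([theta[lab] for lab in labels])
    theta_df = pd.DataFrame(
        np.asarray(theta_rows).T, index=list(labels), columns=list(names)
    )
    return HansenFit(
        trait_names=tuple(names),
        regime_labels=labels,
        alpha=np.asarray(alphas),
        sigma2=np.asarray(sigmas),
        theta=theta_df,
        loglik=np.asarray(logLs),
        aicc_per_trait=np.asarray(aiccs),
        aicc=float(np.sum(aiccs)),
        n_tips=ctx.n,
        n_regimes=R,
    )


def _as_matrix(traits, tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Coerce traits to an array in tree tip order, with column names."""
    if isinstance(traits, pd.DataFrame):
        missing = [t for t in tree.tip_labels if t not in traits.index]
        if missing:
            raise ModelError(f"traits missing for tips: {missing[:5]}")
        Y = traits.loc[list(tree.tip_labels)].to_numpy(dtype=float)
        names = [str(c) for c in traits.columns]
    else:
        Y = np.asarray(traits, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != tree.n_tips:
            raise ModelError(f"traits have {Y.shape[0]} rows for {tree.n_tips} tips")
        names = [f"trait{j + 1}" for j in range(Y.shape[1])]
    if not np.all(np.isfinite(Y)):
        raise ModelError("traits contain non-finite values")
    return Y, names


# ----------------------------------------------------------------------
# stepwise SURFACE-style search


@dataclasses.dataclass
class SurfaceResult:
    """Outcome of the two-phase stepwise regime search.

    ``n_shifts`` counts branches where a regime originates (the root regime
    does not count as a shift); a regime is *convergent* when two or more
    shifts lead into it, and ``convergence_fraction`` is the fraction of
    all shifts that lead into convergent regimes.
    """

    painting: RegimePainting
    fit: HansenFit
    fit_ou1: HansenFit
    bm_aicc: float
    bm_loglik: float
    forward_history: list[dict]
    backward_history: list[dict]
    n_shifts: int
    n_regimes: int
    n_convergent_regimes: int
    n_convergent_shifts: int
    convergence_fraction: float
    shift_branches: dict[int, str]

    def summary(self) -> dict:
        """Flat JSON-serialisable model-comparison summary."""
        fit = self.fit
        per_trait = {
            name: {
                "alpha": float(fit.alpha[j]),
                "half_life": float(fit.half_life[j]),
                "sigma2": float(fit.sigma2[j]),
                "theta": {r: float(fit.theta.loc[r, name]) for r in fit.regime_labels},
            }
            for j, name in enumerate(fit.trait_names)
        }
        return {
            "aicc_multipeak_ou": float(fit.aicc),
            "aicc_ou1": float(self.fit_ou1.aicc),
            "aicc_bm": float(self.bm_aicc),
            "n_regimes": self.n_regimes,
            "n_shifts": self.n_shifts,
            "n_convergent_regimes": self.n_convergent_regimes,
            "n_convergent_shifts": self.n_convergent_shifts,
            "convergence_fraction": self.convergence_fraction,
            "per_trait": per_trait,
        }


def count_convergence(tree: Tree, painting: RegimePainting) -> dict:
    """Shift/regime bookkeeping for a painting.

    Shifts are branches where the regime changes relative to the parent
    branch; a regime entered by >= 2 shifts is convergent (the root origin
    of the root regime is not a shift, so a regime holding the root plus a
    single shifted clade is not convergent).
    """
    shifts = painting.shifts(tree)
    k = len(shifts)
    mult: dict[str, int] = {}
    for lab in shifts.values():
        mult[lab] = mult.get(lab, 0) + 1
    convergent = sorted(lab for lab, m in mult.items() if m >= 2)
    c = sum(mult[lab] for lab in convergent)
    return {
        "n_shifts": k,
        "n_regimes": len(painting.regime_labels()),
        "convergent_regimes": convergent,
        "n_convergent_regimes": len(convergent),
        "n_convergent_shifts": c,
        "convergence_fraction": (c / k) if k else 0.0,
    }


def surface_forward(
    traits,
    tree: Tree,
    *,
    max_shifts: int | None = None,
    _ctx: TreeLikelihoodContext | None = None,
) -> tuple[RegimePainting, list[dict]]:
    """Forward phase: greedily add regime shifts while AICc improves.

    Starts from a single-regime OU model and, at each step, evaluates
    placing a brand-new regime at the origin of every non-root branch not
    already bearing a shift; the candidate with the largest AICc decrease
    is retained (pre-order position breaks ties).  Stops when no candidate
    improves AICc.
    """
    ctx = _ctx or TreeLikelihoodContext(tree)
    Y, _ = _as_matrix(traits, tree)
    if not 1 <= Y.shape[1] <= 4:
        raise ModelError("the regime search expects 1-4 trait columns")
    shifts: dict[int, str] = {}
    painting = RegimePainting.from_shifts(tree, shifts)
    current = hansen_fit(Y, tree, painting, _ctx=ctx).aicc
    history = [{"step": 0, "branch": None, "aicc": current}]
    preord = [v for v in tree.preorder() if v != tree.root]
    while max_shifts is None or len(shifts) < max_shifts:
        new_label = _regime_label(len(shifts) + 1)
        best_aicc, best_branch = current, None
        for v in preord:
            if v in shifts:
                continue
            cand = RegimePainting.from_shifts(tree, {**shifts, v: new_label})
            try:
                a = hansen_fit(Y, tree, cand, _ctx=ctx).aicc
            except ModelError:
                continue
            if a < best_aicc - 1e-10:
                best_aicc, best_branch = a, v
        if best_branch is None:
            break
        shifts[best_branch] = new_label
        current = best_aicc
        history.append({"step": len(history), "branch": best_branch, "aicc": current})
    return RegimePainting.from_shifts(tree, shifts), history


def surface_backward(
    traits,
    tree: Tree,
    painting: RegimePainting,
    *,
    _ctx: TreeLikelihoodContext | None = None,
) -> SurfaceResult:
    """Backward phase: greedily collapse regime pairs while AICc improves.

    Every unordered pair of regimes currently in use is tried: one label is
    rewritten to the other, the model refitted, and the best improvement
    accepted; repeated until no collapse improves AICc.  Regimes entered by
    two or more shifts in the final model are the convergent regimes.
    """
    ctx = _ctx or TreeLikelihoodContext(tree)
    Y, _ = _as_matrix(traits, tree)
    shifts = dict(painting.shifts(tree))
    root_reg = painting.root_regime
    cur_painting = RegimePainting.from_shifts(tree, shifts, root_reg)
    cur_fit = hansen_fit(Y, tree, cur_painting, _ctx=ctx)
    history: list[dict] = [{"step": 0, "merge": None, "aicc": cur_fit.aicc}]
    while True:
        labels = cur_painting.regime_labels()
        best = None  # (aicc, fit, shifts, painting, merge)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                # rewrite the later label into the earlier one
                src, dst = labels[j], labels[i]
                cand_shifts = {
                    v: (dst if lab == src else lab) for v, lab in shifts.items()
                }
                cand_root = dst if root_reg == src else root_reg
                cand = RegimePainting.from_shifts(tree, cand_shifts, cand_root)
                try:
                    fit = hansen_fit(Y, tree, cand, _ctx=ctx)
                except ModelError:
                    continue
                if fit.aicc < cur_fit.aicc - 1e-10 and (
                    best is None or fit.aicc < best[0] - 1e-10
                ):
                    best = (fit.aicc, fit, cand_shifts, cand, (src, dst))
        if best is None:
            break
        _, cur_fit, shifts, cur_painting, merge = best
        shifts = dict(cur_painting.shifts(tree))  # drop shifts made vacuous
        root_reg = cur_painting.root_regime
        history.append(
            {"step": len(history), "merge": merge, "aicc": cur_fit.aicc}
        )
    # comparison models
    ou1 = hansen_fit(Y, tree, RegimePainting.from_shifts(tree, {}, root_reg), _ctx=ctx)
    bm_ll = 0.0
    bm_ic = 0.0
    for j in range(Y.shape[1]):
        _, _, ll, ic = bm_fit(Y[:, j], tree, _ctx=ctx)
        bm_ll += ll
        bm_ic += ic
    counts = count_convergence(tree, cur_painting)
    return SurfaceResult(
        painting=cur_painting,
        fit=cur_fit,
        fit_ou1=ou1,
        bm_aicc=bm_ic,
        bm_loglik=bm_ll,
        forward_history=[],
        backward_history=history,
        n_shifts=counts["n_shifts"],
        n_regimes=counts["n_regimes"],
        n_convergent_regimes=counts["n_convergent_regimes"],
        n_convergent_shifts=counts["n_convergent_shifts"],
        convergence_fraction=counts["convergence_fraction"],
        shift_branches=dict(cur_painting.shifts(tree)),
    )


def surface(traits, tree: Tree, *, max_shifts: int | None = None) -> SurfaceResult:
    """Full two-phase stepwise regime search (forward then backward)."""
    ctx = TreeLikelihoodContext(tree)
    painting, fwd = surface_forward(traits, tree, max_shifts=max_shifts, _ctx=ctx)
    res = surface_backward(traits, tree, painting, _ctx=ctx)
    res.forward_history = fwd
    return res
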