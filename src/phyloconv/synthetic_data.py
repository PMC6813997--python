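"""Synthetic datasets with the statistical structure the analyses assume.

Every stage of the pipeline can be exercised without any external download:
pure-birth (Yule) ultrametric trees, regime paintings with planted
convergent shifts, traits evolved under Brownian motion or multi-peak
Ornstein-Uhlenbeck processes with known parameters, landmark configurations
built from a smooth 3-D curve plus group-specific deformation and noise,
and ecology tables whose categories are correlated with regime membership.

Desk-scale defaults mirror the study system this emulates: a few dozen tips
on a tree ~36 time units deep (an odontocete-like timescale), 2 traits for
the regime search and up to 30 for the distance-based metrics.  All
generators are bit-reproducible from a single integer seed; sub-streams are
derived deterministically per operation.
"""
from __future__ import annotations

import dataclasses
import json
import random
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .ecology_assoc import DIETS, DIVES, FEEDING, HABITATS, EcologyTable
from .morphometrics import LandmarkSet, SemilandmarkScheme, write_pts
from .regime_models import RegimePainting
from .trees import Tree

__all__ = [
    "SyntheticDataset",
    "simulate_tree",
    "paint_random_shifts",
    "simulate_bm",
    "simulate_hansen",
    "simulate_landmarks",
    "simulate_ecology",
    "make_convergence_dataset",
    "recovered_convergent_pair",
    "default_scheme",
    "save_dataset",
]

DEFAULT_N_TIPS = 32
DEFAULT_DEPTH = 36.0  # time units; matches the clade age the study spans


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# trees


def simulate_tree(
    n_tips: int = DEFAULT_N_TIPS,
    depth: float = DEFAULT_DEPTH,
    seed: int | None = None,
) -> Tree:
    """Pure-birth (Yule) tree rescaled to an exact root-to-tip depth."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(_as_rng(seed).integers(0, 2**31)))
    from dendropy.model import birthdeath

    dtree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    parent: list[int] = []
    blen: list[float] = []
    labels: dict[int, str] = {}
    index: dict[int, int] = {}
    tip_counter = 0
    for nd in dtree.preorder_node_iter():
        my = len(parent)
        index[id(nd)] = my
        if nd.parent_node is None:
            parent.append(-1)
            blen.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            blen.append(float(nd.edge.length or 0.0))
        if nd.is_leaf():
            tip_counter += 1
            labels[my] = f"t{tip_counter:02d}"
    # exact ultrametry: scale every root-to-tip path to `depth`
    parent_a = np.asarray(parent)
    blen_a = np.asarray(blen, dtype=float)
    depths = np.zeros(len(parent))
    order = _preorder(parent_a)
    for v in order:
        if parent_a[v] >= 0:
            depths[v] = depths[parent_a[v]] + blen_a[v]
    tipset = [v for v in range(len(parent)) if v in labels]
    mean_depth = depths[tipset].mean()
    scale = depth / mean_depth if mean_depth > 0 else 0.0
    blen_a *= scale
    depths *= scale
    # absorb residual per-tip rounding into terminal branches
    for v in tipset:
        blen_a[v] += depth - depths[v]
    blen_a = np.maximum(blen_a, 1e-12)
    return Tree(parent_a, blen_a, labels)


def _preorder(parent: np.ndarray) -> list[int]:
    children: dict[int, list[int]] = {}
    root = -1
    for v, p in enumerate(parent):
        if p < 0:
            root = v
        else:
            children.setdefault(int(p), []).append(v)
    order, stack = [], [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children.get(v, [])))
    return order


# ----------------------------------------------------------------------
# paintings


def paint_random_shifts(
    tree: Tree,
    n_shifts: int,
    n_convergent_pairs: int = 0,
    seed: int | None = None,
    min_tips_per_shift: int = 2,
    max_origin_frac: float | None = None,
) -> RegimePainting:
    """Random regime painting with a known number of shifts.

    Shift branches are drawn without ancestor/descendant conflicts (no
    shift sits inside another shift's clade) and never jointly cover every
    tip, so the root regime always retains tips of its own (a painting
    whose shifted clades partition all tips is statistically
    non-identifiable).  The first ``2 * n_convergent_pairs`` shifts are
    paired to share a regime label — convergent by construction.

    ``max_origin_frac`` optionally restricts shift branches to those
    originating within the oldest given fraction of tree depth, so planted
    regimes have time to express their optima.
    """
    if 2 * n_convergent_pairs > n_shifts:
        raise ValueError("more convergent pairs than shifts allow")
    rng = _as_rng(seed)
    candidates = [
        v
        for v in tree.preorder()
        if v != tree.root and len(tree.subtree_tip_rows(v)) >= min_tips_per_shift
        and len(tree.subtree_tip_rows(v)) <= tree.n_tips - min_tips_per_shift
        and (
            max_origin_frac is None
            or tree.depths[int(tree.parent[v])] <= max_origin_frac * tree.depth
        )
    ]
    chosen: list[int] = []
    anc_cache: dict[int, set[int]] = {}

    def ancestors(v: int) -> set[int]:
        if v not in anc_cache:
            out, x = set(), v
            while x >= 0:
                out.add(x)
                x = int(tree.parent[x])
            anc_cache[v] = out
        return anc_cache[v]

    covered = 0
    order = rng.permutation(len(candidates))
    for i in order:
        if len(chosen) == n_shifts:
            break
        v = candidates[int(i)]
        if any(v in ancestors(u) or u in ancestors(v) for u in chosen):
            continue
        n_below = len(tree.subtree_tip_rows(v))
        if covered + n_below > tree.n_tips - min_tips_per_shift:
            continue  # keep tips for the root regime (identifiability)
        chosen.append(v)
        covered += n_below
    if len(chosen) < n_shifts:
        raise ValueError(
            f"could not place {n_shifts} non-nested shifts on this tree "
            f"(managed {len(chosen)})"
        )
    labels: dict[int, str] = {}
    lab_i = 0
    letters = "bcdefghijklmnopqrstuvwxyz"
    for pair in range(n_convergent_pairs):
        lab = letters[lab_i]
        lab_i += 1
        labels[chosen[2 * pair]] = lab
        labels[chosen[2 * pair + 1]] = lab
    for v in chosen[2 * n_convergent_pairs :]:
        labels[v] = letters[lab_i]
        lab_i += 1
    return RegimePainting.from_shifts(tree, labels, root_regime="a")


# ----------------------------------------------------------------------
# trait evolution


def simulate_bm(
    tree: Tree,
    rate: np.ndarray | float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    root: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Multivariate Brownian motion on the tree: tips x m trait matrix.

    Increments along each branch are Gaussian with covariance
    ``branch_length * R``; the root state defaults to 0.
    """
    rng = rng if rng is not None else _as_rng(seed)
    R = np.atleast_2d(np.asarray(rate, dtype=float))
    m = R.shape[0]
    w = np.linalg.eigvalsh(0.5 * (R + R.T))
    if w.min() < -1e-9 * max(abs(w).max(), 1.0):
        raise ValueError("rate matrix must be positive semidefinite")
    Lc = _psd_cholesky(R)
    states = np.zeros((tree.n_nodes, m))
    states[tree.root] = np.broadcast_to(np.asarray(root, dtype=float), (m,))
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        z = rng.standard_normal(m)
        states[v] = states[p] + np.sqrt(tree.blen[v]) * (Lc @ z)
    out = np.empty((tree.n_tips, m))
    for v, lab in zip(tree.tips, tree.tip_labels):
        out[tree.tip_index(lab)] = states[v]
    return out


def _psd_cholesky(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(0.5 * (R + R.T))
        return Q @ np.diag(np.sqrt(np.maximum(w, 0.0)))


def simulate_hansen(
    tree: Tree,
    painting: RegimePainting,
    alpha,
    sigma2,
    theta: Mapping[str, float | np.ndarray],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multi-peak OU traits by exact branch-wise transition sampling.

    Along a branch of length *t* in regime *r*,

        x_child ~ N(theta_r + (x_parent - theta_r) e^{-a t},
                    s2 / (2 a) (1 - e^{-2 a t})),

    with the root started at the root regime's optimum.  ``alpha``,
    ``sigma2`` may be scalars or length-m arrays; ``theta`` maps each
    regime label to a scalar or length-m optimum.
    """
    rng = rng if rng is not None else _as_rng(seed)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    m = max(alpha.size, sigma2.size, *(np.atleast_1d(v).size for v in theta.values()))
    alpha = np.broadcast_to(alpha, (m,))
    sigma2 = np.broadcast_to(sigma2, (m,))
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    th = {}
    for lab, val in theta.items():
        th[lab] = np.broadcast_to(np.atleast_1d(np.asarray(val, dtype=float)), (m,))
    for lab in set(painting.branch_regimes.values()) | {painting.root_regime}:
        if lab not in th:
            raise ValueError(f"no optimum supplied for regime {lab!r}")
    states = np.zeros((tree.n_nodes, m))
    states[tree.root] = th[painting.root_regime]
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        t = tree.blen[v]
        mu_r = th[painting.branch_regimes[v]]
        decay = np.exp(-alpha * t)
        mean = mu_r + (states[p] - mu_r) * decay
        var = sigma2 / (2.0 * alpha) * (-np.expm1(-2.0 * alpha * t))
        states[v] = mean + np.sqrt(var) * rng.standard_normal(m)
    out = np.empty((tree.n_tips, m))
    for v, lab in zip(tree.tips, tree.tip_labels):
        out[tree.tip_index(lab)] = states[v]
    return out


# ----------------------------------------------------------------------
# landmarks


def default_scheme(n_curves: int = 4, points_per_curve: int = 5) -> SemilandmarkScheme:
    """Contiguous curves covering ``n_curves * points_per_curve`` landmarks."""
    curves, k = [], 0
    for _ in range(n_curves):
        curves.append(list(range(k, k + points_per_curve)))
        k += points_per_curve
    return SemilandmarkScheme(curves=curves)


def _base_curve(L: int) -> np.ndarray:
    """Smooth helix-like 3-D template curve (loosely cochlear in spirit)."""
    t = np.linspace(0.0, 3.0 * np.pi, L)
    r = 1.0 - 0.18 * t / (3.0 * np.pi) * t / np.pi
    return np.column_stack([r * np.cos(t), r * np.sin(t), 0.35 * t / np.pi])


def simulate_landmarks(
    n_specimens: int,
    scheme: SemilandmarkScheme,
    groups: list[int] | None = None,
    deformation_scale: float = 0.15,
    noise_sd: float = 0.01,
    seed: int | None = None,
    rigid_motion: bool = True,
) -> LandmarkSet:
    """Landmark configurations from a template curve plus group deformation.

    Each group receives a smooth low-frequency sinusoidal deformation field
    of amplitude ``deformation_scale``; iid Gaussian coordinate noise of sd
    ``noise_sd`` is added per specimen; finally each specimen is randomly
    rotated (proper rotation), translated and scaled so the alignment has
    something to undo.
    """
    rng = _as_rng(seed)
    L = scheme.n_landmarks
    base = _base_curve(L)
    if groups is None:
        groups = [0] * n_specimens
    if len(groups) != n_specimens:
        raise ValueError("groups length != n_specimens")
    g_ids = sorted(set(groups))
    fields = {}
    for g in g_ids:
        coef = rng.normal(scale=deformation_scale, size=(3, 3))
        phase = rng.uniform(0, 2 * np.pi, size=3)
        t = np.linspace(0, 1, L)
        disp = np.zeros_like(base)
        for ax in range(3):
            disp[:, ax] = (
                coef[ax, 0] * np.sin(2 * np.pi * t + phase[ax])
                + coef[ax, 1] * np.cos(4 * np.pi * t + phase[ax])
                + coef[ax, 2] * t
            )
        fields[g] = disp
    coords = np.empty((n_specimens, L, 3))
    for i in range(n_specimens):
        x = base + fields[groups[i]] + rng.normal(scale=noise_sd, size=(L, 3))
        if rigid_motion:
            A = rng.standard_normal((3, 3))
            Q, Rq = np.linalg.qr(A)
            Q *= np.sign(np.diag(Rq))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1.0
            s = float(np.exp(rng.normal(scale=0.3)))
            tsl = rng.normal(scale=2.0, size=3)
            x = s * x @ Q + tsl
        coords[i] = x
    return LandmarkSet(labels=[f"s{i + 1:02d}" for i in range(n_specimens)], coords=coords)


# ----------------------------------------------------------------------
# ecology


def simulate_ecology(
    tree: Tree,
    painting: RegimePainting,
    strength: float = 0.9,
    seed: int | None = None,
) -> EcologyTable:
    """Species ecology correlated with regime membership.

    With probability ``strength`` a species takes its regime's preferred
    category for each factor, otherwise a uniformly random one.  Ambiguous
    (multi-valued) habitat/dive cells appear with probability
    ``0.2 * (1 - strength)``, so ``strength = 1`` is fully deterministic.
    Body masses are log-normal with a regime-specific median.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = _as_rng(seed)
    tip_regime = {
        lab: painting.branch_regimes[v] for v, lab in zip(tree.tips, tree.tip_labels)
    }
    regimes = sorted(set(tip_regime.values()))
    prefs = {}
    for i, r in enumerate(regimes):
        prefs[r] = {
            "habitat": HABITATS[i % len(HABITATS)],
            "diet": DIETS[i % len(DIETS)],
            "feeding": FEEDING[i % len(FEEDING)],
            "dive": DIVES[i % len(DIVES)],
            "log_mass": 2.0 + 1.5 * i,
        }
    domains = {"habitat": HABITATS, "diet": DIETS, "feeding": FEEDING, "dive": DIVES}
    amb_p = 0.2 * (1.0 - strength)
    rows = {}
    for sp in tree.tip_labels:
        r = tip_regime[sp]
        rec = {}
        for f, dom in domains.items():
            if rng.random() < strength:
                cat = prefs[r][f]
            else:
                cat = dom[int(rng.integers(len(dom)))]
            if f in ("habitat", "dive") and rng.random() < amb_p:
                others = [c for c in dom if c != cat]
                cat = cat + "|" + others[int(rng.integers(len(others)))]
            rec[f] = cat
        rec["mass_kg"] = float(np.exp(prefs[r]["log_mass"] + 0.5 * rng.standard_normal()))
        rows[sp] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return EcologyTable(df[["habitat", "diet", "feeding", "dive", "mass_kg"]])


# ----------------------------------------------------------------------
# bundled datasets


@dataclasses.dataclass
class SyntheticDataset:
    """A complete simulated study: tree, truth, traits and optional extras."""

    tree: Tree
    painting: RegimePainting
    alpha: np.ndarray
    sigma2: np.ndarray
    theta: dict[str, np.ndarray]
    traits: pd.DataFrame
    landmarks: LandmarkSet | None
    ecology: EcologyTable | None
    seed: int
    provenance: dict


def make_convergence_dataset(
    seed: int,
    n_tips: int = DEFAULT_N_TIPS,
    depth: float = DEFAULT_DEPTH,
    n_shifts: int = 2,
    n_convergent_pairs: int = 1,
    m_traits: int = 2,
    alpha: float = 0.2,
    sigma2: float = 0.01,
    theta_sep: float = 1.0,
    with_ecology: bool = False,
    ecology_strength: float = 0.9,
) -> SyntheticDataset:
    """Tree + painted convergent shifts + OU traits, reproducible from a seed.

    Defaults plant one convergent regime reached by two shifts on a
    32-tip, 36-unit-deep tree, with strong attraction (``alpha * depth``
    ~ 7) and optima separated by many stationary standard deviations
    (``theta_sep`` vs ``sqrt(sigma2 / 2 alpha)`` ~ 0.16) — the regime
    structure the stepwise search is meant to recover.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_paint, s_traits, s_eco = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    tree = simulate_tree(n_tips, depth, seed=s_tree)
    painting = paint_random_shifts(tree, n_shifts, n_convergent_pairs, seed=s_paint)
    labels = painting.regime_labels()
    theta = {}
    for i, lab in enumerate(labels):
        if lab == painting.root_regime:
            theta[lab] = np.zeros(m_traits)
        else:
            # alternate optima on a +-theta_sep grid per trait
            vec = theta_sep * np.array(
                [(1.0 if (i + j) % 2 == 0 else -1.0) for j in range(m_traits)]
            )
            theta[lab] = vec
    Y = simulate_hansen(tree, painting, alpha, sigma2, theta, seed=s_traits)
    traits = pd.DataFrame(
        Y, index=list(tree.tip_labels), columns=[f"PC{j + 1}" for j in range(m_traits)]
    )
    traits.index.name = "species"
    ecology = (
        simulate_ecology(tree, painting, ecology_strength, seed=s_eco)
        if with_ecology
        else None
    )
    prov = {
        "seed": seed,
        "n_tips": n_tips,
        "depth": depth,
        "n_shifts": n_shifts,
        "n_convergent_pairs": n_convergent_pairs,
        "m_traits": m_traits,
        "alpha": alpha,
        "sigma2": sigma2,
        "theta_sep": theta_sep,
        "ecology_strength": ecology_strength if with_ecology else None,
    }
    return SyntheticDataset(
        tree=tree,
        painting=painting,
        alpha=np.full(m_traits, alpha),
        sigma2=np.full(m_traits, sigma2),
        theta=theta,
        traits=traits,
        landmarks=None,
        ecology=ecology,
        seed=seed,
        provenance=prov,
    )


def recovered_convergent_pair(
    tree: Tree,
    true_shifts: Mapping[int, str] | list[int],
    found_shifts: Mapping[int, str],
) -> bool:
    """Did a regime search recover a planted convergent shift pair?

    Success means: for each of the two planted shift branches there is a
    detected shift on that branch or an immediately adjacent one (parent or
    child), the two detected shifts are distinct branches, and they carry
    the same regime label (i.e. the search also collapsed them into one
    convergent regime).
    """
    true_nodes = sorted(true_shifts)
    if len(true_nodes) != 2:
        raise ValueError("expects exactly two planted shifts")

    def neighbourhood(v: int) -> set[int]:
        nb = {v}
        p = int(tree.parent[v])
        if p >= 0:
            nb.add(p)
        nb.update(tree.children[v])
        return nb

    cand_a = [f for f in found_shifts if f in neighbourhood(true_nodes[0])]
    cand_b = [f for f in found_shifts if f in neighbourhood(true_nodes[1])]
    for fa in cand_a:
        for fb in cand_b:
            if fa != fb and found_shifts[fa] == found_shifts[fb]:
                return True
    return False


def save_dataset(ds: SyntheticDataset, outdir) -> None:
    """Serialise a dataset directory: tree.nwk, painting.csv, traits.csv,
    ecology.csv, landmarks/*.pts, provenance.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(ds.tree.to_newick() + "\n")
    ds.painting.to_branch_table(ds.tree).to_csv(out / "painting.csv", index=False)
    ds.traits.to_csv(out / "traits.csv")
    if ds.ecology is not None:
        ds.ecology.to_csv(out / "ecology.csv")
    if ds.landmarks is not None:
        lmdir = out / "landmarks"
        lmdir.mkdir(exist_ok=True)
        for i, lab in enumerate(ds.landmarks.labels):
            write_pts(lmdir / f"{lab}.pts", ds.landmarks.coords[i])
    (out / "provenance.json").write_text(json.dumps(ds.provenance, indent=2) + "\n")
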