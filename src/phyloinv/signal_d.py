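"""Fritz-Purvis D statistic for binary traits.

D measures phylogenetic signal in a binary trait by comparing the
observed sum of sister-clade character contrasts, d_obs, against two
null anchors estimated by simulation on the same tree at the same
prevalence:

* a *permutation* null - the trait is randomly shuffled across tips
  (no signal); and
* a *Brownian threshold* null - a continuous liability evolves by
  Brownian motion on the tree and the tips with the largest liabilities
  are assigned state 1 (signal as strong as Brownian evolution).

``D = (d_obs - mean_d_brownian) / (mean_d_random - mean_d_brownian)``,
so E[D] = 1 for a random trait and E[D] = 0 for a Brownian-threshold
trait.  D < 1 means the trait is more phylogenetically clustered than
random; D > 1 more overdispersed.

The contrast sum uses the branch-length-weighted down-pass of the
independent-contrasts algorithm: ancestral node values are the
1/branch-length weighted averages of their daughters (with daughter
branch lengths inflated as in Felsenstein's pruning), and d is the sum
over internal nodes of |difference between the two daughter values|.
Zero-length daughter branches receive a small epsilon so the weights
stay finite; polytomies are resolved to zero-length bifurcations
(deterministically) before the pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_core import DatedTree

__all__ = [
    "contrast_sum",
    "contrast_sums_batch",
    "permutation_null",
    "brownian_null",
    "d_statistic",
    "d_by_group",
    "DStatResult",
]


@dataclass
class DStatResult:
    """Result of a D-statistic computation.

    ``p_random`` is the fraction of permutation-null contrast sums
    <= d_obs (small when the trait is more clustered than random);
    ``p_brownian`` is the fraction of Brownian-null contrast sums
    >= d_obs (small when the trait is less clustered than Brownian).
    """

    n_state1: int
    n_state0: int
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_randomizations: int
    seed: int | None
    defined: bool = True


def _prep_binary(tree: DatedTree):
    """Binary tree plus the per-node arrays the down-pass needs."""
    bt = tree.resolve_polytomies()
    child1 = np.full(bt.n_nodes, -1, dtype=np.int64)
    child2 = np.full(bt.n_nodes, -1, dtype=np.int64)
    for i, ch in enumerate(bt.children):
        if ch:
            child1[i], child2[i] = ch
    pos_len = bt.length[bt.length > 0]
    eps = 1e-8 * (pos_len.mean() if pos_len.size else 1.0)
    vadj0 = np.where(bt.length > 0, bt.length, eps)
    return bt, child1, child2, vadj0


def _trait_vector(tree: DatedTree, trait01) -> np.ndarray:
    """0/1 trait aligned with ``tree.tip_labels``."""
    if isinstance(trait01, pd.Series):
        trait01 = trait01.to_dict()
    if isinstance(trait01, dict):
        missing = [lab for lab in tree.tip_labels if lab not in trait01]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]} ...")
        v = np.array([trait01[lab] for lab in tree.tip_labels], dtype=float)
    else:
        v = np.asarray(trait01, dtype=float)
        if v.size != tree.n_tips:
            raise ValueError("trait vector length must equal number of tips")
    if not np.all(np.isin(v, (0.0, 1.0))):
        raise ValueError("trait must be binary 0/1")
    if v.min() == v.max():
        raise ValueError("monomorphic trait: D is undefined")
    return v


def contrast_sums_batch(tree: DatedTree, X: np.ndarray) -> np.ndarray:
    """Contrast sums for each column of ``X`` (shape n_tips x m).

    Columns are tip values in ``tree.tip_labels`` order.  The weighted
    down-pass is linear in the tip values, so all columns share one
    traversal.
    """
    bt, child1, child2, vadj0 = _prep_binary(tree)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != bt.n_tips:
        X = X.T
    if X.shape[0] != bt.n_tips:
        raise ValueError("X must have one row per tip")
    m = X.shape[1]
    vals = np.empty((bt.n_nodes, m))
    vals[bt.tip_ids] = X
    vadj = vadj0.copy()
    d = np.zeros(m)
    for i in range(bt.n_nodes - 1, -1, -1):
        c1, c2 = child1[i], child2[i]
        if c1 < 0:
            continue
        v1, v2 = vadj[c1], vadj[c2]
        d += np.abs(vals[c1] - vals[c2])
        vals[i] = (vals[c1] * v2 + vals[c2] * v1) / (v1 + v2)
        vadj[i] = vadj[i] + v1 * v2 / (v1 + v2)
    return d


def contrast_sum(tree: DatedTree, trait01) -> float:
    """Observed contrast sum d for a binary trait (both states required)."""
    v = _trait_vector(tree, trait01)
    return float(contrast_sums_batch(tree, v[:, None])[0])


def permutation_null(
    tree: DatedTree, trait01, n: int, seed=None
) -> np.ndarray:
    """Contrast sums for ``n`` uniform random permutations of the labels.

    Prevalence is preserved exactly in every replicate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    v = _trait_vector(tree, trait01)
    X = rng.permuted(np.tile(v, (n, 1)), axis=1).T
    return contrast_sums_batch(tree, X)


def brownian_null(tree: DatedTree, k: int, n: int, seed=None) -> np.ndarray:
    """Contrast sums under the Brownian threshold model.

    Per replicate, a unit-rate Brownian liability is simulated on the
    tree and the ``k`` tips with the largest values get state 1 (rank
    thresholding, so prevalence is exactly ``k`` every time).
    """
    if not 1 <= k <= tree.n_tips - 1:
        raise ValueError("k must be between 1 and n_tips - 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    liab = tree.simulate_brownian(n, rng)
    top = np.argpartition(-liab, k - 1, axis=0)[:k]
    X = np.zeros_like(liab)
    X[top, np.arange(n)[None, :]] = 1.0
    return contrast_sums_batch(tree, X)


def d_statistic(
    tree: DatedTree, trait01, n: int = 10000, seed=None
) -> DStatResult:
    """D with permutation and Brownian-threshold nulls (n randomizations).

    A degenerate scaling denominator (the two null means agree to within
    tolerance) yields a flagged, NaN-valued result rather than an
    exception.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    v = _trait_vector(tree, trait01)
    k = int(v.sum())
    d_obs = contrast_sum(tree, v)
    perm = permutation_null(tree, v, n, rng)
    brow = brownian_null(tree, k, n, rng)
    mean_r, mean_b = float(perm.mean()), float(brow.mean())
    denom = mean_r - mean_b
    defined = abs(denom) > 1e-9 * max(abs(mean_r), abs(mean_b), 1.0)
    D = (d_obs - mean_b) / denom if defined else float("nan")
    return DStatResult(
        n_state1=k,
        n_state0=int(v.size - k),
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=D,
        p_random=float(np.mean(perm <= d_obs)),
        p_brownian=float(np.mean(brow >= d_obs)),
        n_randomizations=int(n),
        seed=seed if isinstance(seed, int) else None,
        defined=defined,
    )


def d_by_group(
    tree: DatedTree,
    species: pd.DataFrame,
    n: int = 10000,
    seed=None,
) -> pd.DataFrame:
    """D of invasiveness among naturalized aliens and within alien groups.

    For each group (all naturalized aliens, neophytes, archaeophytes)
    the tree is pruned to the group's tips before computing D.  Groups
    lacking both states are flagged and skipped with a warning.  Output
    columns follow the usual signal-table shape: group, n_invasive,
    n_noninvasive, D, p_random, p_brownian.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tips = set(tree.tip_labels)
    aliens = species.loc[
        (species["status"] != "native") & species["species"].isin(tips)
    ]
    groups = {
        "naturalized aliens": aliens,
        "neophytes": aliens.loc[aliens["alien_group"] == "neophyte"],
        "archaeophytes": aliens.loc[aliens["alien_group"] == "archaeophyte"],
    }
    rows = []
    for name, grp in groups.items():
        n1 = int(grp["invasive"].sum())
        n0 = int(len(grp) - n1)
        if n1 == 0 or n0 == 0:
            warnings.warn(
                f"group {name!r} has a single invasiveness state; skipped"
            )
            rows.append(
                {
                    "group": name, "n_invasive": n1, "n_noninvasive": n0,
                    "D": float("nan"), "p_random": float("nan"),
                    "p_brownian": float("nan"),
                }
            )
            continue
        sub = tree.prune(grp["species"])
        trait = dict(zip(grp["species"], grp["invasive"]))
        res = d_statistic(sub, trait, n=n, seed=rng)
        rows.append(
            {
                "group": name, "n_invasive": n1, "n_noninvasive": n0,
                "D": res.D, "p_random": res.p_random,
                "p_brownian": res.p_brownian,
            }
        )
    return pd.DataFrame(rows)
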