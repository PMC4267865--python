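"""Synthetic flora, survey and atlas data with known statistical structure.

The generators emulate the inputs of a country-scale invasion analysis:

* a dated ultrametric phylogeny (~100-1600 tips),
* species status labels (native / non-invasive alien / invasive alien,
  aliens split into archaeophytes and neophytes) at realistic prevalences,
* PLANTATT-style traits with phylogenetic signal (Ellenberg L/F/N/R/S,
  height, Raunkiaer life-form, clonality, change index),
* Countryside-Survey-style plot assemblages (square -> plot -> species),
* hectad richness surfaces with spatial autocorrelation.

Every generator is a pure function of its inputs and a seed.  A single
root seed deterministically derives per-stage child generators via
``numpy.random.SeedSequence([root_seed, STAGE_INDEX])`` (see
:func:`stage_rng`), so stages can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core import DatedTree

__all__ = [
    "SimConfig",
    "stage_rng",
    "simulate_tree",
    "assign_status",
    "simulate_traits",
    "simulate_invasiveness_from_traits",
    "simulate_plots",
    "simulate_hectad_grid",
    "simulate_dataset",
]

NATIVE = "native"
NON_INVASIVE = "non-invasive alien"
INVASIVE = "invasive alien"

LIFE_FORMS = [
    "hemicryptophyte",
    "therophyte",
    "phanerophyte",
    "nanophanerophyte",
    "chamaephyte",
    "geophyte_bulbous",
    "geophyte_nonbulbous",
    "hydrophyte",
]

# stage name -> child-seed index (documented derivation; see stage_rng)
STAGES = {
    "tree": 0,
    "status": 1,
    "traits": 2,
    "invasiveness": 3,
    "plots": 4,
    "grid": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one root seed.

    ``SeedSequence([seed, STAGES[stage]])`` gives independent streams per
    stage while keeping the whole dataset a pure function of ``seed``.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, STAGES[stage]]))


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the British-flora setting the pipeline targets:
    1612 species (1249 native, 274 non-invasive alien, 89 invasive alien),
    aliens split 135 archaeophytes : 228 neophytes, a ~450 My deep tree,
    ~1.5 alien occurrences per retained survey plot, and a hectad grid
    (10 km cells) with a shared, spatially autocorrelated richness field.
    """

    n_tips: int = 1612
    tree_depth: float = 450.0
    prevalence_native: float = 1249 / 1612
    prevalence_noninvasive: float = 274 / 1612
    prevalence_invasive: float = 89 / 1612
    archaeophyte_fraction: float = 135 / 363
    trait_signal_mode: str = "brownian_threshold"  # or "random"
    logistic_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": -3.92,
            "ellenberg_F": 0.30,
            "ellenberg_N": 0.26,
        }
    )
    n_squares: int = 120
    plots_per_square: int = 30
    plot_native_rate: float = 10.0
    plot_alien_rate: float = 1.53
    grid_side: int = 53
    cell_size: float = 10.0
    spatial_range: float = 100.0
    seed: int = 0

    def __post_init__(self):
        prev = (
            self.prevalence_native,
            self.prevalence_noninvasive,
            self.prevalence_invasive,
        )
        if any(p < 0 or p > 1 for p in prev):
            raise ValueError("prevalences must lie in [0, 1]")
        if abs(sum(prev) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        for name in ("n_tips", "n_squares", "plots_per_square", "grid_side"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be positive")
        if self.trait_signal_mode not in ("random", "brownian_threshold"):
            raise ValueError(
                "trait_signal_mode must be 'random' or 'brownian_threshold'"
            )


def _largest_remainder(n: int, proportions) -> np.ndarray:
    """Integer counts summing to n, by largest-remainder rounding."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(np.int64)
    short = n - counts.sum()
    # ties broken by class order (stable argsort of -remainder)
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_tree(
    n_tips: int, depth: float, seed: int | np.random.Generator
) -> DatedTree:
    """Ultrametric pure-birth (Yule) tree, rescaled to the given depth.

    Lineages split at unit rate; the process stops when ``n_tips``
    lineages exist, all extant lineages are extended to the stopping
    time, and the tree is rescaled so every root-to-tip path equals
    ``depth`` (My).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # node bookkeeping in birth order; root = 0 with children 1, 2
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]  # time at which the node's edge starts
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        a, b = len(parent), len(parent) + 1
        parent.extend([node, node])
        birth.extend([t, t])
        active[i] = a
        active.append(b)
    t += rng.exponential(1.0 / len(active))  # extend tips past last split
    length = np.zeros(len(parent))
    is_tip = np.ones(len(parent), dtype=bool)
    for i in range(1, len(parent)):
        is_tip[parent[i]] = False
    split_time = {}  # node -> time at which it split
    for j in range(1, len(parent)):
        split_time.setdefault(parent[j], birth[j])
    for i in range(1, len(parent)):
        end = t if is_tip[i] else split_time[i]
        length[i] = end - birth[i]
    length *= depth / t
    width = len(str(n_tips))
    labels = {}
    k = 0
    for i in range(len(parent)):
        if is_tip[i]:
            k += 1
            labels[i] = f"t{k:0{width}d}"
    return DatedTree(parent, length, labels)


def assign_status(tree: DatedTree, cfg: SimConfig) -> pd.DataFrame:
    """Label every tip native / non-invasive alien / invasive alien.

    Counts follow the configured prevalences exactly (largest-remainder
    rounding).  Which tips are alien is always an exchangeable random
    choice; *which aliens are invasive* depends on the mode:

    * ``random`` - an exchangeable permutation (no phylogenetic signal;
      the D statistic is calibrated to 1 in expectation);
    * ``brownian_threshold`` - the aliens with the largest Brownian
      liabilities (simulated on the tree) are invasive, so invasiveness
      carries Brownian signal and D is calibrated to 0 in expectation.

    Aliens are further split into archaeophytes and neophytes (random,
    largest-remainder at ``archaeophyte_fraction``).
    """
    rng = stage_rng(cfg.seed, "status")
    n = tree.n_tips
    counts = _largest_remainder(
        n,
        (
            cfg.prevalence_native,
            cfg.prevalence_noninvasive,
            cfg.prevalence_invasive,
        ),
    )
    n_native, n_non, n_inv = (int(c) for c in counts)
    if n_non + n_inv < 2 or n_inv < 1 or n_non < 1:
        raise ValueError(
            "need at least one invasive and one non-invasive alien to form "
            "the invasiveness contrast"
        )
    labels = np.array(tree.tip_labels)
    perm = rng.permutation(n)
    alien_idx = perm[: n_non + n_inv]
    status = np.full(n, NATIVE, dtype=object)
    if cfg.trait_signal_mode == "random":
        inv_set = alien_idx[:n_inv]
    else:
        liab = tree.simulate_brownian(1, rng)[:, 0]
        alien_liab = liab[alien_idx]
        inv_set = alien_idx[np.argsort(-alien_liab, kind="stable")[:n_inv]]
    status[alien_idx] = NON_INVASIVE
    status[inv_set] = INVASIVE
    group = np.full(n, "", dtype=object)
    n_arch = _largest_remainder(
        n_non + n_inv,
        (cfg.archaeophyte_fraction, 1 - cfg.archaeophyte_fraction),
    )[0]
    grp_perm = rng.permutation(alien_idx)
    group[grp_perm[:n_arch]] = "archaeophyte"
    group[grp_perm[n_arch:]] = "neophyte"
    df = pd.DataFrame(
        {
            "species": labels,
            "status": status,
            "alien_group": np.where(status == NATIVE, pd.NA, group),
            "invasive": (status == INVASIVE).astype(int),
        }
    )
    return df.sort_values("species", ignore_index=True)


def _ordinal_from_ranks(values: np.ndarray, levels) -> np.ndarray:
    """Rank-quantile binning of continuous values onto an ordinal scale.

    Equal-count bins in rank order preserve the phylogenetic signal of
    the underlying Brownian values in the discretized trait.
    """
    levels = np.asarray(levels)
    ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    q = (ranks + 0.5) / values.size
    return levels[np.minimum((q * levels.size).astype(int), levels.size - 1)]


def _markov_life_form(
    tree: DatedTree, rng: np.random.Generator, rate: float = 0.004
) -> np.ndarray:
    """Equal-rates k-state Markov process along the tree (Raunkiaer forms)."""
    k = len(LIFE_FORMS)
    state = np.zeros(tree.n_nodes, dtype=np.int64)
    u = rng.random(tree.n_nodes)
    new = rng.integers(0, k, size=tree.n_nodes)
    # P(at least one change over edge of length t) under equal rates,
    # landing uniformly on the k states (Jukes-Cantor-style)
    p_change = 1.0 - np.exp(-rate * tree.length)
    for i in range(1, tree.n_nodes):
        state[i] = new[i] if u[i] < p_change[i] else state[tree.parent[i]]
    return state[tree.tip_ids]


def simulate_traits(
    tree: DatedTree, cfg: SimConfig, bm_rate: float = 1.0
) -> pd.DataFrame:
    """PLANTATT-style trait table with phylogenetic signal.

    Ellenberg indicators evolve as Brownian motion on the tree and are
    discretized by rank-quantile binning (L, F, N, R on 1-9; salt
    tolerance S on 0-9 with a zero-heavy marginal, as in real floras).
    Height is lognormal around a Brownian component; life-form is an
    equal-rates Markov process; clonality is thresholded Brownian.
    ``bm_rate = 0`` degenerates to all tips sharing the root value.
    """
    rng = stage_rng(cfg.seed, "traits")
    n_cont = 7  # L F N R S height clonality
    bm = tree.simulate_brownian(n_cont, rng, rate=bm_rate)
    if bm_rate == 0:
        bm = np.zeros_like(bm)
    out = pd.DataFrame({"species": list(tree.tip_labels)})
    scale19 = np.arange(1, 10)
    for j, name in enumerate(["L", "F", "N", "R"]):
        if bm_rate == 0:
            out[f"ellenberg_{name}"] = 5
        else:
            out[f"ellenberg_{name}"] = _ordinal_from_ranks(bm[:, j], scale19)
    # salt tolerance: mostly 0, upper tail spread over 1..9
    if bm_rate == 0:
        out["ellenberg_S"] = 0
    else:
        s_levels = np.concatenate([np.zeros(16, dtype=int), np.arange(1, 10)])
        out["ellenberg_S"] = _ordinal_from_ranks(bm[:, 4], s_levels)
    depth = max(tree.tip_depths().max(), 1.0)
    z_h = bm[:, 5] / math.sqrt(depth)  # ~unit variance at the tips
    log_h = math.log(30.0) + 1.0 * z_h + 0.3 * rng.standard_normal(tree.n_tips)
    out["height"] = np.exp(log_h)
    out["log_height"] = log_h
    lf = _markov_life_form(tree, rng)
    out["life_form"] = pd.Categorical.from_codes(lf, LIFE_FORMS)
    clo = bm[:, 6]
    out["clonal"] = (clo >= np.median(clo)).astype(int)
    # range-change index (PLANTATT-style), filled per status later
    out["change_index"] = rng.normal(0.0, 0.6, tree.n_tips)
    return out


def simulate_invasiveness_from_traits(
    species: pd.DataFrame, coefficients: dict, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Redraw the invasive flag of aliens from a logistic trait model.

    ``P(invasive | alien) = logit^-1(intercept + sum_v beta_v x_v)`` on
    the raw trait columns; natives are never invasive.  Provides ground
    truth for model-averaging recovery experiments.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    missing = [
        v for v in coefficients if v != "intercept" and v not in species
    ]
    if missing:
        raise KeyError(f"coefficients reference unknown columns: {missing}")
    eta = np.full(len(species), float(coefficients.get("intercept", 0.0)))
    for var, beta in coefficients.items():
        if var == "intercept":
            continue
        eta += float(beta) * species[var].to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    draw = (rng.random(len(species)) < p).astype(int)
    out = species.copy()
    is_alien = out["status"] != NATIVE
    out["invasive"] = np.where(is_alien, draw, 0)
    out.loc[is_alien & (out["invasive"] == 1), "status"] = INVASIVE
    out.loc[is_alien & (out["invasive"] == 0), "status"] = NON_INVASIVE
    return out


def _solve_unconditional_rate(target_conditional_mean: float) -> float:
    """lambda with lambda / (1 - exp(-lambda)) = target (Newton)."""
    c = float(target_conditional_mean)
    if c <= 1.0:
        raise ValueError("conditional mean must exceed 1")
    lam = c
    for _ in range(60):
        f = lam / (1.0 - math.exp(-lam)) - c
        h = 1e-7
        fp = (
            (lam + h) / (1.0 - math.exp(-(lam + h)))
            - (lam - h) / (1.0 - math.exp(-(lam - h)))
        ) / (2 * h)
        lam -= f / fp
        lam = max(lam, 1e-9)
    return lam


def simulate_plots(
    species: pd.DataFrame,
    cfg: SimConfig,
    species_sd: float = 0.5,
    square_sd: float = 0.5,
    max_aliens: int = 12,
) -> pd.DataFrame:
    """Survey plots: squares x plots, species drawn by inclusion odds.

    Each species has a random intercept, and each 1-km square a random
    intercept, on the log-odds of inclusion, so species- and
    square-level variance exists for the mixed-model stage.  Plots are
    resampled until they contain >= 1 native and >= 1 alien (mirroring
    the survey filter), so the requested plot count is met exactly; the
    per-plot alien count is clipped at ``max_aliens``.  Base rates are
    chosen so the *conditional* mean aliens per retained plot matches
    ``cfg.plot_alien_rate``.
    """
    rng = stage_rng(cfg.seed, "plots")
    natives = species.loc[species["status"] == NATIVE, "species"].to_numpy()
    aliens = species.loc[species["status"] != NATIVE, "species"].to_numpy()
    if natives.size < 1 or aliens.size < 1:
        raise ValueError("need at least one native and one alien species")
    lam_alien = _solve_unconditional_rate(cfg.plot_alien_rate)
    # per-species inclusion odds; normal random intercepts on log-odds
    def base_logit(rate, pool):
        p = min(rate / pool.size, 0.5)
        return math.log(p / (1 - p))

    u_nat = rng.normal(0.0, species_sd, natives.size)
    u_ali = rng.normal(0.0, species_sd, aliens.size)
    # mean(sigmoid(logit(p0)+u)) > p0; rescale to keep marginal rates
    def probs(rate, pool, u):
        p = 1.0 / (1.0 + np.exp(-(base_logit(rate, pool) + u)))
        return p * (rate / pool.size) / p.mean()

    p_nat = probs(cfg.plot_native_rate, natives, u_nat)
    p_ali = probs(lam_alien, aliens, u_ali)
    rows_sq, rows_plot, rows_sp = [], [], []
    for sq in range(cfg.n_squares):
        v = rng.normal(0.0, square_sd)
        mult = math.exp(v)
        pn = np.clip(p_nat * mult, 0, 1)
        pa = np.clip(p_ali * mult, 0, 1)
        for pl in range(cfg.plots_per_square):
            for _ in range(1000):
                nat_in = natives[rng.random(natives.size) < pn]
                ali_in = aliens[rng.random(aliens.size) < pa]
                if nat_in.size >= 1 and 1 <= ali_in.size:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("plot resampling failed 1000 times")
            if ali_in.size > max_aliens:
                ali_in = rng.choice(ali_in, size=max_aliens, replace=False)
            sp = np.concatenate([nat_in, ali_in])
            rows_sq.extend([sq] * sp.size)
            rows_plot.extend([pl] * sp.size)
            rows_sp.extend(sp.tolist())
    return pd.DataFrame(
        {
            "square": np.array(rows_sq, dtype=np.int64),
            "plot": np.array(rows_plot, dtype=np.int64),
            "species": rows_sp,
        }
    )


def _gaussian_random_field(
    coords: np.ndarray, spatial_range: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Zero-mean unit-variance fields with exponential covariance."""
    from scipy.spatial.distance import pdist, squareform

    if spatial_range <= 0:
        return rng.standard_normal((coords.shape[0], n))
    d = squareform(pdist(coords))
    cov = np.exp(-d / spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((coords.shape[0], n))


def simulate_hectad_grid(
    cfg: SimConfig,
    shared_weight: float = 0.98,
    sigma: float = 1.0,
    mean_richness: tuple[float, float] = (20.0, 60.0),
) -> pd.DataFrame:
    """Atlas-style richness surfaces for invasive and non-invasive aliens.

    A shared spatially autocorrelated Gaussian field (exponential
    covariance, range ``cfg.spatial_range``) plus independent noise
    drives log-Poisson counts in each group, so richness of the two
    groups is spatially congruent to a degree set by ``shared_weight``
    (0 = independent surfaces, 1 = a common field).  Doubly-empty cells
    can occur and are left in: downstream analyses must drop them.
    """
    if cfg.grid_side < 3:
        raise ValueError("grid_side must be >= 3")
    if not 0.0 <= shared_weight <= 1.0:
        raise ValueError("shared_weight must lie in [0, 1]")
    rng = stage_rng(cfg.seed, "grid")
    side = cfg.grid_side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = (
        np.column_stack([xs.ravel(), ys.ravel()]).astype(float) + 0.5
    ) * cfg.cell_size
    fields = _gaussian_random_field(coords, cfg.spatial_range, rng, 3)
    shared, e_inv, e_non = fields.T
    w = shared_weight
    z_inv = w * shared + math.sqrt(max(1 - w * w, 0.0)) * e_inv
    z_non = w * shared + math.sqrt(max(1 - w * w, 0.0)) * e_non
    lam_inv = np.exp(math.log(mean_richness[0]) + sigma * z_inv)
    lam_non = np.exp(math.log(mean_richness[1]) + sigma * z_non)
    return pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "richness_invasive": rng.poisson(lam_inv),
            "richness_noninvasive": rng.poisson(lam_non),
        }
    )


def simulate_dataset(cfg: SimConfig) -> dict:
    """Full synthetic bundle: tree, species table, plots and hectad grid."""
    tree = simulate_tree(cfg.n_tips, cfg.tree_depth, stage_rng(cfg.seed, "tree"))
    status = assign_status(tree, cfg)
    traits = simulate_traits(tree, cfg)
    species = status.merge(traits, on="species", validate="1:1")
    # invasive aliens increased more in range than non-invasive aliens
    is_alien = species["status"] != NATIVE
    species.loc[~is_alien, "change_index"] = np.nan
    species.loc[is_alien & (species["invasive"] == 1), "change_index"] += 0.7
    plots = simulate_plots(species, cfg)
    grid = simulate_hectad_grid(cfg)
    return {"tree": tree, "species": species, "plots": plots, "grid": grid}
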