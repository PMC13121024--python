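"""Gaussian integrated information decomposition (ΦID) and derived measures.

For two (possibly multivariate) parts X and Y of a stationary process, the
time-delayed mutual information I(X_{t-τ}, Y_{t-τ}; X_t, Y_t) is decomposed
into 16 "atoms", one for each pair of nodes of the redundancy lattice
{Red, UnX, UnY, Syn} taken at past and future.  Redundancy is measured with
the minimum-mutual-information (MMI) rule, which for jointly Gaussian
variables reduces every computation to log-determinants of sub-covariances.

The double-redundancy function evaluated at a pair of lattice nodes (α, β)
is min over all mutual informations between a source collection of α in the
past and a source collection of β in the future.  At the bottom node pair
this is the minimum of the four single-part lagged MIs; at the top node pair
it is the full time-delayed mutual information.  Atoms are recovered by
Möbius inversion of this function over the product partial order.

Derived quantities:

* ``phi_r``      — revised integrated information: all synergy-containing
                   atoms plus the two pure-transfer atoms.  Equals
                   whole-minus-sum information with the persistent
                   redundancy added back.
* ``phi_2008``   — original whole-minus-sum integrated information,
                   ``phi_r`` minus persistent redundancy; may be negative
                   in redundancy-dominated systems.
* ``causal density`` — sum of the two directed transfer entropies.
* ``net flow``   — absolute imbalance of the two pure-transfer atoms.

All quantities are returned in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .io import RegionalTimeseries

logger = logging.getLogger(__name__)

__all__ = [
    "LaggedGaussianModel",
    "PhiIDAtoms",
    "InfoMeasures",
    "ATOM_NAMES",
    "estimate_lagged_model",
    "model_from_cov",
    "model_from_var",
    "gaussian_mi",
    "double_redundancy_mmi",
    "phiid_atoms",
    "info_measures",
    "pairwise_matrix",
    "bipartition_phi",
    "debias",
]

# ---------------------------------------------------------------------------
# lattice bookkeeping
#
# PID nodes over two sources, each node an antichain of source collections:
#   Red = {{X},{Y}},  UnX = {{X}},  UnY = {{Y}},  Syn = {{X,Y}}
# Partial order: Red <= UnX, UnY <= Syn; UnX, UnY incomparable.

_NODES = ("r", "x", "y", "s")
_COLLECTIONS = {  # each collection is a frozenset of parts (0 = X, 1 = Y)
    "r": (frozenset({0}), frozenset({1})),
    "x": (frozenset({0}),),
    "y": (frozenset({1}),),
    "s": (frozenset({0, 1}),),
}
_LEQ = {
    ("r", "r"): True, ("r", "x"): True, ("r", "y"): True, ("r", "s"): True,
    ("x", "x"): True, ("x", "s"): True,
    ("y", "y"): True, ("y", "s"): True,
    ("s", "s"): True,
}

#: the 16 atom names, past node major: rtr = Red→Red, xty = UnX→UnY, ...
ATOM_NAMES = tuple(f"{p}t{f}" for p in _NODES for f in _NODES)


def _build_zeta() -> np.ndarray:
    """Zeta matrix of the product order: Z[i, j] = 1 iff atom j <= node pair i."""
    pairs = [(p, f) for p in _NODES for f in _NODES]
    z = np.zeros((16, 16))
    for i, (p_i, f_i) in enumerate(pairs):
        for j, (p_j, f_j) in enumerate(pairs):
            if _LEQ.get((p_j, p_i), False) and _LEQ.get((f_j, f_i), False):
                z[i, j] = 1.0
    return z


_ZETA = _build_zeta()
_ZETA_INV = np.linalg.inv(_ZETA)


# ---------------------------------------------------------------------------
# model container


@dataclass
class LaggedGaussianModel:
    """Joint Gaussian model of (past of X, past of Y, future of X, future of Y).

    ``joint_cov`` is ordered [past part-1 dims, past part-2 dims,
    future part-1 dims, future part-2 dims].
    """

    joint_cov: np.ndarray
    dims: tuple[int, int]
    lag: int = 1

    def __post_init__(self):
        self.joint_cov = np.asarray(self.joint_cov, dtype=float)
        d = sum(self.dims)
        if self.joint_cov.shape != (2 * d, 2 * d):
            raise ValueError("joint covariance has wrong shape for dims")
        if np.max(np.abs(self.joint_cov - self.joint_cov.T)) > 1e-10:
            raise ValueError("joint covariance must be symmetric")
        if min(self.dims) < 1:
            raise ValueError("both parts must have at least one dimension")
        if self.lag < 1:
            raise ValueError("lag must be a positive number of samples "
                             "(past must precede future)")
        self.joint_cov = (self.joint_cov + self.joint_cov.T) / 2.0

    # stacked index sets -----------------------------------------------------
    def past_indices(self, parts: frozenset[int]) -> list[int]:
        d1, _ = self.dims
        out = []
        if 0 in parts:
            out += list(range(0, d1))
        if 1 in parts:
            out += list(range(d1, sum(self.dims)))
        return out

    def future_indices(self, parts: frozenset[int]) -> list[int]:
        d = sum(self.dims)
        return [d + i for i in self.past_indices(parts)]


def _logdet(m: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular or indefinite sub-covariance")
    return ld


def gaussian_mi(model: LaggedGaussianModel, set_a, set_b) -> float:
    """Gaussian mutual information (nats) between two stacked index sets.

    I(a; b) = 1/2 [ log det Σ_a + log det Σ_b − log det Σ_ab ].
    """
    a = list(set_a)
    b = list(set_b)
    if not a or not b:
        raise ValueError("index sets must be non-empty")
    if set(a) & set(b):
        raise ValueError("index sets must be disjoint")
    cov = model.joint_cov
    try:
        ld_a = _logdet(cov[np.ix_(a, a)])
        ld_b = _logdet(cov[np.ix_(b, b)])
        ld_ab = _logdet(cov[np.ix_(a + b, a + b)])
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular sub-covariance in MI computation: {exc}") from exc
    return 0.5 * (ld_a + ld_b - ld_ab)


def _collection_mis(model: LaggedGaussianModel) -> dict:
    """MI between every past source collection and every future collection."""
    colls = [frozenset({0}), frozenset({1}), frozenset({0, 1})]
    out = {}
    for a in colls:
        for b in colls:
            out[(a, b)] = gaussian_mi(model, model.past_indices(a),
                                      model.future_indices(b))
    return out


def _node_pair_redundancy(mis: dict, past_node: str, fut_node: str) -> float:
    """MMI double redundancy at one product-lattice node pair."""
    return min(mis[(a, b)]
               for a in _COLLECTIONS[past_node]
               for b in _COLLECTIONS[fut_node])


def double_redundancy_mmi(model: LaggedGaussianModel) -> float:
    """Persistent redundancy Red→Red: minimum of the four lagged MIs."""
    mis = _collection_mis(model)
    return _node_pair_redundancy(mis, "r", "r")


@dataclass
class PhiIDAtoms:
    """The 16 ΦID atoms in nats (may legitimately be negative; never clipped)."""

    values: dict

    def __post_init__(self):
        if set(self.values) != set(ATOM_NAMES):
            raise ValueError("atoms must carry exactly the 16 canonical names")

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in ATOM_NAMES])

    @property
    def tdmi(self) -> float:
        return float(sum(self.values.values()))


def phiid_atoms(model: LaggedGaussianModel) -> PhiIDAtoms:
    """All 16 atoms by Möbius inversion of the MMI double-redundancy function."""
    mis = _collection_mis(model)
    red = np.array([_node_pair_redundancy(mis, p, f)
                    for p in _NODES for f in _NODES])
    atoms = _ZETA_INV @ red
    return PhiIDAtoms(dict(zip(ATOM_NAMES, atoms)))


@dataclass
class InfoMeasures:
    """Scalar information-dynamic summaries of a two-part lagged model (nats)."""

    tdmi: float
    phi_r: float
    phi_2008: float
    double_redundancy: float
    causal_density: float
    net_flow: float
    te_xy: float
    te_yx: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


#: atoms summed into Φ_R: every synergy-containing atom plus pure transfer
PHI_R_ATOMS = ("sts", "stx", "sty", "str", "rts", "xts", "yts", "xty", "ytx")


def info_measures(atoms: PhiIDAtoms, model: LaggedGaussianModel | None = None
                  ) -> InfoMeasures:
    """Derived measures from the 16 atoms.

    ``phi_r`` sums the nine synergy/transfer atoms; ``phi_2008`` removes the
    persistent redundancy; transfer entropies and causal density follow the
    atom-level decomposition of directed transfer.
    """
    a = atoms.values
    phi_r = float(sum(a[k] for k in PHI_R_ATOMS))
    te_xy = float(a["str"] + a["sty"] + a["xtr"] + a["xty"])
    te_yx = float(a["str"] + a["stx"] + a["ytr"] + a["ytx"])
    return InfoMeasures(
        tdmi=atoms.tdmi,
        phi_r=phi_r,
        phi_2008=phi_r - a["rtr"],
        double_redundancy=float(a["rtr"]),
        causal_density=te_xy + te_yx,
        net_flow=float(abs(a["xty"] - a["ytx"])),
        te_xy=te_xy,
        te_yx=te_yx,
    )


# ---------------------------------------------------------------------------
# model estimation


def _stacked_lagged_cov(values: np.ndarray, lag: int) -> np.ndarray:
    """Sample covariance of [x_{t-lag}, x_t] after per-region z-scoring."""
    v = values - values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    v = v / sd
    stacked = np.hstack([v[:-lag], v[lag:]])
    return np.cov(stacked, rowvar=False)


def _condition_cov(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Diagonal loading if the smallest eigenvalue is below the floor."""
    eig_min = np.linalg.eigvalsh(cov).min()
    if eig_min < floor:
        eps = 1e-9 * float(np.mean(np.diag(cov))) + max(0.0, -eig_min)
        cov = cov + eps * np.eye(cov.shape[0])
        if np.linalg.eigvalsh(cov).min() < floor / 10:
            raise ValueError(
                "covariance rank-deficient after diagonal loading "
                f"(min eigenvalue {eig_min:.3e})")
    return cov


def _model_from_stacked(full_cov: np.ndarray, n_regions: int,
                        part1, part2, lag: int) -> LaggedGaussianModel:
    """Slice a (2N x 2N) stacked lagged covariance down to a two-part model."""
    p1 = list(part1)
    p2 = list(part2)
    idx = p1 + p2 + [n_regions + i for i in p1] + [n_regions + i for i in p2]
    cov = _condition_cov(full_cov[np.ix_(idx, idx)])
    return LaggedGaussianModel(cov, (len(p1), len(p2)), lag)


def estimate_lagged_model(ts: RegionalTimeseries, part1, part2,
                          lag: int = 1) -> LaggedGaussianModel:
    """Fit the joint Gaussian past/future model for two groups of regions.

    Regions are z-scored over time; the joint covariance is the sample
    covariance of the stacked vector (both parts at t−lag, both parts at t).
    """
    part1 = sorted(part1)
    part2 = sorted(part2)
    if not part1 or not part2:
        raise ValueError("both parts must be non-empty")
    if set(part1) & set(part2):
        raise ValueError("parts must be disjoint region sets")
    if lag < 1:
        raise ValueError("lag must be >= 1 sample (past must precede future)")
    d = len(part1) + len(part2)
    if ts.n_time - lag < 10 * d:
        raise ValueError(
            f"too few samples: need at least {10 * d + lag} timepoints "
            f"for {d} total dimensions at lag {lag}")
    sub = ts.values[:, part1 + list(part2)]
    full = _stacked_lagged_cov(sub, lag)
    k = len(part1) + len(part2)
    return _model_from_stacked(full, k, range(len(part1)),
                               range(len(part1), k), lag)


def model_from_cov(sigma0: np.ndarray, sigma_lag: np.ndarray,
                   part1, part2, lag: int = 1) -> LaggedGaussianModel:
    """Exact model from analytic covariances.

    ``sigma0`` is the stationary covariance, ``sigma_lag[i, j]`` the
    covariance Cov(x_t[i], x_{t-lag}[j]).
    """
    part1 = list(part1)
    part2 = list(part2)
    idx = part1 + part2
    s0 = np.asarray(sigma0, float)[np.ix_(idx, idx)]
    sl = np.asarray(sigma_lag, float)[np.ix_(idx, idx)]
    joint = np.block([[s0, sl.T], [sl, s0]])
    return LaggedGaussianModel(joint, (len(part1), len(part2)), lag)


def model_from_var(coupling: np.ndarray, noise_cov: np.ndarray,
                   part1, part2, lag: int = 1) -> LaggedGaussianModel:
    """Exact model of a stationary VAR(1): Σ from the discrete Lyapunov
    equation, lagged covariance A^lag Σ."""
    a = np.asarray(coupling, float)
    q = np.asarray(noise_cov, float)
    if np.max(np.abs(np.linalg.eigvals(a))) >= 1:
        raise ValueError("VAR coupling is not stationary")
    sigma0 = solve_discrete_lyapunov(a, q)
    sigma0 = (sigma0 + sigma0.T) / 2
    sigma_lag = np.linalg.matrix_power(a, lag) @ sigma0
    return model_from_cov(sigma0, sigma_lag, part1, part2, lag)


# ---------------------------------------------------------------------------
# aggregation over pairs / bipartitions

_MEASURES = ("phi_r", "phi_2008", "tdmi", "double_redundancy",
             "causal_density", "net_flow", "te_xy", "te_yx")


def measures_for_model(model: LaggedGaussianModel) -> InfoMeasures:
    return info_measures(phiid_atoms(model), model)


def pairwise_matrix(ts: RegionalTimeseries, lag: int = 1,
                    measure: str = "phi_r"):
    """Measure for every unordered region pair.

    Returns ``(matrix, global_mean)``: an N x N symmetric matrix with NaN
    diagonal, and the mean over the N(N-1)/2 unordered pairs.  Pairs whose
    estimation fails are recorded as NaN, excluded from the mean and counted
    in the log.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; one of {_MEASURES}")
    n = ts.n_regions
    if n < 2:
        raise ValueError("need at least two regions")
    full = _stacked_lagged_cov(ts.values, lag)
    mat = np.full((n, n), np.nan)
    failed = 0
    for i, j in combinations(range(n), 2):
        try:
            model = _model_from_stacked(full, n, [i], [j], lag)
            val = getattr(measures_for_model(model), measure)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        mat[i, j] = mat[j, i] = val
    if failed:
        logger.warning("pairwise_matrix: %d of %d pairs failed estimation",
                       failed, n * (n - 1) // 2)
    vals = mat[np.triu_indices(n, 1)]
    return mat, float(np.nanmean(vals))


def pairwise_means(ts: RegionalTimeseries, lag: int = 1) -> InfoMeasures:
    """Global (pairwise-mean) value of every measure in one pass."""
    n = ts.n_regions
    full = _stacked_lagged_cov(ts.values, lag)
    sums = dict.fromkeys(_MEASURES, 0.0)
    count = 0
    for i, j in combinations(range(n), 2):
        try:
            model = _model_from_stacked(full, n, [i], [j], lag)
            m = measures_for_model(model)
        except (ValueError, np.linalg.LinAlgError):
            continue
        for k in _MEASURES:
            sums[k] += getattr(m, k)
        count += 1
    if count == 0:
        raise ValueError("no region pair could be estimated")
    return InfoMeasures(**{k: sums[k] / count for k in _MEASURES})


def bipartition_phi(ts: RegionalTimeseries, k: int = 6, n_sets: int = 2000,
                    lag: int = 1, seed: int = 0) -> float:
    """Mean Φ_R over randomly sampled K-region sets split into even halves.

    Trades the purely pairwise view for interactions among more regions
    while keeping estimation tractable: sample ``n_sets`` subsets of ``k``
    regions, split each at random into two halves of k/2, and average Φ_R
    between the halves.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if k % 2 or k < 2:
        raise ValueError("k must be a positive even number")
    if ts.n_regions < k:
        raise ValueError("k exceeds the number of regions")
    rng = np.random.default_rng(seed)
    full = _stacked_lagged_cov(ts.values, lag)
    vals = []
    for _ in range(n_sets):
        regions = rng.choice(ts.n_regions, size=k, replace=False)
        rng.shuffle(regions)
        half = k // 2
        model = _model_from_stacked(full, ts.n_regions,
                                    sorted(regions[:half]),
                                    sorted(regions[half:]), lag)
        vals.append(measures_for_model(model).phi_r)
    return float(np.mean(vals))


def debias(ts: RegionalTimeseries, lag: int = 1, n_surrogates: int = 10,
           seed: int = 0) -> InfoMeasures:
    """Surrogate-debiased pairwise-mean measures.

    The bias of each measure is estimated on surrogate timeseries that keep
    every region's value distribution and the zero-lag covariance but destroy
    temporal order (a joint permutation of timepoints); the debiased value is
    empirical minus the surrogate mean.
    """
    from .synthetic import time_shuffle_surrogate

    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    emp = pairwise_means(ts, lag)
    rng = np.random.default_rng(seed)
    surr_vals = {k: [] for k in _MEASURES}
    for _ in range(n_surrogates):
        surr = time_shuffle_surrogate(ts, seed=int(rng.integers(2**31 - 1)))
        sm = pairwise_means(surr, lag)
        for k in _MEASURES:
            surr_vals[k].append(getattr(sm, k))
    return InfoMeasures(**{k: getattr(emp, k) - float(np.mean(surr_vals[k]))
                           for k in _MEASURES})
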