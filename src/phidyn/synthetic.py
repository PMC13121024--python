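"""Synthetic inputs with known ground truth.

Everything downstream of this module (information decomposition, control
energy, statistics, whole studies) is exercised on data generated here:
vector-autoregressive timeseries whose lagged covariance is known in closed
form, weighted connectomes with topological null variants, spatially
autocorrelated regional maps, surrogate generators, and whole multi-subject
multi-condition "studies" with a planted coupling manipulation and an
arousal score on a 0-11 behavioural scale.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .io import (Connectome, RegionalMap, RegionalTimeseries,
                 read_connectome, read_map, read_timeseries,
                 write_connectome, write_map, write_timeseries)

__all__ = [
    "VarSystem",
    "ConditionSpec",
    "SyntheticStudy",
    "DEFAULT_CONDITIONS",
    "DBS_CONDITIONS",
    "generate_var",
    "two_node_ar",
    "synthetic_connectome",
    "rewire_connectome",
    "add_hub_node",
    "spatial_map",
    "morans_i",
    "distance_weights",
    "msr_surrogate_maps",
    "time_shuffle_surrogate",
    "synthetic_study",
    "save_study",
    "load_study",
]


# ---------------------------------------------------------------------------
# VAR generation


@dataclass
class VarSystem:
    """Lag-1 vector-autoregressive system x_t = A x_{t-1} + ε_t."""

    coupling: np.ndarray
    noise_cov: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = self.coupling.shape[0]
        if self.coupling.shape != (n, n) or self.noise_cov.shape != (n, n):
            raise ValueError("coupling and noise covariance must be square "
                             "matrices of the same size")
        rho = self.spectral_radius
        if rho >= 1:
            raise ValueError(f"non-stationary coupling: spectral radius "
                             f"{rho:.4f} >= 1")
        if np.max(np.abs(self.noise_cov - self.noise_cov.T)) > 1e-10:
            raise ValueError("noise covariance must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() < -1e-10:
            raise ValueError("noise covariance must be positive semi-definite")
        if not self.labels:
            self.labels = [f"R{i:03d}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.coupling.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coupling))))

    def stationary_cov(self) -> np.ndarray:
        """Solution Σ of the discrete Lyapunov equation Σ = AΣAᵀ + Q."""
        s = solve_discrete_lyapunov(self.coupling, self.noise_cov)
        return (s + s.T) / 2

    def lagged_cov(self, lag: int = 1) -> np.ndarray:
        """Cov(x_t, x_{t-lag}) = A^lag Σ."""
        return np.linalg.matrix_power(self.coupling, lag) @ self.stationary_cov()


def _psd_sqrt(q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(q)
    w = np.clip(w, 0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def generate_var(system: VarSystem, n_time: int, seed: int,
                 burn_in: int = 100, tr: float = 1.0) -> RegionalTimeseries:
    """Sample a stationary VAR(1) trajectory; burn-in steps are discarded."""
    if n_time < 10:
        raise ValueError("n_time must be >= 10")
    rng = np.random.default_rng(seed)
    n = system.n
    sq = _psd_sqrt(system.noise_cov)
    eps = rng.standard_normal((burn_in + n_time, n)) @ sq.T
    x = np.zeros((burn_in + n_time, n))
    a_t = system.coupling.T
    for t in range(1, burn_in + n_time):
        x[t] = x[t - 1] @ a_t + eps[t]
    return RegionalTimeseries(x[burn_in:], list(system.labels), tr=tr)


def two_node_ar(a: float, c: float, n_time: int, seed: int,
                self_coupling: float = 0.2) -> RegionalTimeseries:
    """Two-node coupled autoregressive process with two key parameters.

    ``a`` is the symmetric cross-coupling between the nodes and ``c`` the
    correlation of their innovations ("common noise").  Rising ``a``
    strengthens the nodes' mutual influence and hence synergy; rising ``c``
    floods the system with shared noise and hence redundancy.  Each node
    also keeps a modest memory of its own past (``self_coupling``), giving
    the channels brain-like temporal autocorrelation — without it the
    redundancy-dominated regime (negative whole-minus-sum integrated
    information at high ``c``) cannot appear, because all lagged mutual
    informations vanish at a = 0.
    """
    if not abs(a) < 1:
        raise ValueError("|a| must be < 1")
    if not abs(c) <= 1:
        raise ValueError("|c| must be <= 1")
    system = two_node_system(a, c, self_coupling)
    return generate_var(system, n_time, seed)


def two_node_system(a: float, c: float, self_coupling: float = 0.2) -> VarSystem:
    """The VarSystem underlying :func:`two_node_ar` (for analytic work)."""
    coupling = np.array([[self_coupling, a], [a, self_coupling]])
    noise = np.array([[1.0, c], [c, 1.0]])
    return VarSystem(coupling, noise, ["X", "Y"])


# ---------------------------------------------------------------------------
# connectomes


def _ring_pairs(n: int):
    """All unordered pairs sorted by ring distance (deterministic ties)."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return sorted(pairs, key=lambda p: (min(p[1] - p[0], n - (p[1] - p[0])),
                                        p[0], p[1]))


def _modular_base(n: int, m_edges: int, rng: np.random.Generator,
                  n_modules: int = 4) -> np.ndarray:
    """Weighted modular graph: dense strong within-module connectivity plus
    sparse weaker between-module links (an empirical-connectome-like
    topology with community structure and heavy-tailed weights)."""
    module = np.arange(n) % n_modules
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    same = np.array([module[i] == module[j] for i, j in pairs], dtype=float)
    prob = np.where(same > 0, 4.0, 1.0)
    prob = prob / prob.sum()
    chosen = rng.choice(len(pairs), size=m_edges, replace=False, p=prob)
    w = np.zeros((n, n))
    weights = np.exp(rng.normal(0.0, 1.0, size=m_edges))  # lognormal weights
    for idx, e in enumerate(chosen):
        i, j = pairs[e]
        scale = 2.0 if module[i] == module[j] else 1.0
        w[i, j] = w[j, i] = weights[idx] * scale
    return w


def synthetic_connectome(n: int, density: float, kind: str = "modular",
                         seed: int = 0) -> Connectome:
    """Synthetic weighted connectome of a given size, density and topology.

    ``kind`` one of ``modular`` (empirical-like community structure),
    ``lattice``, ``random``, ``degree-preserving``, ``strength-preserving``.
    All non-modular kinds are null variants of the modular graph generated
    with the same (n, density, seed): they keep size and density exactly;
    lattice/random/degree-preserving also keep the weight multiset exactly,
    and the degree/strength variants preserve the stated node properties.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    m_edges = int(round(density * n * (n - 1) / 2))
    if m_edges < 1 or m_edges > n * (n - 1) / 2:
        raise ValueError(f"density {density} incompatible with n={n}")
    rng = np.random.default_rng(seed)
    base = _modular_base(n, m_edges, rng)
    kind = kind.replace("modular-empirical-like", "modular")
    if kind == "modular":
        return Connectome(base)
    return rewire_connectome(Connectome(base), kind,
                             seed=int(rng.integers(2**31 - 1)))


def add_hub_node(conn: Connectome, weight_scale: float = 2.0,
                 label: str = "HUB") -> Connectome:
    """Augment a connectome with one broadly connected hub node.

    The new node links to every existing node with ``weight_scale`` times
    the mean existing edge weight — a minimal stand-in for augmenting a
    cortical connectome with a densely projecting subcortical nucleus.
    """
    n = conn.n
    w = np.zeros((n + 1, n + 1))
    w[:n, :n] = conn.weights
    hub_w = weight_scale * float(np.mean(conn.weights[conn.weights > 0]))
    w[n, :n] = hub_w
    w[:n, n] = hub_w
    return Connectome(w, list(conn.labels) + [label])


def rewire_connectome(conn: Connectome, kind: str, seed: int = 0) -> Connectome:
    """Topological null of a weighted graph.

    ``lattice``: the weight multiset laid out on a ring lattice (nearest
    neighbours first); ``random``: weights on uniformly random edges;
    ``degree-preserving``: Maslov–Sneppen double-edge swaps, weights
    travelling with their edges; ``strength-preserving``: degree-preserving
    rewire followed by iterative proportional fitting of the weights back
    to the original strength sequence.
    """
    rng = np.random.default_rng(seed)
    w = conn.weights
    n = conn.n
    iu = np.triu_indices(n, 1)
    mask = w[iu] > 0
    weights = w[iu][mask]
    m_edges = weights.size

    def build(pairs, wts):
        out = np.zeros((n, n))
        for (i, j), x in zip(pairs, wts):
            out[i, j] = out[j, i] = x
        return Connectome(out, list(conn.labels))

    if kind == "lattice":
        pairs = _ring_pairs(n)[:m_edges]
        return build(pairs, rng.permutation(weights))
    if kind == "random":
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = rng.choice(len(all_pairs), size=m_edges, replace=False)
        return build([all_pairs[k] for k in chosen], rng.permutation(weights))
    if kind in ("degree-preserving", "strength-preserving"):
        adj = {(i, j): w[i, j] for i, j in zip(*iu) if w[i, j] > 0}
        edges = list(adj.keys())
        n_swaps = 10 * m_edges
        for _ in range(n_swaps):
            e1, e2 = rng.integers(0, m_edges, 2)
            if e1 == e2:
                continue
            (a, b), (c, d) = edges[e1], edges[e2]
            if len({a, b, c, d}) < 4:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in adj or new2 in adj:
                continue
            w1, w2 = adj.pop((a, b)), adj.pop((c, d))
            adj[new1], adj[new2] = w1, w2
            edges[e1], edges[e2] = new1, new2
        rewired = build(list(adj.keys()), list(adj.values()))
        if kind == "degree-preserving":
            return rewired
        return _ipf_strengths(rewired, conn.strengths())
    raise ValueError(f"unknown rewiring kind {kind!r}")


def _ipf_strengths(conn: Connectome, target: np.ndarray,
                   tol: float = 1e-9, max_iter: int = 5000) -> Connectome:
    """Rescale weights on a fixed topology to match a strength sequence."""
    w = conn.weights.copy()
    for _ in range(max_iter):
        s = w.sum(axis=0)
        if np.max(np.abs(s - target) / np.maximum(target, 1e-12)) < tol:
            break
        r = np.sqrt(target / np.maximum(s, 1e-12))
        w = w * np.outer(r, r)
        np.fill_diagonal(w, 0.0)
    return Connectome(w, list(conn.labels))


# ---------------------------------------------------------------------------
# spatial maps, Moran's I and surrogates


def spatial_map(coords: np.ndarray, corr_length: float, seed: int = 0,
                nugget: float = 1e-8) -> RegionalMap:
    """Gaussian random field over region coordinates.

    Squared-exponential covariance exp(-d²/(2ℓ²)); returned raw
    (unnormalized).  Small corr_length gives spatially uncorrelated values,
    large corr_length a smooth gradient.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 4:
        raise ValueError("coords must be (N >= 4) x d positions")
    if corr_length <= 0:
        raise ValueError("corr_length must be positive")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if np.max(d) == 0:
        raise ValueError("degenerate coordinates: all positions identical")
    k = np.exp(-d**2 / (2 * corr_length**2)) + nugget * np.eye(len(coords))
    rng = np.random.default_rng(seed)
    values = _psd_sqrt(k) @ rng.standard_normal(len(coords))
    return RegionalMap(values)


def distance_weights(coords: np.ndarray) -> np.ndarray:
    """Default spatial weight matrix: inverse Euclidean distance, zero
    diagonal, symmetrically scaled to unit mean weight."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    off = w[np.triu_indices_from(w, 1)]
    if off.max() > 0:
        w = w / off.mean()
    return w


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation statistic."""
    z = np.asarray(values, float) - np.mean(values)
    w = np.asarray(weights, float)
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    return float(len(z) / w.sum() * (z @ w @ z) / denom)


def msr_surrogate_maps(m: RegionalMap, weights: np.ndarray, n_surr: int,
                       seed: int = 0, block_tol: float = 0.05,
                       match_distribution: bool = False
                       ) -> list[RegionalMap]:
    """Moran spectral randomization surrogates of a regional map.

    The map is projected onto the eigenvectors of the doubly centred spatial
    weight matrix; surrogates randomize coefficient signs and permute
    coefficients within blocks of near-equal eigenvalue (relative tolerance
    ``block_tol``), then the mean is restored.  Each surrogate preserves the
    input's mean exactly and its Moran's I approximately, while being
    otherwise random.

    With ``match_distribution=True`` each surrogate's ranks are remapped
    onto the input's sorted values, so the value multiset (hence mean,
    range and any normalization) is preserved exactly alongside the
    randomized-but-autocorrelation-like spatial arrangement.  Use this for
    downstream statistics that are sensitive to the value distribution
    (e.g. control weights entering a matrix inverse).
    """
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    w = np.asarray(weights, float)
    n = m.n
    if w.shape != (n, n):
        raise ValueError("weight matrix size does not match map")
    if np.max(np.abs(w - w.T)) > 1e-8 or np.any(w < 0) or np.any(np.diag(w) != 0):
        raise ValueError("weights must be symmetric nonnegative with zero diagonal")
    h = np.eye(n) - np.ones((n, n)) / n
    lam, vec = np.linalg.eigh(h @ w @ h)
    # drop the constant direction (eigenvalue 0 eigenvector ∝ 1)
    keep = np.abs(vec.T @ np.ones(n)) < 1e-8 * np.sqrt(n)
    lam, vec = lam[keep], vec[:, keep]
    order = np.argsort(lam)
    lam, vec = lam[order], vec[:, order]
    mean = float(np.mean(m.values))
    coeff = vec.T @ (m.values - mean)
    # blocks of eigenvalue-similar components
    blocks, start = [], 0
    for i in range(1, lam.size + 1):
        if i == lam.size or abs(lam[i] - lam[start]) > block_tol * max(
                abs(lam[start]), 1e-12):
            blocks.append(np.arange(start, i))
            start = i
    rng = np.random.default_rng(seed)
    sorted_vals = np.sort(m.values)
    out = []
    for _ in range(n_surr):
        c = coeff.copy()
        for b in blocks:
            c[b] = c[rng.permutation(b)]
        c *= rng.choice([-1.0, 1.0], size=c.size)
        vals = mean + vec @ c
        vals = vals - vals.mean() + mean  # enforce exact mean
        if match_distribution:
            ranks = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
            vals = sorted_vals[ranks]
            out.append(RegionalMap(vals, list(m.labels), m.normalized))
        else:
            out.append(RegionalMap(vals, list(m.labels)))
    return out


def time_shuffle_surrogate(ts: RegionalTimeseries, seed: int = 0
                           ) -> RegionalTimeseries:
    """Order-destroying surrogate: one random permutation of timepoints
    applied jointly to all regions.

    Preserves every region's marginal distribution and the zero-lag
    covariance bit-exactly (rows travel together) while destroying all
    past-future structure; used to estimate and subtract estimation bias.
    """
    if ts.n_time < 10:
        raise ValueError("need at least 10 timepoints")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ts.n_time)
    return RegionalTimeseries(ts.values[perm], list(ts.labels), tr=ts.tr)


# ---------------------------------------------------------------------------
# whole studies


@dataclass
class ConditionSpec:
    """Generating parameters for one scanning condition.

    ``coupling_scale`` multiplies the inter-regional coupling (lower under
    anaesthesia-like conditions); ``common_noise`` is the shared fraction of
    innovation variance (higher = more redundancy); ``map_inhibition``
    attenuates each region's incoming coupling in proportion to the study's
    truth map.
    """

    name: str
    coupling_scale: float = 1.0
    common_noise: float = 0.15
    map_inhibition: float = 0.0


#: default study conditions: an awake-like state with full coupling and a
#: deeply anaesthetized state with reduced coupling and more common noise
DEFAULT_CONDITIONS = (
    ConditionSpec("awake", coupling_scale=1.0, common_noise=0.15),
    ConditionSpec("anaesthesia", coupling_scale=0.4, common_noise=0.25),
)

#: graded-arousal design emulating an anaesthesia + thalamic-stimulation
#: study: the anaesthetic reduces coupling and raises common noise;
#: stimulation partially restores coupling while the drug is still present
DBS_CONDITIONS = (
    ConditionSpec("awake", coupling_scale=1.0, common_noise=0.15),
    ConditionSpec("anaesthesia", coupling_scale=0.4, common_noise=0.25),
    ConditionSpec("dbs_low", coupling_scale=0.6, common_noise=0.22),
    ConditionSpec("dbs_high", coupling_scale=0.85, common_noise=0.18),
)


@dataclass
class SyntheticStudy:
    """A complete synthetic multi-subject, multi-condition dataset."""

    subjects: dict          # condition name -> list[RegionalTimeseries]
    connectome: Connectome
    coords: np.ndarray
    truth_map: RegionalMap
    arousal: dict           # condition name -> list[int]
    effect_params: dict
    seed: int

    @property
    def conditions(self) -> list[str]:
        return list(self.subjects.keys())

    @property
    def n_subjects(self) -> int:
        return len(next(iter(self.subjects.values())))


def _study_var_system(conn: Connectome, truth_map: RegionalMap,
                      cond: ConditionSpec, base_radius: float = 0.55,
                      self_coupling: float = 0.2) -> VarSystem:
    """Condition-specific VAR on the study connectome.

    Coupling is the connectome scaled to a base spectral radius, multiplied
    by the condition's coupling scale, with each region's incoming coupling
    attenuated by (1 - map_inhibition * truth_map); nodes keep a fixed
    self-coupling.  Innovations share a common-noise component.
    """
    c = conn.weights
    lam = np.max(np.abs(np.linalg.eigvals(c)))
    a = c / lam * base_radius * cond.coupling_scale
    atten = 1.0 - cond.map_inhibition * truth_map.values
    a = atten[:, None] * a
    a = a + self_coupling * np.eye(conn.n)
    rho = np.max(np.abs(np.linalg.eigvals(a)))
    if rho >= 0.98:  # keep a stationarity margin at extreme scalings
        a = a * (0.98 / rho)
    n = conn.n
    q = (1 - cond.common_noise) * np.eye(n) + cond.common_noise * np.ones((n, n))
    return VarSystem(a, q, list(conn.labels))


def synthetic_study(n_subjects: int = 12, n_regions: int = 30,
                    condition_spec=DEFAULT_CONDITIONS, seed: int = 0,
                    n_time: int = 400, tr: float = 2.0,
                    density: float = 0.3) -> SyntheticStudy:
    """Generate a full study: connectome, truth map, per-subject-condition
    timeseries and arousal scores.

    Arousal is a monotone function of the condition's coupling scale —
    round(11 * coupling_scale) plus integer noise in {-1, 0, 1} — clipped to
    the 0-11 behavioural scale (0 = complete unresponsiveness).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    conditions = list(condition_spec)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValueError("condition names must be unique")
    rng = np.random.default_rng(seed)
    conn = synthetic_connectome(n_regions, density, "modular",
                                seed=int(rng.integers(2**31 - 1)))
    coords = rng.uniform(0, 1, size=(n_regions, 3))
    raw = spatial_map(coords, corr_length=0.3,
                      seed=int(rng.integers(2**31 - 1)))
    v = raw.values
    tm = (v - v.min()) / (v.max() - v.min())
    truth_map = RegionalMap(tm, list(conn.labels), normalized=True)
    subjects = {c.name: [] for c in conditions}
    arousal = {c.name: [] for c in conditions}
    for cond in conditions:
        system = _study_var_system(conn, truth_map, cond)
        for _ in range(n_subjects):
            ts = generate_var(system, n_time,
                              seed=int(rng.integers(2**31 - 1)), tr=tr)
            subjects[cond.name].append(ts)
            score = int(round(11 * cond.coupling_scale)) + int(rng.integers(-1, 2))
            arousal[cond.name].append(int(np.clip(score, 0, 11)))
    effect = {c.name: {"coupling_scale": c.coupling_scale,
                       "common_noise": c.common_noise,
                       "map_inhibition": c.map_inhibition}
              for c in conditions}
    return SyntheticStudy(subjects, conn, coords, truth_map, arousal,
                          effect, seed)


def save_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write a study to disk; returns the path of the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_connectome(study.connectome, outdir / "connectome.tsv")
    write_map(study.truth_map, outdir / "truth_map.tsv")
    np.savetxt(outdir / "coords.tsv", study.coords, delimiter="\t")
    manifest = {"connectome": "connectome.tsv", "truth_map": "truth_map.tsv",
                "coords": "coords.tsv", "seed": study.seed,
                "effect_params": study.effect_params, "conditions": {}}
    for cond, ts_list in study.subjects.items():
        entries = []
        for i, ts in enumerate(ts_list):
            fname = f"ts_{cond}_{i:03d}.tsv"
            write_timeseries(ts, outdir / fname)
            entries.append({"path": fname, "arousal": study.arousal[cond][i]})
        manifest["conditions"][cond] = entries
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)  # keep condition order
        fh.write("\n")
    return mpath


def load_study(manifest_path: str | Path) -> SyntheticStudy:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    conn = read_connectome(root / manifest["connectome"])
    truth_map = read_map(root / manifest["truth_map"])
    coords = np.loadtxt(root / manifest["coords"], delimiter="\t")
    subjects, arousal = {}, {}
    for cond, entries in manifest["conditions"].items():
        subjects[cond] = [read_timeseries(root / e["path"]) for e in entries]
        arousal[cond] = [int(e["arousal"]) for e in entries]
    return SyntheticStudy(subjects, conn, coords, truth_map, arousal,
                          manifest["effect_params"], manifest["seed"])
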