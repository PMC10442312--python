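"""Closed-form source-identification theory on tree approximations.

The pipeline mirrors the chain of model simplifications used to analyse the
backward-tracing algorithms:

1. On the RB tree with the no-recovery epidemic, the probability that LS
   finds the source is ``sum_n (1-p)^n P(d(s,h)=n)`` where ``p`` is the
   probability that a node is asymptomatic given it is not hospitalized and
   ``d(s,h)`` is the transmission-path length to the first hospitalized
   node. For LS+ a combinatorial lower bound weighs each path length by a
   count of household-structured path embeddings, normalized by the RB-tree
   level population (a two-type branching count with eigenvalues
   ``(d_c - 1 +/- D)/2``, ``D = sqrt((d_c-1)^2 + 4 d_c d_h)``).

2. The path-length distribution itself is approximated by collapsing network
   and epidemic into a ``(d_r, d)``-ary random exponential tree (RET): every
   open child slot fills independently with probability ``p_i`` per (rescaled)
   day. Its expected level profile ``a_{t,l}`` has a closed form.

3. Hospitalizations are grafted on via the stopped deterministic exponential
   tree (DET): nodes arrive level by level with a prescribed profile, each
   hospitalized with probability ``(1-p_a) p_h`` in uniform within-day order,
   and growth stops at the first hospitalization. Substituting the RET's
   expected profile into the stopped-DET path-length law yields the analytic
   path-length distribution consumed by step 1.

All series are evaluated in double precision with explicit tail cutoffs
(the discarded terms carry weights below 1e-300 by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .epidemics import EpidemicParams
from .networks import rb_level_count

DEFAULT_N_MAX = 20
DEFAULT_T_MAX = 200
_TINY = 1e-300


@dataclass(frozen=True)
class TheoryParams:
    """Effective parameters of the RET/DET approximation chain."""

    p: float          # asymptomatic probability conditioned on not hospitalized
    p_a: float
    p_h: float
    d_c: int
    d_h: int
    d_r: int          # RET root capacity (= d_c + d_h)
    d: float          # uniform RET degree (branching-stationary mean RB degree)
    p_i_eff: float    # infection probability rescaled to T_E' = 1
    n_max: int = DEFAULT_N_MAX
    t_max: int = DEFAULT_T_MAX

    @classmethod
    def from_epidemic(cls, params: EpidemicParams, d_c: int, d_h: int,
                      n_max: int = DEFAULT_N_MAX,
                      t_max: int = DEFAULT_T_MAX) -> "TheoryParams":
        p = p_asym_given_not_hosp(params.p_a, params.p_h)
        p_i_eff, d_r, d = effective_params(params.p_i, params.T_E, d_c, d_h)
        return cls(p=p, p_a=params.p_a, p_h=params.p_h, d_c=d_c, d_h=d_h,
                   d_r=d_r, d=d, p_i_eff=p_i_eff, n_max=n_max, t_max=t_max)


@dataclass
class PathLengthDistribution:
    """Probability mass over transmission-path length n = 0..n_max."""

    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < -1e-12):
            raise ValueError("negative mass")
        self.mass = np.clip(self.mass, 0.0, None)

    @property
    def n_max(self) -> int:
        return len(self.mass) - 1

    @property
    def truncation_deficit(self) -> float:
        return max(0.0, 1.0 - float(self.mass.sum()))

    @classmethod
    def point_mass(cls, n: int, n_max: Optional[int] = None) -> "PathLengthDistribution":
        m = np.zeros((n_max if n_max is not None else n) + 1)
        m[n] = 1.0
        return cls(m)


def p_asym_given_not_hosp(p_a: float, p_h: float) -> float:
    """P(asymptomatic | not hospitalized) = p_a / (p_a + (1-p_a)(1-p_h))."""
    denom = p_a + (1.0 - p_a) * (1.0 - p_h)
    if denom == 0.0:
        raise ValueError("degenerate parameters: every node is hospitalized")
    return p_a / denom


def ls_success_probability(dist: PathLengthDistribution, p: float) -> float:
    """Exact LS success on the tree model: sum_n (1-p)^n * P(d(s,h)=n)."""
    n = np.arange(len(dist.mass))
    return float(np.sum((1.0 - p) ** n * dist.mass))


def valid_k_set(n: int, alpha: int, beta: int) -> list[int]:
    """Integers k with parity(k) != parity(n), 2-(a+b) <= k <= n+1-2(a+b)."""
    lo, hi = 2 - (alpha + beta), n + 1 - 2 * (alpha + beta)
    return [k for k in range(lo, hi + 1) if (k - n) % 2 != 0]


def _rb_eigen(d_c: int, d_h: int) -> tuple[float, float, float]:
    """(D, lambda1, lambda2) of the red/blue level recurrence."""
    D = math.sqrt((d_c - 1) ** 2 + 4 * d_c * d_h)
    lam1 = (d_c + 1 + D) * (2 * d_h + d_c - 1 + D) / (2 * D * (d_c - 1 + D))
    lam2 = (D - d_c - 1) * (2 * d_h + d_c - 1 - D) / (2 * D * (d_c - 1 - D))
    return D, lam1, lam2


def rb_level_count_closed_form(d_c: int, d_h: int, n: int) -> float:
    """Spectral form of the RB level population; matches rb_level_count."""
    if n == 0:
        return 1.0
    if d_h == 0:
        # single-type tree: the spectral form degenerates (D = d_c - 1)
        return float(d_c * (d_c - 1) ** (n - 1))
    D, lam1, lam2 = _rb_eigen(d_c, d_h)
    return lam1 * ((d_c - 1 + D) / 2) ** n + lam2 * ((d_c - 1 - D) / 2) ** n


def ls_plus_success_lower_bound(dist: PathLengthDistribution, p: float,
                                d_c: int, d_h: int) -> float:
    """Lower bound on LS+ success by counting household-path embeddings.

    A length-``n`` path in the RB tree decomposes into ``k`` nodes that are
    the only path node in their household and ``j = (n+1-k)/2`` households
    contributing two path nodes (a red head and one blue child); binary
    indicators ``alpha`` / ``beta`` record whether the source / the endpoint
    shares its household with another path node. LS+ provably succeeds when
    the source is symptomatic and every path household contains a
    symptomatic path node, so an embedding of type ``(k, alpha, beta)``
    succeeds with probability at least
    ``(1-p)^{k+j-1} (1-p^2)^{j-alpha-beta}`` (the endpoint's household is
    free — it holds the hospitalized node — as is the second member of the
    source's or endpoint's own two-node household). There are
    ``C(k+j-2, k-2+alpha+beta) d_h^j d_c^{j-alpha-beta+1} (d_c-1)^{k+alpha+beta-2}``
    such paths among the ``rb_level_count(n)`` endpoints at level ``n``; at
    ``p = 0`` the weighted counts sum to exactly that level population.

    ``d_c = 1`` degenerates the embedding count; the LS value (itself a
    lower bound for LS+) is returned in that case.
    """
    if d_c < 1:
        raise ValueError("d_c must be >= 1")
    if d_c == 1:
        return ls_success_probability(dist, p)
    mass = dist.mass
    total = float(mass[0]) if len(mass) > 0 else 0.0
    if len(mass) > 1:
        total += (1.0 - p) * float(mass[1])
    for n in range(2, len(mass)):
        if mass[n] == 0.0:
            continue
        denom = rb_level_count_closed_form(d_c, d_h, n)
        s = 0.0
        for alpha in (0, 1):
            for beta in (0, 1):
                for k in valid_k_set(n, alpha, beta):
                    j = (n + 1 - k) // 2
                    top = k + j - 2
                    low = k - 2 + alpha + beta
                    if low < 0 or top < 0 or low > top:
                        continue  # combinatorially empty configuration
                    s += (
                        math.comb(top, low)
                        * d_h ** j
                        * (1.0 - p) ** (k + j - 1)
                        * (d_c * (1.0 + p)) ** (j - alpha - beta)
                        * d_c
                        * (d_c - 1) ** (k + alpha + beta - 2)
                    )
        total += s / denom * float(mass[n])
    return total


# ---------------------------------------------------------------------------
# Random exponential trees
# ---------------------------------------------------------------------------


def ret_expected_profile(t: int, l: int, d_r: float, d: float, p_i: float) -> float:
    """Expected number of RET nodes at level l on day t.

    ``a_{t,0} = 1``; for ``t >= l >= 1``,
    ``a_{t,l} = d_r p_i (d p_i)^{l-1} sum_{m=l-1}^{t-1} C(m, l-1) (1-p_i)^{m-l+1}``;
    zero for ``l > t``.
    """
    if t < 0 or l < 0:
        raise ValueError("t and l must be >= 0")
    if l == 0:
        return 1.0
    if l > t:
        return 0.0
    s = sum(
        math.comb(m, l - 1) * (1.0 - p_i) ** (m - l + 1) for m in range(l - 1, t)
    )
    return d_r * p_i * (d * p_i) ** (l - 1) * s


def ret_expected_size(t: int, d_r: float, d: float, p_i: float) -> float:
    """Expected RET size on day t: 1 + d_r ((1-p_i+d p_i)^t - 1)/(d-1)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if d == 1:
        raise ValueError("d must differ from 1 (degenerate growth factor)")
    return 1.0 + d_r * ((1.0 - p_i + d * p_i) ** t - 1.0) / (d - 1.0)


def effective_params(p_i: float, T_E: int, d_c: int, d_h: int
                     ) -> tuple[float, int, float]:
    """Map epidemic/network parameters onto the RET's (p_i_eff, d_r, d).

    Time is rescaled so one unit equals the exposed period:
    ``p_i_eff = 1 - (1-p_i)^{T_E}``. The root keeps the RB root degree
    ``d_r = d_c + d_h``. The uniform degree ``d`` is the mean RB-tree degree
    under the stationary red/blue composition of the branching process
    (red fraction ``f_r = rho / (rho + d_h)`` with ``rho`` the leading
    eigenvalue of the level recurrence): red nodes have degree
    ``d_c + d_h``, blue nodes ``d_c + 1``.
    """
    p_i_eff = 1.0 - (1.0 - p_i) ** T_E
    d_r = d_c + d_h
    if d_h == 0:
        return p_i_eff, d_r, float(d_c)
    D = math.sqrt((d_c - 1) ** 2 + 4 * d_c * d_h)
    rho = (d_c - 1 + D) / 2.0
    f_r = rho / (rho + d_h)
    d = f_r * (d_c + d_h) + (1.0 - f_r) * (d_c + 1)
    return p_i_eff, d_r, d


# ---------------------------------------------------------------------------
# Stopped deterministic / random exponential trees
# ---------------------------------------------------------------------------


def det_stopped_path_dist(c: Sequence[Sequence[float]], p_a: float, p_h: float
                          ) -> PathLengthDistribution:
    """Path-length law of the stopped DET with level profile ``c[t][l]``.

    Nodes arrive in uniform random within-day order, each hospitalized with
    probability ``(1-p_a) p_h``; the tree stops at the first hospitalization.
    The first hospitalized node sits at level l with probability
    ``sum_t (c_{t,l}-c_{t-1,l})/(c_t-c_{t-1}) q^{c_{t-1}} (1-q^{c_t-c_{t-1}})``
    with ``q = 1-(1-p_a) p_h`` (0^0 = 1). Fractional profiles are accepted.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2:
        raise ValueError("profile must be a 2-D array c[t][l]")
    if c[0, 0] != 1.0 or np.any(c[0, 1:] != 0.0):
        raise ValueError("profile must start from a single root: c[0] = (1, 0, ...)")
    if np.any(np.diff(c, axis=0) < -1e-12):
        raise ValueError("levels may never shrink: require c[t,l] >= c[t-1,l]")
    totals = c.sum(axis=1)
    growth = np.diff(np.concatenate([[0.0], totals]))
    if np.any(growth <= 0.0):
        raise ValueError("total size must strictly grow: require c_t > c_{t-1}")

    q = 1.0 - (1.0 - p_a) * p_h
    T, L = c.shape
    mass = np.zeros(L)
    prev_total = 0.0
    prev_row = np.zeros(L)
    for t in range(T):
        delta = totals[t] - prev_total
        survive = q ** prev_total if prev_total > 0 else 1.0
        if survive < _TINY:
            break
        hit = 1.0 - q ** delta
        mass += (c[t] - prev_row) / delta * survive * hit
        prev_total = totals[t]
        prev_row = c[t]
    return PathLengthDistribution(mass)


def ret_profile_array(params: TheoryParams, t_max: Optional[int] = None,
                      l_max: Optional[int] = None) -> np.ndarray:
    """The expected RET profile a_{t,l} as a DET-ready array."""
    T = (t_max if t_max is not None else params.t_max) + 1
    L = (l_max if l_max is not None else params.n_max) + 1
    out = np.zeros((T, L))
    for t in range(T):
        for l in range(L):
            out[t, l] = ret_expected_profile(t, l, params.d_r, params.d,
                                             params.p_i_eff)
    return out


def ret_stopped_path_dist(params: TheoryParams) -> PathLengthDistribution:
    """Analytic path-length law of the stopped (d_r, d)-RET.

    This is the stopped-DET law evaluated on the RET's expected profile
    ``a_{t,l}`` (so ``c_t - c_{t-1} = d_r p_i (1-p_i+d p_i)^{t-1}`` and
    ``c_{t-1} = a_{t-1}``), written out so the t-sum can run far beyond any
    materialized array. The l = 0 term is the root's own day-0
    hospitalization mass ``(1-p_a) p_h``.
    """
    p_i, d_r, d = params.p_i_eff, params.d_r, params.d
    if d == 1:
        raise ValueError("d must differ from 1")
    q = 1.0 - (1.0 - params.p_a) * params.p_h
    mass = np.zeros(params.n_max + 1)
    mass[0] = 1.0 - q
    if p_i > 0.0:
        growth = 1.0 - p_i + d * p_i
        for l in range(1, params.n_max + 1):
            acc = 0.0
            for t in range(l, params.t_max + 1):
                g_tm1 = growth ** (t - 1)
                a_prev = 1.0 + d_r * (g_tm1 - 1.0) / (d - 1.0)
                survive = q ** a_prev
                if survive < _TINY:
                    break
                ratio = (
                    (d * p_i) ** (l - 1)
                    * math.comb(t - 1, l - 1)
                    * (1.0 - p_i) ** (t - l)
                    / g_tm1
                )
                acc += ratio * survive * (1.0 - q ** (d_r * p_i * g_tm1))
            mass[l] = acc
    return PathLengthDistribution(mass)


def simulate_ret_profiles(d_r: int, d: int, p_i: float, t: int, n_reps: int,
                          seed: int) -> np.ndarray:
    """Monte-Carlo RET level counts: array of shape (n_reps, t+1, t+1).

    ``out[r, s, l]`` is the number of nodes replicate ``r`` has at level
    ``l`` on day ``s``. Only per-level counts are needed for profile
    statistics, so open child slots are tracked per level and filled with
    vectorized binomial draws. ``d``-ary means ``d`` child slots per
    non-root node (the root has ``d_r``), matching the level law
    ``a_{t,l} ~ (d p_i)^{l-1}`` and the size recurrence
    ``S_t = S_{t-1} (1 - p_i + d p_i)`` for open slots.
    """
    rng = np.random.default_rng(seed)
    L = t + 1
    counts = np.zeros((n_reps, L), dtype=np.int64)
    slots = np.zeros((n_reps, L + 1), dtype=np.int64)
    counts[:, 0] = 1
    slots[:, 1] = d_r
    out = np.zeros((n_reps, t + 1, L), dtype=np.int64)
    out[:, 0] = counts
    for day in range(1, t + 1):
        new = rng.binomial(slots[:, :L], p_i)
        counts += new
        slots[:, :L] -= new
        slots[:, 1:] += new * d
        out[:, day] = counts
    return out


def simulate_ret_stopped(d_r: int, d: float, p_i: float, p_a: float, p_h: float,
                         seed, t_max: int = 200, max_size: float = 1e7
                         ) -> tuple[np.ndarray, Optional[int]]:
    """One stopped-RET run: grow day by day, halt at the first hospitalization.

    ``d`` is rounded to the nearest integer for slot counts (the analytic
    formulas keep it fractional). Each day's new nodes are ordered by a
    uniform random permutation and hospitalized independently with
    probability ``(1-p_a) p_h``; by permutation symmetry the first
    hospitalized node is uniform over the day's arrivals, so its level is a
    categorical draw over the day's per-level counts. Returns the level-count
    profile at the stopping day and the level of the hospitalized node
    (``None`` if no hospitalization occurred: caller discards the run).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_int = int(round(d))
    q_hosp = (1.0 - p_a) * p_h
    counts = np.zeros(t_max + 2, dtype=np.int64)
    slots = np.zeros(t_max + 2, dtype=np.int64)
    counts[0] = 1
    slots[1] = d_r
    if rng.random() < q_hosp:  # the root's own draw on day 0
        return counts[:1].copy(), 0
    for day in range(1, t_max + 1):
        new = rng.binomial(slots[: day + 1], p_i)
        m = int(new.sum())
        if m > 0 and rng.random() < 1.0 - (1.0 - q_hosp) ** m:
            level = int(rng.choice(day + 1, p=new / m))
            counts[: day + 1] += new
            return counts[: day + 1].copy(), level
        counts[: day + 1] += new
        slots[: day + 1] -= new
        slots[1 : day + 2] += new * d_int
        if counts.sum() > max_size:
            break
    return counts.copy(), None


def predict_success(kind: str, params: EpidemicParams, d_c: int, d_h: int,
                    n_max: int = DEFAULT_N_MAX,
                    t_max: int = DEFAULT_T_MAX) -> float:
    """Analytic success probability (LS: exact on the model; LS+: lower bound).

    Composes the effective-parameter mapping, the stopped-RET path-length
    law, and the per-path-length success formulas.
    """
    if kind not in ("LS", "LS+"):
        raise ValueError("kind must be 'LS' or 'LS+'")
    tp = TheoryParams.from_epidemic(params, d_c, d_h, n_max=n_max, t_max=t_max)
    dist = ret_stopped_path_dist(tp)
    if kind == "LS":
        return ls_success_probability(dist, tp.p)
    return ls_plus_success_lower_bound(dist, tp.p, d_c, d_h)
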