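"""Seeded experiment batches: sweeps, metrics, and theory overlays.

A run draws a fresh network (or RB tree), a uniform random source, simulates
the epidemic until the first hospitalization (runs with none within the
horizon are discarded and redrawn, with discards counted), then executes
each algorithm through its own sealed oracle on the shared trace — so
algorithms are compared at equal epidemics. Success rates carry Wilson score
intervals; mean query counts carry Student-t intervals. Everything is a
deterministic function of the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .epidemics import EpidemicParams, simulate_dde, simulate_dde_nr
from .local_search import VARIANTS, run_local_search
from .networks import RBTree, generate_hnm
from .oracle import SictfOracle
from .size_gain import SGConfig, run_size_gain

ALGORITHMS = VARIANTS + ("SG",)


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    # the Wilson bounds are exactly 0 / 1 at the extremes; clamp float fuzz
    lo = 0.0 if k == 0 else max(0.0, float(lo))
    hi = 1.0 if k == n else min(1.0, float(hi))
    return lo, hi


def mean_interval(xs, confidence: float = 0.95) -> tuple[float, float, float]:
    """(mean, low, high) using the Student-t distribution."""
    xs = np.asarray(xs, dtype=float)
    m = float(xs.mean())
    if len(xs) < 2 or xs.std(ddof=1) == 0.0:
        return m, m, m
    half = float(
        stats.t.ppf((1 + confidence) / 2, len(xs) - 1)
        * xs.std(ddof=1) / np.sqrt(len(xs))
    )
    return m, m - half, m + half


@dataclass
class SweepConfig:
    """One parameter sweep: vary ``param`` over ``grid`` at fixed defaults."""

    param: str                      # name of the swept field ('p_a', 'p_h', 'p_i', 'd_h', 'd_c')
    grid: tuple = ()
    base_params: EpidemicParams = field(default_factory=EpidemicParams)
    N: int = 402
    d_h: int = 2
    d_c: int = 3
    realizations: int = 4800
    algorithms: tuple = ("LS", "LS+")
    base_seed: int = 0
    horizon: int = 100
    substrate: str = "hnm"          # 'hnm' (DDE) or 'rb_tree' (no-recovery variant)
    sg_config: SGConfig = field(default_factory=SGConfig)
    sg_deadline_extra: int = 14     # fallback deadline when LS/LS+ are absent
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("grid must be nonempty")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")

    def point_settings(self, value) -> tuple[EpidemicParams, int, int]:
        """(params, d_h, d_c) at one grid value of the swept parameter."""
        if self.param in ("d_h", "d_c"):
            d_h = int(value) if self.param == "d_h" else self.d_h
            d_c = int(value) if self.param == "d_c" else self.d_c
            return self.base_params, d_h, d_c
        return replace(self.base_params, **{self.param: value}), self.d_h, self.d_c


def _draw_conditioned_trace(substrate: str, N: int, d_h: int, d_c: int,
                            params: EpidemicParams, horizon: int,
                            seed_seq: np.random.SeedSequence,
                            max_redraws: int = 200):
    """Redraw (network, source, epidemic) until a hospitalization is observed."""
    discards = 0
    for child in seed_seq.spawn(max_redraws):
        s_net, s_src, s_epi = (int(s) for s in child.generate_state(3) % (2**31))
        if substrate == "hnm":
            net = generate_hnm(N, d_h, d_c, seed=s_net)
            source = int(np.random.default_rng(s_src).integers(N))
            trace = simulate_dde(net, source, params, seed=s_epi, horizon=horizon)
        else:
            net = RBTree(d_c, d_h)
            trace = simulate_dde_nr(net, params, seed=s_epi, horizon=horizon)
        if trace.first_hospitalized is not None:
            return net, trace, discards
        discards += 1
    raise RuntimeError(
        f"no hospitalization in {max_redraws} redraws; parameters likely degenerate"
    )


def run_point(config: SweepConfig, value, n_runs: Optional[int] = None) -> pd.DataFrame:
    """Per-run records for all algorithms at one grid point."""
    params, d_h, d_c = config.point_settings(value)
    n_runs = n_runs or config.realizations
    records = []
    for i in range(n_runs):
        param_key = int.from_bytes(config.param.encode(), "little") % (2**31)
        ss = np.random.SeedSequence((config.base_seed, param_key,
                                     int(round(float(value) * 10**6)), i))
        net, trace, discards = _draw_conditioned_trace(
            config.substrate, config.N, d_h, d_c, params, config.horizon, ss
        )
        ls_days = {}
        for alg in config.algorithms:
            if alg == "SG":
                continue
            oracle = SictfOracle(trace, net)
            res = run_local_search(oracle, alg)
            ls_days[alg] = res.days_elapsed
            records.append(
                {"param": config.param, "value": value, "algorithm": alg,
                 "run": i, "discards": discards, **res.to_dict()}
            )
        if "SG" in config.algorithms:
            detect_day = trace.first_hospitalized[1]
            if ls_days:
                deadline = detect_day + max(ls_days.values())
            else:
                deadline = detect_day + config.sg_deadline_extra
            oracle = SictfOracle(trace, net)
            sg_seed = int(ss.generate_state(4)[3] % (2**31))
            res = run_size_gain(oracle, net, deadline_day=deadline, seed=sg_seed,
                                config=config.sg_config)
            records.append(
                {"param": config.param, "value": value, "algorithm": "SG",
                 "run": i, "discards": discards, **res.to_dict()}
            )
    return pd.DataFrame.from_records(records)


def summarize(runs: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Aggregate per-run records into one row per (point, algorithm)."""
    rows = []
    for (param, value, alg), g in runs.groupby(["param", "value", "algorithm"],
                                               sort=True):
        n = len(g)
        k_src = int(g["found_source"].sum())
        k_fs = int(g["found_first_symptomatic"].sum())
        lo_s, hi_s = wilson_interval(k_src, n, confidence)
        lo_f, hi_f = wilson_interval(k_fs, n, confidence)
        t_m, t_lo, t_hi = mean_interval(g["tests_used"], confidence)
        e_m, e_lo, e_hi = mean_interval(g["edges_revealed"], confidence)
        rows.append({
            "param": param, "value": value, "algorithm": alg, "runs": n,
            "discarded_runs": int(g["discards"].sum()),
            "success_source": k_src / n,
            "success_source_low": lo_s, "success_source_high": hi_s,
            "success_first_symptomatic": k_fs / n,
            "success_first_symptomatic_low": lo_f,
            "success_first_symptomatic_high": hi_f,
            "tests_mean": t_m, "tests_low": t_lo, "tests_high": t_hi,
            "edges_mean": e_m, "edges_low": e_lo, "edges_high": e_hi,
        })
    return pd.DataFrame(rows)


def run_experiment(config: SweepConfig) -> pd.DataFrame:
    """Full sweep: one summary row per (grid point, algorithm)."""
    frames = [run_point(config, v) for v in config.grid]
    return summarize(pd.concat(frames, ignore_index=True), config.confidence)


def overlay_theory(rows: pd.DataFrame, config: SweepConfig,
                   n_max: int = 20) -> pd.DataFrame:
    """Join simulated rates with analytic predictions; flag disagreements.

    Adds ``prediction`` (the analytic LS value or LS+ lower bound at each
    grid point) and ``flag``: for LS, the prediction leaving the Wilson band;
    for LS+, the lower bound exceeding the simulated rate by more than the
    band half-width.
    """
    from .theory import predict_success

    rows = rows.copy()
    preds, flags = [], []
    grid_vals = set(rows["value"])
    if not grid_vals <= set(config.grid):
        raise ValueError("rows contain grid points absent from the config")
    for _, r in rows.iterrows():
        if r["algorithm"] not in ("LS", "LS+"):
            preds.append(np.nan)
            flags.append(False)
            continue
        params, d_h, d_c = config.point_settings(r["value"])
        pred = predict_success(r["algorithm"], params, d_c, d_h, n_max=n_max)
        preds.append(pred)
        if r["algorithm"] == "LS":
            flags.append(
                not (r["success_source_low"] <= pred <= r["success_source_high"])
            )
        else:
            half = (r["success_source_high"] - r["success_source_low"]) / 2
            flags.append(pred > r["success_source"] + half)
    rows["prediction"] = preds
    rows["flag"] = flags
    return rows
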