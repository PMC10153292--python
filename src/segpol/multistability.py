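"""Multistability screen: how often does a random parameter set admit more
than one steady state?

For each of ``p`` random parameter sets (drawn with the same log-uniform
rules as the robustness screens), ``i`` random initial conditions are
sampled uniformly in [0, 1] over all 132 species concentrations of the
1 x 4 model and relaxed to steady state by integration only.  The states
found are clustered (single linkage, max-norm, tolerance well above the
steady-state resolution so one basin is not split by integration error)
and a parameter set counts as multistable when more than one distinct
state remains.  Runs that fail to converge — limit-cycle suspects —
contribute no steady state.

The mono- vs multi-stable parameter distributions are then compared by
the per-parameter ratio of medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ParameterSet
from .grid import GridSpec, build_grid
from .kinetics import GuardConfig
from .model import build_model
from .sampling import SamplingConfig, sample_parameters
from .simulate import SteadyStateConfig, find_steady_state

__all__ = [
    "MultistabilityConfig",
    "MultistabilityResult",
    "multistability_screen",
    "cluster_states",
    "median_fold_comparison",
    "distribution_plots",
]


@dataclass(frozen=True)
class MultistabilityConfig:
    p: int = 5000            # parameter sets
    i: int = 15              # initial conditions per set
    distinct_tol: float = 1e-2  # max-norm clustering tolerance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.i < 2:
            raise ValueError("i must be >= 2 for multistability to be detectable")
        if self.distinct_tol <= 0:
            raise ValueError("distinct_tol must be positive")


@dataclass
class MultistabilityResult:
    config: MultistabilityConfig
    per_set: pd.DataFrame        # one row per parameter set
    parameters: pd.DataFrame     # sampled parameter values per set
    states: list[list[np.ndarray]] = field(repr=False, default_factory=list)

    @property
    def n_with_steady_state(self) -> int:
        return int((self.per_set["distinct_states"] >= 1).sum())

    @property
    def n_multistable(self) -> int:
        return int((self.per_set["distinct_states"] > 1).sum())

    def summary(self) -> dict:
        p = self.config.p
        n_ss = self.n_with_steady_state
        return {
            "p": p, "i": self.config.i, "seed": self.config.seed,
            "n_with_steady_state": n_ss,
            "n_multistable": self.n_multistable,
            "fraction_with_steady_state": n_ss / p,
            "fraction_multistable_among_ss": (
                self.n_multistable / n_ss if n_ss else float("nan")),
        }

    def split_parameters(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(monostable, multistable) sampled-parameter tables."""
        d = self.per_set["distinct_states"]
        mono = self.parameters[(d == 1).to_numpy()]
        multi = self.parameters[(d > 1).to_numpy()]
        return mono.reset_index(drop=True), multi.reset_index(drop=True)


def cluster_states(states: list[np.ndarray], tol: float) -> tuple[int, list[np.ndarray]]:
    """Single-linkage grouping under max-norm distance <= tol.

    Returns (number of groups, one representative per group).
    """
    states = [np.asarray(s, dtype=float) for s in states]
    n = len(states)
    if n == 0:
        return 0, []
    # union-find over pairwise links
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if np.max(np.abs(states[a] - states[b])) <= tol:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    reps = {}
    for a in range(n):
        reps.setdefault(find(a), states[a])
    return len(reps), list(reps.values())


def multistability_screen(
    cfg: MultistabilityConfig | None = None,
    sampling_cfg: SamplingConfig | None = None,
    ss_cfg: SteadyStateConfig | None = None,
    guard: GuardConfig | None = None,
) -> MultistabilityResult:
    """Run the p x i steady-state screen on the 1 x 4 model."""
    if cfg is None:
        cfg = MultistabilityConfig()
    if sampling_cfg is None:
        sampling_cfg = SamplingConfig()
    if ss_cfg is None:
        ss_cfg = SteadyStateConfig()
    if guard is None:
        guard = GuardConfig()
    grid = build_grid(GridSpec(1, 4))
    sampled = sampling_cfg.catalog.sampled_names

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.p)
    rows = []
    prows = []
    all_states: list[list[np.ndarray]] = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = sample_parameters(sampling_cfg, rng)
        model = build_model(grid, params, guard)
        found: list[np.ndarray] = []
        failures = 0
        unconverged = 0
        for _ in range(cfg.i):
            x0 = rng.uniform(0.0, 1.0, model.n_states)
            res = find_steady_state(model, x0, ss_cfg)
            if res.found:
                found.append(res.state)
            elif res.failed:
                failures += 1
            else:
                unconverged += 1
        n_distinct, _ = cluster_states(found, cfg.distinct_tol)
        rows.append({"set": k, "steady_states_found": len(found),
                     "distinct_states": n_distinct,
                     "unconverged": unconverged, "failures": failures})
        prows.append({p: params[p] for p in sampled})
        all_states.append(found)
    return MultistabilityResult(
        config=cfg,
        per_set=pd.DataFrame(rows),
        parameters=pd.DataFrame(prows),
        states=all_states,
    )


def median_fold_comparison(mono: pd.DataFrame, multi: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter fold change of medians, multi / mono, sorted by |log fold|."""
    if len(mono) == 0 or len(multi) == 0:
        raise ValueError("both parameter sets must be nonempty")
    common = [c for c in mono.columns if c in multi.columns]
    recs = []
    for c in common:
        md_mono = float(mono[c].median())
        md_multi = float(multi[c].median())
        fold = md_multi / md_mono
        recs.append({"parameter": c, "median_mono": md_mono,
                     "median_multi": md_multi, "fold": fold,
                     "abs_log_fold": abs(np.log(fold))})
    df = pd.DataFrame(recs).sort_values(
        "abs_log_fold", ascending=False).reset_index(drop=True)
    return df


def distribution_plots(
    mono: pd.DataFrame,
    multi: pd.DataFrame,
    parameters: tuple[str, str] = ("kappa_CNptc", "kappa_CNen"),
    sampling_cfg: SamplingConfig | None = None,
    n_bins: int = 20,
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables for a parameter pair: scatter points + log histograms."""
    if sampling_cfg is None:
        sampling_cfg = SamplingConfig()
    for p in parameters:
        if p not in mono.columns or p not in multi.columns:
            raise KeyError(f"unknown parameter {p!r}")
    px, py = parameters
    scatter = pd.concat([
        pd.DataFrame({px: mono[px], py: mono[py], "class": "monostable"}),
        pd.DataFrame({px: multi[px], py: multi[py], "class": "multistable"}),
    ]).reset_index(drop=True)
    hists = {}
    for p in parameters:
        lo, hi = sampling_cfg.range_of(p)
        edges = np.geomspace(lo, hi, n_bins + 1)
        h_mono, _ = np.histogram(mono[p], bins=edges)
        h_multi, _ = np.histogram(multi[p], bins=edges)
        hists[p] = pd.DataFrame({
            "bin_low": edges[:-1], "bin_high": edges[1:],
            "monostable": h_mono, "multistable": h_multi})
    return {"scatter": scatter, **{f"hist_{p}": h for p, h in hists.items()}}
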