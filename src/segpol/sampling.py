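"""Random-parameter sampling, initial-condition schemes, and the hit screen.

This is the package's synthetic-data generator: it draws the 48 sampled
kinetic parameters log-uniformly over their catalog ranges (PTC0/HH0 in
1..1000), builds the preset starting states used by the robustness
screens, and drives attempt -> sample -> integrate -> classify loops with
per-attempt child seeds for bit-reproducible tallies.

Initial-condition levels follow the three-level vocabulary 0.15 / 0.4 /
0.9 (standing for "< 20%", "20-60%" and "60-100%" of a species' range).
The seven preset schemes are reconstructions of the screen rows of the
reference study; the exact per-species assignments of the stripe/band
schemes were never tabulated, so they are best-effort and configurable
(the ``degraded`` scheme ships in ``data/degraded_ic.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .catalog import ParameterCatalog, ParameterSet, load_catalog
from .grid import CellGrid, GridSpec, build_grid
from .kinetics import GuardConfig
from .model import build_model
from .scoring import HIT_THRESHOLD, PatternTemplate, classify_screen_run, default_template
from .simulate import SimulationConfig, integrate

__all__ = [
    "SCHEMES",
    "SamplingConfig",
    "ScreenResult",
    "sample_parameters",
    "initial_condition",
    "run_screen",
    "plot_solutions",
]

SCHEMES = (
    "crisp",
    "degraded",
    "crisp_plus_ci_ptc",
    "ci_band_wg_stripe",
    "ptc_band_en_stripe",
    "ptc_band_ci_band",
    "near_target",
)

_LO, _MID, _HI = 0.15, 0.4, 0.9


@dataclass(frozen=True)
class SamplingConfig:
    """Log-ranges for the sampled parameters (defaults from the catalog)."""

    catalog: ParameterCatalog = field(default_factory=load_catalog)
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def range_of(self, name: str) -> tuple[float, float]:
        if name in self.overrides:
            lo, hi = self.overrides[name]
        else:
            e = self.catalog[name]
            lo, hi = e.lo, e.hi
        if not (0 < lo <= hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        return float(lo), float(hi)


def sample_parameters(cfg: SamplingConfig | None = None,
                      rng: np.random.Generator | None = None) -> ParameterSet:
    """Draw the 48 sampled parameters log-uniformly; rest at catalog defaults."""
    if cfg is None:
        cfg = SamplingConfig()
    if rng is None:
        rng = np.random.default_rng()
    vals: dict[str, float | None] = {}
    for e in cfg.catalog.entries:
        if e.sampled:
            lo, hi = cfg.range_of(e.name)
            vals[e.name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            vals[e.name] = e.default
    return ParameterSet(vals, catalog=cfg.catalog)


# ---------------------------------------------------------------------------
# initial-condition schemes
# ---------------------------------------------------------------------------

def _load_degraded() -> dict[str, list[float]]:
    text = (resources.files("segpol") / "data" / "degraded_ic.yaml").read_text()
    return yaml.safe_load(text)


def _scheme_levels(scheme: str) -> dict[str, list[float]]:
    """Per-species, per-cell levels for the 1 x 4 presets (background 0.15)."""
    wg_stripe = [_LO, _HI, _LO, _LO]       # cell 2
    en_stripe = [_LO, _LO, _HI, _LO]       # cell 3
    band_no3 = [_HI, _HI, _LO, _HI]        # 3-cell band omitting cell 3
    band_no1 = [_LO, _HI, _HI, _HI]        # out-of-phase band omitting cell 1
    ci_broad = [_HI, _HI, _LO, _HI]        # ci complementary to the en stripe

    if scheme == "crisp":
        return {s: wg_stripe for s in ("wg", "IWG", "EWG")} | {
            s: en_stripe for s in ("en", "EN", "hh", "HH")}
    if scheme == "degraded":
        return dict(_load_degraded())
    if scheme == "crisp_plus_ci_ptc":
        return _scheme_levels("crisp") | {
            "ci": [_LO] * 4, "CI": [_LO] * 4,
            "ptc": [_LO] * 4, "PTC": [_LO] * 4}
    if scheme == "ci_band_wg_stripe":
        return {"ci": band_no3, "CI": band_no3,
                "wg": wg_stripe, "IWG": wg_stripe, "EWG": wg_stripe}
    if scheme == "ptc_band_en_stripe":
        return {"ptc": band_no3, "PTC": band_no3,
                "en": en_stripe, "EN": en_stripe}
    if scheme == "ptc_band_ci_band":
        return {"ptc": band_no3, "PTC": band_no3,
                "ci": band_no1, "CI": band_no1}
    if scheme == "near_target":
        # "close to target" = close to the solution state.  In the target
        # the en cell has shut ci (and hence ptc, CI, CN) fully off, so
        # those coordinates are 0 there, not merely low; and the derived
        # repressor CN is part of the state: high where free PTC drives
        # cleavage (cells 1 and 4), low in the HH-cleared wg cell.
        zero3 = [_HI, _HI, 0.0, _HI]
        ptc_target = [_LO, _HI, 0.0, _LO]
        return ({s: wg_stripe for s in ("wg", "IWG", "EWG")}
                | {s: en_stripe for s in ("en", "EN", "hh", "HH")}
                | {"ptc": ptc_target, "PTC": ptc_target,
                   "ci": zero3, "CI": zero3,
                   "CN": [_HI, _LO, 0.0, _HI]})
    raise KeyError(f"unknown initial-condition scheme {scheme!r}; "
                   f"known: {SCHEMES}")


def initial_condition(scheme: str, grid: CellGrid | GridSpec) -> np.ndarray:
    """Full state vector for a named scheme on the 1 x 4 row.

    Level semantics: a level is a fraction of the species' attainable
    range, using the three-level vocabulary 0.15 / 0.4 / 0.9.  The levels
    annotate the species a scheme names — a striped species carries 0.15
    in its OFF cells — and species a scheme does not mention start at 0
    (this is what makes "crisp plus ubiquitous low-level ci and ptc" a
    distinct condition from plain crisp).  A membrane species' level is
    distributed across its six side pools (level / 6 per side), since
    translation splits its supply six ways and the attainable per-side
    range is one sixth of the cytosolic one.
    """
    if isinstance(grid, GridSpec):
        grid = build_grid(grid)
    if (grid.spec.rows, grid.spec.cols) != (1, 4):
        raise ValueError(
            f"preset schemes are defined for the 1x4 row, got "
            f"{grid.spec.rows}x{grid.spec.cols}")
    model = build_model(grid)  # for the state layout only
    from .model import MEMBRANE

    x = np.zeros(model.n_states)
    for name, per_cell in _scheme_levels(scheme).items():
        for c, lvl in enumerate(per_cell):
            if not 0.0 <= lvl <= 1.0:
                raise ValueError(f"level out of [0,1] for {name}: {lvl}")
            if name in MEMBRANE:
                for s in range(1, 7):
                    x[model.species_index(name, c, s)] = lvl / 6.0
            else:
                x[model.species_index(name, c)] = lvl
    return x


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    scheme: str
    seed: int
    hits: int
    tries: int        # completed integrations
    failures: int
    records: pd.DataFrame  # one row per attempt

    @property
    def attempts(self) -> int:
        return self.tries + self.failures

    @property
    def hit_rate(self) -> float:
        return self.hits / self.tries if self.tries else float("nan")

    @property
    def hit_records(self) -> pd.DataFrame:
        return self.records[self.records["outcome"] == "hit"].reset_index(drop=True)

    def summary(self) -> dict:
        return {
            "scheme": self.scheme, "seed": self.seed,
            "hits": self.hits, "tries": self.tries, "failures": self.failures,
            "hit_rate": self.hit_rate,
            "tries_per_hit": self.tries / self.hits if self.hits else None,
        }


def run_screen(
    n: int,
    scheme: str = "crisp",
    sampling_cfg: SamplingConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    template: PatternTemplate | None = None,
    threshold: float = HIT_THRESHOLD,
    seed: int = 0,
    guard: GuardConfig | None = None,
) -> ScreenResult:
    """Run ``n`` attempts: sample parameters, integrate from the scheme's
    starting state, classify against the template.

    Failures (non-finite states) are tallied, not raised; "tries" counts
    completed integrations only.  The result is bit-reproducible under
    ``seed`` (one child RNG stream per attempt).
    """
    if sampling_cfg is None:
        sampling_cfg = SamplingConfig()
    if sim_cfg is None:
        sim_cfg = SimulationConfig()
    if template is None:
        # screens score {wg, en, hh}: ptc's steady level is structurally
        # symmetric between the two cells flanking the en stripe (it has no
        # wingless input), so a ptc target confined to one flank is not
        # attainable and would veto every otherwise-correct pattern
        template = default_template(include_ptc=False)
    if guard is None:
        guard = GuardConfig()
    grid = build_grid(GridSpec(1, 4))
    x0 = initial_condition(scheme, grid)

    children = np.random.SeedSequence(seed).spawn(n)
    rows = []
    hits = tries = failures = 0
    sampled = sampling_cfg.catalog.sampled_names
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = sample_parameters(sampling_cfg, rng)
        model = build_model(grid, params, guard)
        traj = integrate(model, x0, sim_cfg)
        outcome, score = classify_screen_run(traj, template, model, threshold)
        if outcome == "failure":
            failures += 1
        else:
            tries += 1
            hits += outcome == "hit"
        rows.append({"attempt": k, "outcome": outcome, "score": score}
                    | {p: params[p] for p in sampled})
    records = pd.DataFrame(rows)
    return ScreenResult(scheme=scheme, seed=seed, hits=hits, tries=tries,
                        failures=failures, records=records)


def plot_solutions(hits: pd.DataFrame,
                   catalog: ParameterCatalog | None = None,
                   sampling_cfg: SamplingConfig | None = None) -> pd.DataFrame:
    """Spoke-plot data table for the hit parameter sets.

    One column per displayed parameter (half-lives and cooperativity
    coefficients are omitted), values mapped to the normalized log
    position in the sampling range (0 = low end, 1 = high end); the last
    two rows are the column mean and standard deviation.
    """
    if catalog is None:
        catalog = load_catalog()
    if sampling_cfg is None:
        sampling_cfg = SamplingConfig(catalog=catalog)
    shown = [e.name for e in catalog.entries
             if e.sampled and e.role not in ("half-life", "nu")]
    if len(hits) == 0:
        import warnings

        warnings.warn("no hits to plot; returning empty table")
        return pd.DataFrame(columns=shown)
    pos = {}
    for name in shown:
        lo, hi = sampling_cfg.range_of(name)
        pos[name] = (np.log(hits[name].to_numpy()) - np.log(lo)) / (
            np.log(hi) - np.log(lo))
    table = pd.DataFrame(pos)
    table.index = [f"hit_{i}" for i in range(len(table))]
    stats = pd.DataFrame(
        [table.mean(), table.std(ddof=1)], index=["mean", "sd"])
    return pd.concat([table, stats])
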