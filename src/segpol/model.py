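"""Segment polarity network model builder.

Builds the full reaction network / ODE system for an arbitrary hexagonal
cell grid.  Each cell carries 33 state variables:

* mRNAs: ``en``, ``wg``, ``ptc``, ``ci``, ``hh``
* cytosolic proteins: ``EN``, ``IWG`` (intracellular wingless), ``CI``,
  ``CN`` (the cleaved repressor fragment of CI)
* membrane proteins in six per-side pools: ``EWG`` (exocytosed wingless),
  ``PTC``, ``HH``, and the ``PH`` patched-hedgehog complex

Wiring (every regulatory edge of the full network):

* ``en`` transcription is induced by total wingless protein on the apposed
  faces of the six neighbors (EWG_T) and repressed by CN; EN translates
  from ``en``.
* ``ci`` is transcribed constitutively under EN repression; CI translates
  from ``ci`` and is cleaved to CN at a rate promoted by total free
  patched (PTC_T) on the cell's own membrane.
* ``wg`` uses the composite law (CI activation plus wingless
  autoactivation through IWG, under CN repression); IWG exchanges with the
  six EWG membrane pools by exo/endocytosis and EWG diffuses laterally
  between adjacent sides.
* ``ptc`` is induced by CI and repressed by CN; PTC is translated equally
  to the six sides, diffuses laterally, and is consumed by capture of HH
  arriving from the apposed neighbor face, producing PH on the
  PTC-owning side.
* ``hh`` is induced by EN and repressed by CN; HH is translated equally to
  the six sides, diffuses laterally, and is consumed by the capture.

Maximal transcription rates are tied to mRNA decay (V = ln2 / H) and
translation rates default to ln2 / (protein half-life), so every species
relaxes within [0, 1] under full drive.  All fluxes exist in two
semantics: guarded (exponentiation through ``max(eps, .)``, finite for any
finite state) and unguarded (IEEE semantics, NaN on tiny negative bases —
the historical failure mode the guard exists to fix).

The compiled right-hand side (numba) is the production path; an
interpreted evaluator over the explicit reaction table
(:func:`rhs_from_reactions`) serves as its structural cross-check and as
the source for SBML export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from numba import njit

from .catalog import ParameterCatalog, ParameterSet, load_catalog
from .grid import CellGrid, GridSpec, build_grid
from .kinetics import DEFAULT_EPSILON, GuardConfig

__all__ = [
    "N_SPECIES_PER_CELL",
    "MRNAS",
    "CYTOSOLIC",
    "MEMBRANE",
    "ODESystem",
    "Reaction",
    "build_model",
    "single_cell_model",
    "species_index",
    "neighbor_ewg_total",
    "rhs_from_reactions",
]

MRNAS = ("en", "wg", "ptc", "ci", "hh")
CYTOSOLIC = ("EN", "IWG", "CI", "CN")
MEMBRANE = ("EWG", "PTC", "HH", "PH")
N_SPECIES_PER_CELL = len(MRNAS) + len(CYTOSOLIC) + 6 * len(MEMBRANE)  # 33

# per-cell state layout
_OFF = {"en": 0, "EN": 1, "wg": 2, "IWG": 3, "ci": 4, "CI": 5, "CN": 6, "ptc": 7, "hh": 8}
_MEM_OFF = {"EWG": 9, "PTC": 15, "HH": 21, "PH": 27}

# regulatory Hill pairs, in packing order
_PAIRS = (
    "WGen", "CNen", "CNwg", "CIwg", "WGwg",
    "CNptc", "CIptc", "ENci", "ENhh", "CNhh", "PTCCI",
)


@dataclass(frozen=True)
class Reaction:
    """One reaction of the network, with enough structure to re-derive its flux.

    ``law`` names the rate-law template; ``args`` are parameter names /
    numbers the template consumes; ``reactants``/``products`` map state
    index -> stoichiometry; ``modifiers`` are state indices read by the law.
    """

    rid: str
    law: str
    args: tuple
    reactants: tuple[tuple[int, float], ...]
    products: tuple[tuple[int, float], ...]
    modifiers: tuple[int, ...] = ()


class ODESystem:
    """A built model: state layout, bound parameters, and the RHS callable."""

    def __init__(
        self,
        grid: CellGrid,
        params: ParameterSet,
        guard: GuardConfig,
        *,
        fixed_neighbors: Mapping[str, Sequence[float]] | None = None,
    ):
        self.grid = grid
        self.params = params
        self.guard = guard
        self.n_cells = grid.n_cells
        self.n_states = N_SPECIES_PER_CELL * self.n_cells
        self._single = fixed_neighbors is not None

        # 0-based neighbor tables: nbr_cell[c, s], nbr_side[c, s]
        nbr_cell = np.zeros((self.n_cells, 6), dtype=np.int64)
        nbr_side = np.zeros((self.n_cells, 6), dtype=np.int64)
        cell_of = {cell: i for i, cell in enumerate(grid.cells)}
        for i, cell in enumerate(grid.cells):
            for s in range(1, 7):
                ncell, nside = grid.neighbor(cell, s)
                nbr_cell[i, s - 1] = cell_of[ncell]
                nbr_side[i, s - 1] = nside - 1
        self._nbr_cell = nbr_cell
        self._nbr_side = nbr_side

        if self._single:
            if self.n_cells != 1:
                raise ValueError("fixed neighbor inputs require a single-cell grid")
            fixed = dict(fixed_neighbors)
            missing = {"EWG", "HH", "PTC"} - set(fixed)
            if missing:
                raise KeyError(f"missing fixed neighbor species: {sorted(missing)}")
            self._fixed_ewg = np.asarray(fixed["EWG"], dtype=float)
            self._fixed_hh = np.asarray(fixed["HH"], dtype=float)
            self._fixed_ptc = np.asarray(fixed["PTC"], dtype=float)
            for name, arr in (("EWG", self._fixed_ewg), ("HH", self._fixed_hh), ("PTC", self._fixed_ptc)):
                if arr.shape != (6,):
                    raise ValueError(f"fixed {name} must have 6 per-side values")
        else:
            self._fixed_ewg = np.zeros(6)
            self._fixed_hh = np.zeros(6)
            self._fixed_ptc = np.zeros(6)

        self._pv = _pack_parameters(params)
        self._reactions: tuple[Reaction, ...] | None = None

    # -- state indexing ----------------------------------------------------

    def species_index(self, name: str, cell: tuple[int, int] | int, side: int | None = None) -> int:
        """Index of a species in the state vector.

        ``side`` (1..6) is required iff the species is a membrane protein.
        """
        c = cell if isinstance(cell, int) else self.grid.cell_index(tuple(cell))
        if not 0 <= c < self.n_cells:
            raise KeyError(f"unknown cell: {cell}")
        base = N_SPECIES_PER_CELL * c
        if name in _OFF:
            if side is not None:
                raise KeyError(f"{name} is not a membrane species; no side argument")
            return base + _OFF[name]
        if name in _MEM_OFF:
            if side is None or not 1 <= side <= 6:
                raise KeyError(f"membrane species {name} needs a side in 1..6")
            return base + _MEM_OFF[name] + side - 1
        raise KeyError(f"unknown species: {name!r}")

    def species_name(self, index: int) -> str:
        """Inverse of :meth:`species_index` (stable, documented ordering)."""
        if not 0 <= index < self.n_states:
            raise KeyError(f"state index out of range: {index}")
        c, k = divmod(index, N_SPECIES_PER_CELL)
        r, col = self.grid.cells[c]
        for nm, off in _OFF.items():
            if k == off:
                return f"{nm}_{r}_{col}"
        for nm, off in _MEM_OFF.items():
            if off <= k < off + 6:
                return f"{nm}{k - off + 1}_{r}_{col}"
        raise AssertionError("unreachable")

    @property
    def species_names(self) -> list[str]:
        return [self.species_name(i) for i in range(self.n_states)]

    # -- evaluation --------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """dy/dt at state ``y`` (time does not enter explicitly)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_states,):
            raise ValueError(f"state length must be {self.n_states}, got {y.shape}")
        out = np.empty_like(y)
        _rhs_kernel(
            y, self._pv, self._nbr_cell, self._nbr_side,
            self.guard.enabled, self.guard.epsilon,
            self._single, self._fixed_ewg, self._fixed_hh, self._fixed_ptc,
            out,
        )
        return out

    def odeint_rhs(self, y: np.ndarray, t: float) -> np.ndarray:
        """Unchecked RHS in odeint's (y, t) argument order, for hot loops.

        Reuses one output buffer per model instance (the solver copies the
        values immediately), so a model must not be integrated from two
        threads at once.
        """
        try:
            out = self._out_buf
        except AttributeError:
            out = self._out_buf = np.empty(self.n_states)
        _rhs_kernel(
            y, self._pv, self._nbr_cell, self._nbr_side,
            self.guard.enabled, self.guard.epsilon,
            self._single, self._fixed_ewg, self._fixed_hh, self._fixed_ptc,
            out,
        )
        return out

    def neighbor_ewg_total(self, state: np.ndarray, cell: tuple[int, int] | int) -> float:
        """Total EWG on the six neighbor faces apposed to ``cell`` (EWG_T)."""
        c = cell if isinstance(cell, int) else self.grid.cell_index(tuple(cell))
        if self._single:
            return float(self._fixed_ewg.sum())
        tot = 0.0
        for s in range(6):
            n = self._nbr_cell[c, s]
            t = self._nbr_side[c, s]
            tot += state[N_SPECIES_PER_CELL * n + _MEM_OFF["EWG"] + t]
        return float(tot)

    # -- reaction network --------------------------------------------------

    @property
    def reactions(self) -> tuple[Reaction, ...]:
        if self._reactions is None:
            self._reactions = tuple(_enumerate_reactions(self))
        return self._reactions

    def summary(self) -> dict:
        """JSON-ready dump: species, parameters, reactions."""
        return {
            "grid": {"rows": self.grid.spec.rows, "cols": self.grid.spec.cols,
                     "periodic": list(self.grid.spec.periodic)},
            "n_cells": self.n_cells,
            "n_states": self.n_states,
            "guard": {"enabled": self.guard.enabled, "epsilon": self.guard.epsilon},
            "species": self.species_names,
            "parameters": self.params.to_dict(),
            "n_parameters": len(self.params),
            "n_sampled": len(self.params.catalog.sampled_names),
            "reactions": [
                {"id": r.rid, "law": r.law,
                 "reactants": {self.species_name(i): st for i, st in r.reactants},
                 "products": {self.species_name(i): st for i, st in r.products},
                 "modifiers": [self.species_name(i) for i in r.modifiers]}
                for r in self.reactions
            ],
        }


def build_model(
    grid: CellGrid | GridSpec,
    params: ParameterSet | None = None,
    guard: GuardConfig | None = None,
) -> ODESystem:
    """Build the full multicellular model (33 species per cell)."""
    if isinstance(grid, GridSpec):
        grid = build_grid(grid)
    if params is None:
        params = load_catalog().defaults()
    if guard is None:
        guard = GuardConfig()
    return ODESystem(grid, params, guard)


def single_cell_model(
    params: ParameterSet | None = None,
    fixed_neighbor_inputs: Mapping[str, Sequence[float]] | None = None,
    guard: GuardConfig | None = None,
) -> ODESystem:
    """One-cell model where cross-cell species are fixed concentrations.

    ``fixed_neighbor_inputs`` must provide per-side values (length 6) for
    the apposed-face species ``EWG``, ``HH`` and ``PTC``.
    """
    if fixed_neighbor_inputs is None:
        raise KeyError("fixed neighbor inputs are required (EWG, HH, PTC per side)")
    if params is None:
        params = load_catalog().defaults()
    if guard is None:
        guard = GuardConfig()
    grid = build_grid(GridSpec(1, 1))
    return ODESystem(grid, params, guard, fixed_neighbors=fixed_neighbor_inputs)


def species_index(model: ODESystem, name: str, cell, side: int | None = None) -> int:
    return model.species_index(name, cell, side)


def neighbor_ewg_total(state: np.ndarray, model: ODESystem, cell) -> float:
    return model.neighbor_ewg_total(state, cell)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

# packed vector layout (see _rhs_kernel):
#  0..12  decay rate constants ln2/H for
#         en, EN, wg, IWG, EWG, ptc, PTC, ci, CI, CN, hh, HH, PH
# 13..17  V_en, V_wg, V_ptc, V_ci, V_hh (= ln2 / mRNA half-life)
# 18..22  T_en, T_wg, T_ptc, T_ci, T_hh
# 23..44  per regulatory pair (order _PAIRS): kappa^nu, nu
# 45..46  alpha_CIwg, alpha_WGwg
# 47..52  r_ExoWG, r_EndoWG, r_MxferWG, r_MxferPTC, r_MxferHH, r_MxferPH
# 53      C_CI
# 54..57  kappa_PTCHH, nu_PTCHH, PTC0, HH0
_HL_ORDER = ("H_en", "H_EN", "H_wg", "H_IWG", "H_EWG", "H_ptc", "H_PTC",
             "H_ci", "H_CI", "H_CN", "H_hh", "H_HH", "H_PH")
N_PACKED = 58


def _pack_parameters(params: ParameterSet) -> np.ndarray:
    ln2 = math.log(2.0)
    pv = np.empty(N_PACKED)
    for i, h in enumerate(_HL_ORDER):
        pv[i] = ln2 / params[h]
    for j, g in enumerate(("en", "wg", "ptc", "ci", "hh")):
        pv[13 + j] = ln2 / params[f"H_{g}"]
    for j, g in enumerate(("en", "wg", "ptc", "ci", "hh")):
        pv[18 + j] = params[f"T_{g}"]
    for j, pair in enumerate(_PAIRS):
        kappa = params[f"kappa_{pair}"]
        nu = params[f"nu_{pair}"]
        pv[23 + 2 * j] = kappa ** nu
        pv[24 + 2 * j] = nu
    pv[45] = params["alpha_CIwg"]
    pv[46] = params["alpha_WGwg"]
    for j, r in enumerate(("r_ExoWG", "r_EndoWG", "r_MxferWG",
                           "r_MxferPTC", "r_MxferHH", "r_MxferPH")):
        pv[47 + j] = params[r]
    pv[53] = params["C_CI"]
    pv[54] = params["kappa_PTCHH"]
    pv[55] = params["nu_PTCHH"]
    pv[56] = params["PTC0"]
    pv[57] = params["HH0"]
    return pv


# pair slots in the packed vector
def _pair_slot(pair: str) -> int:
    return 23 + 2 * _PAIRS.index(pair)


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _gpow(base, expo, guarded, eps):
    if guarded and base < eps:
        base = eps
    return base ** expo


@njit(cache=True, inline="always")
def _phi(x, kpow, nu, guarded, eps):
    # activating Hill: x^nu / (kappa^nu + x^nu)
    xn = _gpow(x, nu, guarded, eps)
    return xn / (kpow + xn)


@njit(cache=True, inline="always")
def _txn(I, R, V, kI_pow, nI, kR_pow, nR, guarded, eps):
    # inducer-repressor transcription: V (I psi)^nI / (kI^nI + (I psi)^nI)
    rn = _gpow(R, nR, guarded, eps)
    psi = 1.0 - rn / (kR_pow + rn)
    if guarded and psi < eps:
        psi = eps
    x = _gpow(I * psi, nI, guarded, eps)
    return V * x / (kI_pow + x)


@njit(cache=True)
def _rhs_kernel(y, pv, nbr_cell, nbr_side, guarded, eps,
                single, fx_ewg, fx_hh, fx_ptc, out):
    n_cells = nbr_cell.shape[0]
    M = 33
    # decay constants
    d_en = pv[0]; d_EN = pv[1]; d_wg = pv[2]; d_IWG = pv[3]; d_EWG = pv[4]
    d_ptc = pv[5]; d_PTC = pv[6]; d_ci = pv[7]; d_CI = pv[8]; d_CN = pv[9]
    d_hh = pv[10]; d_HH = pv[11]; d_PH = pv[12]
    V_en = pv[13]; V_wg = pv[14]; V_ptc = pv[15]; V_ci = pv[16]; V_hh = pv[17]
    T_en = pv[18]; T_wg = pv[19]; T_ptc = pv[20]; T_ci = pv[21]; T_hh = pv[22]
    kWGen = pv[23]; nWGen = pv[24]; kCNen = pv[25]; nCNen = pv[26]
    kCNwg = pv[27]; nCNwg = pv[28]; kCIwg = pv[29]; nCIwg = pv[30]
    kWGwg = pv[31]; nWGwg = pv[32]; kCNptc = pv[33]; nCNptc = pv[34]
    kCIptc = pv[35]; nCIptc = pv[36]; kENci = pv[37]; nENci = pv[38]
    kENhh = pv[39]; nENhh = pv[40]; kCNhh = pv[41]; nCNhh = pv[42]
    kPTCCI = pv[43]; nPTCCI = pv[44]
    a_CI = pv[45]; a_WG = pv[46]
    r_exo = pv[47]; r_endo = pv[48]; r_mxWG = pv[49]; r_mxPTC = pv[50]
    r_mxHH = pv[51]; r_mxPH = pv[52]
    C_CI = pv[53]; k_bind = pv[54]; n_bind = pv[55]; PTC0 = pv[56]; HH0 = pv[57]

    for c in range(n_cells):
        o = M * c
        en = y[o]; EN = y[o + 1]; wg = y[o + 2]; IWG = y[o + 3]
        ci = y[o + 4]; CI = y[o + 5]; CN = y[o + 6]; ptc = y[o + 7]; hh = y[o + 8]

        # totals over membrane pools
        ewg_T = 0.0  # EWG on the six apposed neighbor faces
        ptc_T = 0.0  # free PTC on this cell's own six sides
        for s in range(6):
            if single:
                ewg_T += fx_ewg[s]
            else:
                ewg_T += y[M * nbr_cell[c, s] + 9 + nbr_side[c, s]]
            ptc_T += y[o + 15 + s]

        # mRNAs
        out[o] = _txn(ewg_T, CN, V_en, kWGen, nWGen, kCNen, nCNen, guarded, eps) - d_en * en
        # composite wg: CN represses the CI drive (competition at the CI
        # sites); the autoactivation term is CN-free
        phi_ci = _phi(CI, kCIwg, nCIwg, guarded, eps)
        phi_wg = _phi(IWG, kWGwg, nWGwg, guarded, eps)
        cn_n = _gpow(CN, nCNwg, guarded, eps)
        psi_cn = 1.0 - cn_n / (kCNwg + cn_n)
        if guarded and psi_cn < eps:
            psi_cn = eps
        Ssum = a_CI * phi_ci * psi_cn + a_WG * phi_wg
        out[o + 2] = V_wg * Ssum / (1.0 + Ssum) - d_wg * wg
        out[o + 7] = _txn(CI, CN, V_ptc, kCIptc, nCIptc, kCNptc, nCNptc, guarded, eps) - d_ptc * ptc
        # ci: constitutive under EN repression
        en_n = _gpow(EN, nENci, guarded, eps)
        psi_en = 1.0 - en_n / (kENci + en_n)
        if guarded and psi_en < eps:
            psi_en = eps
        out[o + 4] = V_ci * psi_en - d_ci * ci
        out[o + 8] = _txn(EN, CN, V_hh, kENhh, nENhh, kCNhh, nCNhh, guarded, eps) - d_hh * hh

        # cytosolic proteins
        out[o + 1] = T_en * en - d_EN * EN
        cleave = C_CI * CI * _phi(ptc_T, kPTCCI, nPTCCI, guarded, eps)
        out[o + 5] = T_ci * ci - d_CI * CI - cleave
        out[o + 6] = cleave - d_CN * CN

        # IWG <-> EWG exchange
        ewg_sum = 0.0
        for s in range(6):
            ewg_sum += y[o + 9 + s]
        out[o + 3] = T_wg * wg + r_endo * ewg_sum - r_exo * IWG - d_IWG * IWG

        # membrane pools
        for s in range(6):
            sm = (s + 5) % 6
            sp = (s + 1) % 6
            # EWG
            e = y[o + 9 + s]
            out[o + 9 + s] = (r_exo / 6.0 * IWG - r_endo * e
                              + r_mxWG * (y[o + 9 + sm] + y[o + 9 + sp] - 2.0 * e)
                              - d_EWG * e)
            # apposed-face HH seen by this cell's PTC on side s
            if single:
                hh_app = fx_hh[s]
                ptc_app = fx_ptc[s]
            else:
                nb = M * nbr_cell[c, s] + nbr_side[c, s]
                hh_app = y[nb + 21]
                ptc_app = y[nb + 15]
            p = y[o + 15 + s]
            if n_bind == 1.0:
                hh_app_n = hh_app
            else:
                hh_app_n = _gpow(hh_app, n_bind, guarded, eps)
            capture = k_bind * p * hh_app_n  # base bimolecular flux on side s
            out[o + 15 + s] = (T_ptc / 6.0 * ptc
                               + r_mxPTC * (y[o + 15 + sm] + y[o + 15 + sp] - 2.0 * p)
                               - d_PTC * p - HH0 * capture)
            # HH on side s is consumed by the apposed neighbor's PTC
            h = y[o + 21 + s]
            if n_bind == 1.0:
                h_n = h
            else:
                h_n = _gpow(h, n_bind, guarded, eps)
            out[o + 21 + s] = (T_hh / 6.0 * hh
                               + r_mxHH * (y[o + 21 + sm] + y[o + 21 + sp] - 2.0 * h)
                               - d_HH * h - PTC0 * k_bind * ptc_app * h_n)
            # PH forms on the PTC-owning side
            q = y[o + 27 + s]
            out[o + 27 + s] = (HH0 * capture
                               + r_mxPH * (y[o + 27 + sm] + y[o + 27 + sp] - 2.0 * q)
                               - d_PH * q)


# ---------------------------------------------------------------------------
# reaction table (structural mirror of the kernel; feeds SBML export)
# ---------------------------------------------------------------------------

def _enumerate_reactions(model: ODESystem) -> list[Reaction]:
    """Enumerate every reaction with explicit indices and law templates.

    Law templates (args refer to catalog parameter names):

    * ``txn_ind_rep (V_gene, inducer_pair, repressor_pair)`` — inducer is
      the first modifier (or the EWG_T sum over modifiers for ``en``),
      repressor the last.
    * ``txn_ci (V_gene, repressor_pair)``
    * ``txn_wg (V_gene,)`` — modifiers CI, IWG, CN
    * ``linear (rate_name, scale)`` — flux = scale * rate * reactant
    * ``cleave ()`` — C_CI * CI * phi(PTC_T); modifiers CI + 6 PTC sides
    * ``bind ()`` — base flux kappa_PTCHH * PTC * HH^nu_PTCHH with
      stoichiometries HH0 (PTC, PH) and PTC0 (HH)
    """
    rxns: list[Reaction] = []
    m = model
    for ci_, cell in enumerate(m.grid.cells):
        tag = f"{cell[0]}_{cell[1]}"
        ix = lambda name, side=None: m.species_index(name, ci_, side)

        # transcription
        ewg_faces = []
        for s in range(6):
            n = m._nbr_cell[ci_, s]
            t = m._nbr_side[ci_, s]
            ewg_faces.append(N_SPECIES_PER_CELL * n + _MEM_OFF["EWG"] + t)
        rxns.append(Reaction(
            f"txn_en_{tag}", "txn_ind_rep", ("H_en", "WGen", "CNen"),
            (), ((ix("en"), 1.0),), tuple(ewg_faces) + (ix("CN"),)))
        rxns.append(Reaction(
            f"txn_wg_{tag}", "txn_wg", ("H_wg",),
            (), ((ix("wg"), 1.0),), (ix("CI"), ix("IWG"), ix("CN"))))
        rxns.append(Reaction(
            f"txn_ptc_{tag}", "txn_ind_rep", ("H_ptc", "CIptc", "CNptc"),
            (), ((ix("ptc"), 1.0),), (ix("CI"), ix("CN"))))
        rxns.append(Reaction(
            f"txn_ci_{tag}", "txn_ci", ("H_ci", "ENci"),
            (), ((ix("ci"), 1.0),), (ix("EN"),)))
        rxns.append(Reaction(
            f"txn_hh_{tag}", "txn_ind_rep", ("H_hh", "ENhh", "CNhh"),
            (), ((ix("hh"), 1.0),), (ix("EN"), ix("CN"))))

        # translation
        rxns.append(Reaction(f"tl_EN_{tag}", "linear", ("T_en", 1.0),
                             (), ((ix("EN"), 1.0),), (ix("en"),)))
        rxns.append(Reaction(f"tl_CI_{tag}", "linear", ("T_ci", 1.0),
                             (), ((ix("CI"), 1.0),), (ix("ci"),)))
        rxns.append(Reaction(f"tl_IWG_{tag}", "linear", ("T_wg", 1.0),
                             (), ((ix("IWG"), 1.0),), (ix("wg"),)))
        for s in range(1, 7):
            rxns.append(Reaction(f"tl_PTC{s}_{tag}", "linear", ("T_ptc", 1.0 / 6.0),
                                 (), ((ix("PTC", s), 1.0),), (ix("ptc"),)))
            rxns.append(Reaction(f"tl_HH{s}_{tag}", "linear", ("T_hh", 1.0 / 6.0),
                                 (), ((ix("HH", s), 1.0),), (ix("hh"),)))

        # CI cleavage
        rxns.append(Reaction(
            f"cleave_CI_{tag}", "cleave", (),
            ((ix("CI"), 1.0),), ((ix("CN"), 1.0),),
            tuple(ix("PTC", s) for s in range(1, 7))))

        # wingless trafficking
        for s in range(1, 7):
            rxns.append(Reaction(f"exo_WG{s}_{tag}", "linear", ("r_ExoWG", 1.0 / 6.0),
                                 ((ix("IWG"), 1.0),), ((ix("EWG", s), 1.0),)))
            rxns.append(Reaction(f"endo_WG{s}_{tag}", "linear", ("r_EndoWG", 1.0),
                                 ((ix("EWG", s), 1.0),), ((ix("IWG"), 1.0),)))

        # lateral membrane diffusion (directed edges s -> s+1 and s -> s-1)
        for sp_name, rate in (("EWG", "r_MxferWG"), ("PTC", "r_MxferPTC"),
                              ("HH", "r_MxferHH"), ("PH", "r_MxferPH")):
            for s in range(1, 7):
                for t in (s % 6 + 1, (s + 4) % 6 + 1):
                    rxns.append(Reaction(
                        f"mx_{sp_name}{s}to{t}_{tag}", "linear", (rate, 1.0),
                        ((ix(sp_name, s), 1.0),), ((ix(sp_name, t), 1.0),)))

        # decay
        for nm in MRNAS + CYTOSOLIC:
            rxns.append(Reaction(f"dec_{nm}_{tag}", "linear", (f"H_{nm}", "halflife"),
                                 ((ix(nm), 1.0),), ()))
        for nm in MEMBRANE:
            for s in range(1, 7):
                rxns.append(Reaction(f"dec_{nm}{s}_{tag}", "linear", (f"H_{nm}", "halflife"),
                                     ((ix(nm, s), 1.0),), ()))

        # PTC + apposed HH -> PH capture (per PTC-owning side)
        if not model._single:
            for s in range(1, 7):
                n = m._nbr_cell[ci_, s - 1]
                t = m._nbr_side[ci_, s - 1]
                hh_idx = N_SPECIES_PER_CELL * n + _MEM_OFF["HH"] + t
                rxns.append(Reaction(
                    f"bind_PH{s}_{tag}", "bind", (),
                    ((ix("PTC", s), None), (hh_idx, None)),  # stoich filled by law
                    ((ix("PH", s), None),)))
    return rxns


def rhs_from_reactions(model: ODESystem, y: np.ndarray) -> np.ndarray:
    """Interpreted RHS assembled from the reaction table.

    Slow but structurally explicit; used to cross-check the compiled
    kernel and as the semantic reference for SBML export.  Guarded
    semantics only.
    """
    from . import kinetics as K

    p = model.params
    g = model.guard
    ln2 = math.log(2.0)
    y = np.asarray(y, dtype=float)
    out = np.zeros_like(y)

    def pair(name: str) -> K.HillParams:
        return K.HillParams(p[f"kappa_{name}"], p[f"nu_{name}"])

    for rx in model.reactions:
        if rx.law == "txn_ind_rep":
            hgene, ipair, rpair = rx.args
            mods = rx.modifiers
            if len(mods) > 2:  # en: inducer is the EWG_T sum
                I = float(sum(y[i] for i in mods[:-1]))
            else:
                I = float(y[mods[0]])
            R = float(y[mods[-1]])
            prms = K.TxnRateParams(ln2 / p[hgene], pair(ipair), pair(rpair))
            flux = K.txn_inducer_repressor(I, R, prms, g)
        elif rx.law == "txn_ci":
            hgene, rpair = rx.args
            psi = K.hill_repression(float(y[rx.modifiers[0]]), pair(rpair), g)
            if g.enabled:
                psi = max(g.epsilon, psi)
            flux = ln2 / p[hgene] * psi
        elif rx.law == "txn_wg":
            (hgene,) = rx.args
            CI_, IWG_, CN_ = (float(y[i]) for i in rx.modifiers)
            flux = K.txn_composite_wg(
                CI_, CN_, IWG_,
                alpha_CIwg=p["alpha_CIwg"], alpha_WGwg=p["alpha_WGwg"],
                hill_CIwg=pair("CIwg"), hill_WGwg=pair("WGwg"),
                hill_CNwg=pair("CNwg"), V=ln2 / p[hgene], guard=g)
        elif rx.law == "linear":
            rate_name, scale = rx.args
            rate = ln2 / p[rate_name] if scale == "halflife" else p[rate_name] * scale
            src = rx.reactants[0][0] if rx.reactants else rx.modifiers[0]
            flux = rate * float(y[src])
        elif rx.law == "cleave":
            CI_ = float(y[rx.reactants[0][0]])
            ptc_T = float(sum(y[i] for i in rx.modifiers))
            flux = p["C_CI"] * CI_ * K.hill_activation(ptc_T, pair("PTCCI"), g)
        elif rx.law == "bind":
            (iptc, _), (ihh, _) = rx.reactants
            (iph, _) = rx.products[0]
            fp, fh = K.bind_ptc_hh(
                float(y[iptc]), float(y[ihh]), p["kappa_PTCHH"],
                p["PTC0"], p["HH0"], nu=p["nu_PTCHH"], guard=g)
            out[iptc] -= fp
            out[iph] += fp
            out[ihh] -= fh
            continue
        else:  # pragma: no cover
            raise AssertionError(f"unknown law {rx.law}")
        for i, st in rx.reactants:
            out[i] -= st * flux
        for i, st in rx.products:
            out[i] += st * flux
    return out
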