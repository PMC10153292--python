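"""Rate-law catalog for the segment polarity network model.

All concentrations are dimensionless, normalized so that a species whose
synthesis is driven at its maximal rate relaxes toward 1.  The central
numerical device is *guarded exponentiation*,

    base ** nu  ~  max(eps, base) ** nu,   eps > 0 (default 1e-80),

which keeps every rate law finite when an integrator briefly pushes a
concentration infinitesimally below zero (a bare negative base raised to a
non-integer power is NaN in IEEE arithmetic).  Hill half-saturation
constants are never guarded: they are strictly positive parameters.

These scalar forms are mirrored by the vectorized compiled right-hand side
in :mod:`segpol.model`; property tests hold the two in agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DEFAULT_EPSILON",
    "GuardConfig",
    "HillParams",
    "TxnRateParams",
    "guarded_pow",
    "hill_activation",
    "hill_repression",
    "txn_inducer_repressor",
    "txn_composite_wg",
    "decay_rate",
    "bind_ptc_hh",
]

DEFAULT_EPSILON = 1e-80


@dataclass(frozen=True)
class GuardConfig:
    """Whether and how to guard exponentiation (eps defaults to 1e-80)."""

    enabled: bool = True
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"guard epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class HillParams:
    """Half-saturation constant kappa (> 0) and cooperativity nu (>= 1)."""

    kappa: float
    nu: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.nu < 1:
            raise ValueError(f"nu must be >= 1, got {self.nu}")


@dataclass(frozen=True)
class TxnRateParams:
    """Maximal rate V plus inducer (k1, h1) and repressor (k2, h2) Hills."""

    V: float
    inducer: HillParams
    repressor: HillParams

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError(f"maximal rate V must be nonnegative, got {self.V}")


def guarded_pow(base: float, exponent: float, eps: float = DEFAULT_EPSILON) -> float:
    """``max(eps, base) ** exponent`` — finite and positive for any finite base.

    This is the guard that keeps Hill terms out of NaN territory when a
    solver step makes a concentration slightly negative.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    return max(eps, base) ** exponent


def _pow(base: float, exponent: float, guard: GuardConfig | None) -> float:
    if guard is not None and guard.enabled:
        return max(guard.epsilon, base) ** exponent
    # unguarded: negative base with non-integer exponent yields NaN (IEEE
    # pow semantics), which callers are expected to detect — that is the
    # failure mode the guard exists to remove
    try:
        return math.pow(base, exponent)
    except (ValueError, OverflowError, ZeroDivisionError):
        return math.nan


def hill_activation(x: float, p: HillParams, guard: GuardConfig | None = None) -> float:
    """Activating Hill response x^nu / (kappa^nu + x^nu), in [0, 1] for x >= 0."""
    xn = _pow(x, p.nu, guard)
    return xn / (p.kappa ** p.nu + xn)


def hill_repression(x: float, p: HillParams, guard: GuardConfig | None = None) -> float:
    """Repressing Hill response 1 - x^nu / (kappa^nu + x^nu)."""
    return 1.0 - hill_activation(x, p, guard)


def txn_inducer_repressor(
    I: float,
    R: float,
    p: TxnRateParams,
    guard: GuardConfig | None = None,
) -> float:
    """Transcription driven by an inducer I and damped by a repressor R.

    Unguarded form:  V * (I * psi)^h1 / (k1^h1 + (I * psi)^h1)  with
    psi = 1 - R^h2 / (k2^h2 + R^h2).  The guarded form applies
    max(eps, .) to R and to the psi factor; k1^h1 and k2^h2 are plain
    powers of always-positive constants.
    """
    k1, h1 = p.inducer.kappa, p.inducer.nu
    k2, h2 = p.repressor.kappa, p.repressor.nu
    if guard is not None and guard.enabled:
        eps = guard.epsilon
        rn = max(eps, R) ** h2
        psi = max(eps, 1.0 - rn / (k2 ** h2 + rn))
        x = max(eps, I * psi) ** h1
    else:
        rn = _pow(R, h2, None)
        psi = 1.0 - rn / (k2 ** h2 + rn)
        x = _pow(I * psi, h1, None)
    return p.V * x / (k1 ** h1 + x)


def txn_composite_wg(
    CI: float,
    CN: float,
    WG: float,
    *,
    alpha_CIwg: float,
    alpha_WGwg: float,
    hill_CIwg: HillParams,
    hill_WGwg: HillParams,
    hill_CNwg: HillParams,
    V: float,
    guard: GuardConfig | None = None,
    repress_sum: bool = False,
) -> float:
    """Composite wingless transcription: CI activation plus autoactivation,
    with CN repression.

    Default form (CN competes with CI at its binding sites, so repression
    acts inside the CI term and leaves the autoactivation loop CN-free):

        rate = V * S / (1 + S),
        S = alpha_CIwg * phi(CI) * psi(CN) + alpha_WGwg * phi(WG).

    With ``repress_sum=True`` the repressing Hill psi(CN) instead
    multiplies the whole saturating sum.  Both are bounded above by V.
    """
    if alpha_CIwg < 0 or alpha_WGwg < 0:
        raise ValueError("alpha weights must be nonnegative")
    phi_ci = hill_activation(CI, hill_CIwg, guard)
    phi_wg = hill_activation(WG, hill_WGwg, guard)
    psi = hill_repression(CN, hill_CNwg, guard)
    if guard is not None and guard.enabled:
        psi = max(guard.epsilon, psi)
    if repress_sum:
        S = alpha_CIwg * phi_ci + alpha_WGwg * phi_wg
        return V * psi * S / (1.0 + S)
    S = alpha_CIwg * phi_ci * psi + alpha_WGwg * phi_wg
    return V * S / (1.0 + S)


def decay_rate(X: float, halflife: float) -> float:
    """First-order decay flux (ln 2 / halflife) * X."""
    if halflife <= 0:
        raise ValueError(f"half-life must be positive, got {halflife}")
    return math.log(2.0) / halflife * X


def bind_ptc_hh(
    PTC_side: float,
    HH_apposed: float,
    k: float,
    PTC0: float,
    HH0: float,
    nu: float = 1.0,
    guard: GuardConfig | None = None,
) -> tuple[float, float]:
    """Second-order PTC + HH -> PH capture across an apposed membrane pair.

    Returns ``(flux_ptc_ph, flux_hh)``: the first applies to the PTC and PH
    balances (k * HH0 * PTC * HH^nu), the second to the apposed-cell HH
    balance (k * PTC0 * PTC * HH^nu).  PTC0 and HH0 rescale the normalized
    concentrations so the bimolecular step has consistent units; nu = 1 is
    plain mass action, nu > 1 an effective cooperativity of ligand capture.
    """
    if PTC0 <= 0 or HH0 <= 0:
        raise ValueError("PTC0 and HH0 scales must be positive")
    hh = _pow(HH_apposed, nu, guard) if nu != 1.0 else HH_apposed
    base = k * PTC_side * hh
    return HH0 * base, PTC0 * base
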