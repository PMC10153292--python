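# Parameter catalog for the segment polarity network model (default 4-cell build).
#
# This file is the single source of truth for parameter names, roles, defaults,
# sampled flags and log-scale sampling ranges.  53 parameters, 48 sampled.
#
# NOTE ON PROVENANCE: the published description of this model names the
# parameters and states that 48 of 53 are sampled, with PTC0/HH0 ranged
# 1-1000 and half-lives / Hill constants sampled on log scales, but it does
# not reprint every range.  The ranges below for kappas (1e-3..1), nus
# (1..10), half-lives (5..100 time units), transport/binding/cleavage rates
# (1e-3..1) and alpha weights (1..10) are reconstructions and are meant to
# be edited against the archival model files if exactness matters.
#
# Roles: half-life (first-order decay, time units), kappa (Hill
# half-saturation), nu (Hill cooperativity), alpha-weight (relative input
# strength in the composite wg law), rate (first/second-order rate
# constant, 1/time), scale (concentration scale for bimolecular capture).
#
# "tied: <H_name>" means the default value is ln2 / value(H_name), resolved
# at build time (translation is normalized so a protein tracks its mRNA
# into [0, 1]); an explicit numeric default overrides the tie.

parameters:
  # --- half-lives (sampled) ---------------------------------------------
  - {name: H_en,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_EN,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_wg,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_IWG, role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_EWG, role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_ptc, role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_PTC, role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_ci,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_CI,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_CN,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_hh,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_HH,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}
  - {name: H_PH,  role: half-life, default: 20.0, sampled: true, range: [5.0, 100.0]}

  # --- Hill half-saturation constants (sampled) -------------------------
  - {name: kappa_WGen,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_CNen,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_CNwg,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_CIwg,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_WGwg,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_CNptc, role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_CIptc, role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_ENci,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_ENhh,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_CNhh,  role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: kappa_PTCCI, role: kappa, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  # second-order capture rate constant for PTC + HH -> PH
  - {name: kappa_PTCHH, role: rate,  default: 0.03, sampled: true, range: [1.0e-3, 1.0]}

  # --- Hill cooperativity exponents (sampled) ---------------------------
  - {name: nu_WGen,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_CNen,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_CNwg,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_CIwg,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_WGwg,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_CNptc, role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_CIptc, role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_ENci,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_ENhh,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_CNhh,  role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: nu_PTCCI, role: nu, default: 3.0, sampled: true, range: [1.0, 10.0]}
  # effective cooperativity of HH capture; 1 = plain mass action
  - {name: nu_PTCHH, role: nu, default: 1.0, sampled: true, range: [1.0, 10.0]}

  # --- composite wg input weights (sampled) -----------------------------
  - {name: alpha_CIwg, role: alpha-weight, default: 3.0, sampled: true, range: [1.0, 10.0]}
  - {name: alpha_WGwg, role: alpha-weight, default: 3.0, sampled: true, range: [1.0, 10.0]}

  # --- membrane transport rates (sampled) -------------------------------
  - {name: r_ExoWG,   role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: r_EndoWG,  role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: r_MxferWG, role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: r_MxferPTC, role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: r_MxferHH, role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}
  - {name: r_MxferPH, role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}

  # --- CI cleavage (sampled) --------------------------------------------
  - {name: C_CI, role: rate, default: 0.03, sampled: true, range: [1.0e-3, 1.0]}

  # --- concentration scales for bimolecular capture (sampled) -----------
  - {name: PTC0, role: scale, default: 30.0, sampled: true, range: [1.0, 1000.0]}
  - {name: HH0,  role: scale, default: 30.0, sampled: true, range: [1.0, 1000.0]}

  # --- translation rate constants (NOT sampled; tied defaults) ----------
  - {name: T_en,  role: rate, default: null, tied: H_EN,  sampled: false}
  - {name: T_wg,  role: rate, default: null, tied: H_IWG, sampled: false}
  - {name: T_ptc, role: rate, default: null, tied: H_PTC, sampled: false}
  - {name: T_ci,  role: rate, default: null, tied: H_CI,  sampled: false}
  - {name: T_hh,  role: rate, default: null, tied: H_HH,  sampled: false}
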