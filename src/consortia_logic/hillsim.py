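"""Steady-state model of the two-cell XOR consortium.

The consortium distributes XOR over two E. coli populations:

* the upstream cell (USC) carries the genetic AND gate — arabinose drives
  P_BAD, salicylate drives P_Sal, and the amber-mutated T7 polymerase
  (T7ptag) is only rescued by supD tRNA when both are expressed; its output
  is LuxI, the synthase of the quorum-sensing molecule AHL;

* the downstream cell (DSC) ORs the two environmental inputs onto supD
  through tandem promoters and ANDs the result with T7ptag expressed from
  P_lux_rep, an engineered promoter that AHL *represses* — the chemical wire
  carries the design's NOT at zero intracellular cost.

Each regulatory stage is a lumped Hill function at steady state (the
repressive promoter responds much faster than the co-culture grows, so the
algebraic composition stands in for the full kinetics).  The translation
strength of the ribosome binding site upstream of luxI enters as an
attenuation factor f >= 1 relative to the reference RBS (BBa_B0034):
fine-tuning f is what makes or breaks the XOR behaviour, because leaky luxI
expression at f = 1 floods the wire with AHL and silences the downstream
cell even in the logical-ON states.

Default parameters are calibrated data (data/default_params.yaml), anchored
to three qualitative behaviours of the experimental system: an upstream
on/off ratio above 100, a signal-background ratio of at least 10 near
10-fold RBS attenuation across USC:DSC ratios 1:20..1:1, and an interior
optimum of the attenuation scan.  They are a stand-in model, not a fit to
the original raw fluorescence data.
"""
from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml
from scipy.optimize import least_squares

from .errors import ConsortiaLogicError, ParameterError

XOR_ON_STATES = ((1, 0), (0, 1))
XOR_OFF_STATES = ((0, 0), (1, 1))


@dataclass(frozen=True)
class SimParams:
    """Hill constants and circuit-level couplings (concentrations in M)."""

    K_ara: float = 1e-4      # P_BAD half-activation
    h_ara: float = 1.5
    l_ara: float = 2e-3      # leakage fraction
    K_sal: float = 1e-6      # P_Sal half-activation
    h_sal: float = 1.5
    l_sal: float = 2e-3
    K_ahl: float = 1e-8      # P_lux_rep half-repression
    h_ahl: float = 2.0
    l_ahl: float = 5e-3      # residual expression at saturating AHL
    K_T: float = 0.5         # T7ptag*supD complementation constant
    sigma: float = 1e-6      # M of AHL per normalized LuxI per unit producer odds
    rbs_attenuation: float = 10.0   # f, fold-reduction vs reference RBS
    phi: float = 0.25        # USC fraction of the co-culture
    beta: float = 1.0        # output gain (normalized fluorescence units)
    ahl_scaling: str = "odds"  # "odds": phi/(1-phi);  "fraction": phi
    ara_on: float = 1e-2     # saturating inducer levels for logic states
    sal_on: float = 1e-4

    def __post_init__(self):
        for name in ("K_ara", "K_sal", "K_ahl", "K_T", "sigma", "beta",
                     "ara_on", "sal_on"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("h_ara", "h_sal", "h_ahl"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("l_ara", "l_sal", "l_ahl"):
            if not 0 <= getattr(self, name) < 1:
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.rbs_attenuation < 1:
            raise ParameterError("rbs_attenuation must be >= 1")
        if not 0 < self.phi < 1:
            raise ParameterError("phi must lie strictly inside (0, 1)")
        if self.ahl_scaling not in ("odds", "fraction"):
            raise ParameterError("ahl_scaling must be 'odds' or 'fraction'")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_params() -> SimParams:
    ref = importlib.resources.files("consortia_logic") / "data" / \
        "default_params.yaml"
    return SimParams.from_dict(yaml.safe_load(ref.read_text()))


# ----------------------------------------------------------------------
# elementary stages
# ----------------------------------------------------------------------
def _check_conc(*concs):
    for c in concs:
        if np.any(np.asarray(c) < 0):
            raise ParameterError("concentrations must be >= 0")


def hill_activation(x, K, h, leak):
    x = np.asarray(x, dtype=float)
    return leak + (1.0 - leak) * x ** h / (K ** h + x ** h)


def hill_repression(x, K, h, leak):
    x = np.asarray(x, dtype=float)
    return leak + (1.0 - leak) / (1.0 + (x / K) ** h)


def or_combine(u, v):
    """Two independent promoters driving one gene: bounded, symmetric."""
    return u + v - u * v


def and_gate(u, v, K_T, beta):
    """T7ptag/supD complementation: saturating in the product of the parts."""
    p = u * v
    return beta * p / (K_T + p)


# ----------------------------------------------------------------------
# transfer functions
# ----------------------------------------------------------------------
def usc_transfer(ara, sal, p: SimParams):
    """Normalized LuxI output of the upstream AND cell.

    Monotone non-decreasing in both inducers; the RBS attenuation factor
    scales translation of luxI down by 1/f.
    """
    _check_conc(ara, sal)
    a = hill_activation(ara, p.K_ara, p.h_ara, p.l_ara)
    s = hill_activation(sal, p.K_sal, p.h_sal, p.l_sal)
    return and_gate(a, s, p.K_T, p.beta) / p.rbs_attenuation


def dsc_transfer(ara, sal, ahl, p: SimParams):
    """Normalized GFP output of the downstream cell: (ara OR sal) AND NOT ahl."""
    _check_conc(ara, sal, ahl)
    a = hill_activation(ara, p.K_ara, p.h_ara, p.l_ara)
    s = hill_activation(sal, p.K_sal, p.h_sal, p.l_sal)
    supd = or_combine(a, s)
    t7 = hill_repression(ahl, p.K_ahl, p.h_ahl, p.l_ahl)
    return and_gate(t7, supd, p.K_T, p.beta)


def ahl_level(ara, sal, p: SimParams):
    """Steady-state AHL set by the USC population's LuxI output."""
    factor = p.phi / (1.0 - p.phi) if p.ahl_scaling == "odds" else p.phi
    return p.sigma * factor * usc_transfer(ara, sal, p)


def consortium_response(ara, sal, p: SimParams):
    """Consortium output (DSC fluorescence) at given inducer levels."""
    return dsc_transfer(ara, sal, ahl_level(ara, sal, p), p)


# ----------------------------------------------------------------------
# logic-level summaries
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimResponse:
    outputs: Dict[Tuple[int, int], float]  # (ara_state, sal_state) -> output
    sb_ratio: float

    def to_dict(self) -> dict:
        return {"outputs": {f"{a}{s}": v for (a, s), v in
                            sorted(self.outputs.items())},
                "sb_ratio": self.sb_ratio}


def logic_states(p: SimParams) -> Dict[Tuple[int, int], Tuple[float, float]]:
    return {(a, s): (p.ara_on if a else 0.0, p.sal_on if s else 0.0)
            for a in (0, 1) for s in (0, 1)}


def xor_response(p: SimParams) -> SimResponse:
    """Outputs on the four saturating input states and the XOR
    signal-background ratio: min over ON states / max over OFF states."""
    outs = {}
    for state, (ara, sal) in logic_states(p).items():
        outs[state] = float(consortium_response(ara, sal, p))
    on = min(outs[s] for s in XOR_ON_STATES)
    off = max(outs[s] for s in XOR_OFF_STATES)
    return SimResponse(outs, on / off if off > 0 else float("inf"))


def scan_rbs(factors: Sequence[float], p: SimParams) -> List[Tuple[float, float]]:
    """Signal-background ratio as a function of RBS attenuation; the
    returned table is ordered as given, ready for argmax inspection."""
    factors = list(factors)
    if not factors:
        raise ConsortiaLogicError("factor list must not be empty")
    return [(f, xor_response(p.replace(rbs_attenuation=f)).sb_ratio)
            for f in factors]


def best_rbs(factors: Sequence[float], p: SimParams) -> Tuple[float, float]:
    table = scan_rbs(factors, p)
    return max(table, key=lambda fw: fw[1])


def proportion_robustness(phis: Sequence[float], p: SimParams,
                          threshold: float = 10.0
                          ) -> List[Tuple[float, float, bool]]:
    """(phi, sb_ratio, xor_ok) per USC population fraction."""
    out = []
    for phi in phis:
        sb = xor_response(p.replace(phi=phi)).sb_ratio
        out.append((phi, sb, bool(sb >= threshold)))
    return out


def phi_from_ratio(usc: float, dsc: float) -> float:
    """USC fraction for an inoculation ratio USC:DSC."""
    if usc <= 0 or dsc <= 0:
        raise ParameterError("population ratio parts must be > 0")
    return usc / (usc + dsc)


# ----------------------------------------------------------------------
# characterization grids and parameter recovery
# ----------------------------------------------------------------------
ARA_GRID = tuple(10.0 ** -e for e in range(1, 9))    # 1e-1 .. 1e-8 M
SAL_GRID = tuple(10.0 ** -e for e in range(3, 11))   # 1e-3 .. 1e-10 M
AHL_GRID = tuple(10.0 ** -e for e in range(5, 12))   # 1e-5 .. 1e-11 M


def usc_grid(p: SimParams, ara_grid=ARA_GRID, sal_grid=SAL_GRID):
    a = np.asarray(ara_grid)[:, None]
    s = np.asarray(sal_grid)[None, :]
    return usc_transfer(a, s, p)


def dsc_ahl_curve(p: SimParams, ahl_grid=AHL_GRID, ara=None):
    ara = p.ara_on if ara is None else ara
    return dsc_transfer(ara, 0.0, np.asarray(ahl_grid), p)


def noisy(values, rng: np.random.Generator, cv: float = 0.1):
    """Multiplicative log-normal measurement noise with the given CV."""
    sd = np.sqrt(np.log(1.0 + cv ** 2))
    return np.asarray(values) * rng.lognormal(mean=-sd ** 2 / 2, sigma=sd,
                                              size=np.shape(values))


def recover_parameters(p: SimParams, seed: int, cv: float = 0.1) -> dict:
    """Self-consistency check standing in for fitting the experimental
    transfer functions: simulate the characterization grids from `p`, corrupt
    them with multiplicative noise, and re-fit the three binding constants.

    Returns true/fitted pairs and fold errors for K_ara, K_sal, K_ahl.
    """
    rng = np.random.default_rng(seed)
    usc_data = noisy(usc_grid(p), rng, cv)
    dsc_data = noisy(dsc_ahl_curve(p), rng, cv)

    a = np.asarray(ARA_GRID)[:, None]
    s = np.asarray(SAL_GRID)[None, :]

    def usc_model(log10_ks):
        q = p.replace(K_ara=10.0 ** log10_ks[0], K_sal=10.0 ** log10_ks[1])
        return usc_transfer(a, s, q)

    def usc_resid(log10_ks):
        return np.log(usc_model(log10_ks) / usc_data).ravel()

    fit1 = least_squares(usc_resid,
                         x0=[np.log10(p.K_ara) + 0.5, np.log10(p.K_sal) - 0.5],
                         bounds=([-10, -12], [0, -2]))
    k_ara_fit = 10.0 ** fit1.x[0]
    k_sal_fit = 10.0 ** fit1.x[1]

    ahl = np.asarray(AHL_GRID)

    def dsc_resid(log10_k):
        q = p.replace(K_ahl=10.0 ** log10_k[0])
        return np.log(dsc_transfer(p.ara_on, 0.0, ahl, q) / dsc_data).ravel()

    fit2 = least_squares(dsc_resid, x0=[np.log10(p.K_ahl) + 0.5],
                         bounds=([-12], [-4]))
    k_ahl_fit = 10.0 ** fit2.x[0]

    def fold(a_, b_):
        return float(max(a_ / b_, b_ / a_))

    return {
        "K_ara": {"true": p.K_ara, "fit": float(k_ara_fit),
                  "fold_error": fold(p.K_ara, k_ara_fit)},
        "K_sal": {"true": p.K_sal, "fit": float(k_sal_fit),
                  "fold_error": fold(p.K_sal, k_sal_fit)},
        "K_ahl": {"true": p.K_ahl, "fit": float(k_ahl_fit),
                  "fold_error": fold(p.K_ahl, k_ahl_fit)},
    }


def phase_diagram(p: SimParams, ara_grid=ARA_GRID, sal_grid=SAL_GRID):
    """Consortium output over an (arabinose, salicylate) grid."""
    a = np.asarray(ara_grid)[:, None]
    s = np.asarray(sal_grid)[None, :]
    return consortium_response(a, s, p)
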