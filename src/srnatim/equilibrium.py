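"""Mass-action equilibrium of mRNA, sRNA and ribosome; the signed fold change.

Species: free mRNA m_F, sRNA-bound m_S, ribosome-bound m_R, doubly bound
m_SR, free sRNA s_F, free ribosome r_F.  Ribosome binding acts on the
RDS-exposing fraction of its substrate (m_F* = P_EF m_F, m_S* = P_ES m_S)
with constant K_R; sRNA binding on free mRNA with constant K_S.  Each
initiation event removes n ribosomes from the free pool (default n = 20,
the mean loading of an actively translated bacterial mRNA).

Two topologies:

* overlap -- the sRNA site intersects the RDS, so M_SR cannot exist;
  eliminating all but m_F gives a cubic polynomial.
* nonoverlap -- ribosome and sRNA can bind simultaneously; the
  translationally active pool is m_TA = m_R + m_SR and elimination gives
  a quintic polynomial (here in the free-ribosome concentration r_F).

Both polynomials were derived symbolically from the balance equations
and are verified in the test suite against an independent
multidimensional root-finder on the un-eliminated system
(:func:`oracle_solve`).  Copy numbers per cell are treated as
dimensionless activities and used directly against the exponential
equilibrium constants, a deliberate simplification of the model.

The signed fold change of translational activity is
alpha = m_TA(s_T)/m_TA(0), reported as -m_TA(0)/m_TA(s_T) when the sRNA
represses, so that |alpha| >= 1 always and |alpha| > 2 flags putative
regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq, root

from .nearest_neighbor import DEFAULT_TEMPERATURE, rt_kcal

Topology = Literal["overlap", "nonoverlap"]

_NEWTON_TOL = 1e-12  # relative+absolute convergence of the scalar solve
_RESIDUAL_TOL = 1e-9  # post-hoc mass-balance residual per unit of total


def energy_to_constant(delta_G: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """K = exp(-dG / RT) for a binding free energy in kcal/mol."""
    if not math.isfinite(delta_G):
        raise ValueError(f"free energy must be finite, got {delta_G}")
    return math.exp(-delta_G / rt_kcal(temperature))


def constant_to_probability(K: float) -> float:
    """P = K / (1 + K), the exposure probability of an opening constant."""
    if K < 0:
        raise ValueError(f"equilibrium constant must be >= 0, got {K}")
    if math.isinf(K):
        return 1.0
    return K / (1.0 + K)


def probability_to_constant(p: float) -> float:
    """K = P / (1 - P), inverse of :func:`constant_to_probability`."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    return p / (1.0 - p)


@dataclass(frozen=True)
class EquilibriumParams:
    """Inputs of the equilibrium system for one evaluated binding site."""

    K_R: float
    K_S: float
    P_EF: float
    m_T: float
    s_T: float
    r_T: float
    n: float = 20.0
    P_ES: float | None = None
    topology: Topology = "overlap"

    def __post_init__(self) -> None:
        if self.K_R <= 0 or self.K_S <= 0:
            raise ValueError("binding constants must be positive")
        if not 0.0 < self.P_EF <= 1.0:
            raise ValueError(f"P_EF must be in (0, 1], got {self.P_EF}")
        if min(self.m_T, self.s_T, self.r_T) < 0:
            raise ValueError("total concentrations must be >= 0")
        if self.n < 1:
            raise ValueError(f"ribosome occupancy n must be >= 1, got {self.n}")
        if self.topology == "nonoverlap":
            if self.P_ES is None or not 0.0 < self.P_ES <= 1.0:
                raise ValueError("nonoverlap topology requires P_ES in (0, 1]")


@dataclass(frozen=True)
class EquilibriumResult:
    """Solved species (copies/cell) and per-balance residuals."""

    m_F: float
    m_S: float
    m_R: float
    m_SR: float
    s_F: float
    r_F: float
    m_TA: float
    residuals: dict[str, float] = field(default_factory=dict)


class EquilibriumError(RuntimeError):
    """Numeric failure or feasibility-guard violation in a solver."""


def solve_no_srna(
    K_R: float, P_EF: float, m_T: float, r_T: float, n: float
) -> float:
    """Baseline ribosome-bound mRNA with no sRNA present (closed form).

    Solves m_R = K_R P_EF (m_T - m_R)(r_T - n m_R); the feasible root of
    the quadratic, 0 <= m_R <= min(m_T, r_T/n), is the smaller one,
    evaluated in the numerically stable product form.
    """
    A = K_R * P_EF
    if A == 0 or m_T == 0 or r_T == 0:
        return 0.0
    a = A * n
    b = A * (r_T + n * m_T) + 1.0
    c = A * m_T * r_T
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise EquilibriumError(f"no real root in baseline solve (disc={disc})")
    m_R = 2.0 * c / (b + math.sqrt(disc))
    cap = min(m_T, r_T / n)
    if not -1e-9 * cap <= m_R <= cap * (1 + 1e-9):
        raise EquilibriumError(f"baseline root {m_R} outside [0, {cap}]")
    return min(max(m_R, 0.0), cap)


# --- overlap topology -----------------------------------------------------


def _overlap_cubic(p: EquilibriumParams) -> np.ndarray:
    """Coefficients (highest first) of the eliminated cubic in x = m_F.

    From m_T = x + K_S x s_T/(1+K_S x) + A x r_T/(1+A n x), A = K_R P_EF,
    cleared of denominators.
    """
    A = p.K_R * p.P_EF
    Ks, mT, sT, rT, n = p.K_S, p.m_T, p.s_T, p.r_T, p.n
    c3 = A * n * Ks
    c2 = Ks + A * n - mT * A * n * Ks + Ks * sT * A * n + A * rT * Ks
    c1 = 1.0 - mT * (Ks + A * n) + Ks * sT + A * rT
    c0 = -mT
    return np.array([c3, c2, c1, c0])


def _overlap_rational(x: float, p: EquilibriumParams) -> float:
    """Denominator-free-of-cancellation form of the same scalar equation."""
    A = p.K_R * p.P_EF
    return (
        x
        + p.K_S * x * p.s_T / (1.0 + p.K_S * x)
        + A * x * p.r_T / (1.0 + A * p.n * x)
        - p.m_T
    )


def _overlap_species(x: float, p: EquilibriumParams) -> EquilibriumResult:
    A = p.K_R * p.P_EF
    s_F = p.s_T / (1.0 + p.K_S * x)
    m_S = p.K_S * x * s_F
    m_R = A * x * p.r_T / (1.0 + A * p.n * x)
    # cancellation-free form of r_T - n m_R
    r_F = p.r_T / (1.0 + A * p.n * x)
    res = {
        "srna_balance": s_F + m_S - p.s_T,
        "mrna_balance": x + m_S + m_R - p.m_T,
        "ribosome_balance": r_F + p.n * m_R - p.r_T,
        "ribosome_law": A * x * r_F - m_R,
        "srna_law": p.K_S * x * s_F - m_S,
    }
    return EquilibriumResult(x, m_S, m_R, 0.0, s_F, r_F, m_TA=m_R, residuals=res)


def solve_overlap(p: EquilibriumParams) -> EquilibriumResult:
    """Equilibrium when the sRNA site overlaps the RDS (m_SR = 0)."""
    if p.topology != "overlap":
        raise ValueError("params are not for the overlap topology")
    if p.m_T == 0:
        return _overlap_species(0.0, p)
    coeffs = _overlap_cubic(p)
    x = _solve_scalar(
        lambda x: float(np.polyval(coeffs, x)),
        lambda x: float(np.polyval(np.polyder(coeffs), x)),
        lambda x: _overlap_rational(x, p),
        lo=0.0,
        hi=p.m_T,
    )
    result = _overlap_species(x, p)
    _check_result(result, p, coeffs, lambda r: _overlap_species(r, p),
                  lambda r: _overlap_rational(r, p), hi=p.m_T)
    return result


# --- nonoverlap topology --------------------------------------------------


def _nonoverlap_quintic(p: EquilibriumParams) -> np.ndarray:
    """Coefficients (highest first) of the eliminated quintic in r = r_F.

    Obtained as the resultant, in m_F, of the mRNA- and ribosome-balance
    equations after substituting the mass-action laws; a spurious factor
    (1 + B r), never zero for r >= 0, is dropped.  A = K_R P_EF,
    B = K_R P_ES.
    """
    A = p.K_R * p.P_EF
    B = p.K_R * p.P_ES  # type: ignore[operator]
    Ks, mT, sT, rT, n = p.K_S, p.m_T, p.s_T, p.r_T, p.n
    x28 = (
        -A * n + mT * Ks * B * n + sT * Ks * B * n + A * Ks * mT * n
        - A * Ks * n * sT + B * n
    )
    c5 = B * B * A * Ks * Ks
    c4 = B * Ks * (-B * 2 * A * rT + B + 2 * A * B * n * mT + 2 * A)
    c3 = (
        -4 * B * rT * A * Ks
        + B * 2 * Ks
        + A * Ks * 3 * B * n * mT
        - A * Ks * sT * B * n
        + A * Ks
        - n * A * A
        - rT * B * B * 2 * Ks
        + n * sT * Ks * B * B
        - mT * n * Ks * B * B * 2 * A * rT
        + mT * n * Ks * B * B
        + B * B * A * Ks * rT * rT
        + B * B * A * Ks * mT * mT * n * n
        + A * B * n
    )
    c2 = (
        A * B * mT * n * n
        + B * A * Ks * mT * mT * n * n
        + B * Ks * rT * rT * 2 * A
        - Ks * 2 * A * rT
        + Ks
        + rT * n * A * A
        - 4 * rT * B * Ks
        - rT * A * B * n
        - sT * A * Ks * B * mT * n * n
        + sT * Ks * B * B * mT * n * n
        + B * B * Ks * rT * rT
        - A * A * mT * n * n
        - A * Ks * rT * 3 * B * n * mT
        + A * Ks * rT * sT * B * n
        - mT * n * Ks * rT * B * B
        - n * sT * Ks * rT * B * B
        + x28
    )
    c1 = rT * (A * Ks * rT + 2 * B * Ks * rT - x28 - 2 * Ks)
    c0 = Ks * rT * rT
    return np.array([c5, c4, c3, c2, c1, c0])


def _nonoverlap_mF(r: float, p: EquilibriumParams) -> float:
    """m_F as the unique positive root of the quadratic mRNA balance at fixed r_F."""
    A = p.K_R * p.P_EF
    B = p.K_R * p.P_ES  # type: ignore[operator]
    q = p.K_S * (1.0 + B * r)
    a2 = -(1.0 + A * r) * q
    a1 = p.m_T * q - (1.0 + A * r) - q * p.s_T
    a0 = p.m_T
    if a2 == 0:  # K_S -> 0 degenerate; linear
        return -a0 / a1 if a1 != 0 else 0.0
    disc = max(a1 * a1 - 4.0 * a2 * a0, 0.0)
    # a2 < 0, a0 > 0: roots have opposite signs.  Citardauq-style stable
    # evaluation: the large-magnitude root via the quadratic formula with
    # matching signs, the other via the root product, then pick positive.
    qq = -0.5 * (a1 + math.copysign(math.sqrt(disc), a1))
    roots = []
    if qq != 0.0:
        roots.append(a0 / qq)
    if a2 != 0.0 and qq != 0.0:
        roots.append(qq / a2)
    pos = [x for x in roots if x > 0.0]
    return min(pos) if pos else 0.0


def _nonoverlap_rational(r: float, p: EquilibriumParams) -> float:
    """Ribosome balance residual at fixed r_F with m_F from the quadratic."""
    A = p.K_R * p.P_EF
    B = p.K_R * p.P_ES  # type: ignore[operator]
    x = _nonoverlap_mF(r, p)
    s_F = p.s_T / (1.0 + p.K_S * x * (1.0 + B * r))
    m_S = p.K_S * x * s_F
    return r + p.n * (A * x * r + B * m_S * r) - p.r_T


def _nonoverlap_species(r: float, p: EquilibriumParams) -> EquilibriumResult:
    A = p.K_R * p.P_EF
    B = p.K_R * p.P_ES  # type: ignore[operator]
    x = _nonoverlap_mF(r, p)
    s_F = p.s_T / (1.0 + p.K_S * x * (1.0 + B * r))
    m_S = p.K_S * x * s_F
    m_R = A * x * r
    m_SR = B * m_S * r
    res = {
        "srna_balance": s_F + m_S + m_SR - p.s_T,
        "mrna_balance": x + m_S + m_R + m_SR - p.m_T,
        "ribosome_balance": r + p.n * (m_R + m_SR) - p.r_T,
        "ribosome_law": A * x * r - m_R,
        "srna_law": p.K_S * x * s_F - m_S,
        "complex_law": B * m_S * r - m_SR,
    }
    return EquilibriumResult(
        x, m_S, m_R, m_SR, s_F, r, m_TA=m_R + m_SR, residuals=res
    )


def solve_nonoverlap(p: EquilibriumParams) -> EquilibriumResult:
    """Equilibrium when the sRNA site and RDS are spatially separated."""
    if p.topology != "nonoverlap":
        raise ValueError("params are not for the nonoverlap topology")
    if p.r_T == 0:
        return _nonoverlap_species(0.0, p)
    coeffs = _nonoverlap_quintic(p)
    r = _solve_scalar(
        lambda r: float(np.polyval(coeffs, r)),
        lambda r: float(np.polyval(np.polyder(coeffs), r)),
        lambda r: _nonoverlap_rational(r, p),
        lo=0.0,
        hi=p.r_T,
    )
    result = _nonoverlap_species(r, p)
    _check_result(result, p, coeffs, lambda r_: _nonoverlap_species(r_, p),
                  lambda r_: _nonoverlap_rational(r_, p), hi=p.r_T)
    return result


# --- shared scalar machinery ---------------------------------------------


def _solve_scalar(f_poly, df_poly, f_rational, lo: float, hi: float) -> float:
    """Newton on the eliminated polynomial, bracketed bisection fallback.

    Newton runs from the box midpoint with analytic derivative; whenever
    an iterate escapes [lo, hi] or stalls, the better-conditioned
    rational form of the same equation is solved by bracketed root
    finding.  The rational form is monotone on the physical box, so the
    bracket [lo, hi] always encloses exactly the feasible root.
    """
    x = 0.5 * (lo + hi)
    converged = False
    for _ in range(100):
        fx = f_poly(x)
        dfx = df_poly(x)
        if dfx == 0 or not math.isfinite(fx):
            break
        step = fx / dfx
        x_new = x - step
        if not lo <= x_new <= hi:
            break
        if abs(step) <= _NEWTON_TOL * (abs(x_new) + _NEWTON_TOL):
            x = x_new
            converged = True
            break
        x = x_new
    if converged:
        # polish on the rational form; accept only if it stays bracketed
        x = _polish(f_rational, x, lo, hi)
        return x
    return _bisect_rational(f_rational, lo, hi)


def _polish(f, x: float, lo: float, hi: float) -> float:
    fx = f(x)
    if fx == 0.0:
        return x
    # tiny bracket around the Newton solution; widen geometrically
    span = max(abs(x), 1.0) * 1e-9
    for _ in range(60):
        a, b = max(lo, x - span), min(hi, x + span)
        fa, fb = f(a), f(b)
        if fa == 0.0:
            return a
        if fb == 0.0:
            return b
        if fa * fb < 0:
            return brentq(f, a, b, xtol=1e-300, rtol=8.9e-16, maxiter=200)
        span *= 4.0
        if a == lo and b == hi:
            break
    return _bisect_rational(f, lo, hi)


def _bisect_rational(f, lo: float, hi: float) -> float:
    fa, fb = f(lo), f(hi)
    if fa == 0.0:
        return lo
    if fb == 0.0:
        return hi
    if fa * fb > 0:
        raise EquilibriumError(
            f"no sign change of the balance equation on [{lo}, {hi}]: "
            f"f(lo)={fa}, f(hi)={fb}"
        )
    return brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=300)


def _feasible(res: EquilibriumResult, p: EquilibriumParams, tol: float = 1e-6) -> bool:
    totals = {
        "m_F": p.m_T, "m_S": p.m_T, "m_R": p.m_T, "m_SR": p.m_T,
        "s_F": p.s_T, "r_F": p.r_T,
    }
    for name, total in totals.items():
        v = getattr(res, name)
        if v < -tol * max(total, 1.0) or v > total * (1.0 + tol) + tol:
            return False
    return True


def _check_result(result, p, coeffs, reconstruct, f_rational, hi: float) -> None:
    """Residual check plus the unique-feasible-root guard.

    Polynomial roots under extreme binding constants carry rounding
    noise, so candidate roots are re-qualified on the well-conditioned
    rational form of the balance equation before they count as feasible.
    """
    scale = {
        "srna_balance": max(p.s_T, 1.0),
        "mrna_balance": max(p.m_T, 1.0),
        "ribosome_balance": max(p.r_T, 1.0),
    }
    for name, s in scale.items():
        if abs(result.residuals[name]) > _RESIDUAL_TOL * s:
            raise EquilibriumError(
                f"balance residual {name}={result.residuals[name]:.3e} "
                f"exceeds {_RESIDUAL_TOL:.0e} * {s:.3e}"
            )
    rational_scale = max(abs(f_rational(0.0)), abs(f_rational(hi)), 1e-300)
    roots = np.roots(coeffs)
    feasible: list[float] = []
    for z in roots:
        if abs(z.imag) > 1e-7 * (abs(z.real) + 1.0):
            continue
        r = min(max(float(z.real), 0.0), hi)
        if float(z.real) < -1e-6 * hi or float(z.real) > hi * (1 + 1e-6):
            continue
        if abs(f_rational(r)) > 1e-5 * rational_scale:
            continue
        if _feasible(reconstruct(r), p):
            if not any(abs(r - o) <= 1e-5 * abs(o) + 1e-7 * hi for o in feasible):
                feasible.append(r)
    if len(feasible) > 1:
        raise EquilibriumError(
            f"multiple feasible roots of the eliminated polynomial: {feasible}"
        )


def solve(p: EquilibriumParams) -> EquilibriumResult:
    """Dispatch to the topology-matching solver."""
    return solve_overlap(p) if p.topology == "overlap" else solve_nonoverlap(p)


def fold_change(m_with: float, m_without: float) -> float:
    """Signed ratio alpha of translational activity with vs without sRNA.

    alpha = m_with/m_without when activity rises (or is unchanged), else
    -m_without/m_with; |alpha| >= 1 always.  A vanished activity under
    sRNA maps to -inf; a zero baseline is an error ("baseline inactive").
    """
    if m_without <= 0:
        raise ValueError("baseline inactive: m_TA(0) must be > 0")
    if m_with >= m_without:
        return m_with / m_without
    if m_with == 0:
        return -math.inf
    return -m_without / m_with


def alpha_for(p: EquilibriumParams) -> tuple[float, float, float]:
    """Convenience: (alpha, m_TA with sRNA, m_TA baseline) for one site.

    s_T = 0 is the baseline system itself, so alpha is +1 exactly there,
    with no round-off from solving the same equations twice.
    """
    baseline = solve_no_srna(p.K_R, p.P_EF, p.m_T, p.r_T, p.n)
    if p.s_T == 0:
        return 1.0, baseline, baseline
    with_srna = solve(p).m_TA
    return fold_change(with_srna, baseline), with_srna, baseline


# --- independent oracle ---------------------------------------------------


def oracle_solve(
    p: EquilibriumParams, rng: np.random.Generator | None = None, n_starts: int = 24
) -> EquilibriumResult:
    """Solve the un-eliminated system by multidimensional root-finding.

    Works on (log m_F, log s_F, log r_F) with the three conservation
    equations (mass-action laws substituted), started from multiple
    feasible interior points; never touches the eliminated polynomial.
    Intended as the independent verification path for the solvers.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if p.s_T == 0:
        m_R = solve_no_srna(p.K_R, p.P_EF, p.m_T, p.r_T, p.n)
        r_F = p.r_T - p.n * m_R
        m_F = p.m_T - m_R
        base = EquilibriumParams(
            p.K_R, p.K_S, p.P_EF, p.m_T, 0.0, p.r_T, p.n, p.P_ES, p.topology
        )
        rec = _overlap_species if p.topology == "overlap" else _nonoverlap_species
        return rec(m_F if p.topology == "overlap" else r_F, base)

    A = p.K_R * p.P_EF
    B = p.K_R * (p.P_ES if p.topology == "nonoverlap" else 0.0)

    def residuals(logs: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            m_F, s_F, r_F = np.exp(np.minimum(logs, 700.0))
            m_S = p.K_S * m_F * s_F
            m_R = A * m_F * r_F
            m_SR = B * m_S * r_F
            out = np.array(
                [
                    (m_F + m_S + m_R + m_SR - p.m_T) / max(p.m_T, 1.0),
                    (s_F + m_S + m_SR - p.s_T) / max(p.s_T, 1.0),
                    (r_F + p.n * (m_R + m_SR) - p.r_T) / max(p.r_T, 1.0),
                ]
            )
        return np.nan_to_num(out, nan=1e6, posinf=1e6, neginf=-1e6)

    def jacobian(logs: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            m_F, s_F, r_F = np.exp(np.minimum(logs, 700.0))
            ms = p.K_S * m_F * s_F
            mr = A * m_F * r_F
            msr = B * ms * r_F
            M, S, R = max(p.m_T, 1.0), max(p.s_T, 1.0), max(p.r_T, 1.0)
            J = np.array(
                [
                    [(m_F + ms + mr + msr) / M, (ms + msr) / M, (mr + msr) / M],
                    [(ms + msr) / S, (s_F + ms + msr) / S, msr / S],
                    [p.n * (mr + msr) / R, p.n * msr / R,
                     (r_F + p.n * (mr + msr)) / R],
                ]
            )
        return np.nan_to_num(J, nan=0.0, posinf=1e12, neginf=-1e12)

    def damped_iteration(frac: np.ndarray) -> np.ndarray:
        """Damped log-space fixed point of the conservation laws."""
        m_F = max(p.m_T * frac[0], 1e-300)
        s_F = max(p.s_T * frac[1], 1e-300)
        r_F = max(p.r_T * frac[2], 1e-300)
        lam = 0.5
        for _ in range(2000):
            s_F_new = p.s_T / (1.0 + p.K_S * m_F * (1.0 + B * r_F))
            r_F_new = p.r_T / (1.0 + p.n * m_F * (A + B * p.K_S * s_F))
            m_F_new = p.m_T / (1.0 + p.K_S * s_F * (1.0 + B * r_F) + A * r_F)
            m_F = math.exp((1 - lam) * math.log(m_F) + lam * math.log(max(m_F_new, 1e-300)))
            s_F = math.exp((1 - lam) * math.log(s_F) + lam * math.log(max(s_F_new, 1e-300)))
            r_F = math.exp((1 - lam) * math.log(r_F) + lam * math.log(max(r_F_new, 1e-300)))
        return np.log(np.array([m_F, s_F, r_F]))

    best = None
    for k in range(n_starts):
        frac = rng.uniform(0.05, 0.95, size=3) if k else np.array([0.5, 0.5, 0.5])
        x0 = damped_iteration(frac)
        for method in ("lm", "hybr"):
            sol = root(residuals, x0, jac=jacobian, method=method, tol=1e-15)
            err = float(np.max(np.abs(residuals(sol.x))))
            if best is None or err < best[0]:
                best = (err, sol.x)
            if err < 1e-11:
                break
        if best is not None and best[0] < 1e-11:
            break
    assert best is not None
    err, logs = best
    if err > 1e-8:
        raise EquilibriumError(f"oracle did not converge: max residual {err:.3e}")
    m_F, s_F, r_F = (float(v) for v in np.exp(logs))
    m_S = p.K_S * m_F * s_F
    m_R = A * m_F * r_F
    m_SR = B * m_S * r_F
    res = {
        "srna_balance": s_F + m_S + m_SR - p.s_T,
        "mrna_balance": m_F + m_S + m_R + m_SR - p.m_T,
        "ribosome_balance": r_F + p.n * (m_R + m_SR) - p.r_T,
    }
    m_TA = m_R + (m_SR if p.topology == "nonoverlap" else 0.0)
    return EquilibriumResult(m_F, m_S, m_R, m_SR, s_F, r_F, m_TA, res)
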