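"""Mass-action ODE construction, simulation, fixed points and stability.

For a network with stoichiometric matrix N and rate constants k the
mass-action vector field is

    dx/dt = N · diag(k) · m(x),      m_r(x) = prod_s x_s^lhs_mult(s, r),

a polynomial field whose Jacobian is available in closed form.  The
support of any fixed point (the species with strictly positive
concentration) is necessarily a chemical organization of the network,
which :func:`fixed_point_support_check` verifies against the algebraic
machinery in :mod:`orgcycle.organization`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .network import NetworkError, ReactionNetwork, stoichiometric_matrix

__all__ = [
    "RateAssignment",
    "ODESystem",
    "Trajectory",
    "FixedPoint",
    "build_odes",
    "simulate",
    "find_fixed_point",
    "stability",
    "fixed_point_support_check",
    "positive_fixed_point_search",
]

#: eigenvalue tolerance separating stable / marginal / unstable verdicts
TOL_EIG = 1e-9


class RateAssignment(dict):
    """Per-reaction positive rate constants (reaction id -> k).

    Missing reactions default to ``forward`` (1.0), or to ``reverse``
    (default 0.1) when the reaction id ends in ``_rev`` or the reaction
    was produced by splitting a reversible reaction.  A zero or negative
    constant is rejected: to disable a reaction remove it from the network.
    """

    def __init__(
        self,
        rates: Optional[Mapping[str, float]] = None,
        forward: float = 1.0,
        reverse: float = 0.1,
    ):
        super().__init__(rates or {})
        self.forward = float(forward)
        self.reverse = float(reverse)
        for rid, k in self.items():
            if not k > 0:
                raise NetworkError(
                    f"rate constant of {rid!r} must be > 0, got {k!r}"
                )

    def constant(self, rid: str, is_reverse: bool = False) -> float:
        if rid in self:
            return float(self[rid])
        if is_reverse or rid.endswith("_rev"):
            return self.reverse
        return self.forward

    def vector(self, net: ReactionNetwork) -> np.ndarray:
        return np.array(
            [
                self.constant(r.id, is_reverse=r.reversible_origin is not None
                              and r.id.endswith("_rev"))
                for r in net.reactions
            ]
        )


@dataclass
class ODESystem:
    """Mass-action vector field with analytic Jacobian."""

    network: ReactionNetwork
    rate_constants: np.ndarray  # per reaction, network order
    N: np.ndarray  # stoichiometric matrix, species x reactions
    exponents: np.ndarray  # lhs multiplicities, species x reactions

    @property
    def species(self) -> Tuple[str, ...]:
        return self.network.species

    def monomials(self, x: np.ndarray) -> np.ndarray:
        xs = np.clip(np.asarray(x, dtype=float), 0.0, None)
        # prod over species of x_s^e_sr, vectorized over reactions
        with np.errstate(divide="ignore"):
            logs = np.where(xs[:, None] > 0, np.log(np.where(xs[:, None] > 0, xs[:, None], 1.0)), -np.inf)
        expo = self.exponents
        out = np.empty(expo.shape[1])
        for j in range(expo.shape[1]):
            mask = expo[:, j] > 0
            if not mask.any():
                out[j] = 1.0
            else:
                out[j] = np.prod(xs[mask] ** expo[mask, j])
        return out

    def rates(self, x: np.ndarray) -> np.ndarray:
        return self.rate_constants * self.monomials(x)

    def field(self, x: np.ndarray) -> np.ndarray:
        return self.N @ self.rates(x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Closed-form Jacobian of the polynomial field at x."""
        xs = np.clip(np.asarray(x, dtype=float), 0.0, None)
        n_s, n_r = self.exponents.shape
        drate = np.zeros((n_r, n_s))
        mono = self.monomials(xs)
        for j in range(n_r):
            for i in range(n_s):
                e = self.exponents[i, j]
                if e == 0:
                    continue
                if xs[i] > 0:
                    drate[j, i] = self.rate_constants[j] * mono[j] * e / xs[i]
                else:
                    # derivative at the boundary: e * x^(e-1) * rest
                    if e == 1:
                        rest = 1.0
                        for k in range(n_s):
                            if k == i:
                                continue
                            ek = self.exponents[k, j]
                            if ek:
                                rest *= xs[k] ** ek
                        drate[j, i] = self.rate_constants[j] * rest
                    else:
                        drate[j, i] = 0.0
        return self.N @ drate

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.field(x)


def build_odes(
    net: ReactionNetwork,
    rates: Optional[RateAssignment | Mapping[str, float]] = None,
) -> ODESystem:
    """Assemble the mass-action ODE system for a network."""
    if rates is None:
        rates = RateAssignment()
    elif not isinstance(rates, RateAssignment):
        rates = RateAssignment(rates)
    if any(r.reversible for r in net.reactions):
        raise NetworkError(
            "network still contains unexpanded reversible reactions; "
            "run split_reversible first"
        )
    sm = stoichiometric_matrix(net)
    si = net.species_index()
    E = np.zeros_like(sm.matrix)
    for j, r in enumerate(net.reactions):
        for s, m in r.lhs.items():
            E[si[s], j] = m
    return ODESystem(
        network=net,
        rate_constants=rates.vector(net),
        N=sm.matrix.astype(float),
        exponents=E,
    )


@dataclass
class Trajectory:
    """Simulation result: times, states (len(t) x n_species), diagnostics."""

    t: np.ndarray
    x: np.ndarray
    species: Tuple[str, ...]
    success: bool
    message: str
    clipped: bool = False  # negative excursions were clipped to 0

    def final(self) -> np.ndarray:
        return self.x[-1]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.x, columns=list(self.species), index=self.t)


def simulate(
    sys: ODESystem,
    x0: Sequence[float] | Mapping[str, float],
    t_end: float = 100.0,
    n_points: int = 200,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the mass-action system from a non-negative initial state.

    Uses a stiff-capable adaptive integrator; tiny negative numerical
    excursions (>= -1e-12) are clipped to zero and flagged.
    """
    if isinstance(x0, Mapping):
        x0 = [float(x0.get(s, 0.0)) for s in sys.species]
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (len(sys.species),):
        raise NetworkError(
            f"initial state needs {len(sys.species)} entries, got {x0.shape}"
        )
    if (x0 < 0).any():
        raise NetworkError("initial concentrations must be non-negative")
    t_eval = np.linspace(0.0, t_end, n_points)

    def blow_up(t, x):
        # terminal guard against finite-time escape: polynomial fields can
        # diverge with step sizes shrinking to nothing
        return 1e6 - float(np.abs(x).max())

    blow_up.terminal = True

    sol = solve_ivp(
        sys, (0.0, t_end), x0, method=method, t_eval=t_eval,
        jac=lambda t, x: sys.jacobian(x), rtol=rtol, atol=atol,
        events=[blow_up],
    )
    if sol.status == 1 or (sol.t.size and sol.t[-1] < t_end * (1 - 1e-9)):
        raise RuntimeError(
            "integration diverged (unbounded growth; no finite attractor "
            "along this trajectory)"
        )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    x = sol.y.T
    if not np.isfinite(x).all():
        raise RuntimeError("integration produced non-finite values")
    clipped = bool((x < 0).any())
    if (x < -1e-9).any():
        # beyond harmless round-off; still clip but say so in the message
        msg = f"{sol.message} (negative excursion {x.min():.2e} clipped)"
    else:
        msg = sol.message
    return Trajectory(
        t=sol.t, x=np.clip(x, 0.0, None), species=sys.species,
        success=sol.success, message=msg, clipped=clipped,
    )


@dataclass
class FixedPoint:
    """A candidate steady state with its stability verdict.

    ``verdict`` is ``"stable"`` when every Jacobian eigenvalue has real
    part below -TOL_EIG, ``"unstable"`` when some real part exceeds
    +TOL_EIG, and ``"marginal"`` otherwise (eigenvalues on the imaginary
    axis within tolerance, e.g. from a conserved quantity).
    """

    state: np.ndarray
    species: Tuple[str, ...]
    residual: float
    converged: bool
    eigenvalues: Optional[np.ndarray] = None
    verdict: Optional[str] = None

    def support(self, threshold: Optional[float] = None) -> frozenset:
        """Species with concentration above threshold.

        Default threshold max(1e-6, 1e-6 * max concentration) separates
        decayed from persistent species across stiff regimes.
        """
        if threshold is None:
            mx = float(self.state.max()) if self.state.size else 0.0
            threshold = max(1e-6, 1e-6 * mx)
        return frozenset(
            s for s, v in zip(self.species, self.state) if v > threshold
        )

    def is_strictly_positive(self, threshold: float = 1e-6) -> bool:
        return bool((self.state > threshold).all())


def find_fixed_point(
    sys: ODESystem,
    guess: Sequence[float] | Mapping[str, float],
    tol: float = 1e-9,
    max_newton: int = 50,
) -> FixedPoint:
    """Locate a non-negative root of the vector field near ``guess``.

    A bounded trust-region least-squares pass (analytic Jacobian,
    non-negativity enforced through the bounds) finds the basin; a short
    damped-Newton polish then pushes the residual to tolerance.  Raises
    RuntimeError carrying the best iterate when no root is reached.
    """
    if isinstance(guess, Mapping):
        guess = [float(guess.get(s, 0.0)) for s in sys.species]
    x = np.clip(np.asarray(guess, dtype=float), 0.0, None)
    if not np.isfinite(x).all() or x.max(initial=0.0) > 1e8:
        raise RuntimeError("fixed-point search started from a divergent state")

    res = least_squares(
        sys.field, x, jac=lambda v: sys.jacobian(v),
        bounds=(0.0, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=300,
    )
    x = np.clip(res.x, 0.0, None)

    # damped Newton polish
    for _ in range(max_newton):
        f = sys.field(x)
        if np.linalg.norm(f, np.inf) < tol:
            break
        J = sys.jacobian(x)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        alpha = 1.0
        base = np.linalg.norm(f)
        while alpha > 1e-8:
            xn = np.clip(x + alpha * step, 0.0, None)
            if np.linalg.norm(sys.field(xn)) < base:
                x = xn
                break
            alpha /= 2.0
        else:
            break

    residual = float(np.linalg.norm(sys.field(x), np.inf))
    fp = FixedPoint(
        state=x, species=sys.species, residual=residual,
        converged=residual < tol,
    )
    if not fp.converged:
        err = RuntimeError(
            f"fixed-point search did not converge (residual {residual:.2e})"
        )
        err.best = fp  # type: ignore[attr-defined]
        raise err
    return fp


def stability(sys: ODESystem, fp: FixedPoint, tol_eig: float = TOL_EIG) -> FixedPoint:
    """Attach Jacobian eigenvalues and a stability verdict to a fixed point."""
    eig = np.linalg.eigvals(sys.jacobian(fp.state))
    mx = float(eig.real.max()) if eig.size else -np.inf
    if mx < -tol_eig:
        verdict = "stable"
    elif mx > tol_eig:
        verdict = "unstable"
    else:
        verdict = "marginal"
    fp.eigenvalues = eig
    fp.verdict = verdict
    return fp


def fixed_point_support_check(
    net: ReactionNetwork,
    fp: FixedPoint,
    threshold: Optional[float] = None,
) -> bool:
    """Does the fixed point's support form a chemical organization?

    Any exact fixed point of the mass-action dynamics must be supported on
    an organization; failure on a converged fixed point indicates either a
    threshold artefact or an implementation bug.
    """
    from .organization import is_organization

    return is_organization(net, fp.support(threshold))


def positive_fixed_point_search(
    sys: ODESystem,
    n_starts: int = 20,
    seed: int = 0,
    scale: float = 2.0,
    t_settle: float = 50.0,
    tol: float = 1e-9,
) -> Optional[FixedPoint]:
    """Search for a strictly positive fixed point from seeded random starts.

    Each start draws a positive random state, relaxes it by a short
    simulation, then runs the root finder.  Returns the first strictly
    positive converged fixed point, or None when every start ends on the
    boundary (some coordinate zero) — the dynamical signature of a full
    species set that is not self-maintaining.
    """
    rng = np.random.default_rng(seed)
    best: Optional[FixedPoint] = None
    for _ in range(n_starts):
        x0 = rng.uniform(0.1, scale, size=len(sys.species))
        try:
            settled = simulate(sys, x0, t_end=t_settle, n_points=20).final()
        except RuntimeError:
            settled = x0
        try:
            fp = find_fixed_point(sys, settled, tol=tol)
        except RuntimeError:
            continue
        if fp.is_strictly_positive():
            return stability(sys, fp)
        best = fp
    return None
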