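"""Minimization of metabolic adjustment (MOMA).

A knockout mutant is not assumed to re-optimize growth.  Instead its
flux state x is predicted as the point of the mutant's feasible space
Φ = {x : S·x = 0, bounds, x_j = 0 for disabled j} closest in Euclidean
distance D(w, x) = sqrt(Σ_i (w_i − x_i)²) to a wild-type reference
vector w.  The objective is convex (we minimize the squared distance,
same argmin), so the flux solution is unique; growth is read off x,
never optimized.

Numerically the QP is reduced before solving: every equality — the
mass balances, knocked-out reactions, and bound pairs with
lower = upper — is eliminated through an orthonormal nullspace basis N
(x = x₀ + N·t with x₀ a feasible point obtained from an LP).  Because
N is orthonormal the reduced problem is a least-distance program
(projection of a point onto a low-dimensional polytope).  The active
constraint set is located with the Lawson-Hanson dual-NNLS
construction and the projection is then re-solved exactly on that set
by least squares, with a bounded add/drop correction loop enforcing the
KKT conditions.  Mass balance holds to machine precision by
construction of the nullspace parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import nnls

from .fba import (
    BIG_BOUND,
    ConstraintSet,
    FluxDistribution,
    InfeasibleProblem,
    _effective_bounds,
    _extra_rows,
    fba,
)
from .model import MetabolicModel, ModelError, build_stoichiometric_matrix

__all__ = ["MomaSolution", "moma"]

CONVERGENCE_TOL = 1.0e-8


@dataclass
class MomaSolution:
    fluxes: FluxDistribution
    distance: float
    reference: FluxDistribution

    @property
    def growth(self) -> float:
        return self.fluxes.objective_value


def _solve_on_set(
    c: np.ndarray, A: np.ndarray, b: np.ndarray, work: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Projection of c onto the affine hull of the working rows
    {t : A_W t = b_W}; returns (t, multipliers)."""
    if not work:
        return c.copy(), np.zeros(0)
    Aw = A[work]
    lam, *_ = np.linalg.lstsq(Aw @ Aw.T, Aw @ c - b[work], rcond=None)
    return c - Aw.T @ lam, lam


def _project_onto_polytope(
    c: np.ndarray, A: np.ndarray, b: np.ndarray, tol: float = 1.0e-9
) -> np.ndarray:
    """argmin ||t − c||  subject to  A·t ≤ b,  assuming t = 0 is feasible.

    The rows are normalized, the active set is estimated from the
    support of the Lawson-Hanson dual NNLS solution of the equivalent
    least-distance program, and KKT violations are repaired by a short
    add/drop loop, each step an exact least-squares projection.
    """

    m, d = A.shape
    if m == 0:
        return c.copy()
    scale = np.linalg.norm(A, axis=1)
    scale[scale == 0] = 1.0
    A = A / scale[:, None]
    b = b / scale

    # dual NNLS on normalized [A; b] locates the active rows
    f = A @ c - b  # violation of each row at the unconstrained optimum
    work: list[int]
    if (f <= tol).all():
        return c.copy()
    E = -A
    norm2 = np.sqrt((E**2).sum(axis=1) + f**2)
    norm2[norm2 == 0] = 1.0
    M = np.vstack([(E / norm2[:, None]).T, (f / norm2)[None, :]])
    rhs = np.zeros(d + 1)
    rhs[-1] = 1.0
    try:
        z, _ = nnls(M, rhs)
        work = list(np.flatnonzero(z > 0))
    except Exception:  # pragma: no cover - nnls failure, cold start instead
        work = []

    best: np.ndarray | None = None
    for _ in range(200):
        t, lam = _solve_on_set(c, A, b, work)
        if len(work) and lam.min() < -tol:
            work.pop(int(np.argmin(lam)))
            continue
        viol = A @ t - b
        worst = int(np.argmax(viol))
        if viol[worst] <= tol * (1.0 + float(np.linalg.norm(t))):
            return t
        best = t
        if worst in work:  # numerically stuck; fall back below
            break
        work.append(worst)
    # Guaranteed-feasible fallback: pull the last iterate toward the
    # feasible point 0 until every constraint holds (upper bound on the
    # true projection quality, used only in pathological cases).
    t = best if best is not None else c.copy()
    viol = A @ t - b
    shrink = 1.0
    for i in np.flatnonzero(viol > 0):
        denom = float(A[i] @ t)
        if denom > b[i] and denom != 0:
            shrink = min(shrink, b[i] / denom if denom > 0 else 1.0)
    return t * max(shrink, 0.0)


def moma(
    model: MetabolicModel,
    mutant_constraints: ConstraintSet | None,
    disabled: Iterable[str],
    wild_type: FluxDistribution,
    big: float = BIG_BOUND,
) -> MomaSolution:
    """Predict the mutant flux state closest to ``wild_type``.

    ``disabled`` reactions are clamped to zero flux on top of
    ``mutant_constraints``.  Raises :class:`InfeasibleProblem` when the
    mutant polytope is empty.  The reported ``distance`` is the Euclidean
    distance between the wild-type and mutant vectors.
    """

    disabled = set(disabled)
    unknown = disabled - set(model.reactions)
    if unknown:
        raise ModelError(f"unknown reaction id(s) in deletions: {sorted(unknown)}")
    constraints = (mutant_constraints or ConstraintSet()).merged(
        {r: (0.0, 0.0) for r in disabled}
    )
    order, lo, hi = _effective_bounds(model, constraints, big)
    missing = [r for r in order if r not in wild_type.fluxes]
    if missing:
        raise ModelError(f"wild-type vector lacks reactions: {missing[:3]}")
    w = wild_type.as_array(order)

    # Feasibility check + a particular feasible point x0 via an LP.
    try:
        start = fba(model, constraints, big=big)
    except InfeasibleProblem:
        raise InfeasibleProblem(
            f"mutant with deletions {sorted(disabled)} has an empty feasible space"
        )
    x0 = start.as_array(order)

    n = len(order)
    S = build_stoichiometric_matrix(model).matrix
    fixed = np.isclose(lo, hi)
    eq_rows = [S] if S.size else [np.zeros((0, n))]
    for j in np.flatnonzero(fixed):
        e = np.zeros(n)
        e[j] = 1.0
        eq_rows.append(e[None, :])
    A_eq = np.vstack(eq_rows)
    N = null_space(A_eq)
    d = N.shape[1]
    x0 = np.clip(x0, lo, hi)

    if d == 0:  # fully determined mutant
        x = x0
    else:
        # inequality rows G x <= g  (free bounds plus extra linear constraints)
        free = ~fixed
        G_list = [np.eye(n)[free], -np.eye(n)[free]]
        g_list = [hi[free], -lo[free]]
        A_ub, b_ub = _extra_rows(constraints, order)
        if A_ub is not None:
            G_list.append(A_ub)
            g_list.append(b_ub)
        G = np.vstack(G_list)
        g = np.concatenate(g_list)
        GN = G @ N
        slack0 = np.maximum(g - G @ x0, 0.0)

        # In reduced coordinates (N orthonormal): project c onto
        # {t : GN t <= slack0}, a set containing t = 0.
        c = N.T @ (w - x0)
        radius = 2.0 * float(np.linalg.norm(c)) + 1.0
        row_norm = np.linalg.norm(GN, axis=1)
        keep = slack0 <= row_norm * radius  # rows reachable by the projection
        t = _project_onto_polytope(c, GN[keep], slack0[keep])
        x = x0 + N @ t

    x = np.clip(x, lo, hi)
    fluxes = {r: float(x[j]) for j, r in enumerate(order)}
    biomass = model.objective_reaction_id
    dist = float(np.linalg.norm(x - w))
    return MomaSolution(
        fluxes=FluxDistribution(fluxes, fluxes[biomass], biomass),
        distance=dist,
        reference=wild_type,
    )
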