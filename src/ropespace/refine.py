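"""Torsion refinement: fit an ideal-geometry rebuild to deposited coordinates.

Measuring torsions directly from a deposited structure and rebuilding with
ideal bond lengths and angles produces a drifting, nonsensical polypeptide
path — thousands of small local-geometry differences accumulate along the
chain.  Refinement repairs this by optimising the torsions themselves so the
rebuilt chain best matches the deposited atomic coordinates.

Procedure: torsions are first (re)estimated by measuring each dihedral from
the deposited coordinates (accepted only if it improves the fit), then
optimised by damped Gauss-Newton with an analytic Jacobian — the derivative
of a subtree atom's position with respect to its driving torsion is the
cross product of the rotation axis with the lever arm.  The objective is the
all-heavy-atom RMSD after rigid superposition of the rebuild onto the
deposit (per ordered segment), so refined torsions are invariant to any
rigid-body placement of the deposited chain.  A per-torsion analytic
coordinate-descent sweep serves as a fallback when a Gauss-Newton step
cannot improve.  Every accepted step decreases the objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coords import kabsch
from .geometry import InternalModel, measure_dihedral, wrap_angle
from .structure_io import ChainModel


@dataclass
class RefinementSettings:
    convergence_tol: float = 1e-4  # Angstrom change in fit RMSD per iteration
    max_sweeps: int = 50
    step_init: float = 2.0  # degrees; cap warm-up coordinate-descent steps
    damping_init: float = 1e-4  # initial Levenberg damping

    def __post_init__(self):
        if min(self.convergence_tol, self.max_sweeps,
               self.step_init, self.damping_init) <= 0:
            raise ValueError("all refinement settings must be positive")


@dataclass
class RefinementResult:
    refined: InternalModel
    fit_rmsd: float  # Angstrom, superposed all-heavy-atom RMSD
    sweeps_used: int
    converged: bool
    trace: list = field(default_factory=list)  # RMSD after each iteration


def _rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    ux, uy, uz = u
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(u, u)


def _segment_indices(internal: InternalModel) -> list[np.ndarray]:
    return [np.flatnonzero(internal.segment == s)
            for s in np.unique(internal.segment)]


def target_coordinates(chain: ChainModel, internal: InternalModel) -> np.ndarray:
    """Deposited coordinates reordered to the internal model's atom order."""
    res_atoms = chain.residue_atoms()
    target = np.zeros((internal.n_atoms, 3))
    for i, name in enumerate(internal.atom_names):
        num, icode, _ = internal.residues[internal.atom_res[i]]
        target[i] = res_atoms[(num, icode)][name].position
    return target


class _Fit:
    """Shared state for one refinement run."""

    def __init__(self, work: InternalModel, target: np.ndarray):
        self.work = work
        self.target = target
        self.segments = _segment_indices(work)
        self.torsion_atoms = work.torsion_atoms()
        desc = work.descendants()
        self.subtrees = [np.asarray(desc[i], dtype=int)
                         for i in self.torsion_atoms]

    def aligned(self, coords: np.ndarray) -> np.ndarray:
        out = coords.copy()
        for sel in self.segments:
            if len(sel) >= 3:
                sup = kabsch(coords[sel], self.target[sel])
                out[sel] = sup.apply(coords[sel])
        return out

    def objective(self, coords: np.ndarray) -> float:
        total, n = 0.0, 0
        for sel in self.segments:
            if len(sel) >= 3:
                r = kabsch(coords[sel], self.target[sel]).rmsd
                total += r * r * len(sel)
                n += len(sel)
        return math.sqrt(total / n) if n else 0.0

    def current(self) -> tuple[np.ndarray, float]:
        coords = self.work.rebuild_coords()
        return coords, self.objective(coords)

    def measured_reset(self, best: float) -> float:
        """Set every torsion to its dihedral measured from the deposit;
        keep the reset only if the fit improves."""
        trial = self.work.copy()
        t = self.target
        for i in self.torsion_atoms:
            gg, g, p = trial.ggp[i], trial.gp[i], trial.parent[i]
            try:
                trial.torsions[i] = measure_dihedral(t[gg], t[g], t[p], t[i])
            except ValueError:
                pass
        score = self.objective(trial.rebuild_coords())
        if score < best:
            self.work.torsions[:] = trial.torsions
            return score
        return best

    def sweep(self, coords: np.ndarray, step_cap: float) -> np.ndarray:
        """One N-to-C coordinate-descent pass; each torsion moves to its
        capped 1D optimum of the fixed-frame sum of squares."""
        coords = self.aligned(coords)
        for i, sub in zip(self.torsion_atoms, self.subtrees):
            p, g = self.work.parent[i], self.work.gp[i]
            pivot = coords[p]
            axis = pivot - coords[g]
            u = axis / np.linalg.norm(axis)
            y = coords[sub] - pivot
            z = self.target[sub] - pivot
            perp = y - (y @ u)[:, None] * u[None, :]
            b = float(np.sum(z * perp))
            c = float(np.sum(z * np.cross(u[None, :], y)))
            if math.sqrt(b * b + c * c) - b < 1e-15:
                continue
            delta = math.degrees(math.atan2(c, b))
            delta = max(-step_cap, min(step_cap, delta))
            rot = _rotation(axis, delta)
            coords[sub] = (coords[sub] - pivot) @ rot.T + pivot
            self.work.torsions[i] = wrap_angle(self.work.torsions[i] + delta)
        return coords

    def jacobian(self, coords: np.ndarray) -> np.ndarray:
        """d(position)/d(torsion in radians) in the current frame."""
        n = self.work.n_atoms
        jac = np.zeros((3 * n, len(self.torsion_atoms)))
        for col, (i, sub) in enumerate(zip(self.torsion_atoms, self.subtrees)):
            p, g = self.work.parent[i], self.work.gp[i]
            u = coords[p] - coords[g]
            u = u / np.linalg.norm(u)
            lever = np.cross(u[None, :], coords[sub] - coords[p])
            rows = (sub[:, None] * 3 + np.arange(3)[None, :]).ravel()
            jac[rows, col] = lever.ravel()
        return jac


def refine_torsions(chain: ChainModel, internal: InternalModel,
                    settings: RefinementSettings | None = None,
                    callback=None) -> RefinementResult:
    """Optimise ``internal``'s torsions so its rebuild matches ``chain``.

    Returns a :class:`RefinementResult`; the objective trace is monotone
    non-increasing and ``callback(rmsd)`` fires after every accepted step.
    """
    settings = settings or RefinementSettings()
    work = internal.copy()
    if work.n_atoms < 3 or len(work.torsion_atoms()) == 0:
        return RefinementResult(work, 0.0, 0, True, [])
    fit = _Fit(work, target_coordinates(chain, work))

    coords, best = fit.current()
    trace = [best]
    best = fit.measured_reset(best)
    if best < trace[-1]:
        coords = work.rebuild_coords()
        trace.append(best)
        if callback is not None:
            callback(best)

    lam = settings.damping_init
    sweeps = 0
    converged = False
    ta = fit.torsion_atoms
    for sweep in range(settings.max_sweeps):
        sweeps = sweep + 1
        start = best
        aligned = fit.aligned(coords)
        jac = fit.jacobian(aligned)
        jtj = jac.T @ jac
        jtr = jac.T @ (aligned - fit.target).ravel()
        diag = np.diag(jtj).copy()
        accepted = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(
                    jtj + lam * np.diag(diag + 1e-9), -jtr)
            except np.linalg.LinAlgError:
                break
            trial = work.torsions[ta] + np.degrees(delta)
            saved = work.torsions[ta].copy()
            work.torsions[ta] = wrap_angle(trial)
            cand = work.rebuild_coords()
            score = fit.objective(cand)
            if score < best - 1e-13:
                coords, best = cand, score
                lam = max(lam * 0.3, 1e-9)
                accepted = True
                if callback is not None:
                    callback(best)
                break
            work.torsions[ta] = saved
            lam *= 10.0
        if not accepted:
            # fallback: one analytic coordinate-descent sweep
            saved = work.torsions.copy()
            cand = fit.sweep(coords.copy(), settings.step_init)
            score = fit.objective(cand)
            if score < best - 1e-13:
                coords, best = cand, score
                if callback is not None:
                    callback(best)
            else:
                work.torsions[:] = saved
        trace.append(best)
        if start - best < settings.convergence_tol:
            converged = True
            break
    return RefinementResult(
        refined=work, fit_rmsd=best, sweeps_used=sweeps,
        converged=converged, trace=trace,
    )
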