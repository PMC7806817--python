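"""Pressure-driven unfolding of a folded surface mesh.

The folded epithelial sheet is modeled as a near-inextensible elastic
membrane: every mesh edge is a linear spring at its rest length, every
interior edge carries a weak hinge penalty on the deviation of its dihedral
angle from the rest dihedral, and an internal pressure performs work
``p * V`` on the enclosed volume.  Minimizing

    E(x) = sum_edges  k_s / (2 l0) (l - l0)^2
         + sum_hinges k_b (1 - cos(theta - theta0))
         - p * V(x)

by steepest descent inflates the mesh like a balloon: stored surface (the
folds and furrows) deploys while the membrane itself barely stretches, so
the unfolded shape is dictated by the folding pattern alone.

Open meshes (drumhead fixtures) must have their entire boundary loop pinned;
the enclosed volume is then taken against the implicit triangle fan closing
the pinned rim onto its centroid.  Because the rim never moves, the fan
contributes a constant to the gradient of the free vertices (namely zero).

Each descent run records a :class:`SimulationTrajectory` of position
snapshots over frozen connectivity.  Correspondence between the folded and
unfolded states is therefore exact vertex identity — a region outlined on
the inflated mesh is "rewound" simply by reading the same vertex indices in
an earlier snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import RegionMask, TriangleMesh

__all__ = [
    "MaterialParams",
    "SimulationTrajectory",
    "DivergenceError",
    "compute_energy",
    "inflate",
    "map_region",
]


class DivergenceError(RuntimeError):
    """Raised when descent cannot decrease the energy (step size too large)."""


@dataclass
class MaterialParams:
    """Material and solver constants of the unfolding simulation.

    k_stretch : edge spring stiffness (energy / length); the membrane scale.
    pressure : internal pressure (energy / length^3).  ``None`` picks the
        default nondimensional ratio ``pressure * L / k_stretch = 0.05``
        with ``L`` the mean rest edge length — strong enough to deploy the
        folds, weak enough to keep membrane strain at the few-percent level.
    k_bend : hinge stiffness (energy).  ``None`` picks
        ``1e-4 * k_stretch * mean(l0)^2``, a pure anti-crumpling regularizer.
    step_size : descent step (length^2 / energy); ``None`` picks
        ``0.2 * L * l_min / k_stretch``, then backtracking adapts it.
    max_steps : iteration cap.
    grad_tol : convergence threshold on the max per-vertex gradient norm;
        ``None`` picks ``1e-3 * pressure * L^2`` (residual forces small
        against the pressure forcing).
    pinned : vertices held exactly fixed (zero gradient rows).
    snapshot_stride : record every this-many accepted steps (first and last
        always kept).
    method : ``"lbfgs"`` (default) minimizes with a memory-limited
        quasi-Newton direction and Armijo backtracking; ``"steepest"`` is
        plain steepest descent with adaptive step.  Both are monotone in
        energy; steepest descent needs orders of magnitude more steps on
        strongly folded meshes.
    """

    k_stretch: float = 1.0
    pressure: float | None = None
    k_bend: float | None = None
    step_size: float | None = None
    max_steps: int = 200_000
    grad_tol: float | None = None
    pinned: RegionMask | None = None
    snapshot_stride: int = 100
    method: str = "lbfgs"

    def __post_init__(self) -> None:
        if self.method not in ("lbfgs", "steepest"):
            raise ValueError("method must be 'lbfgs' or 'steepest'")
        if self.k_stretch <= 0:
            raise ValueError("k_stretch must be > 0")
        if self.pressure is not None and self.pressure < 0:
            raise ValueError("pressure must be >= 0")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @classmethod
    def with_pressure_ratio(
        cls, rest_mesh: TriangleMesh, ratio: float, **kwargs
    ) -> "MaterialParams":
        """Params with ``pressure = ratio * k_stretch / L`` (L = mean rest edge).

        The nondimensional ratio is the one knob that matters physically:
        0.05 (the default) deploys bellows-like folds fully; drumhead and
        dome fixtures use 0.0125 so the membrane stays within the
        few-percent-strain regime while their furrow patches unfold.
        """
        k = kwargs.get("k_stretch", 1.0)
        e = rest_mesh.edges_unique()
        L = float(
            np.linalg.norm(
                rest_mesh.vertices[e[:, 1]] - rest_mesh.vertices[e[:, 0]], axis=1
            ).mean()
        )
        return cls(pressure=ratio * k / L, **kwargs)

    def resolved(self, rest_mesh: TriangleMesh) -> "_ResolvedParams":
        """Fill the ``None`` defaults from the rest mesh's edge-length scale."""
        e = rest_mesh.edges_unique()
        l0 = np.linalg.norm(
            rest_mesh.vertices[e[:, 1]] - rest_mesh.vertices[e[:, 0]], axis=1
        )
        L = float(l0.mean())
        pressure = self.pressure if self.pressure is not None else 0.05 * self.k_stretch / L
        k_bend = (
            self.k_bend if self.k_bend is not None else 1e-4 * self.k_stretch * L**2
        )
        step = (
            self.step_size
            if self.step_size is not None
            else 0.2 * L * float(l0.min()) / self.k_stretch
        )
        tol = (
            self.grad_tol
            if self.grad_tol is not None
            else 1e-3 * max(pressure, 1e-30) * L**2
        )
        return _ResolvedParams(
            k_stretch=self.k_stretch,
            pressure=pressure,
            k_bend=k_bend,
            step_size=step,
            max_steps=self.max_steps,
            grad_tol=tol,
            pinned=self.pinned,
            snapshot_stride=self.snapshot_stride,
            method=self.method,
        )


@dataclass
class _ResolvedParams:
    k_stretch: float
    pressure: float
    k_bend: float
    step_size: float
    max_steps: int
    grad_tol: float
    pinned: RegionMask | None
    snapshot_stride: int
    method: str


@dataclass
class SimulationTrajectory:
    """Vertex-position snapshots over descent steps, connectivity frozen."""

    steps: list[int]
    snapshots: list[np.ndarray]
    rest_mesh: TriangleMesh
    params: MaterialParams
    converged: bool
    energy_series: list[float] = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def mesh_at(self, index: int) -> TriangleMesh:
        """Mesh with the connectivity of the rest mesh and snapshot positions.

        ``index`` addresses the snapshot list (negative ok); use -1 for the
        final (inflated) state and 0 for the folded input."""
        return self.rest_mesh.with_vertices(self.snapshots[index])

    @property
    def final_mesh(self) -> TriangleMesh:
        return self.mesh_at(-1)


class _EnergyModel:
    """Precomputed connectivity + rest quantities for fast energy/gradient."""

    def __init__(self, rest_mesh: TriangleMesh, params: _ResolvedParams):
        self.mesh = rest_mesh
        self.params = params
        self.faces = rest_mesh.faces
        v0 = rest_mesh.vertices

        self.edges = rest_mesh.edges_unique()
        self.l0 = np.linalg.norm(v0[self.edges[:, 1]] - v0[self.edges[:, 0]], axis=1)
        if np.any(self.l0 <= 0):
            raise ValueError("rest mesh has zero-length edges")

        # hinges: interior edges with both flap vertices, oriented so that
        # face (i, j, k) contains directed edge i->j and face (j, i, l)
        # contains the reverse
        f = self.faces
        directed = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        flap = np.concatenate([f[:, 2], f[:, 0], f[:, 1]])
        und = np.sort(directed, axis=1)
        uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        # interior edges appear exactly twice in `und`
        interior = counts == 2
        # for each interior edge, its two directed occurrences
        occ = np.argsort(inv, kind="stable")
        first_of = np.searchsorted(inv[occ], np.arange(len(uniq)))
        hij, hkl = [], []
        for e_id in np.flatnonzero(interior):
            a, b = occ[first_of[e_id]], occ[first_of[e_id] + 1]
            i, j = directed[a]
            # the twin must be the reverse directed edge if orientation holds
            hij.append((i, j))
            if tuple(directed[b]) == (j, i):
                hkl.append((flap[a], flap[b]))
            else:
                raise ValueError("mesh orientation inconsistent; cannot build hinges")
        self.hinge_ij = np.asarray(hij, dtype=np.int64).reshape(-1, 2)
        self.hinge_kl = np.asarray(hkl, dtype=np.int64).reshape(-1, 2)

        # boundary / pinned bookkeeping
        bverts = rest_mesh.boundary_vertices()
        self.open = len(bverts) > 0
        pinned = np.zeros(rest_mesh.n_vertices, dtype=bool)
        if params.pinned is not None:
            pinned |= params.pinned.to_bool(rest_mesh.n_vertices)
        if self.open:
            if params.pressure > 0 and not pinned[bverts].all():
                raise ValueError(
                    "open mesh: the enclosed volume is undefined unless the "
                    "entire boundary loop is pinned (pinned-base convention)"
                )
            self.closure_centroid = v0[bverts].mean(axis=0)
            self.has_closure = pinned[bverts].all() if len(bverts) else True
            # directed boundary edges for the fan closure volume term
            bmask = counts[inv] == 1
            self.boundary_dir = directed[bmask]
        else:
            self.closure_centroid = None
            self.boundary_dir = None
        self.pinned_mask = pinned

        self.theta0 = self._dihedrals(v0)

    # -- pieces ------------------------------------------------------------
    def _dihedrals(self, x: np.ndarray):
        ij, kl = self.hinge_ij, self.hinge_kl
        xi, xj = x[ij[:, 0]], x[ij[:, 1]]
        xk, xl = x[kl[:, 0]], x[kl[:, 1]]
        e = xj - xi
        n1 = np.cross(xj - xi, xk - xi)
        n2 = np.cross(xi - xj, xl - xj)
        elen = np.linalg.norm(e, axis=1)
        ehat = e / elen[:, None]
        cross12 = np.cross(n1, n2)
        sin = np.einsum("ij,ij->i", cross12, ehat)
        cos = np.einsum("ij,ij->i", n1, n2)
        return np.arctan2(sin, cos)

    def volume(self, x: np.ndarray) -> float:
        f = self.faces
        vol = float(np.einsum("ij,ij->i", x[f[:, 0]], np.cross(x[f[:, 1]], x[f[:, 2]])).sum() / 6.0)
        if self.open and self.closure_centroid is not None:
            bd = self.boundary_dir
            c = self.closure_centroid
            a = x[bd[:, 1]]
            b = x[bd[:, 0]]
            vol += float(
                np.einsum("ij,ij->i", a, np.cross(b, np.broadcast_to(c, a.shape))).sum() / 6.0
            )
        return vol

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.params
        grad = np.zeros_like(x)

        # springs
        i, j = self.edges[:, 0], self.edges[:, 1]
        d = x[j] - x[i]
        l = np.linalg.norm(d, axis=1)
        stretch = l - self.l0
        e_stretch = float((p.k_stretch / (2.0 * self.l0) * stretch**2).sum())
        coef = (p.k_stretch / self.l0) * stretch / np.maximum(l, 1e-300)
        fvec = coef[:, None] * d
        np.add.at(grad, i, -fvec)
        np.add.at(grad, j, fvec)

        # hinges
        e_bend = 0.0
        if len(self.hinge_ij) and p.k_bend > 0:
            ij, kl = self.hinge_ij, self.hinge_kl
            xi, xj = x[ij[:, 0]], x[ij[:, 1]]
            xk, xl = x[kl[:, 0]], x[kl[:, 1]]
            e = xj - xi
            n1 = np.cross(xj - xi, xk - xi)
            n2 = np.cross(xi - xj, xl - xj)
            elen = np.linalg.norm(e, axis=1)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            ehat = e / elen[:, None]
            sin = np.einsum("ij,ij->i", np.cross(n1, n2), ehat)
            cos = np.einsum("ij,ij->i", n1, n2)
            theta = np.arctan2(sin, cos)
            dtheta = theta - self.theta0
            # periodic hinge penalty k_b (1 - cos dtheta): equals
            # k_b dtheta^2 / 2 for small deviations but stays smooth when a
            # crease folds through +-pi (fully closed pleats sit exactly on
            # the dihedral branch cut, where a quadratic penalty jumps)
            e_bend = float((p.k_bend * (1.0 - np.cos(dtheta))).sum())

            # analytic dihedral-angle gradients (discrete-shells hinge form)
            inv1 = elen / np.maximum(n1sq, 1e-300)
            inv2 = elen / np.maximum(n2sq, 1e-300)
            u1 = inv1[:, None] * n1
            u2 = inv2[:, None] * n2
            el2 = np.maximum(elen, 1e-300) ** 2
            a1 = np.einsum("ij,ij->i", xk - xj, e) / el2
            a2 = np.einsum("ij,ij->i", xl - xj, e) / el2
            b1 = np.einsum("ij,ij->i", xk - xi, e) / el2
            b2 = np.einsum("ij,ij->i", xl - xi, e) / el2
            gk = -u1
            gl = -u2
            gi = -(a1[:, None] * u1 + a2[:, None] * u2)
            gj = b1[:, None] * u1 + b2[:, None] * u2
            # gi + gj + gk + gl = 0 (rigid-motion invariance)
            w = (p.k_bend * np.sin(dtheta))[:, None]
            np.add.at(grad, ij[:, 0], w * gi)
            np.add.at(grad, ij[:, 1], w * gj)
            np.add.at(grad, kl[:, 0], w * gk)
            np.add.at(grad, kl[:, 1], w * gl)

        # pressure-volume work
        vol = self.volume(x)
        e_pressure = -p.pressure * vol
        if p.pressure > 0:
            f = self.faces
            a, b, c = x[f[:, 0]], x[f[:, 1]], x[f[:, 2]]
            np.add.at(grad, f[:, 0], -p.pressure / 6.0 * np.cross(b, c))
            np.add.at(grad, f[:, 1], -p.pressure / 6.0 * np.cross(c, a))
            np.add.at(grad, f[:, 2], -p.pressure / 6.0 * np.cross(a, b))
            if self.open:
                bd = self.boundary_dir
                cc = np.broadcast_to(self.closure_centroid, (len(bd), 3))
                np.add.at(grad, bd[:, 1], -p.pressure / 6.0 * np.cross(x[bd[:, 0]], cc))
                np.add.at(grad, bd[:, 0], -p.pressure / 6.0 * np.cross(cc, x[bd[:, 1]]))

        grad[self.pinned_mask] = 0.0
        return e_stretch + e_bend + e_pressure, grad


def compute_energy(
    positions: np.ndarray, rest_mesh: TriangleMesh, params: MaterialParams
) -> tuple[float, np.ndarray]:
    """Total elastic + pressure energy and its exact analytic gradient.

    Gradient rows of pinned vertices are forced to zero.  See the module
    docstring for the functional."""
    x = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
    if len(x) != rest_mesh.n_vertices:
        raise ValueError("positions length must equal rest mesh vertex count")
    model = _EnergyModel(rest_mesh, params.resolved(rest_mesh))
    return model.energy_gradient(x)


def inflate(
    rest_mesh: TriangleMesh,
    params: MaterialParams | None = None,
    verbose: bool = False,
    initial_positions: np.ndarray | None = None,
) -> SimulationTrajectory:
    """Unfold ``rest_mesh`` by monotone energy minimization.

    With ``method="lbfgs"`` (default) the search direction comes from a
    memory-limited quasi-Newton two-loop recursion; with
    ``method="steepest"`` it is the raw negative gradient with an adaptive
    step.  Either way every accepted step strictly lowers the energy
    (Armijo backtracking), so the recorded energy series is non-increasing
    by construction.  Descent stops when the largest per-vertex gradient
    norm falls below ``grad_tol`` (converged) or after ``max_steps``
    accepted steps.  ``initial_positions`` starts the descent away from
    the rest state (e.g. relaxing a perturbed configuration back onto the
    rest metric); default is the rest positions themselves.
    """
    params = params or MaterialParams()
    rp = params.resolved(rest_mesh)
    model = _EnergyModel(rest_mesh, rp)

    if initial_positions is not None:
        x = np.ascontiguousarray(initial_positions, dtype=np.float64).reshape(-1, 3).copy()
        if len(x) != rest_mesh.n_vertices:
            raise ValueError("initial_positions length must match the rest mesh")
    else:
        x = rest_mesh.vertices.copy()
    energy, grad = model.energy_gradient(x)
    steps = [0]
    snaps = [x.copy()]
    energies = [energy]
    converged = False

    # L-BFGS history (flattened); unused for steepest descent
    mem = 8
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    step = rp.step_size
    step_cap = rp.step_size * 10.0

    def direction(g: np.ndarray) -> np.ndarray:
        if rp.method == "steepest" or not s_hist:
            return -g
        q = g.ravel().copy()
        alphas = []
        for s_i, y_i in zip(reversed(s_hist), reversed(y_hist)):
            rho = 1.0 / (y_i @ s_i)
            a = rho * (s_i @ q)
            alphas.append((a, rho, s_i, y_i))
            q -= a * y_i
        s_l, y_l = s_hist[-1], y_hist[-1]
        q *= (s_l @ y_l) / (y_l @ y_l)
        for a, rho, s_i, y_i in reversed(alphas):
            b = rho * (y_i @ q)
            q += (a - b) * s_i
        return -q.reshape(g.shape)

    n_accept = 0
    while n_accept < rp.max_steps:
        gmax = float(np.sqrt((grad**2).sum(axis=1).max()))
        if gmax < rp.grad_tol:
            converged = True
            break
        d = direction(grad)
        gd = float((grad * d).sum())
        if gd >= 0.0:  # history gave an ascent direction: restart
            s_hist.clear()
            y_hist.clear()
            d = -grad
            gd = -float((grad**2).sum())
        alpha = 1.0 if (rp.method == "lbfgs" and s_hist) else step
        accepted = False
        for _ in range(60):
            x_new = x + alpha * d
            # oversized trial steps may overflow; they are simply rejected
            with np.errstate(over="ignore", invalid="ignore"):
                e_new, g_new = model.energy_gradient(x_new)
            if np.isfinite(e_new) and e_new <= energy + 1e-4 * alpha * gd:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if s_hist:  # quasi-Newton direction failed: drop history, retry
                s_hist.clear()
                y_hist.clear()
                continue
            raise DivergenceError(
                f"energy cannot decrease at step {n_accept} (E={energy:.6g}); "
                "reduce step_size"
            )
        if rp.method == "lbfgs":
            s_vec = (x_new - x).ravel()
            y_vec = (g_new - grad).ravel()
            sy = float(s_vec @ y_vec)
            if sy > 1e-12 * float(np.linalg.norm(s_vec) * np.linalg.norm(y_vec)):
                s_hist.append(s_vec)
                y_hist.append(y_vec)
                if len(s_hist) > mem:
                    s_hist.pop(0)
                    y_hist.pop(0)
        else:
            step = min(alpha * 1.2, step_cap)
        x, energy, grad = x_new, e_new, g_new
        if not np.all(np.isfinite(x)):
            raise DivergenceError("NaN positions; reduce step_size")
        n_accept += 1
        if n_accept % rp.snapshot_stride == 0:
            steps.append(n_accept)
            snaps.append(x.copy())
            energies.append(energy)
            if verbose:
                print(f"step {n_accept}: E={energy:.6g} gmax={gmax:.3g}")

    if steps[-1] != n_accept:
        steps.append(n_accept)
        snaps.append(x.copy())
        energies.append(energy)

    return SimulationTrajectory(
        steps=steps,
        snapshots=snaps,
        rest_mesh=rest_mesh,
        params=params,
        converged=converged,
        energy_series=energies,
    )


def map_region(
    trajectory: SimulationTrajectory, mask: RegionMask, at_step: int
) -> RegionMask:
    """Carry a vertex region to another snapshot ("rewind" a marked region).

    Because connectivity is frozen, the correspondence between folded and
    unfolded states is the identity on vertex indices; this returns the same
    index set (validated against the snapshot), so masks drawn on the
    inflated mesh can be exported as positions on any snapshot.
    """
    if not (-trajectory.n_snapshots <= at_step < trajectory.n_snapshots):
        raise IndexError(
            f"snapshot index {at_step} out of range ({trajectory.n_snapshots} snapshots)"
        )
    mask.to_bool(trajectory.rest_mesh.n_vertices)  # validate indices
    return RegionMask(mask.name, mask.indices.copy())
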