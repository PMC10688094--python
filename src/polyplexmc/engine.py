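"""Canonical-ensemble Metropolis Monte Carlo over the bead system.

The sampler draws from the Boltzmann distribution of the primitive-model
Hamiltonian (see :mod:`polyplexmc.energy`) at fixed composition, volume
(a hard spherical cell) and temperature.  Three kinds of trial move are
attempted, mirroring the classic polyelectrolyte MC setup:

* random displacement of a single particle (beads and counterions),
* rigid translation of an entire molecule (chain, dendrimer, conjugate),
* pivot rotations: for a linear chain, the sub-chain beyond a randomly
  chosen bond is rotated rigidly about a random axis through the pivot
  bead; for a branched molecule the full subtree beyond the bond moves.

All moves displace a subset rigidly, so the energy difference reduces to
cross-pair Coulomb terms, boundary-crossing bonds, hard-core checks and
the wall — evaluated incrementally in a compiled kernel.  An "MC step"
is one attempted elementary move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .composition import MoleculeTemplate, SystemComposition
from .energy import InteractionParams, bond_rest_lengths, total_energy

__all__ = [
    "SimulationConfig",
    "ParticleSystem",
    "SystemState",
    "MoveStats",
    "Trajectory",
    "build_system",
    "initialize_state",
    "metropolis_accept",
    "propose_move",
    "apply_move",
    "run",
    "run_replicates",
]

ROLE_CODES = {"DNA": 0, "G2": 1, "G2T": 2, "PEP": 3, "CI": 4}
ROLE_NAMES = {v: k for k, v in ROLE_CODES.items()}

MOVE_SINGLE, MOVE_MOLECULE, MOVE_PIVOT = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Run-length, move-mixture and sampling parameters.

    Step budgets follow the study conditions (2.0e6 equilibration and
    3.0e6 production attempted moves, at least six independent runs);
    ``scale`` multiplies the step budgets only, never the composition.
    Displacement amplitudes were tuned once to give roughly 30-50%
    acceptance on the free-DNA system and then frozen.
    """

    equilibration_steps: int = 2_000_000
    production_steps: int = 3_000_000
    n_replicates: int = 6
    seed: int = 0
    sample_interval: int = 1000
    move_weights: tuple[float, float, float] = (0.8, 0.1, 0.1)
    bead_max_disp: float = 2.5  # A, bonded beads
    ion_max_disp: float = 60.0  # A, free counterions
    molecule_max_disp: float = 40.0  # A, rigid molecule translation
    pivot_max_angle: float = math.pi

    def __post_init__(self):
        if self.equilibration_steps < 0 or self.production_steps < 0:
            raise ValueError("step counts must be non-negative")
        w = self.move_weights
        if len(w) != 3 or any(x < 0 for x in w) or sum(w) == 0:
            raise ValueError("move weights must be non-negative, not all zero")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")

    def scaled(self, scale: float) -> "SimulationConfig":
        """Shrink step budgets by ``scale`` (replicates left untouched)."""
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        return replace(
            self,
            equilibration_steps=max(1, int(self.equilibration_steps * scale)),
            production_steps=max(1, int(self.production_steps * scale)),
        )


@dataclass
class ParticleSystem:
    """Static description of all particles: the immutable half of a state."""

    charges: np.ndarray  # (N,) float64
    radii: np.ndarray  # (N,) float64
    roles: np.ndarray  # (N,) int8 role codes
    molecule_id: np.ndarray  # (N,) int32, -1 for counterions
    bonds: np.ndarray  # (M,2) int64
    bond_r0: np.ndarray  # (M,)
    #: (N, D) bonded neighbours whose bond rest length lies below contact;
    #: these pairs are exempt from hard-sphere exclusion (-1 padding)
    soft_nbrs: np.ndarray
    mol_slices: list[tuple[int, int]]  # bead index ranges per molecule
    labels: list[str]  # per-molecule labels

    @property
    def n_particles(self) -> int:
        return len(self.charges)

    def role_mask(self, *names: str) -> np.ndarray:
        codes = [ROLE_CODES[n] for n in names]
        return np.isin(self.roles, codes)


@dataclass
class SystemState:
    """Coordinates plus the static system description."""

    system: ParticleSystem
    coords: np.ndarray  # (N,3) float64

    def copy(self) -> "SystemState":
        return SystemState(system=self.system, coords=self.coords.copy())


@dataclass
class MoveStats:
    attempts: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    accepts: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))

    def acceptance_rates(self) -> dict[str, float]:
        names = ["single_particle", "molecule_translation", "pivot"]
        out = {}
        for k, name in enumerate(names):
            a = int(self.attempts[k])
            out[name] = float(self.accepts[k]) / a if a else float("nan")
        return out


@dataclass
class Trajectory:
    """Sampled production frames with the system description."""

    system: ParticleSystem
    frames: np.ndarray  # (F, N, 3)
    energies: np.ndarray  # (F,) total energy in kT
    cell_radius: float
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def build_system(composition: SystemComposition) -> ParticleSystem:
    """Flatten a composition into particle arrays plus the counterion bath."""
    charges: list[float] = []
    radii: list[float] = []
    roles: list[int] = []
    mol_id: list[int] = []
    bonds: list[tuple[int, int]] = []
    mol_slices: list[tuple[int, int]] = []
    labels: list[str] = []
    rests: list[float] = []
    m = 0
    for template, count in composition.members:
        t_roles = template.roles or _default_roles(template)
        t_rest = template.bond_rest or tuple(
            template.radii[a] + template.radii[b] for a, b in template.bonds
        )
        for _ in range(count):
            off = len(charges)
            charges.extend(float(z) for z in template.charges)
            radii.extend(template.radii)
            roles.extend(ROLE_CODES[r] for r in t_roles)
            mol_id.extend([m] * template.n_beads)
            bonds.extend((a + off, b + off) for a, b in template.bonds)
            rests.extend(t_rest)
            mol_slices.append((off, len(charges)))
            labels.append(template.label or template.kind)
            m += 1
    ledger = composition.counterions()
    for _ in range(ledger.n_positive):
        charges.append(1.0)
        radii.append(ledger.radius)
        roles.append(ROLE_CODES["CI"])
        mol_id.append(-1)
    for _ in range(ledger.n_negative):
        charges.append(-1.0)
        radii.append(ledger.radius)
        roles.append(ROLE_CODES["CI"])
        mol_id.append(-1)
    charges_a = np.asarray(charges, dtype=np.float64)
    radii_a = np.asarray(radii, dtype=np.float64)
    bonds_a = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    bond_r0 = np.asarray(rests, dtype=np.float64)
    return ParticleSystem(
        charges=charges_a,
        radii=radii_a,
        roles=np.asarray(roles, dtype=np.int8),
        molecule_id=np.asarray(mol_id, dtype=np.int32),
        bonds=bonds_a,
        bond_r0=bond_r0,
        soft_nbrs=soft_pair_table(len(charges_a), bonds_a, bond_r0, radii_a),
        mol_slices=mol_slices,
        labels=labels,
    )


def soft_pair_table(
    n: int, bonds: np.ndarray, bond_r0: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Neighbour table of bonded pairs exempt from hard-sphere exclusion.

    A bond whose rest length lies below the contact distance is a spring
    anchored inside the hard core; its two beads may interpenetrate and
    the spring provides the restoring force.  Second neighbours along
    such springs are likewise excluded (the usual 1-2/1-3 nonbonded
    exclusion of bead-spring models), so a sub-contact spring network is
    free to fold.  Returns an (n, D) int64 array padded with -1 (D >= 1).
    """
    soft_adj: list[set[int]] = [set() for _ in range(n)]
    for (a, b), r0 in zip(bonds, bond_r0):
        if r0 < radii[a] + radii[b] - 1e-9:
            soft_adj[int(a)].add(int(b))
            soft_adj[int(b)].add(int(a))
    lists: list[set[int]] = [set(s) for s in soft_adj]
    for i in range(n):
        for j in soft_adj[i]:
            for k in soft_adj[j]:
                if k != i:
                    lists[i].add(k)
                    lists[k].add(i)
    width = max(1, max((len(x) for x in lists), default=1))
    table = np.full((n, width), -1, dtype=np.int64)
    for i, x in enumerate(lists):
        table[i, : len(x)] = sorted(x)
    return table


def _default_roles(template: MoleculeTemplate) -> tuple[str, ...]:
    if template.kind == "DNA":
        return ("DNA",) * template.n_beads
    if template.kind == "peptide":
        return ("PEP",) * template.n_beads
    if template.kind == "G2":
        return tuple("G2T" if z else "G2" for z in template.charges)
    if template.kind == "conjugate":
        # first 57 beads are the dendrimer, the rest are tail beads
        head = ["G2T" if z else "G2" for z in template.charges[:57]]
        return tuple(head) + ("PEP",) * (template.n_beads - 57)
    raise ValueError(f"unknown template kind {template.kind!r}")


# ---------------------------------------------------------------------------
# topology helpers for pivot moves


def _adjacency(n: int, bonds: np.ndarray) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    return adj


def pivot_tables(system: ParticleSystem):
    """Precompute, for every intramolecular bond, the beads that a pivot
    about that bond displaces.

    For bond (u, v) with u closer to the molecule's first bead (the
    root), the moving set is the connected component containing v once
    the bond is removed; the pivot bead is u.  Returns flat arrays
    suitable for the compiled loop: pivot bead per candidate, moving-set
    members concatenated, and offsets.
    """
    pivots: list[int] = []
    members: list[int] = []
    offsets: list[int] = [0]
    for (lo, hi) in system.mol_slices:
        if hi - lo < 2:
            continue
        mol_bonds = system.bonds[
            (system.bonds[:, 0] >= lo) & (system.bonds[:, 0] < hi)
        ]
        adj = _adjacency(hi - lo, mol_bonds - lo)
        # BFS parents from the root bead (local index 0)
        parent = [-2] * (hi - lo)
        parent[0] = -1
        queue = [0]
        while queue:
            nxt = []
            for u in queue:
                for w in adj[u]:
                    if parent[w] == -2:
                        parent[w] = u
                        nxt.append(w)
            queue = nxt
        # subtree collection per bond (u=parent side, v=child side)
        children: list[list[int]] = [[] for _ in range(hi - lo)]
        for w in range(1, hi - lo):
            children[parent[w]].append(w)
        for a, b in mol_bonds - lo:
            u, v = (int(a), int(b)) if parent[int(b)] == int(a) else (int(b), int(a))
            stack = [v]
            sub = []
            while stack:
                x = stack.pop()
                sub.append(x)
                stack.extend(children[x])
            pivots.append(u + lo)
            members.extend(x + lo for x in sorted(sub))
            offsets.append(len(members))
    return (
        np.asarray(pivots, dtype=np.int64),
        np.asarray(members, dtype=np.int64),
        np.asarray(offsets, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# initialization


def _grow_molecule(template_bonds, radii, rng, max_restart=200):
    """Self-avoiding growth of one molecule: each bead is placed at bond
    contact distance from its parent in a random direction, rejecting
    hard-core overlaps within the molecule."""
    n = len(radii)
    adj = _adjacency(n, np.asarray(template_bonds))
    for _ in range(max_restart):
        coords = np.zeros((n, 3))
        placed = np.zeros(n, dtype=bool)
        placed[0] = True
        order: list[tuple[int, int]] = []
        queue = [0]
        seen = {0}
        while queue:
            u = queue.pop(0)
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    order.append((u, w))
                    queue.append(w)
        ok = True
        for u, w in order:
            r0 = radii[u] + radii[w]
            good = False
            for _try in range(120):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pos = coords[u] + r0 * v
                others = placed.copy()
                others[u] = False  # parent sits at exact bond contact
                d = np.linalg.norm(coords[others] - pos, axis=1)
                rsum = radii[others] + radii[w]
                if np.all(d >= rsum + 1e-7):
                    coords[w] = pos
                    placed[w] = True
                    good = True
                    break
            if not good:
                ok = False
                break
        if ok:
            return coords - coords.mean(axis=0)
    raise RuntimeError("failed to grow a self-avoiding molecule conformation")


def initialize_state(
    system: ParticleSystem,
    params: InteractionParams,
    rng: np.random.Generator,
    max_insert_tries: int = 2000,
) -> SystemState:
    """Random non-overlapping initial configuration inside the cell.

    Molecules are grown self-avoidingly, randomly rotated, and inserted
    at random positions; counterions are inserted uniformly.  Raises if
    the cell is too crowded to place everything within the retry budget.
    """
    n = system.n_particles
    coords = np.full((n, 3), np.nan)
    occupied_idx: list[int] = []
    r_cell = params.cell_radius

    def _no_overlap(pos, rad):
        if not occupied_idx:
            return True
        occ = coords[occupied_idx]
        d = np.linalg.norm(occ - pos, axis=1)
        return bool(np.all(d >= system.radii[occupied_idx] + rad + 1e-7))

    for (lo, hi) in system.mol_slices:
        local_bonds = system.bonds[
            (system.bonds[:, 0] >= lo) & (system.bonds[:, 0] < hi)
        ] - lo
        mol = _grow_molecule(local_bonds, system.radii[lo:hi], rng)
        placed = False
        for _ in range(max_insert_tries):
            # random rotation via QR of a Gaussian matrix
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            rot = mol @ q.T
            extent = np.max(np.linalg.norm(rot, axis=1))
            if extent >= r_cell:
                continue
            centre = _random_point_in_ball(rng, max(r_cell - extent, 1e-9))
            cand = rot + centre
            if all(
                _no_overlap(cand[k], system.radii[lo + k]) for k in range(hi - lo)
            ):
                coords[lo:hi] = cand
                occupied_idx.extend(range(lo, hi))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not insert molecule beads {lo}:{hi}; cell too crowded"
            )
    for i in range(n):
        if system.molecule_id[i] >= 0:
            continue
        placed = False
        for _ in range(max_insert_tries):
            pos = _random_point_in_ball(rng, r_cell)
            if _no_overlap(pos, system.radii[i]):
                coords[i] = pos
                occupied_idx.append(i)
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not insert counterion {i}; cell too crowded")
    return SystemState(system=system, coords=coords)


def _random_point_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if p @ p <= radius * radius:
            return p


# ---------------------------------------------------------------------------
# moves (Python surface used by the tests; the hot loop is compiled below)


def metropolis_accept(delta_u: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_u))."""
    if delta_u <= 0.0:
        return True
    if math.isinf(delta_u):
        return False
    return bool(rng.random() < math.exp(-delta_u))


@dataclass(frozen=True)
class Move:
    """A proposed rigid displacement of a particle subset."""

    kind: int  # MOVE_SINGLE / MOVE_MOLECULE / MOVE_PIVOT
    indices: np.ndarray
    new_pos: np.ndarray


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    kx = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]], dtype=float
    )
    return np.eye(3) + math.sin(angle) * kx + (1 - math.cos(angle)) * (kx @ kx)


def propose_move(
    state: SystemState, config: SimulationConfig, rng: np.random.Generator
) -> Move:
    """Draw one trial move from the configured mixture."""
    system = state.system
    w = np.asarray(config.move_weights, dtype=float)
    movable_mols = [s for s in system.mol_slices if s[1] - s[0] >= 2]
    piv_pivots, piv_members, piv_offsets = pivot_tables(system)
    if not movable_mols:
        w = np.array([1.0, 0.0, 0.0])
    kind = int(rng.choice(3, p=w / w.sum()))
    if kind == MOVE_SINGLE:
        i = int(rng.integers(system.n_particles))
        amp = (
            config.ion_max_disp
            if system.molecule_id[i] < 0
            else config.bead_max_disp
        )
        disp = rng.uniform(-amp, amp, size=3)
        return Move(kind, np.array([i]), state.coords[i] + disp)
    if kind == MOVE_MOLECULE:
        lo, hi = movable_mols[int(rng.integers(len(movable_mols)))]
        disp = rng.uniform(-config.molecule_max_disp, config.molecule_max_disp, 3)
        idx = np.arange(lo, hi)
        return Move(kind, idx, state.coords[lo:hi] + disp)
    p = int(rng.integers(len(piv_pivots)))
    idx = piv_members[piv_offsets[p] : piv_offsets[p + 1]]
    pivot = state.coords[piv_pivots[p]]
    axis = rng.normal(size=3)
    angle = rng.uniform(-config.pivot_max_angle, config.pivot_max_angle)
    rot = _rotation_matrix(axis, angle)
    return Move(kind, idx, (state.coords[idx] - pivot) @ rot.T + pivot)


def apply_move(state: SystemState, move: Move) -> None:
    state.coords[move.indices] = move.new_pos


# ---------------------------------------------------------------------------
# compiled main loop


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_steps(
    coords,
    charges,
    radii,
    bonds,
    bond_r0,
    soft_nbrs,
    molecule_id,
    mol_lo,
    mol_hi,
    piv_pivots,
    piv_members,
    piv_offsets,
    bjerrum,
    kappa,
    bond_k,
    cell_radius,
    w_single,
    w_mol,
    bead_max_disp,
    ion_max_disp,
    molecule_max_disp,
    pivot_max_angle,
    n_steps,
    attempts,
    accepts,
    moved_mask,
    moved_idx_buf,
    new_pos_buf,
):
    """Advance ``n_steps`` attempted moves, mutating ``coords`` in place.

    Move selection, the rigid-subset incremental energy (cross-pair
    Coulomb + hard cores + wall + boundary-crossing bonds) and the
    Metropolis test are fused into one compiled loop.  Tallies attempt
    and acceptance counts per move kind into ``attempts``/``accepts``.
    """
    n = coords.shape[0]
    n_mol = mol_lo.shape[0]
    n_piv = piv_pivots.shape[0]
    cell2 = cell_radius * cell_radius
    for _step in range(n_steps):
        u = np.random.random()
        if u < w_single or n_mol == 0:
            kind = 0
            i = np.random.randint(0, n)
            if molecule_id[i] < 0:
                amp = ion_max_disp
            else:
                amp = bead_max_disp
            m = 1
            moved_idx_buf[0] = i
            new_pos_buf[0, 0] = coords[i, 0] + (2.0 * np.random.random() - 1.0) * amp
            new_pos_buf[0, 1] = coords[i, 1] + (2.0 * np.random.random() - 1.0) * amp
            new_pos_buf[0, 2] = coords[i, 2] + (2.0 * np.random.random() - 1.0) * amp
        elif u < w_single + w_mol or n_piv == 0:
            kind = 1
            mi = np.random.randint(0, n_mol)
            lo = mol_lo[mi]
            m = mol_hi[mi] - lo
            dx = (2.0 * np.random.random() - 1.0) * molecule_max_disp
            dy = (2.0 * np.random.random() - 1.0) * molecule_max_disp
            dz = (2.0 * np.random.random() - 1.0) * molecule_max_disp
            for a in range(m):
                moved_idx_buf[a] = lo + a
                new_pos_buf[a, 0] = coords[lo + a, 0] + dx
                new_pos_buf[a, 1] = coords[lo + a, 1] + dy
                new_pos_buf[a, 2] = coords[lo + a, 2] + dz
        else:
            kind = 2
            p = np.random.randint(0, n_piv)
            off0 = piv_offsets[p]
            m = piv_offsets[p + 1] - off0
            px = coords[piv_pivots[p], 0]
            py = coords[piv_pivots[p], 1]
            pz = coords[piv_pivots[p], 2]
            ax = np.random.normal()
            ay = np.random.normal()
            az = np.random.normal()
            an = math.sqrt(ax * ax + ay * ay + az * az)
            if an == 0.0:
                ax, ay, az, an = 1.0, 0.0, 0.0, 1.0
            ax /= an
            ay /= an
            az /= an
            th = (2.0 * np.random.random() - 1.0) * pivot_max_angle
            c = math.cos(th)
            s = math.sin(th)
            for a in range(m):
                j = piv_members[off0 + a]
                moved_idx_buf[a] = j
                vx = coords[j, 0] - px
                vy = coords[j, 1] - py
                vz = coords[j, 2] - pz
                dot = ax * vx + ay * vy + az * vz
                cx = ay * vz - az * vy
                cy = az * vx - ax * vz
                cz = ax * vy - ay * vx
                new_pos_buf[a, 0] = px + vx * c + cx * s + ax * dot * (1.0 - c)
                new_pos_buf[a, 1] = py + vy * c + cy * s + ay * dot * (1.0 - c)
                new_pos_buf[a, 2] = pz + vz * c + cz * s + az * dot * (1.0 - c)
        attempts[kind] += 1
        for a in range(m):
            moved_mask[moved_idx_buf[a]] = True

        delta = 0.0
        reject = False
        for a in range(m):
            x = new_pos_buf[a, 0]
            y = new_pos_buf[a, 1]
            z = new_pos_buf[a, 2]
            if x * x + y * y + z * z > cell2:
                reject = True
                break
        if not reject:
            for a in range(m):
                i = moved_idx_buf[a]
                xo = coords[i, 0]
                yo = coords[i, 1]
                zo = coords[i, 2]
                xn = new_pos_buf[a, 0]
                yn = new_pos_buf[a, 1]
                zn = new_pos_buf[a, 2]
                qi = charges[i]
                ri = radii[i]
                for j in range(n):
                    if moved_mask[j]:
                        continue
                    dxn = xn - coords[j, 0]
                    dyn = yn - coords[j, 1]
                    dzn = zn - coords[j, 2]
                    rn2 = dxn * dxn + dyn * dyn + dzn * dzn
                    rr = (ri + radii[j]) * (1.0 - 1e-12)
                    if rn2 < rr * rr:
                        soft = False
                        for t in range(soft_nbrs.shape[1]):
                            if soft_nbrs[i, t] == j:
                                soft = True
                                break
                        if not soft:
                            reject = True
                            break
                    qq = qi * charges[j]
                    if qq != 0.0:
                        dxo = xo - coords[j, 0]
                        dyo = yo - coords[j, 1]
                        dzo = zo - coords[j, 2]
                        ro = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
                        rn = math.sqrt(rn2)
                        if kappa > 0.0:
                            delta += bjerrum * qq * (
                                math.exp(-kappa * rn) / rn
                                - math.exp(-kappa * ro) / ro
                            )
                        else:
                            delta += bjerrum * qq * (1.0 / rn - 1.0 / ro)
                if reject:
                    break
        if not reject:
            for b in range(bonds.shape[0]):
                bi = bonds[b, 0]
                bj = bonds[b, 1]
                if moved_mask[bi] == moved_mask[bj]:
                    continue
                if moved_mask[bi]:
                    k_moved = bi
                    other = bj
                else:
                    k_moved = bj
                    other = bi
                slot = -1
                for a in range(m):
                    if moved_idx_buf[a] == k_moved:
                        slot = a
                        break
                dxn = new_pos_buf[slot, 0] - coords[other, 0]
                dyn = new_pos_buf[slot, 1] - coords[other, 1]
                dzn = new_pos_buf[slot, 2] - coords[other, 2]
                rn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
                dxo = coords[k_moved, 0] - coords[other, 0]
                dyo = coords[k_moved, 1] - coords[other, 1]
                dzo = coords[k_moved, 2] - coords[other, 2]
                ro = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
                r0 = bond_r0[b]
                delta += 0.5 * bond_k * ((rn - r0) ** 2 - (ro - r0) ** 2)

        accept = False
        if not reject:
            if delta <= 0.0:
                accept = True
            elif np.random.random() < math.exp(-delta):
                accept = True
        if accept:
            accepts[kind] += 1
            for a in range(m):
                i = moved_idx_buf[a]
                coords[i, 0] = new_pos_buf[a, 0]
                coords[i, 1] = new_pos_buf[a, 1]
                coords[i, 2] = new_pos_buf[a, 2]
        for a in range(m):
            moved_mask[moved_idx_buf[a]] = False


class _CompiledLoop:
    """Binds a ParticleSystem + parameters to the compiled step kernel."""

    def __init__(self, system: ParticleSystem, params: InteractionParams,
                 config: SimulationConfig):
        self.system = system
        self.params = params
        self.config = config
        multi = [(lo, hi) for lo, hi in system.mol_slices if hi - lo >= 2]
        self.mol_lo = np.asarray([lo for lo, _ in multi], dtype=np.int64)
        self.mol_hi = np.asarray([hi for _, hi in multi], dtype=np.int64)
        self.piv_pivots, self.piv_members, self.piv_offsets = pivot_tables(system)
        w = np.asarray(config.move_weights, dtype=float)
        w = w / w.sum()
        self.w_single, self.w_mol = float(w[0]), float(w[1])
        n = system.n_particles
        max_moved = max(
            [1]
            + [hi - lo for lo, hi in multi]
            + list(np.diff(self.piv_offsets))
        )
        self.moved_mask = np.zeros(n, dtype=np.bool_)
        self.moved_idx_buf = np.zeros(int(max_moved), dtype=np.int64)
        self.new_pos_buf = np.zeros((int(max_moved), 3), dtype=np.float64)
        self.stats = MoveStats()

    def advance(self, coords: np.ndarray, n_steps: int) -> None:
        _run_steps(
            coords,
            self.system.charges,
            self.system.radii,
            self.system.bonds,
            self.system.bond_r0,
            self.system.soft_nbrs,
            self.system.molecule_id,
            self.mol_lo,
            self.mol_hi,
            self.piv_pivots,
            self.piv_members,
            self.piv_offsets,
            self.params.bjerrum_length,
            self.params.kappa,
            self.params.bond_k,
            self.params.cell_radius,
            self.w_single,
            self.w_mol,
            self.config.bead_max_disp,
            self.config.ion_max_disp,
            self.config.molecule_max_disp,
            self.config.pivot_max_angle,
            n_steps,
            self.stats.attempts,
            self.stats.accepts,
            self.moved_mask,
            self.moved_idx_buf,
            self.new_pos_buf,
        )


def run(
    composition: SystemComposition,
    config: SimulationConfig,
    params: InteractionParams | None = None,
    seed: int | None = None,
) -> tuple[Trajectory, MoveStats]:
    """Equilibrate and sample one replicate; fully seeded and reproducible.

    Returns the production trajectory (frames every
    ``config.sample_interval`` attempted moves) and the move statistics.
    With ``production_steps == 0`` the trajectory holds only the
    post-equilibration frame.
    """
    if params is None:
        params = InteractionParams()
    if seed is None:
        seed = config.seed
    system = build_system(composition)
    rng = np.random.default_rng(seed)
    state = initialize_state(system, params, rng)
    _seed_numba(int(rng.integers(2**31 - 1)))
    loop = _CompiledLoop(system, params, config)
    loop.advance(state.coords, int(config.equilibration_steps))
    n_frames = config.production_steps // config.sample_interval
    frames = np.empty((max(n_frames, 0) + 1, system.n_particles, 3))
    energies = np.empty(max(n_frames, 0) + 1)
    frames[0] = state.coords
    energies[0] = total_energy(
        state.coords, system.charges, system.radii, system.bonds, params,
        system.bond_r0,
    ).total
    for f in range(n_frames):
        loop.advance(state.coords, int(config.sample_interval))
        frames[f + 1] = state.coords
        energies[f + 1] = total_energy(
            state.coords, system.charges, system.radii, system.bonds, params,
            system.bond_r0,
        ).total
    traj = Trajectory(
        system=system,
        frames=frames,
        energies=energies,
        cell_radius=params.cell_radius,
        seed=seed,
    )
    return traj, loop.stats


def run_replicates(
    composition: SystemComposition,
    config: SimulationConfig,
    params: InteractionParams | None = None,
) -> list[tuple[Trajectory, MoveStats]]:
    """Run ``config.n_replicates`` independent replicates.

    Replicate ``k`` uses seed ``config.seed + k`` so the ensemble is
    reproducible from a single base seed.
    """
    return [
        run(composition, config, params, seed=config.seed + k)
        for k in range(config.n_replicates)
    ]


@njit(cache=True)
def _saw_pivot_chain(coords, sigma, burn, thin, out, seed):
    """Pivot-only sampling of an uncharged tangent hard-sphere chain.

    Pivots preserve all bond lengths, so with charges off the move is
    accepted iff it creates no hard-core overlap.  Records a frame into
    ``out`` every ``thin`` attempted pivots after ``burn`` attempts.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    n_samples = out.shape[0]
    sig2 = sigma * sigma * (1.0 - 1e-12)
    total = burn + thin * n_samples
    rec = 0
    for step in range(total):
        p = np.random.randint(0, n - 1)  # rotate beads p+1 .. n-1 about bead p
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        an = math.sqrt(ax * ax + ay * ay + az * az)
        if an == 0.0:
            ax, ay, az, an = 1.0, 0.0, 0.0, 1.0
        ax /= an
        ay /= an
        az /= an
        th = (2.0 * np.random.random() - 1.0) * math.pi
        c = math.cos(th)
        s = math.sin(th)
        px = coords[p, 0]
        py = coords[p, 1]
        pz = coords[p, 2]
        ok = True
        # rotate into a scratch region at the end of out while checking
        for i in range(p + 1, n):
            vx = coords[i, 0] - px
            vy = coords[i, 1] - py
            vz = coords[i, 2] - pz
            dot = ax * vx + ay * vy + az * vz
            cx = ay * vz - az * vy
            cy = az * vx - ax * vz
            cz = ax * vy - ay * vx
            nx = px + vx * c + cx * s + ax * dot * (1.0 - c)
            ny = py + vy * c + cy * s + ay * dot * (1.0 - c)
            nz = pz + vz * c + cz * s + az * dot * (1.0 - c)
            # check the rotated bead against the fixed segment 0..p
            for j in range(0, p + 1):
                if j == i - 1:
                    continue  # the (p, p+1) bond stays at exact contact
                dx = nx - coords[j, 0]
                dy = ny - coords[j, 1]
                dz = nz - coords[j, 2]
                if dx * dx + dy * dy + dz * dz < sig2:
                    ok = False
                    break
            if not ok:
                break
            coords[i, 0] = nx
            coords[i, 1] = ny
            coords[i, 2] = nz
        if not ok:
            # roll back: rotate the already-moved beads (p+1 .. i-1, bead
            # i itself was never written) by the inverse rotation
            for i2 in range(p + 1, i):
                vx = coords[i2, 0] - px
                vy = coords[i2, 1] - py
                vz = coords[i2, 2] - pz
                dot = ax * vx + ay * vy + az * vz
                cx = ay * vz - az * vy
                cy = az * vx - ax * vz
                cz = ax * vy - ay * vx
                coords[i2, 0] = px + vx * c - cx * s + ax * dot * (1.0 - c)
                coords[i2, 1] = py + vy * c - cy * s + ay * dot * (1.0 - c)
                coords[i2, 2] = pz + vz * c - cz * s + az * dot * (1.0 - c)
        if step >= burn and (step - burn) % thin == thin - 1 and rec < n_samples:
            for i in range(n):
                out[rec, i, 0] = coords[i, 0]
                out[rec, i, 1] = coords[i, 1]
                out[rec, i, 2] = coords[i, 2]
            rec += 1
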