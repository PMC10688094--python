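"""Potential energy of the primitive-model bead system.

The Hamiltonian has four contributions, all evaluated in units of kT:

* hard-sphere exclusion between every particle pair (infinite on overlap),
* Coulomb, ``u_ij = lB * z_i * z_j * exp(-r_ij/lD) / r_ij`` with the
  Bjerrum length ``lB`` (7.14 A for water at 298 K, eps_r = 78.4) and an
  optional Debye length ``lD`` (bare unscreened 1/r by default),
* harmonic bonds, ``1/2 k (r - r0)^2``, with ``r0`` defaulting to the sum
  of the bonded bead radii,
* a hard spherical wall confining every bead centre to the cell radius.

The system is finite and non-periodic (one cell, explicit counterions),
so the Coulomb sum is exact — no cutoff or Ewald machinery is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "InteractionParams",
    "EnergyBreakdown",
    "bjerrum_length_water",
    "pair_energy",
    "total_energy",
    "delta_energy_rigid_subset",
]

_KB = 1.380649e-23  # J/K
_E_CHARGE = 1.602176634e-19  # C
_EPS0 = 8.8541878128e-12  # F/m


def bjerrum_length_water(temperature: float = 298.0, eps_r: float = 78.4) -> float:
    """Bjerrum length in Angstrom for a uniform dielectric."""
    lb_m = _E_CHARGE**2 / (4 * math.pi * _EPS0 * eps_r * _KB * temperature)
    return lb_m * 1e10


# 0.4 N/m expressed in kT/A^2 at 298 K: 0.4e-20 J/A^2 / kB T.
DEFAULT_BOND_K = 0.4e-20 / (_KB * 298.0)


@dataclass(frozen=True)
class InteractionParams:
    """Interaction parameters, lengths in Angstrom, energies in kT.

    Attributes
    ----------
    bjerrum_length : float
        Coulomb coupling; 7.14 A corresponds to water at 298 K.
    screening_length : float or None
        Debye screening length in A; ``None`` means bare (unscreened)
        1/r Coulomb.  A finite value multiplies each pair term by
        exp(-r / screening_length), the Debye-Hueckel form for the
        diffuse salt of a buffered solution.
    bond_k : float
        Harmonic bond force constant in kT/A^2.
    cell_radius : float
        Radius of the hard spherical confinement cell.
    temperature : float
        Informational (energies are already reduced by kT).
    """

    bjerrum_length: float = 7.14
    screening_length: float | None = None
    bond_k: float = DEFAULT_BOND_K
    cell_radius: float = 1200.0
    temperature: float = 298.0

    @property
    def kappa(self) -> float:
        """Inverse screening length in 1/A (0 for bare Coulomb)."""
        return 0.0 if self.screening_length is None else 1.0 / self.screening_length

    def __post_init__(self):
        if self.bjerrum_length <= 0:
            raise ValueError("bjerrum_length must be positive")
        if self.screening_length is not None and self.screening_length <= 0:
            raise ValueError("screening_length must be positive or None")
        if self.bond_k <= 0:
            raise ValueError("bond_k must be positive")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components in kT; ``overlap`` marks a hard-core/wall violation."""

    coulomb: float
    bond: float
    overlap: bool

    @property
    def total(self) -> float:
        return math.inf if self.overlap else self.coulomb + self.bond


def _soft_table(n, bonds, bond_r0, radii):
    """Bonded pairs with sub-contact rest lengths, as a padded table."""
    from .engine import soft_pair_table

    return soft_pair_table(n, bonds, np.asarray(bond_r0, dtype=float),
                           np.asarray(radii, dtype=float))


def bond_rest_lengths(radii: np.ndarray, bonds: np.ndarray) -> np.ndarray:
    """Default equilibrium lengths: contact distance of the bonded beads."""
    if len(bonds) == 0:
        return np.zeros(0)
    return radii[bonds[:, 0]] + radii[bonds[:, 1]]


def pair_energy(
    i: int,
    j: int,
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    params: InteractionParams,
    bond_r0: float | None = None,
) -> float:
    """Energy of one particle pair in kT (+inf on hard-core overlap).

    ``bond_r0`` marks the pair as bonded with the given rest length,
    adding the harmonic term.
    """
    if i == j:
        raise ValueError("pair requires two distinct particles")
    r = float(np.linalg.norm(coords[i] - coords[j]))
    contact = radii[i] + radii[j]
    # tiny relative slack so exact tangent contact does not register as
    # overlap; a bond resting below contact waives the hard core entirely
    hard = bond_r0 is None or bond_r0 >= contact - 1e-9
    if hard and r < contact * (1.0 - 1e-12):
        return math.inf
    u = params.bjerrum_length * charges[i] * charges[j] / r
    if params.screening_length is not None:
        u *= math.exp(-r / params.screening_length)
    if bond_r0 is not None:
        u += 0.5 * params.bond_k * (r - bond_r0) ** 2
    return u


@njit(cache=True)
def _total_energy_kernel(coords, charges, radii, bonds, bond_r0, soft_nbrs,
                         bjerrum, kappa, bond_k, cell_radius):
    n = coords.shape[0]
    coulomb = 0.0
    overlap = 0
    for i in range(n):
        ri = coords[i]
        if ri[0] * ri[0] + ri[1] * ri[1] + ri[2] * ri[2] > cell_radius * cell_radius:
            overlap = 1
        for j in range(i + 1, n):
            dx = ri[0] - coords[j, 0]
            dy = ri[1] - coords[j, 1]
            dz = ri[2] - coords[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < (radii[i] + radii[j]) * (1.0 - 1e-12):
                soft = False
                for t in range(soft_nbrs.shape[1]):
                    if soft_nbrs[i, t] == j:
                        soft = True
                        break
                if not soft:
                    overlap = 1
            if r > 0.0:
                u = bjerrum * charges[i] * charges[j] / r
                if kappa > 0.0:
                    u *= math.exp(-kappa * r)
                coulomb += u
            else:
                overlap = 1
    bond = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        bond += 0.5 * bond_k * (r - bond_r0[b]) ** 2
    return coulomb, bond, overlap


def total_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    bonds: np.ndarray,
    params: InteractionParams,
    bond_r0: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Exact pairwise total energy of a configuration."""
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    if bond_r0 is None:
        bond_r0 = bond_rest_lengths(radii, bonds)
    coulomb, bond, overlap = _total_energy_kernel(
        np.ascontiguousarray(coords, dtype=np.float64),
        np.ascontiguousarray(charges, dtype=np.float64),
        np.ascontiguousarray(radii, dtype=np.float64),
        bonds,
        np.ascontiguousarray(bond_r0, dtype=np.float64),
        _soft_table(len(coords), bonds, bond_r0, radii),
        params.bjerrum_length,
        params.kappa,
        params.bond_k,
        params.cell_radius,
    )
    return EnergyBreakdown(coulomb=coulomb, bond=bond, overlap=bool(overlap))


@njit(cache=True)
def _delta_energy_kernel(coords, charges, radii, moved_idx, new_pos, moved_mask,
                         bonds, bond_r0, soft_nbrs, bjerrum, kappa, bond_k,
                         cell_radius):
    """Energy change for a rigid displacement of the ``moved_idx`` subset.

    Intra-subset distances are assumed unchanged (all moves are rigid on
    the moved set), so only cross pairs and boundary-crossing bonds
    contribute.  Returns +inf on any overlap or wall violation.
    """
    n = coords.shape[0]
    m = moved_idx.shape[0]
    cell2 = cell_radius * cell_radius
    for a in range(m):
        x = new_pos[a, 0]
        y = new_pos[a, 1]
        z = new_pos[a, 2]
        if x * x + y * y + z * z > cell2:
            return math.inf
    delta = 0.0
    for a in range(m):
        i = moved_idx[a]
        xo = coords[i, 0]
        yo = coords[i, 1]
        zo = coords[i, 2]
        xn = new_pos[a, 0]
        yn = new_pos[a, 1]
        zn = new_pos[a, 2]
        qi = charges[i]
        for j in range(n):
            if moved_mask[j]:
                continue
            dxn = xn - coords[j, 0]
            dyn = yn - coords[j, 1]
            dzn = zn - coords[j, 2]
            rn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
            if rn < (radii[i] + radii[j]) * (1.0 - 1e-12):
                soft = False
                for t in range(soft_nbrs.shape[1]):
                    if soft_nbrs[i, t] == j:
                        soft = True
                        break
                if not soft:
                    return math.inf
            dxo = xo - coords[j, 0]
            dyo = yo - coords[j, 1]
            dzo = zo - coords[j, 2]
            ro = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
            qq = qi * charges[j]
            if qq != 0.0:
                if kappa > 0.0:
                    delta += bjerrum * qq * (
                        math.exp(-kappa * rn) / rn - math.exp(-kappa * ro) / ro
                    )
                else:
                    delta += bjerrum * qq * (1.0 / rn - 1.0 / ro)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        mi = moved_mask[i]
        mj = moved_mask[j]
        if mi == mj:
            continue  # both fixed, or both moved rigidly
        # locate the moved endpoint's new position
        if mi:
            k = i
            other = j
        else:
            k = j
            other = i
        a = -1
        for t in range(m):
            if moved_idx[t] == k:
                a = t
                break
        dxn = new_pos[a, 0] - coords[other, 0]
        dyn = new_pos[a, 1] - coords[other, 1]
        dzn = new_pos[a, 2] - coords[other, 2]
        rn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
        dxo = coords[k, 0] - coords[other, 0]
        dyo = coords[k, 1] - coords[other, 1]
        dzo = coords[k, 2] - coords[other, 2]
        ro = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
        r0 = bond_r0[b]
        delta += 0.5 * bond_k * ((rn - r0) ** 2 - (ro - r0) ** 2)
    return delta


def delta_energy_rigid_subset(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    moved_idx: np.ndarray,
    new_pos: np.ndarray,
    bonds: np.ndarray,
    params: InteractionParams,
    bond_r0: np.ndarray | None = None,
) -> float:
    """Energy change (kT) when ``moved_idx`` move rigidly to ``new_pos``.

    Python-facing wrapper around the incremental kernel used by the MC
    engine; valid for any move that preserves distances within the moved
    subset (single-particle, whole-molecule and pivot moves all do).
    """
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    if bond_r0 is None:
        bond_r0 = bond_rest_lengths(radii, bonds)
    moved_idx = np.atleast_1d(np.asarray(moved_idx, dtype=np.int64))
    new_pos = np.asarray(new_pos, dtype=np.float64).reshape(len(moved_idx), 3)
    mask = np.zeros(len(coords), dtype=np.bool_)
    mask[moved_idx] = True
    return _delta_energy_kernel(
        np.ascontiguousarray(coords, dtype=np.float64),
        np.ascontiguousarray(charges, dtype=np.float64),
        np.ascontiguousarray(radii, dtype=np.float64),
        moved_idx,
        np.ascontiguousarray(new_pos, dtype=np.float64),
        mask,
        bonds,
        np.ascontiguousarray(bond_r0, dtype=np.float64),
        _soft_table(len(coords), bonds, bond_r0, radii),
        params.bjerrum_length,
        params.kappa,
        params.bond_k,
        params.cell_radius,
    )
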