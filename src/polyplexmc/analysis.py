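"""Conformational observables computed from trajectories.

Implements the shape statistics used to characterise polyplex
morphology:

* radius of gyration, ``Rg = sqrt((1/N) sum_i |r_i - r_CM|^2)``;
* asphericity from the sorted eigenvalues ``L1^2 <= L2^2 <= L3^2`` of
  the (unit-mass) gyration tensor,

      A = [(L1^2-L2^2)^2 + (L2^2-L3^2)^2 + (L3^2-L1^2)^2]
          / [2 (L1^2+L2^2+L3^2)^2],

  which is 0 for spherically symmetric clouds, exactly 1/4 for a thin
  ring (toroid) and 1 for a straight rod;
* radial distribution functions and the dendrimer diameter as twice the
  centre-to-terminal g(r) peak position;
* contact profiles: the time-averaged number of vector beads within a
  20 A centre-to-centre cutoff of each DNA monomer;
* condensation curves: root-mean-square Rg of the DNA versus charge
  ratio, normalised by the free-DNA value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .engine import Trajectory

__all__ = [
    "radius_of_gyration",
    "gyration_eigenvalues",
    "asphericity",
    "asphericity_invariants",
    "trajectory_rg",
    "trajectory_asphericity",
    "rms_rg",
    "GyrationResult",
    "AsphericityResult",
    "rdf",
    "modal_distance",
    "dendrimer_diameter",
    "ContactProfile",
    "contact_profile",
    "condensation_curve",
    "asphericity_density",
]

CONTACT_CUTOFF = 20.0  # A, centre-to-centre


def radius_of_gyration(coords: np.ndarray, selection: np.ndarray | None = None) -> float:
    """Unweighted Rg of the selected beads of one frame, in Angstrom."""
    x = _select(coords, selection)
    rcm = x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((x - rcm) ** 2, axis=1))))


def gyration_eigenvalues(coords: np.ndarray, selection: np.ndarray | None = None) -> np.ndarray:
    """Sorted eigenvalues (ascending) of the gyration tensor, A^2 units."""
    x = _select(coords, selection)
    x = x - x.mean(axis=0)
    tensor = (x.T @ x) / len(x)
    return np.sort(np.linalg.eigvalsh(tensor))


def asphericity(coords: np.ndarray, selection: np.ndarray | None = None) -> float:
    """Shape anisotropy A in [0, 1] of one frame.

    Raises for a degenerate selection (all beads coincident), where the
    eigenvalue sum vanishes and A is undefined.
    """
    l1, l2, l3 = gyration_eigenvalues(coords, selection)
    s = l1 + l2 + l3
    if s <= 0:
        raise ValueError("all beads coincide; asphericity is undefined")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    return float(num / (2.0 * s * s))


def _select(coords: np.ndarray, selection: np.ndarray | None) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if selection is None:
        x = coords
    else:
        x = coords[np.asarray(selection)]
    if len(x) == 0:
        raise ValueError("empty selection")
    return x


@dataclass
class GyrationResult:
    """Per-frame Rg plus the ensemble root-mean-square summary."""

    per_frame: np.ndarray

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.per_frame**2)))

    def normalized(self, reference_rms: float) -> float:
        if reference_rms <= 0:
            raise ValueError("reference rms Rg must be positive")
        return self.rms / reference_rms


def asphericity_invariants(coords: np.ndarray, selection: np.ndarray | None = None):
    """Numerator and (doubled squared-trace) denominator of A for one frame."""
    l1, l2, l3 = gyration_eigenvalues(coords, selection)
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = 2.0 * (l1 + l2 + l3) ** 2
    return float(num), float(den)


@dataclass
class AsphericityResult:
    """Asphericity summaries of an ensemble.

    ``per_frame`` holds the per-configuration shape ratio used to
    classify morphologies (rodlike above 0.6, toroidlike 0.15-0.25).
    Mean asphericities — per replicate and pooled — are the ratio of
    the ensemble-averaged invariants, <num>/<den>, the convention under
    which an ideal chain gives exactly 10/19 and long self-avoiding
    chains ~0.53; per-frame ratios average systematically lower because
    the denominator fluctuates with the instantaneous size.
    """

    per_frame: np.ndarray
    replicate_means: np.ndarray
    _num_sum: float = 0.0
    _den_sum: float = 0.0

    @property
    def pooled_mean(self) -> float:
        if self._den_sum > 0:
            return self._num_sum / self._den_sum
        return float(np.mean(self.per_frame))


def trajectory_rg(traj: Trajectory, selection: np.ndarray | None = None) -> GyrationResult:
    if selection is None:
        selection = traj.system.role_mask("DNA")
    vals = np.array([radius_of_gyration(f, selection) for f in traj.frames])
    return GyrationResult(per_frame=vals)


def trajectory_asphericity(
    trajectories: Trajectory | list[Trajectory],
    selection: np.ndarray | None = None,
) -> AsphericityResult:
    """Per-frame A pooled over one or more replicate trajectories."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    frames_a: list[np.ndarray] = []
    means: list[float] = []
    num_tot = den_tot = 0.0
    for traj in trajectories:
        sel = traj.system.role_mask("DNA") if selection is None else selection
        pairs = [asphericity_invariants(f, sel) for f in traj.frames]
        frames_a.append(np.array([n / d for n, d in pairs]))
        num = sum(n for n, _ in pairs)
        den = sum(d for _, d in pairs)
        means.append(num / den)
        num_tot += num
        den_tot += den
    return AsphericityResult(
        per_frame=np.concatenate(frames_a),
        replicate_means=np.array(means),
        _num_sum=num_tot,
        _den_sum=den_tot,
    )


def rms_rg(trajectories: list[Trajectory], selection: np.ndarray | None = None) -> float:
    """Root-mean-square Rg over all frames of all replicates."""
    sq = []
    for traj in trajectories:
        sel = traj.system.role_mask("DNA") if selection is None else selection
        sq.extend(radius_of_gyration(f, sel) ** 2 for f in traj.frames)
    return float(np.sqrt(np.mean(sq)))


def rdf(
    frames: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    bin_width: float = 0.5,
    r_max: float | None = None,
    volume: float | None = None,
) -> pd.DataFrame:
    """Distance histogram between two bead groups, shell-volume normalised.

    Returns a DataFrame with bin centres ``r``, mean pair counts per
    frame ``counts`` and the shell-normalised profile ``g``.  With
    ``volume`` given, ``g`` is normalised by the ideal-gas pair density
    ``n_pairs / volume`` (so a uniform gas reads ~1 well away from the
    container boundary); otherwise ``g`` is scaled to unit mean over the
    occupied bins, which leaves the modal distance unaffected.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise ValueError("rdf needs at least one frame")
    ia = np.atleast_1d(np.asarray(group_a))
    ib = np.atleast_1d(np.asarray(group_b))
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("rdf groups must be non-empty")
    same_group = np.array_equal(ia, ib)
    n_pairs = len(ia) * (len(ia) - 1) // 2 if same_group else len(ia) * len(ib)
    dists = []
    for f in frames:
        d = np.linalg.norm(f[ia][:, None, :] - f[ib][None, :, :], axis=-1)
        if same_group:
            iu = np.triu_indices(len(ia), k=1)
            d = d[iu]
        dists.append(np.ravel(d))
    alld = np.concatenate(dists)
    alld = alld[alld > 0]
    if r_max is None:
        r_max = float(alld.max()) + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, edges = np.histogram(alld, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    dens = counts / shell / len(frames)
    if volume is not None:
        g = dens / (n_pairs / volume)
    else:
        occ = dens > 0
        g = dens / dens[occ].mean() if occ.any() else dens
    return pd.DataFrame({"r": centers, "counts": counts / len(frames), "g": g})


def modal_distance(profile: pd.DataFrame, by: str = "counts") -> float:
    """Bin centre of the most populated bin."""
    return float(profile["r"].iloc[int(np.argmax(profile[by].to_numpy()))])


def dendrimer_diameter(traj: Trajectory, bin_width: float = 0.5) -> float:
    """Dendrimer size from the centre-to-terminal RDF.

    Twice the position of the maximum of the shell-normalised radial
    distribution function g(r) between each dendrimer's central bead
    and the charged terminal beads — the terminals trace the molecular
    envelope, so the peak sits at the most probable envelope radius.
    """
    system = traj.system
    term = np.flatnonzero(system.role_mask("G2T"))
    centers = []
    for (lo, hi), label in zip(system.mol_slices, system.labels):
        if label == "G2" or label.startswith("G2+"):
            centers.append(lo)
    if not centers or len(term) == 0:
        raise ValueError("no dendrimer present in this trajectory")
    prof = rdf(traj.frames, np.asarray(centers), term, bin_width=bin_width)
    return 2.0 * modal_distance(prof, by="g")


@dataclass
class ContactProfile:
    """Per-DNA-monomer mean neighbour counts within the contact cutoff."""

    g2_terminals: np.ndarray  # <N_mon> of dendrimer end groups
    tail_beads: np.ndarray  # <N_mon> of peptide beads
    cutoff: float = CONTACT_CUTOFF

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dna_monomer": np.arange(len(self.g2_terminals)),
                "g2_end_groups": self.g2_terminals,
                "tail_beads": self.tail_beads,
            }
        )


def contact_profile(traj: Trajectory, cutoff: float = CONTACT_CUTOFF) -> ContactProfile:
    """Time-averaged counts of G2 end groups and tail beads near each
    DNA monomer (centre-to-centre distance below ``cutoff``)."""
    system = traj.system
    dna = np.flatnonzero(system.role_mask("DNA"))
    if len(dna) == 0:
        raise ValueError("composition contains no DNA")
    term = np.flatnonzero(system.role_mask("G2T"))
    tails = np.flatnonzero(system.role_mask("PEP"))
    n_frames = len(traj.frames)
    acc_t = np.zeros(len(dna))
    acc_p = np.zeros(len(dna))
    for f in traj.frames:
        if len(term):
            d = np.linalg.norm(f[dna][:, None, :] - f[term][None, :, :], axis=-1)
            acc_t += (d < cutoff).sum(axis=1)
        if len(tails):
            d = np.linalg.norm(f[dna][:, None, :] - f[tails][None, :, :], axis=-1)
            acc_p += (d < cutoff).sum(axis=1)
    return ContactProfile(
        g2_terminals=acc_t / n_frames, tail_beads=acc_p / n_frames, cutoff=cutoff
    )


def condensation_curve(
    groups: dict[float, list[Trajectory]],
    reference_r_charge: float = 0.0,
) -> pd.DataFrame:
    """Normalised rms Rg of the DNA versus charge ratio.

    ``groups`` maps r_charge to replicate trajectories; the group at
    ``reference_r_charge`` (free DNA) provides the normalisation.  The
    spread column is the standard deviation of per-replicate rms values.
    """
    if reference_r_charge not in groups:
        raise ValueError("condensation curve requires a free-DNA reference group")
    ref = rms_rg(groups[reference_r_charge])
    rows = []
    for r_charge in sorted(groups):
        trajs = groups[r_charge]
        per_rep = np.array([rms_rg([t]) for t in trajs])
        rows.append(
            {
                "r_charge": r_charge,
                "rms_rg": rms_rg(trajs),
                "rms_rg_norm": rms_rg(trajs) / ref,
                "sd_norm": per_rep.std(ddof=1) / ref if len(per_rep) > 1 else 0.0,
                "n_replicates": len(trajs),
            }
        )
    return pd.DataFrame(rows)


def asphericity_density(
    values: np.ndarray, bandwidth: str | float = "silverman", grid: int = 512
):
    """Kernel density over asphericity values with its local maxima.

    Used for the violin-style morphology summaries: a bimodal density
    with one maximum in the toroid band (0.15-0.25) and one above 0.6
    signals coexisting toroidal and rodlike condensates.  Returns
    (grid, density, list of maxima locations sorted by position).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or np.ptp(values) == 0:
        raise ValueError("need at least two distinct values for a density")
    kde = gaussian_kde(values, bw_method=bandwidth)
    xs = np.linspace(0.0, 1.0, grid)
    ys = kde(xs)
    interior = (ys[1:-1] > ys[:-2]) & (ys[1:-1] >= ys[2:])
    maxima = xs[1:-1][interior]
    return xs, ys, sorted(float(m) for m in maxima)
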