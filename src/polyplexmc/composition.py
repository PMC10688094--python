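"""Molecular composition and charge bookkeeping.

Builds the coarse-grained bead-spring templates used throughout the
package — a 120-bead DNA chain, peptide tails parsed from compact
charge-pattern tokens, the hierarchical G2 PAMAM dendrimer, and
peptide-conjugated dendrimers — and performs all charge accounting:
per-template net charges, the counterion ledger that neutralises the
simulation cell, and the nominal charge ratio

    r_charge = (n_vector * Z_vector) / (n_DNA * Z_DNA)

between the charge carried by the condensing vector (dendrimer, peptide
or conjugate) and the negative charge of the DNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeptideSpec",
    "DendrimerTopology",
    "MoleculeTemplate",
    "SystemComposition",
    "CounterionLedger",
    "parse_tail_token",
    "build_g2",
    "build_dna",
    "build_peptide",
    "g2_template",
    "attachment_terminals",
    "build_conjugate",
    "charge_ratio",
    "r_charge_to_molar",
    "r_molar_to_charge",
    "experimental_vector_charge",
    "counterion_plan",
    "TABLE1_TOKENS",
]

# Bead radii in Angstrom.
DNA_BEAD_RADIUS = 4.0
TAIL_BEAD_RADIUS = 1.5
G2_BEAD_RADIUS = 1.5
COUNTERION_RADIUS = 1.2

DNA_N_BEADS = 120
DNA_BEAD_CHARGE = -1
G2_N_TERMINALS = 16

#: Tail tokens studied in the source experiments plus the simulation-only
#: anionic tail "(0N)12 0".  Keys are canonical token strings.
TABLE1_TOKENS = (
    "0_25",
    "(NP)12 N",
    "(0P)12 0",
    "(00P)8",
    "(P)4 0_17 (P)4",
    "0_8 P_8 0_8",
    "(00N)8",
    "(0N)12 0",
)

_SYMBOL_CHARGE = {"0": 0, "P": +1, "N": -1}


class TokenParseError(ValueError):
    """Raised when a peptide charge-pattern token cannot be parsed."""


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide tail as an ordered sequence of charged hard-sphere beads.

    Attributes
    ----------
    token : str
        The compact charge-pattern label, e.g. ``"(0P)12 0"``.
    charges : tuple[int, ...]
        Per-bead charge in elementary charges, each in {-1, 0, +1}.
    radius : float
        Common bead radius in Angstrom (1.5 for a single amino acid).
    """

    token: str
    charges: tuple[int, ...]
    radius: float = TAIL_BEAD_RADIUS

    @property
    def n_beads(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> int:
        """Z_tail: sum of bead charges."""
        return int(sum(self.charges))


@dataclass(frozen=True)
class DendrimerTopology:
    """Branched G2 dendrimer connectivity: a tree of 57 beads.

    The 16 leaf beads (protonated primary amines) carry charge +1; all
    interior beads are neutral.  ``bonds`` hold (parent, child) index
    pairs; bead 0 is the central bead.
    """

    charges: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]
    terminal_indices: tuple[int, ...]
    radius: float = G2_BEAD_RADIUS
    center_index: int = 0

    @property
    def n_beads(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> int:
        return int(sum(self.charges))


@dataclass(frozen=True)
class MoleculeTemplate:
    """A simulatable molecule: beads with charges/radii plus a bond list.

    ``kind`` is one of ``{"DNA", "peptide", "G2", "conjugate"}``.
    ``tail_attachment_bonds`` lists the (G2 terminal index, first tail
    bead index) pairs for conjugates (empty otherwise).
    """

    kind: str
    charges: tuple[int, ...]
    radii: tuple[float, ...]
    bonds: tuple[tuple[int, int], ...]
    label: str = ""
    tail_attachment_bonds: tuple[tuple[int, int], ...] = ()
    #: per-bead role tags ("DNA", "G2", "G2T", "PEP"); empty -> derive from kind
    roles: tuple[str, ...] = ()
    #: per-bond harmonic rest lengths (A); empty -> contact distance of the
    #: bonded beads.  Bonds with rest length below contact are springs
    #: anchored inside the hard core (the bonded pair is then exempt from
    #: hard-sphere exclusion).
    bond_rest: tuple[float, ...] = ()

    @property
    def n_beads(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> int:
        return int(sum(self.charges))

    def is_tree(self) -> bool:
        return len(self.bonds) == self.n_beads - 1


@dataclass(frozen=True)
class CounterionLedger:
    """Counts of monovalent counterions needed to neutralise a system."""

    n_positive: int  # +1 ions (neutralising bead negative charge)
    n_negative: int  # -1 ions
    radius: float = COUNTERION_RADIUS

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def net_charge(self) -> int:
        return self.n_positive - self.n_negative


_GROUP_RE = re.compile(
    r"""
    \(([0NP]+)\)(\d+)      # (motif)k  -> motif repeated k times
  | ([0NP])_(\d+)          # X_k       -> symbol repeated k times
  | ([0NP]+)               # bare run  -> literal symbols
  | (\S)                   # anything else -> error
    """,
    re.VERBOSE,
)


def parse_tail_token(token: str) -> PeptideSpec:
    """Expand a compact charge-pattern token into a :class:`PeptideSpec`.

    The grammar accepts concatenations (whitespace-insensitive) of
    ``(motif)k`` repeats, ``X_k`` runs and bare symbol runs, with symbols
    ``0`` (neutral), ``P`` (+1, lysine) and ``N`` (-1, aspartate).  The
    terminal cysteines used for wet-lab conjugation are not part of the
    model and never appear in tokens.

    >>> parse_tail_token("(0P)12 0").net_charge
    12
    """
    if not token or not token.strip():
        raise TokenParseError("empty peptide token")
    expanded: list[str] = []
    for m in _GROUP_RE.finditer(token):
        motif, k_motif, sym, k_sym, run, bad = m.groups()
        if bad is not None:
            raise TokenParseError(
                f"unknown symbol {bad!r} in token {token!r} "
                f"(expected 0, N, P, '(motif)k' or 'X_k')"
            )
        if motif is not None:
            expanded.append(motif * int(k_motif))
        elif sym is not None:
            expanded.append(sym * int(k_sym))
        elif run is not None:
            expanded.append(run)
    seq = "".join(expanded)
    if not seq:
        raise TokenParseError(f"token {token!r} expands to an empty sequence")
    charges = tuple(_SYMBOL_CHARGE[c] for c in seq)
    return PeptideSpec(token=token, charges=charges)


def build_g2() -> DendrimerTopology:
    """Construct the hierarchical G2 dendrimer tree.

    Four dimers (two-bead arms) are bonded to a single central bead;
    from the end bead of every dimer, two further dimers branch, twice
    over — giving 1 + 8 + 16 + 32 = 57 beads and 16 terminal tips, each
    of which carries charge +1.
    """
    bonds: list[tuple[int, int]] = []
    n = 1  # bead 0 is the centre
    tips: list[int] = []
    # generation 0 grows four dimers from the centre; each later
    # generation grows two dimers from every tip of the previous one
    frontier = [0] * 4
    for _generation in range(3):
        new_tips: list[int] = []
        for parent in frontier:
            a, b = n, n + 1
            n += 2
            bonds.append((parent, a))
            bonds.append((a, b))
            new_tips.append(b)
        frontier = [t for t in new_tips for _ in range(2)]
        tips = new_tips
    charges = [0] * n
    for t in tips:
        charges[t] = +1
    return DendrimerTopology(
        charges=tuple(charges),
        bonds=tuple(bonds),
        terminal_indices=tuple(tips),
    )


def build_dna(n_beads: int = DNA_N_BEADS) -> MoleculeTemplate:
    """Linear DNA chain: ``n_beads`` hard spheres of radius 4 A, charge -1."""
    bonds = tuple((i, i + 1) for i in range(n_beads - 1))
    return MoleculeTemplate(
        kind="DNA",
        label="DNA",
        charges=(DNA_BEAD_CHARGE,) * n_beads,
        radii=(DNA_BEAD_RADIUS,) * n_beads,
        bonds=bonds,
        roles=("DNA",) * n_beads,
    )


def build_peptide(spec: PeptideSpec | str) -> MoleculeTemplate:
    """A free peptide chain template from a token or :class:`PeptideSpec`."""
    if isinstance(spec, str):
        spec = parse_tail_token(spec)
    bonds = tuple((i, i + 1) for i in range(spec.n_beads - 1))
    return MoleculeTemplate(
        kind="peptide",
        label=spec.token,
        charges=spec.charges,
        radii=(spec.radius,) * spec.n_beads,
        bonds=bonds,
        roles=("PEP",) * spec.n_beads,
    )


def g2_template(
    g2: DendrimerTopology | None = None,
    bond_rest_length: float | None = None,
) -> MoleculeTemplate:
    """Wrap a :class:`DendrimerTopology` as a molecule template.

    ``bond_rest_length`` overrides the rest length of the dendrimer's
    internal harmonic bonds (0.0 gives centre-anchored springs, which
    lets the small beads of the branched scaffold interpenetrate their
    bonded neighbours and yields a compact dendrimer); ``None`` keeps
    the contact-distance default.
    """
    if g2 is None:
        g2 = build_g2()
    rest = () if bond_rest_length is None else (bond_rest_length,) * len(g2.bonds)
    return MoleculeTemplate(
        kind="G2",
        label="G2",
        charges=g2.charges,
        radii=(g2.radius,) * g2.n_beads,
        bonds=g2.bonds,
        roles=tuple("G2T" if z else "G2" for z in g2.charges),
        bond_rest=rest,
    )


def _graph_distances(n: int, bonds, source: int) -> np.ndarray:
    """BFS hop counts from ``source`` over an adjacency defined by bonds."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    return dist


def attachment_terminals(g2: DendrimerTopology, n_tails: int) -> tuple[int, ...]:
    """Deterministic choice of the G2 terminals that carry peptide tails.

    One tail attaches to the lowest-index terminal; a second attaches to
    the terminal at maximal graph distance from the first (lowest index
    on ties), so two tails sit on opposite branches.
    """
    first = min(g2.terminal_indices)
    if n_tails == 1:
        return (first,)
    dist = _graph_distances(g2.n_beads, g2.bonds, first)
    others = [t for t in g2.terminal_indices if t != first]
    dmax = max(dist[t] for t in others)
    second = min(t for t in others if dist[t] == dmax)
    return (first, second)


def build_conjugate(
    g2: DendrimerTopology | None,
    tail: PeptideSpec | str,
    n_tails: int,
    g2_bond_rest_length: float | None = None,
) -> MoleculeTemplate:
    """Attach ``n_tails`` copies of a peptide tail to a G2 dendrimer.

    Each tail's first bead is bonded to a distinct G2 terminal; the
    attached terminals keep their +1 charge (the simulation convention —
    linker neutralisation applies only to the experimental charge
    accounting, see :func:`experimental_vector_charge`).  Net charge is
    therefore ``16 + n_tails * Z_tail``.
    """
    if n_tails not in (1, 2):
        raise ValueError(f"n_tails must be 1 or 2, got {n_tails}")
    if g2 is None:
        g2 = build_g2()
    if isinstance(tail, str):
        tail = parse_tail_token(tail)
    charges = list(g2.charges)
    radii = [g2.radius] * g2.n_beads
    bonds = list(g2.bonds)
    # dendrimer-internal bonds may carry an overridden rest length; tail
    # and attachment bonds always use the contact distance
    rest = (
        [] if g2_bond_rest_length is None
        else [float(g2_bond_rest_length)] * len(g2.bonds)
    )
    attach: list[tuple[int, int]] = []
    for terminal in attachment_terminals(g2, n_tails):
        offset = len(charges)
        charges.extend(tail.charges)
        radii.extend([tail.radius] * tail.n_beads)
        bonds.append((terminal, offset))
        attach.append((terminal, offset))
        if rest:
            rest.append(radii[terminal] + tail.radius)
        bonds.extend((offset + i, offset + i + 1) for i in range(tail.n_beads - 1))
        if rest:
            rest.extend([2 * tail.radius] * (tail.n_beads - 1))
    return MoleculeTemplate(
        kind="conjugate",
        label=f"G2+{n_tails}tail/{tail.token}",
        charges=tuple(charges),
        radii=tuple(radii),
        bonds=tuple(bonds),
        tail_attachment_bonds=tuple(attach),
        bond_rest=tuple(rest),
    )


@dataclass
class SystemComposition:
    """Molecule templates with instance counts, plus the counterion ledger.

    ``convention`` selects how vector charges enter the charge-ratio
    arithmetic: ``"simulation"`` sums the model bead charges,
    ``"experimental"`` applies the linker-neutralisation correction for
    conjugates (see :func:`experimental_vector_charge`).
    """

    members: list[tuple[MoleculeTemplate, int]] = field(default_factory=list)
    convention: str = "simulation"
    linker_neutralization: float = 2.3
    tails_per_dendrimer: float = 2.3

    def add(self, template: MoleculeTemplate, count: int = 1) -> "SystemComposition":
        if count < 0:
            raise ValueError("count must be non-negative")
        self.members.append((template, count))
        return self

    @property
    def n_dna(self) -> int:
        return sum(c for t, c in self.members if t.kind == "DNA")

    @property
    def z_dna(self) -> int:
        """Total magnitude of DNA charge across instances (simulation)."""
        return sum(abs(t.net_charge) * c for t, c in self.members if t.kind == "DNA")

    def counterions(self) -> CounterionLedger:
        return counterion_plan(self)

    def total_charge_with_counterions(self) -> int:
        bead = sum(t.net_charge * c for t, c in self.members)
        return bead + self.counterions().net_charge


def counterion_plan(composition: SystemComposition) -> CounterionLedger:
    """One monovalent counterion of opposite charge per charged bead."""
    n_pos = 0
    n_neg = 0
    for template, count in composition.members:
        neg_beads = sum(1 for z in template.charges if z < 0)
        pos_beads = sum(1 for z in template.charges if z > 0)
        n_pos += neg_beads * count
        n_neg += pos_beads * count
    return CounterionLedger(n_positive=n_pos, n_negative=n_neg)


def charge_ratio(
    n_vector: float, z_vector: float, n_dna: float, z_dna: float
) -> float:
    """Nominal charge ratio r_charge = (n_vector Z_vector)/(n_DNA Z_DNA).

    ``z_dna`` is the magnitude of the charge of one DNA molecule (120 for
    the model chain; 2 per base pair for a plasmid).
    """
    if n_dna < 1:
        raise ValueError("need at least one DNA molecule")
    if z_dna <= 0:
        raise ValueError("Z_DNA must be a positive magnitude")
    return (n_vector * z_vector) / (n_dna * z_dna)


def r_charge_to_molar(r_charge: float, z_vector: float, z_dna: float) -> float:
    """Convert a charge ratio to the equivalent vector:DNA molar ratio."""
    if z_vector == 0:
        raise ValueError("zero vector charge: r_molar is unconstrained")
    return r_charge * z_dna / z_vector


def r_molar_to_charge(r_molar: float, z_vector: float, z_dna: float) -> float:
    """Convert a molar ratio to the equivalent charge ratio."""
    if z_dna <= 0:
        raise ValueError("Z_DNA must be a positive magnitude")
    return r_molar * z_vector / z_dna


def experimental_vector_charge(
    z_tail: float,
    tails_per_dendrimer: float = 2.3,
    linker_neutralization: float = 2.3,
) -> float:
    """Conjugate charge under the experimental convention.

    All 16 primary amines are protonated, the SPDP linkers neutralise
    ``linker_neutralization`` of them on average, and the measured mean
    of ``tails_per_dendrimer`` tails each contribute ``z_tail``.
    """
    return 16.0 - linker_neutralization + tails_per_dendrimer * z_tail
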