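"""Molecular graph model, SDF V2000 I/O, chemical perception and flexibility descriptors.

The central quantity here is the effective rotor count

    N_ER = N_R + N_NARA / 5

where ``N_R`` is the number of rotatable bonds and ``N_NARA`` the number of
non-aromatic sp3-hybridised ring atoms.  ``N_ER`` augments the classic
rotatable-bond flexibility measure with a contribution from flexible
(saturated) rings, and together with the non-hydrogen atom count ``N_NHA``
drives the accuracy-prediction regressions in :mod:`confens.accuracy`.

Hydrogens are retained on read but excluded from every descriptor; all
counts below are heavy-atom counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import networkx as nx
import numpy as np

__all__ = [
    "AROMATIC",
    "MoleculeGraph",
    "Conformer",
    "PerceivedGraph",
    "FlexibilityDescriptor",
    "SdfParseError",
    "read_sdf",
    "write_sdf",
    "perceive",
    "effective_rotor_count",
    "fragment_sample_count",
    "filter_ligand_set",
    "descriptor_table",
]

#: Bond-order code for aromatic bonds (SDF V2000 convention).
AROMATIC = 4

_VALID_ORDERS = frozenset({1, 2, 3, AROMATIC})


class SdfParseError(ValueError):
    """Raised for malformed SDF records; message names the record ordinal."""


@dataclass(frozen=True)
class MoleculeGraph:
    """Connected 2-D molecular graph: atoms (element, formal charge) and bonds.

    Bond orders are 1, 2, 3 or :data:`AROMATIC`.  Multi-fragment records are
    rejected: descriptors and superposition are single-molecule concepts.
    """

    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError("molecule has no atoms")
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references atom outside 0..{n - 1}")
            if i == j:
                raise ValueError(f"bond ({i},{j}) endpoints are not distinct")
            if order not in _VALID_ORDERS:
                raise ValueError(f"unsupported bond order {order}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if n > 1:
            g = self.to_networkx()
            if not nx.is_connected(g):
                raise ValueError(
                    f"molecule {self.name!r} has multiple fragments; "
                    "split the record or supply one fragment per record"
                )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, (elem, charge) in enumerate(self.atoms):
            g.add_node(idx, element=elem, charge=charge)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(i for i, (e, _) in enumerate(self.atoms) if e != "H")

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)

    def heavy_subgraph(self) -> "MoleculeGraph":
        """Graph restricted to non-hydrogen atoms (indices remapped)."""
        keep = self.heavy_indices
        remap = {old: new for new, old in enumerate(keep)}
        atoms = tuple(self.atoms[i] for i in keep)
        bonds = tuple(
            (remap[i], remap[j], o)
            for i, j, o in self.bonds
            if i in remap and j in remap
        )
        return MoleculeGraph(atoms=atoms, bonds=bonds, name=self.name)

    def connectivity_key(self) -> tuple:
        """Hashable key identifying atoms + bonds, used to group SDF records."""
        return (self.atoms, tuple(sorted((min(i, j), max(i, j), o) for i, j, o in self.bonds)))


@dataclass
class Conformer:
    """One 3-D coordinate set (Å) for a molecule, optionally with an energy (kcal/mol)."""

    coords: np.ndarray
    energy: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    def heavy_coords(self, mol: MoleculeGraph) -> np.ndarray:
        return self.coords[list(mol.heavy_indices)]


@dataclass(frozen=True)
class FlexibilityDescriptor:
    """Size/flexibility descriptors of a molecule: N_NHA, N_R, N_NARA, N_ER."""

    n_nha: int
    n_r: int
    n_nara: int
    n_er: float

    def __post_init__(self) -> None:
        if not math.isclose(self.n_er, self.n_r + self.n_nara / 5, rel_tol=0, abs_tol=1e-12):
            raise ValueError("n_er must equal n_r + n_nara/5")
        if self.n_nha < 1 or self.n_r < 0:
            raise ValueError("n_nha >= 1 and n_r >= 0 required")

    @property
    def n_er_bin(self) -> int:
        """N_ER rounded half-up to the nearest whole number (for binned reports)."""
        return round_half_up(self.n_er)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PerceivedGraph:
    """A :class:`MoleculeGraph` with rings, aromaticity, hybridisation and rotors assigned.

    Ring perception is a minimum cycle basis (SSSR); aromaticity is single-ring
    Hückel; sp3 means every incident bond is a single bond and the atom is not
    aromatic.  Rotatable bonds are acyclic single bonds whose endpoints both
    have at least two heavy neighbours (amide C-N excluded unless requested).
    """

    base: MoleculeGraph
    rings: tuple[tuple[int, ...], ...]
    aromatic_atoms: frozenset[int]
    sp3_atoms: frozenset[int]
    rotatable_bonds: frozenset[tuple[int, int]]
    ring_bond_count_per_atom: dict[int, int] = field(hash=False)

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return self.base.heavy_indices

    @property
    def n_nha(self) -> int:
        return self.base.n_heavy

    @property
    def n_r(self) -> int:
        return len(self.rotatable_bonds)

    @property
    def n_nara(self) -> int:
        ring_atoms = {a for ring in self.rings for a in ring}
        return len(
            [a for a in ring_atoms if a in self.sp3_atoms and a not in self.aromatic_atoms]
        )


# ---------------------------------------------------------------------------
# SDF V2000 I/O
# ---------------------------------------------------------------------------

def _parse_record(lines: list[str], ordinal: int, energy_tag: str) -> tuple[MoleculeGraph, Conformer]:
    if len(lines) < 4:
        raise SdfParseError(f"record {ordinal}: truncated header block")
    name = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise SdfParseError(f"record {ordinal}: V3000 records are not supported")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise SdfParseError(f"record {ordinal}: malformed counts line {counts!r}") from exc
    if len(lines) < 4 + n_atoms + n_bonds:
        raise SdfParseError(f"record {ordinal}: atom/bond block shorter than counts line claims")

    coords = np.empty((n_atoms, 3))
    atoms: list[tuple[str, int]] = []
    for k in range(n_atoms):
        ln = lines[4 + k]
        try:
            coords[k] = (float(ln[0:10]), float(ln[10:20]), float(ln[20:30]))
            elem = ln[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise SdfParseError(f"record {ordinal}: malformed atom line {k + 1}") from exc
        if not elem:
            raise SdfParseError(f"record {ordinal}: missing element symbol on atom line {k + 1}")
        atoms.append((elem, 0))

    bonds: list[tuple[int, int, int]] = []
    for k in range(n_bonds):
        ln = lines[4 + n_atoms + k]
        try:
            i = int(ln[0:3])
            j = int(ln[3:6])
            order = int(ln[6:9])
        except (ValueError, IndexError) as exc:
            raise SdfParseError(f"record {ordinal}: malformed bond line {k + 1}") from exc
        if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
            raise SdfParseError(
                f"record {ordinal}: bond {k + 1} references atom {max(i, j)} of {n_atoms}"
            )
        bonds.append((i - 1, j - 1, order))

    # properties block: charges override the (deprecated) atom-line field
    charges: dict[int, int] = {}
    energy: float | None = None
    idx = 4 + n_atoms + n_bonds
    while idx < len(lines):
        ln = lines[idx]
        if ln.startswith("M  CHG"):
            fields = ln.split()
            n_entries = int(fields[2])
            for e in range(n_entries):
                charges[int(fields[3 + 2 * e]) - 1] = int(fields[4 + 2 * e])
        elif ln.startswith(">") and f"<{energy_tag}>" in ln:
            if idx + 1 < len(lines):
                try:
                    energy = float(lines[idx + 1].strip())
                except ValueError as exc:
                    raise SdfParseError(
                        f"record {ordinal}: non-numeric {energy_tag} field"
                    ) from exc
        idx += 1

    atoms = [(e, charges.get(k, 0)) for k, (e, _) in enumerate(atoms)]
    try:
        mol = MoleculeGraph(atoms=tuple(atoms), bonds=tuple(bonds), name=name)
    except ValueError as exc:
        raise SdfParseError(f"record {ordinal}: {exc}") from exc
    return mol, Conformer(coords=coords, energy=energy, name=name)


def read_sdf(source: str | TextIO, energy_tag: str = "ENERGY") -> list[tuple[MoleculeGraph, list[Conformer]]]:
    """Read a V2000 SDF, grouping consecutive same-molecule records into ensembles.

    Consecutive records sharing name and connectivity become one
    ``(MoleculeGraph, [Conformer, ...])`` entry.  A data field named
    ``energy_tag`` (default ``ENERGY``, kcal/mol) populates conformer energies.

    Raises :class:`SdfParseError` naming the 1-based record ordinal on
    malformed input.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r") as fh:
            text = fh.read()

    records: list[list[str]] = []
    current: list[str] = []
    for raw in text.splitlines():
        if raw.strip() == "$$$$":
            records.append(current)
            current = []
        else:
            current.append(raw)
    if any(ln.strip() for ln in current):
        records.append(current)

    out: list[tuple[MoleculeGraph, list[Conformer]]] = []
    for ordinal, rec in enumerate(records, start=1):
        mol, conf = _parse_record(rec, ordinal, energy_tag)
        if out and out[-1][0].name == mol.name and out[-1][0].connectivity_key() == mol.connectivity_key():
            out[-1][1].append(conf)
        else:
            out.append((mol, [conf]))
    return out


def write_sdf(
    entries: Iterable[tuple[MoleculeGraph, Sequence[Conformer]]],
    dest: str | TextIO,
    energy_tag: str = "ENERGY",
) -> None:
    """Write molecules/ensembles as a V2000 SDF (coordinates to 4 decimals)."""
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        for mol, confs in entries:
            for conf in confs:
                fh.write(f"{mol.name}\n  confens\n\n")
                fh.write(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000\n")
                for (elem, _), xyz in zip(mol.atoms, conf.coords):
                    fh.write(f"{xyz[0]:10.4f}{xyz[1]:10.4f}{xyz[2]:10.4f} {elem:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n")
                for i, j, order in mol.bonds:
                    fh.write(f"{i + 1:3d}{j + 1:3d}{order:3d}  0\n")
                charged = [(i + 1, c) for i, (_, c) in enumerate(mol.atoms) if c != 0]
                if charged:
                    fh.write(f"M  CHG{len(charged):3d}" + "".join(f"{i:4d}{c:4d}" for i, c in charged) + "\n")
                fh.write("M  END\n")
                if conf.energy is not None:
                    fh.write(f"> <{energy_tag}>\n{conf.energy:.6f}\n\n")
                fh.write("$$$$\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------

_LONE_PAIR_DONORS = frozenset({"N", "O", "S", "P"})


def _ring_is_aromatic(mol: MoleculeGraph, g: nx.Graph, ring: tuple[int, ...]) -> bool:
    """Single-ring Hückel test: every atom sp2-capable, pi count = 4n + 2."""
    pi = 0
    for a in ring:
        elem = mol.atoms[a][0]
        orders = [g.edges[a, nbr]["order"] for nbr in g.neighbors(a)]
        if any(o in (2, 3, AROMATIC) for o in orders):
            pi += 1
        elif elem in _LONE_PAIR_DONORS:
            pi += 2  # pyrrole-type lone-pair contribution
        else:
            return False
    return pi >= 2 and (pi - 2) % 4 == 0


def _is_amide_bond(mol: MoleculeGraph, g: nx.Graph, i: int, j: int) -> bool:
    for c, n in ((i, j), (j, i)):
        if mol.atoms[c][0] == "C" and mol.atoms[n][0] == "N":
            for nbr in g.neighbors(c):
                if mol.atoms[nbr][0] == "O" and g.edges[c, nbr]["order"] == 2:
                    return True
    return False


def perceive(mol: MoleculeGraph, include_amide_rotors: bool = False) -> PerceivedGraph:
    """Assign SSSR rings, aromaticity, sp3 hybridisation and rotatable bonds.

    Deterministic for a fixed input; all sets refer to atom indices of
    ``mol`` (hydrogens can never be ring members, aromatic, or rotor
    endpoints, so the heavy-atom restriction is implicit).
    """
    g = mol.to_networkx()
    heavy = set(mol.heavy_indices)

    raw_rings = nx.minimum_cycle_basis(g)
    rings = tuple(sorted(tuple(sorted(r)) for r in raw_rings))
    # a ring bond is any edge on a cycle, i.e. any non-bridge
    bridges = {(min(i, j), max(i, j)) for i, j in nx.bridges(g)} if len(mol.atoms) > 1 else set()
    ring_bonds = {
        (min(i, j), max(i, j))
        for i, j in g.edges
        if (min(i, j), max(i, j)) not in bridges
    }

    ring_bond_count = {a: 0 for a in range(len(mol.atoms))}
    for i, j in ring_bonds:
        ring_bond_count[i] += 1
        ring_bond_count[j] += 1

    aromatic: set[int] = set()
    for ring in rings:
        if _ring_is_aromatic(mol, g, ring):
            aromatic.update(ring)

    sp3 = {
        a
        for a in range(len(mol.atoms))
        if a not in aromatic
        and all(g.edges[a, nbr]["order"] == 1 for nbr in g.neighbors(a))
    }

    rotatable: set[tuple[int, int]] = set()
    for i, j in g.edges:
        key = (min(i, j), max(i, j))
        if g.edges[i, j]["order"] != 1 or key in ring_bonds:
            continue
        if i in aromatic and j in aromatic:
            continue
        deg_i = sum(1 for nbr in g.neighbors(i) if nbr in heavy)
        deg_j = sum(1 for nbr in g.neighbors(j) if nbr in heavy)
        if deg_i < 2 or deg_j < 2:
            continue
        if not include_amide_rotors and _is_amide_bond(mol, g, i, j):
            continue
        rotatable.add(key)

    return PerceivedGraph(
        base=mol,
        rings=rings,
        aromatic_atoms=frozenset(aromatic),
        sp3_atoms=frozenset(sp3),
        rotatable_bonds=frozenset(rotatable),
        ring_bond_count_per_atom=ring_bond_count,
    )


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def effective_rotor_count(p: PerceivedGraph) -> FlexibilityDescriptor:
    """Compute N_NHA, N_R, N_NARA and N_ER = N_R + N_NARA/5 for a perceived molecule."""
    n_r = p.n_r
    n_nara = p.n_nara
    return FlexibilityDescriptor(
        n_nha=p.n_nha, n_r=n_r, n_nara=n_nara, n_er=n_r + n_nara / 5
    )


def fragment_sample_count(p: PerceivedGraph, startfact: float = 20.0) -> int:
    """Fragment sampling count: 10 + (#atoms with 3 ring bonds - #atoms with 4) * startfact.

    The result is rounded half-up and clamped to >= 1 (a warning is emitted
    when clamping fires: heavily spiro-fused inputs drive the bracketed
    difference negative and the formula has no documented floor).
    """
    if startfact <= 0:
        raise ValueError("startfact must be positive")
    n3 = sum(1 for c in p.ring_bond_count_per_atom.values() if c == 3)
    n4 = sum(1 for c in p.ring_bond_count_per_atom.values() if c == 4)
    value = round_half_up(10 + (n3 - n4) * startfact)
    if value < 1:
        warnings.warn(
            f"fragment sample count {value} < 1 for {p.base.name!r}; clamped to 1",
            stacklevel=2,
        )
        return 1
    return value


#: Rejection reason codes used by :func:`filter_ligand_set`.
REASON_TOO_SMALL = "too_small"
REASON_TOO_LARGE = "too_large"
REASON_TOO_FLEXIBLE = "too_flexible"


def filter_ligand_set(
    records: Sequence[tuple[MoleculeGraph, Sequence[Conformer]]],
    min_nha: int = 2,
    max_nha: int = 50,
    max_rotors: int = 15,
) -> tuple[list, list]:
    """Apply the ligand-set size/flexibility filters.

    Keeps molecules with ``min_nha <= N_NHA <= max_nha`` (default 2-50 heavy
    atoms) and rotatable-bond count ``<= max_rotors`` (default 15).  Returns
    ``(kept, rejected)`` where each rejection is
    ``(record, reason_code)``.
    """
    kept, rejected = [], []
    for rec in records:
        mol = rec[0]
        p = perceive(mol)
        if p.n_nha < min_nha:
            rejected.append((rec, REASON_TOO_SMALL))
        elif p.n_nha > max_nha:
            rejected.append((rec, REASON_TOO_LARGE))
        elif p.n_r > max_rotors:
            rejected.append((rec, REASON_TOO_FLEXIBLE))
        else:
            kept.append(rec)
    return kept, rejected


def descriptor_table(records: Sequence[tuple[MoleculeGraph, Sequence[Conformer]]]):
    """TSV-ready descriptor report: name, n_nha, n_r, n_nara, n_er."""
    import pandas as pd

    rows = []
    for mol, _ in records:
        d = effective_rotor_count(perceive(mol))
        rows.append(
            {"name": mol.name, "n_nha": d.n_nha, "n_r": d.n_r, "n_nara": d.n_nara, "n_er": d.n_er}
        )
    return pd.DataFrame(rows, columns=["name", "n_nha", "n_r", "n_nara", "n_er"])
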