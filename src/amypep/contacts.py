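"""Interface contacts and hydrogen bonds from a docked enzyme-peptide complex.

Works directly on PDB-format text with two chains (enzyme + peptide).  A
hydrogen bond is scored purely geometrically: any enzyme N/O heavy atom
within 3.5 A of a peptide N/O heavy atom, mirroring the "polar contacts"
convention of structure viewers; no donor/acceptor roles or angle terms.
A residue-level interaction is any heavy-atom pair within a configurable
cutoff (default 4.0 A), deduplicated per enzyme residue.

Peptide positions are reported as the 1-based rank of the residue within
the peptide chain counted from the N-terminus, independent of the author
numbering in the file.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .peptides import THREE_TO_ONE

#: Maximum heavy-atom hydrogen-bond length (A).
MAX_HBOND_LENGTH = 3.5
#: Default heavy-atom cutoff for residue-level interactions (A).
DEFAULT_CONTACT_CUTOFF = 4.0

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
_POLAR_ELEMENTS = {"N", "O"}


class Evidence(enum.Enum):
    FIXTURE = "fixture"
    GEOMETRY = "geometry"


@dataclass(frozen=True)
class AtomSite:
    """One heavy atom of the complex."""

    chain_id: str
    res_name: str
    res_seq: int
    atom_name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def residue_label(self) -> str:
        """Viewer-style label, e.g. ``His201``."""
        return f"{self.res_name.capitalize()}{self.res_seq}"


@dataclass(frozen=True)
class InteractionRecord:
    """One (peptide, enzyme residue) contact event feeding IN counts."""

    peptide_id: int
    enzyme_residue_label: str
    evidence: Evidence = Evidence.GEOMETRY


@dataclass(frozen=True)
class HydrogenBond:
    """One enzyme-peptide hydrogen bond.

    ``position`` is the bond's residue position n_i counted from the
    peptide's N-terminus (1-based); ``length`` is d_i in Angstrom.
    """

    peptide_id: int
    position: int
    peptide_residue: str
    length: float
    enzyme_residue_label: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.length <= MAX_HBOND_LENGTH:
            raise ValueError(
                f"hydrogen-bond length must be in (0, {MAX_HBOND_LENGTH}] A, "
                f"got {self.length}"
            )
        if self.position < 1:
            raise ValueError(f"peptide position must be >= 1, got {self.position}")


def parse_complex(
    pdb_content: str, enzyme_chain: str, peptide_chain: str
) -> tuple[list[AtomSite], list[AtomSite]]:
    """Partition the heavy atoms of a PDB-format complex by chain.

    Water molecules and hydrogen/deuterium atoms are excluded.  Raises if a
    requested chain is absent, naming the chains that are present.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", io.StringIO(pdb_content))
    model = next(structure.get_models())
    available = [chain.id for chain in model]
    atoms: dict[str, list[AtomSite]] = {}
    for chain in model:
        sites: list[AtomSite] = []
        for residue in chain:
            if residue.get_resname().strip() in _WATER_NAMES:
                continue
            for atom in residue:
                element = (atom.element or "").strip().upper()
                if element in {"H", "D"}:
                    continue
                x, y, z = (float(v) for v in atom.coord)
                sites.append(
                    AtomSite(
                        chain_id=chain.id,
                        res_name=residue.get_resname().strip(),
                        res_seq=int(residue.id[1]),
                        atom_name=atom.get_name(),
                        element=element,
                        coord=(x, y, z),
                    )
                )
        atoms[chain.id] = sites
    for wanted in (enzyme_chain, peptide_chain):
        if wanted not in atoms or not atoms[wanted]:
            raise ValueError(
                f"chain {wanted!r} not found in structure; available chains: "
                f"{', '.join(sorted(a for a in available if atoms.get(a)))}"
            )
    return atoms[enzyme_chain], atoms[peptide_chain]


def _peptide_position_map(peptide_atoms: Sequence[AtomSite]) -> dict[int, int]:
    """Map author residue numbers of the peptide chain to N->C ranks (1-based)."""
    seen: list[int] = []
    for atom in peptide_atoms:
        if atom.res_seq not in seen:
            seen.append(atom.res_seq)
    return {res_seq: rank for rank, res_seq in enumerate(seen, start=1)}


def _coords(atoms: Sequence[AtomSite]) -> np.ndarray:
    return np.array([a.coord for a in atoms], dtype=float).reshape(len(atoms), 3)


def detect_hydrogen_bonds(
    enzyme_atoms: Sequence[AtomSite],
    peptide_atoms: Sequence[AtomSite],
    max_length: float = MAX_HBOND_LENGTH,
    peptide_id: int = 0,
) -> list[HydrogenBond]:
    """All enzyme-peptide polar heavy-atom pairs within ``max_length`` A.

    Polar means element N or O.  One bond per qualifying atom pair; the
    boundary distance is inclusive.  Zero bonds is a valid outcome.
    """
    if not enzyme_atoms or not peptide_atoms:
        raise ValueError("atom lists must be non-empty")
    epolar = [a for a in enzyme_atoms if a.element in _POLAR_ELEMENTS]
    ppolar = [a for a in peptide_atoms if a.element in _POLAR_ELEMENTS]
    if not epolar or not ppolar:
        return []
    ranks = _peptide_position_map(peptide_atoms)
    dist = cdist(_coords(epolar), _coords(ppolar))
    bonds: list[HydrogenBond] = []
    for i, j in zip(*np.nonzero(dist <= max_length)):
        ea, pa = epolar[i], ppolar[j]
        bonds.append(
            HydrogenBond(
                peptide_id=peptide_id,
                position=ranks[pa.res_seq],
                peptide_residue=THREE_TO_ONE.get(pa.res_name.upper(), "X"),
                length=float(dist[i, j]),
                enzyme_residue_label=ea.residue_label,
            )
        )
    bonds.sort(key=lambda b: (b.position, b.enzyme_residue_label or "", b.length))
    return bonds


def list_interacting_residues(
    enzyme_atoms: Sequence[AtomSite],
    peptide_atoms: Sequence[AtomSite],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    peptide_id: int = 0,
) -> list[InteractionRecord]:
    """Enzyme residues with any heavy atom within ``contact_cutoff`` of the peptide.

    One record per enzyme residue per peptide, regardless of how many atom
    pairs qualify.
    """
    if not enzyme_atoms or not peptide_atoms:
        raise ValueError("atom lists must be non-empty")
    dist = cdist(_coords(enzyme_atoms), _coords(peptide_atoms))
    in_contact = (dist <= contact_cutoff).any(axis=1)
    labels: list[str] = []
    for atom, hit in zip(enzyme_atoms, in_contact):
        if hit and atom.residue_label not in labels:
            labels.append(atom.residue_label)
    return [
        InteractionRecord(peptide_id=peptide_id, enzyme_residue_label=label)
        for label in labels
    ]
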