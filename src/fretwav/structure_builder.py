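"""Idealized B-DNA duplex builder and PDB I/O for coarse-grained structures.

Each nucleotide is reduced to three pseudo-atoms — phosphate, sugar and
base — placed on a canonical B-form helix (rise 3.4 A, twist 36 deg,
helix axis = z).  The radial positions and pseudo-atom radii are chosen to
reproduce the ~20 A steric envelope of duplex DNA, which is what the
accessible-volume calculation is sensitive to; sequence-dependent helical
fine structure is deliberately not modeled.

Atom labels carry 1-based residue indices per strand (strand 0 runs 5'->3'
with residue 1 at z=0; the complementary strand is antiparallel), so
labeling positions given as sequence positions map directly.  The labeled
thymine of a dye attachment is written as ``X`` in the input sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PseudoAtomStructure",
    "AttachmentSite",
    "ROLE_PHOSPHATE",
    "ROLE_SUGAR",
    "ROLE_BASE",
    "SEQ_DONOR_10BP",
    "SEQ_DONOR_17BP",
    "SEQ_ACCEPTOR",
    "build_bdna",
    "build_construct",
    "attachment_sites",
    "read_pdb",
    "write_pdb",
]

ROLE_PHOSPHATE, ROLE_SUGAR, ROLE_BASE = 0, 1, 2
_ROLE_NAMES = {ROLE_PHOSPHATE: "P", ROLE_SUGAR: "S", ROLE_BASE: "B"}
_ROLE_FROM_NAME = {v: k for k, v in _ROLE_NAMES.items()}
_ROLE_ELEMENTS = {ROLE_PHOSPHATE: "P", ROLE_SUGAR: "C", ROLE_BASE: "N"}

# helix geometry: radial distance (A), azimuthal offset from the base-pair
# pseudo-dyad (deg, +/- per strand), pseudo-atom radius (A)
_RADIAL = {ROLE_PHOSPHATE: 9.4, ROLE_SUGAR: 7.4, ROLE_BASE: 2.5}
_AZIMUTH_OFFSET = {ROLE_PHOSPHATE: 77.0, ROLE_SUGAR: 55.0, ROLE_BASE: 33.0}
_RADII = {ROLE_PHOSPHATE: 2.9, ROLE_SUGAR: 2.9, ROLE_BASE: 3.5}

_DEFAULT_VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8, "H": 1.2}
_FALLBACK_VDW = 1.7

# labeled duplexes: X marks the dye-carrying thymine (C6 amino linker at 5')
SEQ_DONOR_10BP = "GGACTAGTCTAGGCGAACGTTTAAGGXGATCTCTGTTTACAACTCCGA"
SEQ_DONOR_17BP = "GGACTAGTCTAGGCGAACGTTTAAGGCGATCTCXGTTTACAACTCCGA"
SEQ_ACCEPTOR = "TCGGAGTTGTAAACAGAGATCGCCTTAAACGXTCGCCTAGACTAGTCC"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "X": "A"}


@dataclass
class PseudoAtomStructure:
    """Coarse-grained structure: positions, radii and per-atom labels."""

    positions: np.ndarray  # (N, 3) A
    radii: np.ndarray  # (N,)
    residue_index: np.ndarray  # (N,) 1-based within strand
    strand: np.ndarray  # (N,) 0 or 1 (0 for generic PDB input)
    role: np.ndarray  # (N,) ROLE_* code
    sequences: tuple[str, ...] = ()
    mismatches: tuple[int, ...] = ()  # base-pair indices (top-strand, 1-based)

    def __post_init__(self) -> None:
        if np.any(self.radii <= 0):
            raise ValueError("pseudo-atom radii must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.radii)

    def atom_index(self, strand: int, residue: int, role: int) -> int:
        hits = np.flatnonzero(
            (self.strand == strand)
            & (self.residue_index == residue)
            & (self.role == role)
        )
        if hits.size != 1:
            raise KeyError(f"no unique atom for strand={strand} residue={residue} role={role}")
        return int(hits[0])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PseudoAtomStructure":
        """Rigidly transformed copy (used for frame-independence checks)."""
        return PseudoAtomStructure(
            positions=self.positions @ np.asarray(rotation).T + np.asarray(translation),
            radii=self.radii.copy(),
            residue_index=self.residue_index.copy(),
            strand=self.strand.copy(),
            role=self.role.copy(),
            sequences=self.sequences,
            mismatches=self.mismatches,
        )


@dataclass(frozen=True)
class AttachmentSite:
    """Dye-linker attachment point: labeled base displaced toward solvent."""

    position: np.ndarray
    residue: int
    strand: int
    atom_index: int  # index of the labeled base pseudo-atom


def build_bdna(
    seq_top: str,
    seq_bottom: str,
    rise: float = 3.4,
    twist: float = 36.0,
) -> PseudoAtomStructure:
    """Idealized B-DNA duplex from two complementary strand sequences.

    ``seq_top`` runs 5'->3' with residue 1 at z=0; ``seq_bottom`` is the
    antiparallel complement (its residue 1 pairs with the top strand's last
    residue).  Non-complementary pairs are tolerated and recorded as
    mismatches.  ``X`` denotes a labeled thymine.
    """
    top = seq_top.upper().replace(" ", "")
    bottom = seq_bottom.upper().replace(" ", "")
    if len(top) != len(bottom):
        raise ValueError("strand lengths differ")
    n = len(top)
    mismatches = []
    for i in range(n):  # top residue i+1 pairs bottom residue n-i
        b_top, b_bot = top[i], bottom[n - 1 - i]
        if _COMPLEMENT.get("T" if b_top == "X" else b_top) != ("T" if b_bot == "X" else b_bot):
            mismatches.append(i + 1)
    pos, rad, res, strnd, role = [], [], [], [], []
    for strand_id, seq in ((0, top), (1, bottom)):
        for j in range(n):
            pair_idx = j if strand_id == 0 else n - 1 - j  # 0-based base-pair step
            dyad = np.deg2rad(twist * pair_idx)
            sign = +1.0 if strand_id == 0 else -1.0
            z = rise * pair_idx
            for r in (ROLE_PHOSPHATE, ROLE_SUGAR, ROLE_BASE):
                phi = dyad + sign * np.deg2rad(_AZIMUTH_OFFSET[r])
                rho = _RADIAL[r]
                pos.append([rho * np.cos(phi), rho * np.sin(phi), z])
                rad.append(_RADII[r])
                res.append(j + 1)
                strnd.append(strand_id)
                role.append(r)
    return PseudoAtomStructure(
        positions=np.asarray(pos),
        radii=np.asarray(rad),
        residue_index=np.asarray(res),
        strand=np.asarray(strnd),
        role=np.asarray(role),
        sequences=(top, bottom),
        mismatches=tuple(mismatches),
    )


def build_construct(separation_bp: int = 17) -> tuple[PseudoAtomStructure, list]:
    """Labeled duplex (donor + acceptor strand) for a 10- or 17-bp separation.

    Returns the structure and its two dye attachment sites
    ``[donor, acceptor]``.
    """
    if separation_bp == 17:
        top = SEQ_DONOR_17BP
    elif separation_bp == 10:
        top = SEQ_DONOR_10BP
    else:
        raise ValueError("separation_bp must be 10 or 17")
    structure = build_bdna(top, SEQ_ACCEPTOR)
    labeled = [(0, top.index("X") + 1), (1, SEQ_ACCEPTOR.index("X") + 1)]
    return structure, attachment_sites(structure, labeled)


def attachment_sites(
    structure: PseudoAtomStructure,
    labeled_positions,
    radial_offset: float = 3.0,
) -> list:
    """Attachment points for labeled residues.

    Each point is the labeled base pseudo-atom displaced radially outward
    (away from the helix axis, toward the groove/solvent side) by
    ``radial_offset`` A.  A labeled residue that is not a thymine triggers
    a warning only.
    """
    sites = []
    for strand, residue in labeled_positions:
        idx = structure.atom_index(strand, residue, ROLE_BASE)
        if structure.sequences:
            base = structure.sequences[strand][residue - 1]
            if base not in ("T", "X"):
                warnings.warn(
                    f"labeled residue {residue} on strand {strand} is {base}, not thymine",
                    stacklevel=2,
                )
        p = structure.positions[idx]
        # radial direction estimated from the local helix axis (z after building;
        # use the mean axis of the structure for generality after transforms)
        axis_point, axis_dir = _principal_axis(structure.positions)
        rel = p - axis_point
        rel_perp = rel - np.dot(rel, axis_dir) * axis_dir
        norm = np.linalg.norm(rel_perp)
        direction = rel_perp / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        sites.append(
            AttachmentSite(
                position=p + radial_offset * direction,
                residue=residue,
                strand=strand,
                atom_index=idx,
            )
        )
    return sites


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    return center, vt[0]


def write_pdb(path, structure: PseudoAtomStructure) -> None:
    """Write pseudo-atoms as HETATM records.

    Convention: atom name encodes the role (P/S/B), residue name ``DNA``,
    chain A/B for the two strands, B-factor column carries the pseudo-atom
    radius in A.
    """
    with open(path, "w") as fh:
        serial = 1
        for i in range(len(structure)):
            x, y, z = structure.positions[i]
            role = int(structure.role[i])
            chain = "AB"[int(structure.strand[i])]
            fh.write(
                f"HETATM{serial:5d} {_ROLE_NAMES[role]:<4s} DNA {chain}"
                f"{int(structure.residue_index[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{structure.radii[i]:6.2f}"
                f"          {_ROLE_ELEMENTS[role]:>2s}\n"
            )
            serial += 1
        fh.write("END\n")


def read_pdb(path) -> PseudoAtomStructure:
    """Read a PDB file into a pseudo-atom structure.

    Files written by :func:`write_pdb` (HETATM/DNA records) round-trip
    with radii taken from the B-factor column.  Any other PDB is read with
    Bio.PDB, assigning default van der Waals radii by element (1.7 A
    fallback for unknown elements, with a warning) and role code BASE for
    every atom.
    """
    own_format = True
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                if not (line.startswith("HETATM") and line[17:20].strip() == "DNA"):
                    own_format = False
                break
    if own_format:
        return _read_own_pdb(path)
    return _read_generic_pdb(path)


def _read_own_pdb(path) -> PseudoAtomStructure:
    pos, rad, res, strnd, role = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("HETATM"):
                continue
            try:
                pos.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                rad.append(float(line[60:66]))
                res.append(int(line[22:26]))
                strnd.append({"A": 0, "B": 1}[line[21]])
                role.append(_ROLE_FROM_NAME[line[12:16].strip()])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable PDB line") from exc
    return PseudoAtomStructure(
        positions=np.asarray(pos),
        radii=np.asarray(rad),
        residue_index=np.asarray(res),
        strand=np.asarray(strnd),
        role=np.asarray(role),
    )


def _read_generic_pdb(path) -> PseudoAtomStructure:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", path).get_models())
    pos, rad, res, strnd, role = [], [], [], [], []
    chains = {}
    for chain in model:
        chains.setdefault(chain.id, len(chains))
        for residue in chain:
            for atom in residue:
                element = (atom.element or "").strip().upper()
                if element not in _DEFAULT_VDW:
                    warnings.warn(
                        f"unknown element {element!r} for atom {atom.get_full_id()}; "
                        f"using radius {_FALLBACK_VDW} A",
                        stacklevel=2,
                    )
                pos.append(atom.coord.astype(float))
                rad.append(_DEFAULT_VDW.get(element, _FALLBACK_VDW))
                res.append(residue.id[1])
                strnd.append(chains[chain.id])
                role.append(ROLE_BASE)
    if not pos:
        raise ValueError(f"{path}: no atoms found")
    return PseudoAtomStructure(
        positions=np.asarray(pos),
        radii=np.asarray(rad),
        residue_index=np.asarray(res),
        strand=np.asarray(strnd),
        role=np.asarray(role),
    )
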