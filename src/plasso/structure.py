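"""Protein structure container, PDB I/O and disulphide-bridge detection.

The package works at C-alpha resolution: a structure is an ordered trace of
C-alpha positions (in Angstrom) plus the one-letter sequence, author residue
numbering, and — for cysteines — optional S-gamma positions used to detect
disulphide bridges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: maximum C-alpha virtual-bond length considered gap-free (Angstrom)
MAX_CA_CA = 4.5
MIN_CA_CA = 2.8

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for malformed or unusable structures."""


@dataclass
class DisulphideBridge:
    """A covalent (or candidate) cystine bridge between residues ``i < j``.

    Indices are 0-based positions in the internal contiguous numbering;
    ``state`` selects how the bridge is modelled downstream.
    """

    i: int
    j: int
    state: str = "oxidized"  # {reduced, oxidized, dynamic}

    def __post_init__(self):
        if self.i > self.j:
            self.i, self.j = self.j, self.i
        if self.j - self.i < 2:
            raise StructureError(f"bridge {self.i}-{self.j}: need j - i >= 2")
        if self.state not in ("reduced", "oxidized", "dynamic"):
            raise StructureError(f"unknown disulphide state {self.state!r}")


@dataclass
class Structure:
    """C-alpha trace of one chain.

    Attributes
    ----------
    residue_ids : (n,) int array
        Author residue numbers, strictly increasing.
    sequence : str
        One-letter codes, same length as the trace.
    ca_coords : (n, 3) float array, Angstrom
    sg_coords : dict[int, (3,) array]
        S-gamma positions keyed by internal residue index (cysteines only).
    chain_id : str
    """

    residue_ids: np.ndarray
    sequence: str
    ca_coords: np.ndarray
    sg_coords: dict = field(default_factory=dict)
    chain_id: str = "A"

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if len(self.sequence) != len(self.ca_coords):
            raise StructureError(
                f"sequence length {len(self.sequence)} != "
                f"{len(self.ca_coords)} coordinates"
            )
        if len(self.residue_ids) != len(self.sequence):
            raise StructureError("residue_ids length mismatch")
        if self.n_residues and np.any(np.diff(self.residue_ids) <= 0):
            raise StructureError("residue_ids must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def cysteines(self) -> list[int]:
        return [k for k, a in enumerate(self.sequence) if a == "C"]

    def chain_breaks(self) -> list[int]:
        """Indices k where the segment k -> k+1 is broken.

        A break is a jump in author numbering or a virtual bond longer than
        ``MAX_CA_CA``.
        """
        breaks = []
        d = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
        gaps = np.diff(self.residue_ids)
        for k in range(self.n_residues - 1):
            if gaps[k] != 1 or d[k] > MAX_CA_CA:
                breaks.append(k)
        return breaks

    def author_to_index(self, author_id: int) -> int:
        hits = np.nonzero(self.residue_ids == author_id)[0]
        if len(hits) != 1:
            raise StructureError(f"author residue {author_id} not present")
        return int(hits[0])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        """Rigid-body copy: x -> R x + t."""
        sg = {k: R @ v + t for k, v in self.sg_coords.items()}
        return replace(self, ca_coords=self.ca_coords @ R.T + t, sg_coords=sg)


def read_structure(path, chain: str | None = None, model: int = 1) -> Structure:
    """Read one chain of a PDB file as a C-alpha trace.

    Residues without a C-alpha atom are dropped with a warning; S-gamma
    coordinates are retained for cysteines when present.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    midx = model - 1
    if midx < 0 or midx >= len(st):
        raise StructureError(f"{path}: model {model} not present")
    mdl = st[midx]
    names = [ch.name for ch in mdl]
    if chain is None:
        if not names:
            raise StructureError(f"{path}: no chains")
        chain = names[0]
    if chain not in names:
        raise StructureError(
            f"{path}: chain {chain!r} not found; available: {names}"
        )
    ch = mdl[chain]

    ids, seq, coords, sg = [], [], [], {}
    for res in ch:
        ca = res.find_atom("CA", "*")
        if ca is None:
            logger.warning(
                "%s %s/%s %s: no CA atom, residue dropped",
                path, chain, res.seqid.num, res.name,
            )
            continue
        one = THREE_TO_ONE.get(res.name, "X")
        ids.append(res.seqid.num)
        seq.append(one)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if one == "C":
            s = res.find_atom("SG", "*")
            if s is not None:
                sg[len(ids) - 1] = np.array([s.pos.x, s.pos.y, s.pos.z])
    if not coords:
        raise StructureError(f"{path}: chain {chain} has no CA atoms")
    return Structure(
        residue_ids=np.array(ids),
        sequence="".join(seq),
        ca_coords=np.array(coords),
        sg_coords=sg,
        chain_id=chain,
    )


def write_structure(s: Structure, path) -> None:
    """Write the trace as standard PDB ATOM records (CA + cysteine SG)."""
    if s.n_residues == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "plasso"
    mdl = gemmi.Model(1)
    ch = gemmi.Chain(s.chain_id)
    for k in range(s.n_residues):
        res = gemmi.Residue()
        res.name = ONE_TO_THREE.get(s.sequence[k], "ALA")
        res.seqid = gemmi.SeqId(int(s.residue_ids[k]), " ")
        ca = gemmi.Atom()
        ca.name = "CA"
        ca.element = gemmi.Element("C")
        ca.pos = gemmi.Position(*s.ca_coords[k])
        ca.occ = 1.0
        res.add_atom(ca)
        if k in s.sg_coords:
            sg = gemmi.Atom()
            sg.name = "SG"
            sg.element = gemmi.Element("S")
            sg.pos = gemmi.Position(*np.asarray(s.sg_coords[k], dtype=float))
            sg.occ = 1.0
            res.add_atom(sg)
        ch.add_residue(res)
    mdl.add_chain(ch)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


def detect_disulphides(
    s: Structure, sg_cutoff: float = 2.5, ca_cutoff: float = 7.0
) -> list[DisulphideBridge]:
    """Pair cysteines into candidate disulphide bridges.

    When both cysteines carry an S-gamma atom the SG-SG distance is compared
    with ``sg_cutoff`` (2.5 A, generous around the 2.05 A bond length);
    otherwise the C-alpha separation is compared with ``ca_cutoff`` (7.0 A,
    chosen so that bonded cystines pass while cross-core contacts do not).
    Each cysteine joins at most one bridge; candidate pairs are accepted
    greedily by increasing distance.
    """
    cys = s.cysteines()
    cand = []
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            i, j = cys[a], cys[b]
            if j - i < 2:
                continue
            if i in s.sg_coords and j in s.sg_coords:
                d = float(np.linalg.norm(s.sg_coords[i] - s.sg_coords[j]))
                cut = sg_cutoff
            else:
                d = float(np.linalg.norm(s.ca_coords[i] - s.ca_coords[j]))
                cut = ca_cutoff
            if d < cut:
                cand.append((d, i, j))
    cand.sort()
    used: set[int] = set()
    bridges = []
    for d, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        bridges.append(DisulphideBridge(i, j))
    return bridges
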