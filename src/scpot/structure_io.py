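"""Structure reading, validation/filtering, and per-residue backbone descriptors.

Structures are parsed from PDB text (via biotite) into a light per-chain residue
model carrying only what the potentials need: the four backbone atoms N, CA, C, O,
the canonical amino-acid identity, and backbone dihedrals. Selenomethionine (MSE)
is treated as methionine; residues with any missing backbone atom are kept but
flagged incomplete so that motif extraction can exclude them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constants import BACKBONE_ATOMS, THREE_TO_ONE, ONE_TO_THREE
from .geometry import torsion

# peptide C-N distances beyond this are treated as chain breaks
PEPTIDE_BOND_MAX = 2.0


class StructureFormatError(ValueError):
    """Input does not parse as PDB."""


class StructureContentError(ValueError):
    """Parsed input holds no usable protein residues."""


@dataclass
class Residue:
    chain_id: str
    seq_index: int  # 0-based position within the chain (internal numbering)
    aa: str  # one-letter canonical code
    backbone: np.ndarray  # (4, 3) in N, CA, C, O order; NaN rows when missing
    complete: bool = True
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    author_id: int | None = None  # original PDB residue number
    icode: str = ""
    burial: int | None = None  # raw neighbor count, assigned by background_model

    def atom(self, name: str) -> np.ndarray:
        return self.backbone[BACKBONE_ATOMS.index(name)]


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None
    method: str | None = None

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def get(self, chain_id: str, seq_index: int) -> Residue:
        try:
            return self.chains[chain_id][seq_index]
        except (KeyError, IndexError):
            raise KeyError(f"no residue {chain_id}/{seq_index} in {self.id}") from None

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def backbone_array(self, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
        """All backbone coordinates of one chain as (n, 4, 3) plus a completeness
        mask of shape (n,)."""
        chain = self.chains[chain_id]
        coords = np.stack([r.backbone for r in chain]) if chain else np.zeros((0, 4, 3))
        mask = np.array([r.complete for r in chain], dtype=bool)
        return coords, mask


@dataclass
class ChainFilterCriteria:
    """Chain-level retention rules for database construction."""

    min_len: int = 40
    max_len: int = 10_000
    max_resolution: float = 2.3

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def _maybe_decompress(data: bytes) -> str:
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode("utf-8", errors="replace")


def read_structure_file(path, structure_id: str | None = None) -> Structure:
    """Read a PDB file (gzip-transparent) from disk."""
    with open(path, "rb") as fh:
        text = _maybe_decompress(fh.read())
    if structure_id is None:
        name = str(path).rsplit("/", 1)[-1]
        for suffix in (".gz", ".pdb", ".ent"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
    else:
        name = structure_id
    return read_structure(text, structure_id=name)


def read_structure(pdb_text: str, structure_id: str = "struct") -> Structure:
    """Parse PDB text into a :class:`Structure` (model 1 only).

    Alternate locations resolve to the highest-occupancy conformer. Residues with
    non-canonical names (other than MSE) are dropped; MSE maps to MET. Residues
    missing any of N/CA/C/O are flagged incomplete.
    """
    if not pdb_text or not pdb_text.strip():
        raise StructureFormatError("empty PDB input")
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several parse error types
        raise StructureFormatError(f"could not parse PDB input: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureContentError("no atoms in PDB input")

    resolution, method = _parse_header(pdb_text)
    struct = Structure(id=structure_id, resolution=resolution, method=method)

    starts = bst.get_residue_starts(atoms, add_exclusive_stop=True)
    for beg, end in zip(starts[:-1], starts[1:]):
        res_name = atoms.res_name[beg]
        aa = THREE_TO_ONE.get(res_name)
        if aa is None:
            continue
        chain_id = str(atoms.chain_id[beg])
        backbone = np.full((4, 3), np.nan)
        for k in range(beg, end):
            name = atoms.atom_name[k]
            if name == "SE" and res_name == "MSE":
                name = "SD"  # selenium is a side-chain atom; irrelevant here
            if name in BACKBONE_ATOMS:
                backbone[BACKBONE_ATOMS.index(name)] = atoms.coord[k]
        chain = struct.chains.setdefault(chain_id, [])
        chain.append(
            Residue(
                chain_id=chain_id,
                seq_index=len(chain),
                aa=aa,
                backbone=backbone,
                complete=bool(np.isfinite(backbone).all()),
                author_id=int(atoms.res_id[beg]),
                icode=str(atoms.ins_code[beg]) if hasattr(atoms, "ins_code") else "",
            )
        )
    if struct.n_residues == 0:
        raise StructureContentError("no protein residues in PDB input")
    return struct


def _parse_header(pdb_text: str) -> tuple[float | None, str | None]:
    resolution = None
    method = None
    for line in pdb_text.splitlines():
        if line.startswith("EXPDTA"):
            method = line[6:].strip()
        elif line.startswith("REMARK   2 RESOLUTION.") and "ANGSTROM" in line:
            try:
                resolution = float(line[22:].split("ANGSTROM")[0])
            except ValueError:
                pass
        elif line.startswith("ATOM"):
            break
    return resolution, method


def filter_chains(s: Structure, c: ChainFilterCriteria) -> Structure:
    """Retain only chains whose length lies within [min_len, max_len] and, when
    the structure carries a resolution, structures at or under max_resolution.

    Returns a new Structure (possibly with no chains). Structures without
    experimental metadata pass the resolution rule, so synthetic inputs survive.
    """
    out = Structure(id=s.id, resolution=s.resolution, method=s.method)
    if s.resolution is not None and s.resolution > c.max_resolution:
        return out
    for chain_id, chain in s.chains.items():
        if c.min_len <= len(chain) <= c.max_len:
            out.chains[chain_id] = chain
    return out


def compute_dihedrals(s: Structure) -> Structure:
    """Populate phi/psi/omega on every complete residue, in degrees in (-180, 180].

    Residues lacking a bonded neighbor (termini, chain breaks, incomplete
    neighbors) get None for the affected angles. Modifies ``s`` in place and
    returns it.
    """
    for chain in s.chains.values():
        for i, res in enumerate(chain):
            if not res.complete:
                continue
            prev_res = chain[i - 1] if i > 0 else None
            next_res = chain[i + 1] if i + 1 < len(chain) else None
            if prev_res is not None and prev_res.complete and _bonded(prev_res, res):
                res.phi = torsion(prev_res.atom("C"), res.atom("N"), res.atom("CA"), res.atom("C"))
                res.omega = torsion(
                    prev_res.atom("CA"), prev_res.atom("C"), res.atom("N"), res.atom("CA")
                )
            if next_res is not None and next_res.complete and _bonded(res, next_res):
                res.psi = torsion(res.atom("N"), res.atom("CA"), res.atom("C"), next_res.atom("N"))
    return s


def _bonded(a: Residue, b: Residue) -> bool:
    d = np.linalg.norm(a.atom("C") - b.atom("N"))
    return bool(d <= PEPTIDE_BOND_MAX)


def write_structure(s: Structure) -> str:
    """Serialize backbone atoms to PDB text (inverse of :func:`read_structure`)."""
    n_atoms = sum(int(np.isfinite(r.backbone[k]).all()) for r in s.residues() for k in range(4))
    atoms = bst.AtomArray(n_atoms)
    i = 0
    for chain_id, chain in s.chains.items():
        for res in chain:
            for k, name in enumerate(BACKBONE_ATOMS):
                if not np.isfinite(res.backbone[k]).all():
                    continue
                atoms.coord[i] = res.backbone[k]
                atoms.chain_id[i] = chain_id
                atoms.res_id[i] = res.author_id if res.author_id is not None else res.seq_index + 1
                atoms.res_name[i] = ONE_TO_THREE[res.aa]
                atoms.atom_name[i] = name
                atoms.element[i] = name[0]
                atoms.hetero[i] = False
                i += 1
    pdb = PDBFile()
    pdb.set_structure(atoms)
    return "\n".join(pdb.lines) + "\n"


def read_structure_list(path) -> list[str]:
    """Plain-text structure list: one path or ID per line, '#' comments allowed."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                entries.append(line)
    return entries
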