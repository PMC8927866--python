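"""Contact degree (CD) and contact databases.

CD quantifies how strongly two backbone positions are poised to host a
side-chain contact: all rotamers of all amino acids are placed at both
positions, rotamers clashing with the main chain are discarded, and CD is the
probability-weighted fraction of remaining rotamer pairs that mutually
interfere (any heavy-atom pair within 3 A):

    CD(p_i, p_j) = sum_{a,b} sum_{r_i in R_i(a)} sum_{r_j in R_j(b)}
                   C(r_i, r_j) * P(a) * P(b) * P(r_i) * P(r_j)

A CD of 0 means no placeable rotamer pair clashes (no contact); 1 means every
pair does (strongest contact). Rotamer probabilities of clash-filtered rotamers
are, by default, NOT renormalized, so heavily occluded positions contribute
less probability mass ("out of all placeable ones").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import AA_ORDER, AA_INDEX, N_AA, uniform_aa_freqs
from .sidechain import build_sidechain, N_CHI
from .structure_io import Structure, Residue

logger = logging.getLogger(__name__)

# interference rule: any heavy-atom pair between two rotamers within 3 A
INTERFERENCE_CUTOFF = 3.0
# a rotamer is disallowed when any of its atoms is within this distance of a
# backbone heavy atom of a residue other than its own and its sequence neighbors
BACKBONE_CLASH_CUTOFF = 2.5

# 11 half-open CD bins: [0, 2^-10), [2^-10, 2^-9), ..., [2^-1, 1] (last closed)
CD_BIN_EDGES = np.concatenate([[0.0], np.power(2.0, np.arange(-10, 0)), [1.0]])
N_CD_BINS = 11


@dataclass
class Rotamer:
    chis: tuple[float, ...]
    prob: float


@dataclass
class RotamerLibrary:
    """Per-amino-acid rotamers with occurrence probabilities.

    ``rotamers`` maps one-letter codes to rotamer lists (backbone-independent
    case). When ``backbone_dependent`` is set, ``binned`` maps
    (aa, phi_bin, psi_bin) on a ``bin_width``-degree grid to rotamer lists and
    ``rotamers`` holds the collapsed backbone-independent fallback.
    """

    rotamers: dict[str, list[Rotamer]]
    aa_freqs: np.ndarray = field(default_factory=uniform_aa_freqs)
    backbone_dependent: bool = False
    binned: dict[tuple[str, int, int], list[Rotamer]] = field(default_factory=dict)
    bin_width: float = 10.0
    _max_reach: float | None = field(default=None, repr=False)

    def rotamers_for(self, aa: str, phi: float | None = None, psi: float | None = None) -> list[Rotamer]:
        if self.backbone_dependent and phi is not None and psi is not None:
            key = (aa, _grid_bin(phi, self.bin_width), _grid_bin(psi, self.bin_width))
            rots = self.binned.get(key)
            if rots:
                return rots
        return self.rotamers.get(aa, [])

    @property
    def max_reach(self) -> float:
        """Largest side-chain atom distance from CA over the whole library, on a
        reference backbone frame. Used only as a conservative distance gate."""
        if self._max_reach is None:
            n = np.array([1.458, 0.0, 0.0])
            ca = np.zeros(3)
            c = np.array([-0.551, 1.422, 0.0])
            reach = 0.0
            for aa, rots in self.rotamers.items():
                for rot in rots:
                    atoms = build_sidechain(n, ca, c, aa, rot.chis)
                    if len(atoms):
                        reach = max(reach, float(np.linalg.norm(atoms - ca, axis=1).max()))
            self._max_reach = reach + 0.5  # margin for backbone-frame variation
        return self._max_reach


def _grid_bin(angle: float, width: float) -> int:
    # half-open (lo, hi] bins over (-180, 180]
    return int(np.ceil((angle + 180.0) / width) - 1)


def load_fixture_library(path=None, aa_freqs: np.ndarray | None = None) -> RotamerLibrary:
    """Load a native-dialect TSV rotamer library (the bundled fixture by default).

    Columns: aa, rotamer, prob, chi1..chi4 (unused chis blank).
    """
    if path is None:
        path = resources.files("scpot.data") / "fixture_rotamers.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    rotamers: dict[str, list[Rotamer]] = {}
    for _, row in df.iterrows():
        aa = str(row["aa"])
        chis = tuple(
            float(row[f"chi{k}"])
            for k in range(1, N_CHI[aa] + 1)
            if f"chi{k}" in row and pd.notna(row[f"chi{k}"])
        )
        rotamers.setdefault(aa, []).append(Rotamer(chis=chis, prob=float(row["prob"])))
    lib = RotamerLibrary(rotamers=rotamers)
    if aa_freqs is not None:
        lib.aa_freqs = np.asarray(aa_freqs, float)
    _validate_library(lib)
    return lib


def load_dunbrack_library(path, aa_freqs: np.ndarray | None = None) -> RotamerLibrary:
    """Load a Dunbrack-2010-style backbone-dependent rotamer library.

    Expects whitespace-separated rows:
    aa3 phi psi count r1 r2 r3 r4 prob chi1 chi2 chi3 chi4 [sigmas...]
    """
    from .constants import THREE_TO_ONE

    binned: dict[tuple[str, int, int], list[Rotamer]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 13:
                continue
            aa = THREE_TO_ONE.get(parts[0].upper())
            if aa is None:
                continue
            phi, psi = float(parts[1]), float(parts[2])
            if phi >= 180.0 or psi >= 180.0:  # duplicated wrap-around rows
                continue
            prob = float(parts[8])
            chis = tuple(float(x) for x in parts[9 : 9 + N_CHI[aa]])
            key = (aa, _grid_bin(phi + 1e-9, 10.0), _grid_bin(psi + 1e-9, 10.0))
            binned.setdefault(key, []).append(Rotamer(chis=chis, prob=prob))
    # collapsed backbone-independent fallback: average probability over bins of
    # the highest-probability rotamers
    collapsed: dict[str, dict[tuple, tuple[float, np.ndarray]]] = {}
    for (aa, _, _), rots in binned.items():
        acc = collapsed.setdefault(aa, {})
        for rot in rots:
            key = tuple(round(c / 120.0) for c in rot.chis)  # crude rotameric class
            w, chi_sum = acc.get(key, (0.0, np.zeros(len(rot.chis))))
            acc[key] = (w + rot.prob, chi_sum + rot.prob * np.array(rot.chis))
    fallback: dict[str, list[Rotamer]] = {}
    for aa, acc in collapsed.items():
        total = sum(w for w, _ in acc.values())
        fallback[aa] = [
            Rotamer(chis=tuple(chi_sum / w), prob=w / total)
            for w, chi_sum in acc.values()
            if w > 0
        ]
    lib = RotamerLibrary(rotamers=fallback, backbone_dependent=True, binned=binned)
    if aa_freqs is not None:
        lib.aa_freqs = np.asarray(aa_freqs, float)
    return lib


def _validate_library(lib: RotamerLibrary) -> None:
    for aa, rots in lib.rotamers.items():
        total = sum(r.prob for r in rots)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"rotamer probabilities for {aa} sum to {total}, not 1")
    if not np.isclose(lib.aa_freqs.sum(), 1.0, atol=1e-6) or (lib.aa_freqs < 0).any():
        raise ValueError("amino-acid background frequencies must be a distribution")


def compute_aa_freqs(db: list[Structure]) -> np.ndarray:
    """Amino-acid background frequencies over all residues of a database."""
    counts = np.zeros(N_AA)
    for s in db:
        for res in s.residues():
            counts[AA_INDEX[res.aa]] += 1
    if counts.sum() == 0:
        raise ValueError("empty structure database")
    return counts / counts.sum()


@dataclass
class ContactRecord:
    structure_id: str
    chain_i: str
    pos_i: int
    chain_j: str
    pos_j: int
    aa_i: str
    aa_j: str
    cd: float
    seq_sep: int  # residues between the contacting positions; -1 for inter-chain

    @property
    def interchain(self) -> bool:
        return self.seq_sep < 0


@dataclass
class ContactDatabase:
    records: list[ContactRecord]
    bin_edges: np.ndarray = field(default_factory=lambda: CD_BIN_EDGES.copy())
    per_bin_counts: np.ndarray | None = None

    def records_in_bin(self, k: int) -> list[ContactRecord]:
        return [r for r in self.records if cd_bin(r.cd) == k]


def cd_bin(cd: float) -> int:
    """Map a CD value in [0, 1] to its bin index (0..10); half-open bins, with
    the last bin [1/2, 1] closed."""
    if not 0.0 <= cd <= 1.0:
        raise ValueError(f"CD out of range: {cd}")
    if cd >= 0.5:
        return N_CD_BINS - 1
    idx = int(np.searchsorted(CD_BIN_EDGES, cd, side="right")) - 1
    return idx


def _backbone_context(s: Structure, exclude: Residue) -> np.ndarray:
    """Backbone heavy atoms of all residues except ``exclude`` and its two
    sequence neighbors."""
    rows = []
    for chain_id, chain in s.chains.items():
        for res in chain:
            if chain_id == exclude.chain_id and abs(res.seq_index - exclude.seq_index) <= 1:
                continue
            bb = res.backbone[np.isfinite(res.backbone).all(axis=1)]
            if len(bb):
                rows.append(bb)
    if not rows:
        return np.zeros((0, 3))
    return np.concatenate(rows)


def allowed_rotamers(
    s: Structure,
    pos: tuple[str, int],
    lib: RotamerLibrary,
    clash_threshold: float = BACKBONE_CLASH_CUTOFF,
    renormalize: bool = False,
) -> dict[str, list[tuple[np.ndarray, float]]]:
    """Rotamers placeable at ``pos`` = (chain_id, seq_index).

    Returns, per amino acid, the (side-chain atoms, probability) of every
    rotamer whose atoms all stay at least ``clash_threshold`` from the backbone
    of non-adjacent residues. Probabilities are P(r) from the library,
    unrenormalized unless ``renormalize`` is set.
    """
    res = s.get(*pos)
    if not res.complete:
        raise ValueError(f"residue {pos} has an incomplete backbone")
    context = _backbone_context(s, res)
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    out: dict[str, list[tuple[np.ndarray, float]]] = {}
    for aa in AA_ORDER:
        survivors = []
        for rot in lib.rotamers_for(aa, res.phi, res.psi):
            atoms = build_sidechain(n, ca, c, aa, rot.chis)
            if len(atoms) and len(context):
                if cdist(atoms, context).min() < clash_threshold:
                    continue
            survivors.append((atoms, rot.prob))
        if renormalize and survivors:
            total = sum(p for _, p in survivors)
            survivors = [(a, p / total) for a, p in survivors]
        out[aa] = survivors
    return out


def contact_degree(
    s: Structure,
    pos_i: tuple[str, int],
    pos_j: tuple[str, int],
    lib: RotamerLibrary,
    aa_freqs: np.ndarray | None = None,
    interference_cutoff: float = INTERFERENCE_CUTOFF,
    clash_threshold: float = BACKBONE_CLASH_CUTOFF,
    renormalize: bool = False,
    _allowed_i: dict | None = None,
    _allowed_j: dict | None = None,
) -> float:
    """Contact degree between two backbone positions, in [0, 1]."""
    freqs = np.asarray(aa_freqs, float) if aa_freqs is not None else lib.aa_freqs
    res_i, res_j = s.get(*pos_i), s.get(*pos_j)
    d_ca = float(np.linalg.norm(res_i.atom("CA") - res_j.atom("CA")))
    if d_ca > 2.0 * lib.max_reach + interference_cutoff:
        return 0.0
    ai = _allowed_i if _allowed_i is not None else allowed_rotamers(s, pos_i, lib, clash_threshold, renormalize)
    aj = _allowed_j if _allowed_j is not None else allowed_rotamers(s, pos_j, lib, clash_threshold, renormalize)
    flat_i = _flatten(ai, freqs)
    flat_j = _flatten(aj, freqs)
    if flat_i is None or flat_j is None:
        logger.warning("no placeable rotamer at %s or %s; CD defined as 0", pos_i, pos_j)
        return 0.0
    atoms_i, rot_of_i, w_i = flat_i
    atoms_j, rot_of_j, w_j = flat_j
    if len(atoms_i) == 0 or len(atoms_j) == 0:
        return 0.0  # only glycine/alanine-like content with no atoms to clash
    close = cdist(atoms_i, atoms_j) < interference_cutoff
    c_mat = np.zeros((len(w_i), len(w_j)), dtype=bool)
    ii, jj = np.nonzero(close)
    c_mat[rot_of_i[ii], rot_of_j[jj]] = True
    return float(w_i @ c_mat @ w_j)


def _flatten(allowed: dict, freqs: np.ndarray):
    """Stack all placed rotamers: atom coordinates, owning-rotamer index, and the
    per-rotamer weight P(a) * P(r)."""
    coords, rot_of, weights = [], [], []
    r = 0
    any_rotamer = False
    for aa, survivors in allowed.items():
        fa = freqs[AA_INDEX[aa]]
        for atoms, prob in survivors:
            any_rotamer = True
            weights.append(fa * prob)
            if len(atoms):
                coords.append(atoms)
                rot_of.append(np.full(len(atoms), r, dtype=int))
            r += 1
    if not any_rotamer:
        return None
    atom_arr = np.concatenate(coords) if coords else np.zeros((0, 3))
    rot_arr = np.concatenate(rot_of) if rot_of else np.zeros(0, dtype=int)
    return atom_arr, rot_arr, np.asarray(weights)


def _window_complete(chain: list[Residue], center: int, flank: int) -> bool:
    if center - flank < 0 or center + flank >= len(chain):
        return False
    return all(chain[k].complete for k in range(center - flank, center + flank + 1))


def enumerate_contacts(
    s: Structure,
    lib: RotamerLibrary,
    min_seq_sep: int = 5,
    flank: int = 2,
    aa_freqs: np.ndarray | None = None,
    min_cd: float = 0.0,
    renormalize: bool = False,
) -> list[ContactRecord]:
    """All residue-pair contacts of a structure with their contact degrees.

    Intra-chain pairs need at least ``min_seq_sep`` residues between the two
    positions; inter-chain pairs are unrestricted. A pair is skipped when either
    (2*flank+1)-residue window is incomplete. Records with cd < ``min_cd`` are
    dropped (use 0.0 to keep all, including non-contacts).
    """
    freqs = np.asarray(aa_freqs, float) if aa_freqs is not None else lib.aa_freqs
    eligible: list[tuple[str, int]] = []
    for chain_id, chain in s.chains.items():
        for res in chain:
            if _window_complete(chain, res.seq_index, flank):
                eligible.append((chain_id, res.seq_index))
    allowed_cache: dict[tuple[str, int], dict] = {}

    def allowed_at(pos):
        if pos not in allowed_cache:
            allowed_cache[pos] = allowed_rotamers(s, pos, lib, renormalize=renormalize)
        return allowed_cache[pos]

    records = []
    gate = 2.0 * lib.max_reach + INTERFERENCE_CUTOFF
    for idx_a in range(len(eligible)):
        for idx_b in range(idx_a + 1, len(eligible)):
            (ci, pi), (cj, pj) = eligible[idx_a], eligible[idx_b]
            if ci == cj:
                sep = abs(pj - pi) - 1
                if sep < min_seq_sep:
                    continue
            else:
                sep = -1
            ri, rj = s.get(ci, pi), s.get(cj, pj)
            if np.linalg.norm(ri.atom("CA") - rj.atom("CA")) > gate:
                cd = 0.0
            else:
                cd = contact_degree(
                    s, (ci, pi), (cj, pj), lib, freqs,
                    _allowed_i=allowed_at((ci, pi)), _allowed_j=allowed_at((cj, pj)),
                )
            if cd < min_cd:
                continue
            records.append(
                ContactRecord(
                    structure_id=s.id, chain_i=ci, pos_i=pi, chain_j=cj, pos_j=pj,
                    aa_i=ri.aa, aa_j=rj.aa, cd=cd, seq_sep=sep,
                )
            )
    return records


def sample_contact_database(
    records: list[ContactRecord], per_bin: int, seed: int
) -> ContactDatabase:
    """Sample min(per_bin, bin size) contacts uniformly without replacement from
    each of the 11 CD bins. Deterministic given the seed."""
    if not records:
        raise ValueError("no contact records to sample from")
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    by_bin: dict[int, list[ContactRecord]] = {k: [] for k in range(N_CD_BINS)}
    for rec in records:
        by_bin[cd_bin(rec.cd)].append(rec)
    sampled: list[ContactRecord] = []
    counts = np.zeros(N_CD_BINS, dtype=int)
    for k in range(N_CD_BINS):
        pool = by_bin[k]
        take = min(per_bin, len(pool))
        if take < per_bin:
            logger.info("CD bin %d holds only %d records (requested %d)", k, len(pool), per_bin)
        if take:
            idx = rng.choice(len(pool), size=take, replace=False)
            sampled.extend(pool[int(i)] for i in np.sort(idx))
        counts[k] = take
    return ContactDatabase(records=sampled, per_bin_counts=counts)


def contacts_to_frame(records: list[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "structure_id": r.structure_id, "chain_i": r.chain_i, "pos_i": r.pos_i,
                "chain_j": r.chain_j, "pos_j": r.pos_j, "aa_i": r.aa_i, "aa_j": r.aa_j,
                "cd": r.cd, "seq_sep": r.seq_sep,
            }
            for r in records
        ]
    )


def frame_to_contacts(df: pd.DataFrame) -> list[ContactRecord]:
    return [
        ContactRecord(
            structure_id=str(row.structure_id), chain_i=str(row.chain_i), pos_i=int(row.pos_i),
            chain_j=str(row.chain_j), pos_j=int(row.pos_j), aa_i=str(row.aa_i),
            aa_j=str(row.aa_j), cd=float(row.cd), seq_sep=int(row.seq_sep),
        )
        for row in df.itertuples()
    ]
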