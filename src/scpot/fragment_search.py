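"""Interaction motifs and backbone-RMSD fragment search.

An interaction motif is a pair of backbone segments centered on two contacting
residues, with flank width k in {0, 1, 2} (1x1, 3x3, 5x5 motifs). Searching a
structure database for all same-size two-segment fragments within a best-fit
backbone RMSD cutoff of the query yields the match ensemble whose central-pair
amino-acid statistics condition the structure-conditioned energies.

The scan is exhaustive over all unordered placements of two disjoint windows in
each database structure; both assignments of query segments to target windows
are evaluated and the better one kept (with the swap recorded so that pair
counts can be transposed downstream). A central-CA distance prefilter, derived
conservatively from the cutoff, prunes candidates without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch_rmsd, kabsch_rmsd_many  # noqa: F401  (re-exported)
from .structure_io import Structure

# default best-fit RMSD cutoffs by flank width (1x1, 3x3, 5x5 motifs)
DEFAULT_RMSD_CUTOFFS = {0: 1.0, 1: 0.79, 2: 0.77}
DEFAULT_MAX_COUNT = 50_000


def default_rmsd_cutoff(flank: int) -> float:
    """Default RMSD cutoff (A) for a motif of the given flank width."""
    try:
        return DEFAULT_RMSD_CUTOFFS[flank]
    except KeyError:
        raise ValueError(f"flank must be one of {sorted(DEFAULT_RMSD_CUTOFFS)}, got {flank}") from None


@dataclass
class Motif:
    """Two backbone segments centered on a contacting residue pair."""

    structure_id: str
    flank: int
    # (chain_id, start_index) of each (2*flank+1)-residue segment; segment 1 is
    # the one whose central residue has the lower canonical (chain, pos) order
    seg1: tuple[str, int]
    seg2: tuple[str, int]
    coords: np.ndarray  # (2 * (2k+1) * 4, 3), atoms N/CA/C/O per residue
    aa_i: str = "?"
    aa_j: str = "?"

    @property
    def seg_len(self) -> int:
        return 2 * self.flank + 1

    @property
    def n_atoms(self) -> int:
        return 2 * self.seg_len * 4

    def central_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        k = self.flank
        return (self.seg1[0], self.seg1[1] + k), (self.seg2[0], self.seg2[1] + k)


@dataclass
class Match:
    structure_id: str
    seg1: tuple[str, int]  # window aligned to the query's first segment
    seg2: tuple[str, int]
    rmsd: float
    swapped: bool
    aa_i: str  # central amino acids, order corrected for the swap
    aa_j: str
    # central-residue descriptors (phi, psi, omega, burial) in aligned order
    desc_i: tuple = (None, None, None, None)
    desc_j: tuple = (None, None, None, None)


@dataclass
class MatchEnsemble:
    query: Motif
    matches: list[Match]
    cutoff: float
    max_count: int = DEFAULT_MAX_COUNT

    def __len__(self) -> int:
        return len(self.matches)

    def truncated(self, max_matches: int | None = None, rmsd_cap: float | None = None) -> "MatchEnsemble":
        """A new ensemble restricted to the lowest-RMSD matches by count and/or
        RMSD cap (matches are already in ascending-RMSD order)."""
        matches = self.matches
        if rmsd_cap is not None:
            matches = [m for m in matches if m.rmsd <= rmsd_cap]
        if max_matches is not None:
            matches = matches[:max_matches]
        cutoff = rmsd_cap if rmsd_cap is not None else self.cutoff
        return MatchEnsemble(query=self.query, matches=list(matches), cutoff=cutoff,
                             max_count=max_matches or self.max_count)


def extract_motif(s: Structure, pos_i: tuple[str, int], pos_j: tuple[str, int], flank: int) -> Motif:
    """Build the flank-k interaction motif centered on residues pos_i and pos_j.

    Raises ValueError when a window runs off its chain, contains an incomplete
    residue, or the two windows overlap.
    """
    if flank not in (0, 1, 2):
        raise ValueError(f"flank must be 0, 1 or 2, got {flank}")
    if (pos_j[0], pos_j[1]) < (pos_i[0], pos_i[1]):
        pos_i, pos_j = pos_j, pos_i
    seg_len = 2 * flank + 1
    segs = []
    for chain_id, pos in (pos_i, pos_j):
        chain = s.chains.get(chain_id)
        if chain is None:
            raise KeyError(f"no chain {chain_id} in {s.id}")
        start = pos - flank
        if start < 0 or pos + flank >= len(chain):
            raise ValueError(f"window around {chain_id}/{pos} runs off the chain")
        window = chain[start : start + seg_len]
        if not all(r.complete for r in window):
            raise ValueError(f"incomplete backbone in window around {chain_id}/{pos}")
        segs.append((chain_id, start, np.concatenate([r.backbone for r in window])))
    if pos_i[0] == pos_j[0] and abs(pos_i[1] - pos_j[1]) < seg_len:
        raise ValueError("motif segments overlap")
    (c1, s1, x1), (c2, s2, x2) = segs
    return Motif(
        structure_id=s.id, flank=flank, seg1=(c1, s1), seg2=(c2, s2),
        coords=np.concatenate([x1, x2]),
        aa_i=s.get(*pos_i).aa, aa_j=s.get(*pos_j).aa,
    )


def _chain_windows(s: Structure, seg_len: int) -> list[tuple[str, int, np.ndarray]]:
    """All complete (chain, start, coords) windows of length seg_len."""
    out = []
    for chain_id in s.chains:
        coords, mask = s.backbone_array(chain_id)
        n = len(mask)
        for start in range(n - seg_len + 1):
            if mask[start : start + seg_len].all():
                out.append((chain_id, start, coords[start : start + seg_len].reshape(-1, 3)))
    return out


@dataclass
class _StructureEntry:
    windows: list[tuple[str, int]]
    pairs: np.ndarray  # (n_pairs, 2) window indices, a < b
    fwd: np.ndarray  # (n_pairs, 2 * seg_len * 4, 3) coords [win_a; win_b]
    rev: np.ndarray  # [win_b; win_a]
    ca_dist: np.ndarray  # central-CA distance per pair


@dataclass
class FragmentIndex:
    """Precomputed candidate window pairs for every structure of a database.

    The two-window coordinate stacks are query-independent, so building them
    once amortizes the enumeration cost over many searches with the same
    segment length.
    """

    seg_len: int
    flank: int
    entries: dict[int, _StructureEntry]  # keyed by structure position in db


def build_index(db: list[Structure], flank: int) -> FragmentIndex:
    seg_len = 2 * flank + 1
    entries = {}
    ca_idx = flank * 4 + 1
    for si, s in enumerate(db):
        windows = _chain_windows(s, seg_len)
        pairs = []
        for a in range(len(windows)):
            ca_chain, ca_start, _ = windows[a]
            for b in range(a + 1, len(windows)):
                cb_chain, cb_start, _ = windows[b]
                if ca_chain == cb_chain and abs(cb_start - ca_start) < seg_len + 1:
                    continue  # overlapping or directly abutting windows
                pairs.append((a, b))
        if not pairs:
            continue
        pair_arr = np.array(pairs, dtype=int)
        coords = np.stack([w[2] for w in windows])
        fwd = np.concatenate([coords[pair_arr[:, 0]], coords[pair_arr[:, 1]]], axis=1)
        rev = np.concatenate([coords[pair_arr[:, 1]], coords[pair_arr[:, 0]]], axis=1)
        ca_dist = np.linalg.norm(
            coords[pair_arr[:, 0], ca_idx] - coords[pair_arr[:, 1], ca_idx], axis=1
        )
        entries[si] = _StructureEntry(
            windows=[(w[0], w[1]) for w in windows], pairs=pair_arr,
            fwd=fwd, rev=rev, ca_dist=ca_dist,
        )
    return FragmentIndex(seg_len=seg_len, flank=flank, entries=entries)


def _residue_descriptor(s: Structure, chain_id: str, idx: int) -> tuple:
    r = s.get(chain_id, idx)
    return (r.phi, r.psi, r.omega, r.burial)


def search_matches(
    q: Motif,
    db: list[Structure],
    cutoff: float | None = None,
    max_count: int = DEFAULT_MAX_COUNT,
    include_self: bool = True,
    prefilter: bool = True,
    index: FragmentIndex | None = None,
) -> MatchEnsemble:
    """Collect all two-window fragments in ``db`` within ``cutoff`` RMSD of the
    query motif, sorted by ascending RMSD and truncated to ``max_count``.

    Both windows of a candidate come from one structure (same or different
    chains); same-chain windows must be separated by at least one residue.
    Ties in RMSD break by (structure_id, segment addresses). Pass a prebuilt
    :class:`FragmentIndex` to amortize candidate enumeration over many queries.
    """
    if not db:
        raise ValueError("empty structure database")
    if cutoff is None:
        cutoff = default_rmsd_cutoff(q.flank)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if index is None:
        index = build_index(db, q.flank)
    elif index.flank != q.flank:
        raise ValueError(f"index built for flank {index.flank}, query has {q.flank}")
    seg_len = q.seg_len
    k = q.flank
    # conservative central-CA distance screen: for any two points, the change in
    # their mutual distance under a superposition with RMSD r is at most
    # 2 * sqrt(n) * r (each point deviates at most sqrt(n) * r)
    ca_slack = 2.0 * np.sqrt(q.n_atoms) * cutoff
    q_ca1 = q.coords[(k * 4) + 1]
    q_ca2 = q.coords[(seg_len + k) * 4 + 1]
    q_ca_dist = np.linalg.norm(q_ca1 - q_ca2)

    found: list[Match] = []
    for si, entry in index.entries.items():
        s = db[si]
        if prefilter:
            keep = np.nonzero(np.abs(entry.ca_dist - q_ca_dist) <= ca_slack)[0]
            if keep.size == 0:
                continue
        else:
            keep = np.arange(len(entry.pairs))
        r_fwd = kabsch_rmsd_many(q.coords, entry.fwd[keep])
        r_rev = kabsch_rmsd_many(q.coords, entry.rev[keep])
        hit = np.minimum(r_fwd, r_rev) <= cutoff
        for pos in np.nonzero(hit)[0]:
            a, b = entry.pairs[keep[pos]]
            rf, rr = r_fwd[pos], r_rev[pos]
            swapped = bool(rr < rf)
            rmsd = float(min(rf, rr))
            seg1, seg2 = (entry.windows[b], entry.windows[a]) if swapped else (
                entry.windows[a], entry.windows[b])
            if not include_self and s.id == q.structure_id and {seg1, seg2} == {q.seg1, q.seg2}:
                continue
            c1 = s.get(seg1[0], seg1[1] + k)
            c2 = s.get(seg2[0], seg2[1] + k)
            found.append(
                Match(
                    structure_id=s.id, seg1=seg1, seg2=seg2, rmsd=rmsd, swapped=swapped,
                    aa_i=c1.aa, aa_j=c2.aa,
                    desc_i=_residue_descriptor(s, seg1[0], seg1[1] + k),
                    desc_j=_residue_descriptor(s, seg2[0], seg2[1] + k),
                )
            )
    found.sort(key=lambda m: (m.rmsd, m.structure_id, m.seg1, m.seg2))
    return MatchEnsemble(query=q, matches=found[:max_count], cutoff=cutoff, max_count=max_count)


def ensemble_to_frame(ens: MatchEnsemble) -> pd.DataFrame:
    rows = []
    for m in ens.matches:
        rows.append(
            {
                "structure_id": m.structure_id,
                "chain_1": m.seg1[0], "start_1": m.seg1[1],
                "chain_2": m.seg2[0], "start_2": m.seg2[1],
                "rmsd": m.rmsd, "swapped": int(m.swapped),
                "aa_i": m.aa_i, "aa_j": m.aa_j,
                "phi_i": m.desc_i[0], "psi_i": m.desc_i[1],
                "omega_i": m.desc_i[2], "burial_i": m.desc_i[3],
                "phi_j": m.desc_j[0], "psi_j": m.desc_j[1],
                "omega_j": m.desc_j[2], "burial_j": m.desc_j[3],
            }
        )
    return pd.DataFrame(rows)


def frame_to_matches(df: pd.DataFrame) -> list[Match]:
    def _num(x):
        return None if pd.isna(x) else float(x)

    matches = []
    for row in df.itertuples():
        matches.append(
            Match(
                structure_id=str(row.structure_id),
                seg1=(str(row.chain_1), int(row.start_1)),
                seg2=(str(row.chain_2), int(row.start_2)),
                rmsd=float(row.rmsd), swapped=bool(row.swapped),
                aa_i=str(row.aa_i), aa_j=str(row.aa_j),
                desc_i=(_num(row.phi_i), _num(row.psi_i), _num(row.omega_i),
                        None if pd.isna(row.burial_i) else int(row.burial_i)),
                desc_j=(_num(row.phi_j), _num(row.psi_j), _num(row.omega_j),
                        None if pd.isna(row.burial_j) else int(row.burial_j)),
            )
        )
    return matches
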