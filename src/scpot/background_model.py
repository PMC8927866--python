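"""Hierarchical first-order pseudo-energy E1 over backbone dihedral and burial bins.

E1(a | m) scores how much amino acid ``a`` prefers the backbone state ``m`` of a
residue, as a sum of three conditional log-odds potentials trained in sequence:

1. phi/psi: 36 x 36 uniform 10-degree bins; observed counts of each amino acid
   per bin against counts expected from its database frequency times the bin
   occupancy.
2. omega: coarse cis/trans bins; observed counts against counts expected given
   each observation's phi/psi preferences.
3. burial: neighbor-count levels (CA atoms within a radius, excluding sequence
   neighbors), binned by training-set quantiles; observed against expected given
   phi/psi and omega.

The burial metric is a standard coordination-number proxy; the hierarchy, not
the particular metric, carries the modeling content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import AA_INDEX, N_AA
from .structure_io import Structure

logger = logging.getLogger(__name__)

PHI_PSI_BIN_WIDTH = 10.0
N_PHI_PSI_BINS = 36
DEFAULT_BURIAL_RADIUS = 12.0
DEFAULT_BURIAL_LEVELS = 5
OMEGA_CIS_RANGE = (-30.0, 30.0)
MIN_OMEGA_OBS = 50
DEFAULT_PSEUDOCOUNT = 1.0


def angle_bin(angle: float, width: float = PHI_PSI_BIN_WIDTH) -> int:
    """Half-open (lo, hi] bin index over (-180, 180]; -180 maps to the first bin."""
    idx = int(np.ceil((angle + 180.0) / width)) - 1
    return int(np.clip(idx, 0, int(360.0 / width) - 1))


def omega_bin(omega: float, cis_range=OMEGA_CIS_RANGE) -> int:
    """0 = cis ([-30, 30] by default), 1 = trans (remainder)."""
    return 0 if cis_range[0] <= omega <= cis_range[1] else 1


@dataclass
class BackgroundModel:
    phi_psi_energy: np.ndarray  # (36, 36, 20)
    omega_energy: np.ndarray  # (n_omega_bins, 20); single row of zeros when merged
    burial_energy: np.ndarray  # (n_levels, 20)
    burial_edges: np.ndarray  # interior quantile edges on raw neighbor counts
    aa_freqs: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    omega_cis_range: tuple[float, float] = OMEGA_CIS_RANGE
    burial_radius: float = DEFAULT_BURIAL_RADIUS

    @property
    def n_burial_levels(self) -> int:
        return self.burial_energy.shape[0]

    def burial_bin(self, burial_count: int) -> int:
        return int(np.searchsorted(self.burial_edges, burial_count, side="right"))

    def to_json(self) -> str:
        return json.dumps(
            {
                "phi_psi_energy": self.phi_psi_energy.tolist(),
                "omega_energy": self.omega_energy.tolist(),
                "burial_energy": self.burial_energy.tolist(),
                "burial_edges": self.burial_edges.tolist(),
                "aa_freqs": self.aa_freqs.tolist(),
                "pseudocount": self.pseudocount,
                "omega_cis_range": list(self.omega_cis_range),
                "burial_radius": self.burial_radius,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BackgroundModel":
        d = json.loads(text)
        return cls(
            phi_psi_energy=np.array(d["phi_psi_energy"]),
            omega_energy=np.array(d["omega_energy"]),
            burial_energy=np.array(d["burial_energy"]),
            burial_edges=np.array(d["burial_edges"]),
            aa_freqs=np.array(d["aa_freqs"]),
            pseudocount=float(d["pseudocount"]),
            omega_cis_range=tuple(d["omega_cis_range"]),
            burial_radius=float(d["burial_radius"]),
        )

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        """A flat model: E1 = 0 everywhere, uniform amino-acid frequencies."""
        return cls(
            phi_psi_energy=np.zeros((N_PHI_PSI_BINS, N_PHI_PSI_BINS, N_AA)),
            omega_energy=np.zeros((1, N_AA)),
            burial_energy=np.zeros((1, N_AA)),
            burial_edges=np.array([]),
            aa_freqs=np.full(N_AA, 1.0 / N_AA),
        )


def raw_burial_count(s: Structure, pos: tuple[str, int], radius: float = DEFAULT_BURIAL_RADIUS) -> int:
    """Number of CA atoms within ``radius`` of the CA at ``pos``, excluding the
    residue itself and its +/-1 sequence neighbors."""
    res = s.get(*pos)
    ca = res.atom("CA")
    if not np.isfinite(ca).all():
        raise ValueError(f"no CA at {pos}")
    count = 0
    for chain_id, chain in s.chains.items():
        for other in chain:
            if chain_id == res.chain_id and abs(other.seq_index - res.seq_index) <= 1:
                continue
            oca = other.atom("CA")
            if np.isfinite(oca).all() and np.linalg.norm(oca - ca) <= radius:
                count += 1
    return count


def assign_burial(db: list[Structure], radius: float = DEFAULT_BURIAL_RADIUS) -> None:
    """Populate ``Residue.burial`` (raw neighbor counts) on every structure."""
    for s in db:
        residues = [r for r in s.residues() if np.isfinite(r.atom("CA")).all()]
        if not residues:
            continue
        cas = np.stack([r.atom("CA") for r in residues])
        d = cdist(cas, cas)
        within = d <= radius
        for i, ri in enumerate(residues):
            n = 0
            for j in np.nonzero(within[i])[0]:
                rj = residues[j]
                if ri.chain_id == rj.chain_id and abs(ri.seq_index - rj.seq_index) <= 1:
                    continue
                n += 1
            ri.burial = n


def burial_level(s: Structure, pos: tuple[str, int], bg: "BackgroundModel") -> int:
    """Burial level of a residue under a trained model's quantile edges."""
    return bg.burial_bin(raw_burial_count(s, pos, bg.burial_radius))


def train_background(
    db: list[Structure],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_burial_levels: int = DEFAULT_BURIAL_LEVELS,
    burial_radius: float = DEFAULT_BURIAL_RADIUS,
    omega_cis_range: tuple[float, float] = OMEGA_CIS_RANGE,
    min_omega_obs: int = MIN_OMEGA_OBS,
) -> BackgroundModel:
    """Train the three-tier hierarchical background model on a structure database.

    Residues need dihedrals populated (compute_dihedrals); burial counts are
    assigned here when missing.
    """
    if not db:
        raise ValueError("empty training database")
    if any(r.burial is None for s in db for r in s.residues()):
        assign_burial(db, burial_radius)

    residues = [r for s in db for r in s.residues()]
    if not residues:
        raise ValueError("no residues in training database")
    aa_counts = np.zeros(N_AA)
    for r in residues:
        aa_counts[AA_INDEX[r.aa]] += 1
    aa_freqs = aa_counts / aa_counts.sum()
    eps = pseudocount

    # --- tier 1: phi/psi ---
    nb = N_PHI_PSI_BINS
    obs_pp = np.zeros((nb, nb, N_AA))
    for r in residues:
        if r.phi is not None and r.psi is not None:
            obs_pp[angle_bin(r.phi), angle_bin(r.psi), AA_INDEX[r.aa]] += 1
    bin_tot = obs_pp.sum(axis=2, keepdims=True)
    exp_pp = aa_freqs[None, None, :] * bin_tot
    e_pp = -np.log((obs_pp + eps) / (exp_pp + eps))

    def p_given_pp(r) -> np.ndarray:
        """P(a | phi/psi bin) under tier 1; database frequencies when undefined."""
        if r.phi is None or r.psi is None:
            return aa_freqs
        w = aa_freqs * np.exp(-e_pp[angle_bin(r.phi), angle_bin(r.psi)])
        return w / w.sum()

    # --- tier 2: omega, conditioned on phi/psi expectations ---
    omega_res = [r for r in residues if r.omega is not None]
    obs_om = np.zeros((2, N_AA))
    exp_om = np.zeros((2, N_AA))
    for r in omega_res:
        b = omega_bin(r.omega, omega_cis_range)
        obs_om[b, AA_INDEX[r.aa]] += 1
        exp_om[b] += p_given_pp(r)
    sparse = obs_om.sum(axis=1) < min_omega_obs
    if sparse.any():
        logger.info("merging sparse omega bin(s) %s into a single bin", np.nonzero(sparse)[0])
        e_om = np.zeros((1, N_AA))
        om_bin_of = lambda omega: 0  # noqa: E731
    else:
        e_om = -np.log((obs_om + eps) / (exp_om + eps))
        om_bin_of = lambda omega: omega_bin(omega, omega_cis_range)  # noqa: E731

    def e_omega_term(r) -> np.ndarray:
        if r.omega is None:
            return np.zeros(N_AA)
        return e_om[om_bin_of(r.omega)]

    # --- tier 3: burial, conditioned on phi/psi and omega ---
    burial_vals = np.array([r.burial for r in residues if r.burial is not None])
    if burial_vals.size == 0 or n_burial_levels <= 1:
        edges = np.array([])
    else:
        qs = np.quantile(burial_vals, np.linspace(0, 1, n_burial_levels + 1)[1:-1])
        edges = np.unique(qs)
        # degenerate quantiles (ties at the extremes) would create empty levels
        edges = edges[(edges > burial_vals.min()) & (edges <= burial_vals.max())]
    n_levels = len(edges) + 1
    obs_bur = np.zeros((n_levels, N_AA))
    exp_bur = np.zeros((n_levels, N_AA))
    for r in residues:
        if r.burial is None:
            continue
        lvl = int(np.searchsorted(edges, r.burial, side="right"))
        obs_bur[lvl, AA_INDEX[r.aa]] += 1
        w = p_given_pp(r) * np.exp(-e_omega_term(r))
        exp_bur[lvl] += w / w.sum()
    e_bur = -np.log((obs_bur + eps) / (exp_bur + eps))

    return BackgroundModel(
        phi_psi_energy=e_pp, omega_energy=e_om, burial_energy=e_bur,
        burial_edges=edges, aa_freqs=aa_freqs, pseudocount=eps,
        omega_cis_range=omega_cis_range, burial_radius=burial_radius,
    )


def e1(
    bg: BackgroundModel,
    aa: str | int,
    phi: float | None,
    psi: float | None,
    omega: float | None,
    burial: int | None,
) -> float:
    """First-order pseudo-energy of an amino acid in a backbone state.

    Undefined descriptors drop the corresponding term (falling back to the
    remaining marginal terms).
    """
    return float(e1_vector(bg, phi, psi, omega, burial)[AA_INDEX[aa] if isinstance(aa, str) else aa])


def e1_vector(
    bg: BackgroundModel,
    phi: float | None,
    psi: float | None,
    omega: float | None,
    burial: int | None,
) -> np.ndarray:
    """E1 for all 20 amino acids at once (vectorized form of :func:`e1`)."""
    total = np.zeros(N_AA)
    if phi is not None and psi is not None:
        total = total + bg.phi_psi_energy[angle_bin(phi), angle_bin(psi)]
    if omega is not None and bg.omega_energy.shape[0] > 1:
        total = total + bg.omega_energy[omega_bin(omega, bg.omega_cis_range)]
    if burial is not None and bg.burial_energy.shape[0] > 1:
        total = total + bg.burial_energy[bg.burial_bin(burial)]
    return total


def e1_table(bg: BackgroundModel, descriptors: list[tuple]) -> np.ndarray:
    """E1 for a batch of (phi, psi, omega, burial) descriptors: (n, 20) array.

    Vectorized equivalent of calling :func:`e1_vector` per descriptor; None
    entries drop the corresponding term, as there.
    """
    n = len(descriptors)
    total = np.zeros((n, N_AA))
    phi = np.array([np.nan if d[0] is None else d[0] for d in descriptors])
    psi = np.array([np.nan if d[1] is None else d[1] for d in descriptors])
    has_pp = np.isfinite(phi) & np.isfinite(psi)
    if has_pp.any():
        width = PHI_PSI_BIN_WIDTH
        nb = N_PHI_PSI_BINS
        pb = np.clip(np.ceil((phi[has_pp] + 180.0) / width).astype(int) - 1, 0, nb - 1)
        sb = np.clip(np.ceil((psi[has_pp] + 180.0) / width).astype(int) - 1, 0, nb - 1)
        total[has_pp] += bg.phi_psi_energy[pb, sb]
    if bg.omega_energy.shape[0] > 1:
        om = np.array([np.nan if d[2] is None else d[2] for d in descriptors])
        has_om = np.isfinite(om)
        if has_om.any():
            lo, hi = bg.omega_cis_range
            ob = np.where((om[has_om] >= lo) & (om[has_om] <= hi), 0, 1)
            total[has_om] += bg.omega_energy[ob]
    if bg.burial_energy.shape[0] > 1:
        bur = np.array([np.nan if d[3] is None else d[3] for d in descriptors])
        has_b = np.isfinite(bur)
        if has_b.any():
            bb = np.searchsorted(bg.burial_edges, bur[has_b], side="right")
            total[has_b] += bg.burial_energy[bb]
    return total
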