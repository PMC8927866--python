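"""Synthetic structure databases, planted-coupling match ensembles, and decoy
model sets.

Everything here is generated from internal coordinates (standard bond lengths
and angles, omega = 180 unless perturbed), so that every other module can be
exercised end-to-end without any external structure database:

* plain two-segment databases with controlled dihedral noise and a rigid
  inter-segment placement;
* match ensembles whose central-pair sequences follow a planted first-order +
  pairwise-coupling (Potts-like) distribution, sampled exactly by enumerating
  the 400 outcomes — the ground truth against which the SCE machinery's
  coupling recovery is measured;
* a "geometry-coupled" world in which a 1-D geometric parameter theta moves one
  segment along an arc while the pair couplings J(theta) drift smoothly, so
  that structural similarity and energetic similarity are linked by
  construction — the regime the clustering and model-scoring analyses probe;
* noise-graded decoys of a native structure labeled by backbone RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AA_ORDER, N_AA,
    BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O,
    ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_CA_C_O,
    HELIX_PHI_PSI, STRAND_PHI_PSI,
)
from .geometry import place_atom, kabsch_rmsd
from .fragment_search import Match, MatchEnsemble, Motif, extract_motif
from .structure_io import Residue, Structure, compute_dihedrals

TEMPLATES = {"helix": HELIX_PHI_PSI, "strand": STRAND_PHI_PSI}


def build_backbone(phis: np.ndarray, psis: np.ndarray, omegas: np.ndarray | None = None) -> np.ndarray:
    """Backbone coordinates (n, 4, 3) in N/CA/C/O order from dihedral arrays.

    phis[0] and omegas[0] are unused (no preceding residue); psis[-1] fixes only
    the final carbonyl-oxygen direction.
    """
    n = len(phis)
    if omegas is None:
        omegas = np.full(n, 180.0)
    coords = np.zeros((n, 4, 3))
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]
    theta = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(n - 1):
        ni, ca, c = coords[i, 0], coords[i, 1], coords[i, 2]
        n_next = place_atom(ni, ca, c, BOND_C_N, ANGLE_CA_C_N, psis[i])
        ca_next = place_atom(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, omegas[i + 1])
        c_next = place_atom(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phis[i + 1])
        coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = n_next, ca_next, c_next
    for i in range(n):
        coords[i, 3] = place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0
        )
    return coords


def segment_backbone(
    length: int, template: str = "helix", sigma: float = 0.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """An ideal helix/strand segment with Gaussian dihedral noise (degrees)."""
    phi0, psi0 = TEMPLATES[template]
    if rng is None or sigma == 0.0:
        phis = np.full(length, phi0)
        psis = np.full(length, psi0)
        omegas = np.full(length, 180.0)
    else:
        phis = phi0 + rng.normal(0.0, sigma, length)
        psis = psi0 + rng.normal(0.0, sigma, length)
        omegas = 180.0 + rng.normal(0.0, sigma / 2.0, length)
    return build_backbone(phis, psis, omegas)


def structure_from_chains(
    structure_id: str, chains: dict[str, tuple[np.ndarray, str]]
) -> Structure:
    """Assemble a Structure from per-chain (backbone coords, sequence) pairs and
    compute its dihedrals."""
    s = Structure(id=structure_id)
    for chain_id, (coords, seq) in chains.items():
        if len(coords) != len(seq):
            raise ValueError("coordinates and sequence length differ")
        s.chains[chain_id] = [
            Residue(chain_id=chain_id, seq_index=k, aa=seq[k],
                    backbone=np.array(coords[k], float), author_id=k + 1)
            for k in range(len(seq))
        ]
    return compute_dihedrals(s)


def _rotation_matrix(euler_deg: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = np.radians(euler_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class GeneratorSpec:
    """Conditions for the plain two-segment synthetic database."""

    template: str = "helix"
    sigma: float = 3.0  # dihedral noise, degrees
    seg_len: int = 7
    n_structures: int = 50
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Euler angles, degrees
    translation: tuple[float, float, float] = (6.5, 0.0, 0.0)
    placement_noise: float = 0.2  # rigid translation jitter sd, A

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.seg_len < 1:
            raise ValueError("seg_len must be >= 1")


def random_sequence(length: int, rng: np.random.Generator, freqs: np.ndarray | None = None) -> str:
    p = freqs if freqs is not None else np.full(N_AA, 1.0 / N_AA)
    return "".join(AA_ORDER[i] for i in rng.choice(N_AA, size=length, p=p))


def generate_synthetic_database(spec: GeneratorSpec, seed: int = 0) -> list[Structure]:
    """Two-chain structures: segment A at the origin, segment B rigidly placed
    per the spec with translation jitter; uniform random sequences."""
    rng = np.random.default_rng(seed)
    rot = _rotation_matrix(spec.rotation)
    out = []
    for k in range(spec.n_structures):
        seg_a = segment_backbone(spec.seg_len, spec.template, spec.sigma, rng)
        seg_b = segment_backbone(spec.seg_len, spec.template, spec.sigma, rng)
        jitter = rng.normal(0.0, spec.placement_noise, 3) if spec.placement_noise > 0 else 0.0
        seg_b = seg_b @ rot.T + np.asarray(spec.translation) + jitter
        out.append(
            structure_from_chains(
                f"synth{k:04d}",
                {"A": (seg_a, random_sequence(spec.seg_len, rng)),
                 "B": (seg_b, random_sequence(spec.seg_len, rng))},
            )
        )
    return out


@dataclass
class PlantedModel:
    """First-order fields plus a pairwise coupling matrix for the central pair.

    P(a, b) is proportional to exp(-h_i(a) - h_j(b) - J(a, b)) at unit
    temperature; more negative couplings make a pair more likely.
    """

    h_i: np.ndarray = field(default_factory=lambda: np.zeros(N_AA))
    h_j: np.ndarray = field(default_factory=lambda: np.zeros(N_AA))
    J: np.ndarray = field(default_factory=lambda: np.zeros((N_AA, N_AA)))

    def pair_probs(self) -> np.ndarray:
        """Exact (20, 20) outcome probabilities by normalized enumeration."""
        logp = -(self.h_i[:, None] + self.h_j[None, :] + self.J)
        p = np.exp(logp - logp.max())
        return p / p.sum()

    def sample_pairs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, 2) array of amino-acid index pairs drawn from pair_probs."""
        flat = rng.choice(N_AA * N_AA, size=n, p=self.pair_probs().ravel())
        return np.column_stack([flat // N_AA, flat % N_AA])


def double_center(m: np.ndarray) -> np.ndarray:
    """Remove row/column means (the additive gauge freedom of pair couplings)."""
    m = np.asarray(m, float)
    return m - m.mean(axis=0, keepdims=True) - m.mean(axis=1, keepdims=True) + m.mean()


def sinkhorn_fields(j: np.ndarray, iters: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Fields (h_i, h_j) making P(a,b) ~ exp(-h_i(a) - h_j(b) - J(a,b)) have
    uniform marginals at both positions (Sinkhorn balancing).

    Flattening the first-order composition this way isolates the pairwise
    signal: the conditional (coupling) structure of P is untouched, since the
    fields only add the row/column gauge that pair statistics cannot identify
    anyway.
    """
    k = np.exp(-(j - j.min()))
    u = np.ones(N_AA)
    v = np.ones(N_AA)
    target = 1.0 / N_AA
    for _ in range(iters):
        u = target / (k @ v)
        v = target / (k.T @ u)
    return -np.log(u), -np.log(v)


def generate_planted_ensemble(
    pm: PlantedModel,
    geometry: GeneratorSpec,
    n_matches: int,
    seed: int = 0,
    cutoff: float | None = None,
) -> MatchEnsemble:
    """A match ensemble whose central-pair sequences follow the planted model.

    The query motif comes from one realization of the geometry spec; matches
    carry dihedral descriptors drawn around the template (sigma noise), uniform
    random flank identities implicitly, and ascending synthetic RMSDs below the
    cutoff.
    """
    if n_matches < 1:
        raise ValueError("n_matches must be >= 1")
    rng = np.random.default_rng(seed)
    flank = min(2, (geometry.seg_len - 1) // 2)
    center = geometry.seg_len // 2
    query_struct = generate_synthetic_database(
        GeneratorSpec(**{**geometry.__dict__, "n_structures": 1}), seed=seed
    )[0]
    query = extract_motif(query_struct, ("A", center), ("B", center), flank)

    pairs = pm.sample_pairs(n_matches, rng)
    rmsds = np.sort(rng.uniform(0.0, cutoff if cutoff is not None else 0.79, n_matches))
    phi0, psi0 = TEMPLATES[geometry.template]
    sig = max(geometry.sigma, 1e-6)
    phis = phi0 + rng.normal(0, sig, (n_matches, 2))
    psis = psi0 + rng.normal(0, sig, (n_matches, 2))
    omegas = 180.0 + rng.normal(0, sig / 2, (n_matches, 2))
    matches = [
        Match(
            structure_id=f"planted{k:05d}", seg1=("A", 0), seg2=("B", 0),
            rmsd=float(rmsds[k]), swapped=False,
            aa_i=AA_ORDER[pairs[k, 0]], aa_j=AA_ORDER[pairs[k, 1]],
            desc_i=(float(phis[k, 0]), float(psis[k, 0]), float(omegas[k, 0]), None),
            desc_j=(float(phis[k, 1]), float(psis[k, 1]), float(omegas[k, 1]), None),
        )
        for k in range(n_matches)
    ]
    return MatchEnsemble(query=query, matches=matches,
                         cutoff=cutoff if cutoff is not None else 0.79, max_count=n_matches)


def generate_model_set(
    native: Structure,
    noise_levels: list[float],
    per_level: int,
    seed: int = 0,
) -> list[tuple[Structure, float]]:
    """Noise-graded decoys: native coordinates plus isotropic Gaussian noise,
    labeled by all-backbone best-fit RMSD to the native."""
    rng = np.random.default_rng(seed)
    native_coords = np.concatenate([r.backbone for r in native.residues()])
    out = []
    for level in noise_levels:
        for rep in range(per_level):
            decoy = Structure(id=f"{native.id}_n{level:g}_r{rep}")
            for chain_id, chain in native.chains.items():
                decoy.chains[chain_id] = [
                    Residue(
                        chain_id=chain_id, seq_index=r.seq_index, aa=r.aa,
                        backbone=r.backbone + rng.normal(0.0, level, (4, 3)) if level > 0
                        else r.backbone.copy(),
                        author_id=r.author_id,
                    )
                    for r in chain
                ]
            compute_dihedrals(decoy)
            decoy_coords = np.concatenate([r.backbone for r in decoy.residues()])
            label = kabsch_rmsd(native_coords, decoy_coords) if level > 0 else 0.0
            out.append((decoy, float(label)))
    return out


def generate_placement_decoys(
    native: Structure,
    contact_axes: list[tuple[tuple[str, int], tuple[str, int]]],
    levels_rad: list[float],
    per_level: int,
    seed: int = 0,
    atom_noise: float = 0.02,
    axis_jitter: float = 0.25,
) -> list[tuple[Structure, float]]:
    """Rigid placement decoys: each mobile chain is rotated about its contact
    axis by a graded angle (random sign, slightly tilted axis per replica),
    labeled by all-backbone RMSD.

    ``contact_axes`` lists (fixed residue, mobile residue) address pairs; the
    chain of each mobile residue is rotated about the axis through that
    residue's CA along the contact direction. This emulates how
    structural-model errors typically look locally: covalent geometry stays
    ideal while the relative placement of interacting elements drifts.
    (Isotropic per-atom noise, by contrast, produces non-protein backbones that
    leave fragment-searchable space at quite small amplitudes.)
    """
    rng = np.random.default_rng(seed)
    mobiles = []  # (chain_id, pivot CA, unit axis)
    for axis_from, axis_to in contact_axes:
        ca_a = native.get(*axis_from).atom("CA")
        ca_b = native.get(*axis_to).atom("CA")
        axis = ca_b - ca_a
        mobiles.append((axis_to[0], ca_b, axis / np.linalg.norm(axis)))
    native_coords = np.concatenate([r.backbone for r in native.residues()])
    out = []
    for level in levels_rad:
        for rep in range(per_level):
            rots = {}
            for chain_id, pivot, axis in mobiles:
                a = axis + axis_jitter * rng.normal(size=3)
                a /= np.linalg.norm(a)
                angle = level * rng.choice([-1.0, 1.0])
                rots[chain_id] = (pivot, _rotvec_matrix(angle * a))
            decoy = Structure(id=f"{native.id}_p{level:g}_r{rep}")
            for chain_id, chain in native.chains.items():
                new_chain = []
                for r in chain:
                    bb = r.backbone.copy()
                    if chain_id in rots:
                        pivot, rot = rots[chain_id]
                        bb = (bb - pivot) @ rot.T + pivot
                    if atom_noise > 0:
                        bb = bb + rng.normal(0.0, atom_noise, bb.shape)
                    new_chain.append(
                        Residue(chain_id=chain_id, seq_index=r.seq_index, aa=r.aa,
                                backbone=bb, author_id=r.author_id)
                    )
                decoy.chains[chain_id] = new_chain
            compute_dihedrals(decoy)
            decoy_coords = np.concatenate([r.backbone for r in decoy.residues()])
            out.append((decoy, float(kabsch_rmsd(native_coords, decoy_coords))))
    return out


# ---------------------------------------------------------------------------
# geometry-coupled world: J varies smoothly with a 1-D placement parameter
# ---------------------------------------------------------------------------


@dataclass
class CoupledWorldSpec:
    """Study conditions for the geometry-coupled synthetic world.

    Each structure is a helical segment (chain A) and a strand segment
    (chain B) forming one central side-chain contact: segment B's central CA
    sits ``contact_distance`` along segment A's central CB direction, with B's
    own CB direction facing back at A. Mixing segment types keeps the motif
    asymmetric, so swapped segment assignments never alias distant spin angles
    into one another's match ensembles. The free
    geometric coordinate theta ~ U(0, 1) spins segment B about the contact axis
    by theta * spin_range radians, which moves the flanking geometry (motif
    RMSD grows near-linearly with the spin difference) while preserving the
    contact itself. The coupling field J(theta) is a Gaussian-process-like
    mixture of random symmetric matrices with RBF weights (correlation length
    ``kernel_ell``), so structurally similar motifs impose similar pair
    preferences and distant ones unrelated preferences.
    """

    n_structures: int = 400
    seg_len: int = 5
    n_units: int = 6  # independent helix-strand contact units per structure
    unit_offset: float = 60.0  # A between units (far beyond any match cutoff)
    template_a: str = "helix"
    template_b: str = "strand"
    sigma: float = 2.0  # dihedral noise, degrees
    contact_distance: float = 6.5  # A, central CA-CA distance
    spin_range: float = 3.0  # radians swept as theta goes 0 -> 1
    kernel_centers: int = 13
    kernel_ell: float = 0.15  # correlation length of J along theta
    j_scale: float = 2.5  # sd of coupling entries (log units)
    jitter: float = 0.05  # per-atom placement noise, A
    # balance fields so central-pair marginals are uniform (isolates the
    # second-order signal; first-order composition carries no geometry cue)
    flatten_marginals: bool = True

    @property
    def center_index(self) -> int:
        return self.seg_len // 2


@dataclass
class CoupledWorld:
    spec: CoupledWorldSpec
    db: list[Structure]
    thetas: np.ndarray
    _basis: np.ndarray  # (K, 20, 20) random symmetric matrices
    _centers: np.ndarray

    def coupling_at(self, theta: float) -> np.ndarray:
        """Ground-truth J(theta), entries with sd j_scale."""
        w = np.exp(-0.5 * ((theta - self._centers) / self.spec.kernel_ell) ** 2)
        w = w / np.sqrt((w**2).sum())
        return self.spec.j_scale * np.einsum("k,kab->ab", w, self._basis)

    def central_pairs(self) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        """The (fixed, mobile) central residue addresses of each contact unit."""
        c = self.spec.center_index
        out = []
        for u in range(self.spec.n_units):
            fixed = chr(ord("A") + 2 * u)
            mobile = chr(ord("A") + 2 * u + 1)
            out.append(((fixed, c), (mobile, c)))
        return out

    def central_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return self.central_pairs()[0]

    def motif(self, k: int, flank: int = 1, unit: int = 0) -> Motif:
        pi, pj = self.central_pairs()[unit]
        return extract_motif(self.db[k], pi, pj, flank)


def _cb_direction(seg: np.ndarray, idx: int) -> np.ndarray:
    """Unit vector from a residue's CA toward its (ideal) CB."""
    from .sidechain import build_sidechain

    cb = build_sidechain(seg[idx, 0], seg[idx, 1], seg[idx, 2], "A", ())[0]
    v = cb - seg[idx, 1]
    return v / np.linalg.norm(v)


def _align_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping unit vector src onto unit vector dst."""
    v = np.cross(src, dst)
    s = np.linalg.norm(v)
    cth = float(np.dot(src, dst))
    if s < 1e-12:
        if cth > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any perpendicular axis
        helper = np.array([1.0, 0.0, 0.0]) if abs(src[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(src, helper)
        axis /= np.linalg.norm(axis)
        return _rotvec_matrix(np.pi * axis)
    return _rotvec_matrix(np.arctan2(s, cth) * v / s)


def _rotvec_matrix(rotvec: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rotvec)
    if theta < 1e-12:
        return np.eye(3)
    k = rotvec / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def generate_coupled_world(spec: CoupledWorldSpec, seed: int = 0) -> CoupledWorld:
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(spec.kernel_centers, N_AA, N_AA))
    basis = (z + z.transpose(0, 2, 1)) / np.sqrt(2.0)
    centers = np.linspace(0.0, 1.0, spec.kernel_centers)
    world = CoupledWorld(spec=spec, db=[], thetas=np.empty(spec.n_structures),
                         _basis=basis, _centers=centers)
    c = spec.center_index
    for k in range(spec.n_structures):
        theta = rng.uniform()
        world.thetas[k] = theta
        j_local = world.coupling_at(theta)
        if spec.flatten_marginals:
            h_i, h_j = sinkhorn_fields(j_local)
            pm = PlantedModel(h_i=h_i, h_j=h_j, J=j_local)
        else:
            pm = PlantedModel(J=j_local)
        chains = {}
        for u in range(spec.n_units):
            seg_a = segment_backbone(spec.seg_len, spec.template_a, spec.sigma, rng)
            seg_b = segment_backbone(spec.seg_len, spec.template_b, spec.sigma, rng)
            u_a = _cb_direction(seg_a, c)
            u_b = _cb_direction(seg_b, c)
            # face B's central side chain back at A's, then spin about the axis
            rot = _rotvec_matrix(theta * spec.spin_range * u_a) @ _align_rotation(u_b, -u_a)
            seg_b = (seg_b - seg_b[c, 1]) @ rot.T + seg_a[c, 1] + spec.contact_distance * u_a
            if spec.jitter > 0:
                seg_b = seg_b + rng.normal(0.0, spec.jitter, seg_b.shape)
                seg_a = seg_a + rng.normal(0.0, spec.jitter, seg_a.shape)
            offset = np.array([u * spec.unit_offset, 0.0, 0.0])
            ai, aj = pm.sample_pairs(1, rng)[0]
            seq_a = list(random_sequence(spec.seg_len, rng))
            seq_b = list(random_sequence(spec.seg_len, rng))
            seq_a[c] = AA_ORDER[ai]
            seq_b[c] = AA_ORDER[aj]
            chains[chr(ord("A") + 2 * u)] = (seg_a + offset, "".join(seq_a))
            chains[chr(ord("A") + 2 * u + 1)] = (seg_b + offset, "".join(seq_b))
        world.db.append(structure_from_chains(f"cw{k:04d}", chains))
    return world
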