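import numpy as np
import pytest

from scpot.constants import AA_ORDER, AA_INDEX
from scpot.contact_geometry import (
    CD_BIN_EDGES, N_CD_BINS, Rotamer, RotamerLibrary,
    allowed_rotamers, cd_bin, compute_aa_freqs, contact_degree,
    contacts_to_frame, enumerate_contacts, frame_to_contacts,
    load_dunbrack_library, load_fixture_library, sample_contact_database,
)
from scpot.structure_io import Residue, Structure
from scpot.synthetic import (
    GeneratorSpec, generate_coupled_world, CoupledWorldSpec, segment_backbone,
    structure_from_chains,
)


def two_residue_structure(separation: float, seq="AA") -> Structure:
    """Two facing single-residue chains a given CA-CA distance apart."""
    from scpot.sidechain import build_sidechain
    from scpot.synthetic import _align_rotation

    bb1 = np.array([[1.458, 0.0, 0.0], [0.0, 0.0, 0.0], [-0.551, 1.422, 0.0],
                    [0.189, 2.367, 0.285]])
    u = build_sidechain(bb1[0], bb1[1], bb1[2], "A", ())[0] - bb1[1]
    u /= np.linalg.norm(u)
    rot = _align_rotation(u, -u)  # turn the second frame's CB back at the first
    bb2 = (bb1 - bb1[1]) @ rot.T + bb1[1] + separation * u
    s = Structure(id="pair")
    s.chains["A"] = [Residue("A", 0, seq[0], bb1)]
    s.chains["B"] = [Residue("B", 0, seq[1], bb2)]
    return s


def toy_library(n_rotamers=2) -> RotamerLibrary:
    """Small library whose rotamers repeat one chi value through the side chain."""
    from scpot.sidechain import N_CHI

    chi1s = [-65.0, 180.0, 62.0][:n_rotamers]
    probs = {1: [1.0], 2: [0.7, 0.3], 3: [0.5, 0.3, 0.2]}[n_rotamers]
    rots = {}
    for aa in AA_ORDER:
        k = N_CHI[aa]
        if k == 0:  # single conformer for G/A
            rots[aa] = [Rotamer(chis=(), prob=1.0)]
        else:
            rots[aa] = [Rotamer(chis=(c,) * k, prob=p) for c, p in zip(chi1s, probs)]
    return RotamerLibrary(rotamers=rots)


class TestAllowedRotamers:
    def test_exposed_position_keeps_everything(self, lib):
        s = two_residue_structure(50.0)
        allowed = allowed_rotamers(s, ("A", 0), lib)
        for aa, survivors in allowed.items():
            assert sum(p for _, p in survivors) == pytest.approx(1.0)

    def test_occluded_position_loses_rotamers(self, lib):
        s = two_residue_structure(50.0)
        # wall of pseudo-backbone residues right on top of the side chain
        wall = [
            Residue("W", k, "A", np.tile(np.array([1.2 + 0.4 * k, -1.0, 0.2]), (4, 1)))
            for k in range(8)
        ]
        s.chains["W"] = wall
        allowed = allowed_rotamers(s, ("A", 0), lib)
        total = sum(p for surv in allowed.values() for _, p in surv)
        assert total < 20.0 - 1e-6  # some probability mass removed
        assert any(len(surv) == 0 for surv in allowed.values())

    def test_renormalization_flag(self, lib):
        s = two_residue_structure(50.0)
        # one blocker close enough to remove some rotamers but not whole fans
        s.chains["W"] = [
            Residue("W", 0, "A", np.tile(np.array([-0.5, -3.5, 2.0]), (4, 1)))
        ]
        raw = allowed_rotamers(s, ("A", 0), lib, renormalize=False)
        ren = allowed_rotamers(s, ("A", 0), lib, renormalize=True)
        partial = [aa for aa in AA_ORDER if 0 < len(raw[aa]) < len(lib.rotamers[aa])]
        assert partial, "expected some partially occluded amino acid"
        for aa in partial:
            assert sum(p for _, p in raw[aa]) < 1.0 - 1e-9
            assert sum(p for _, p in ren[aa]) == pytest.approx(1.0)

    def test_missing_position_raises(self, lib):
        s = two_residue_structure(10.0)
        with pytest.raises(KeyError):
            allowed_rotamers(s, ("C", 5), lib)


def brute_force_cd(s, pos_i, pos_j, lib, cutoff=3.0):
    """Independent CD: explicit sum over all (a, b, r_i, r_j) with a python
    double loop over atom pairs."""
    ai = allowed_rotamers(s, pos_i, lib)
    aj = allowed_rotamers(s, pos_j, lib)
    freqs = lib.aa_freqs
    total = 0.0
    for a in AA_ORDER:
        for b in AA_ORDER:
            for atoms_i, p_i in ai[a]:
                for atoms_j, p_j in aj[b]:
                    clash = any(
                        np.linalg.norm(x - y) < cutoff
                        for x in atoms_i for y in atoms_j
                    )
                    if clash:
                        total += freqs[AA_INDEX[a]] * freqs[AA_INDEX[b]] * p_i * p_j
    return total


class TestContactDegree:
    def test_far_apart_is_zero(self, lib):
        s = two_residue_structure(50.0)
        assert contact_degree(s, ("A", 0), ("B", 0), lib) == 0.0

    def test_equals_brute_force_enumeration(self):
        lib2 = toy_library(2)
        for sep in (5.0, 6.5, 8.0):
            s = two_residue_structure(sep)
            fast = contact_degree(s, ("A", 0), ("B", 0), lib2)
            slow = brute_force_cd(s, ("A", 0), ("B", 0), lib2)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_symmetric_and_bounded(self, lib):
        for sep in (4.0, 6.0, 9.0, 14.0):
            s = two_residue_structure(sep)
            cd_ij = contact_degree(s, ("A", 0), ("B", 0), lib)
            cd_ji = contact_degree(s, ("B", 0), ("A", 0), lib)
            assert cd_ij == pytest.approx(cd_ji, abs=1e-12)
            assert 0.0 <= cd_ij <= 1.0

    def test_non_increasing_with_separation(self, lib):
        # clash filtering off so the rotamer sets stay fixed while the pair is
        # rigidly translated apart; only the interference term then varies
        cds = [contact_degree(two_residue_structure(sep), ("A", 0), ("B", 0), lib,
                              clash_threshold=0.0)
               for sep in (4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 16.0, 25.0)]
        assert all(a >= b - 1e-12 for a, b in zip(cds, cds[1:]))
        assert cds[-1] == 0.0

    def test_all_interfering_pairs_give_one(self):
        """When every placeable rotamer pair clashes, CD reaches 1 exactly.

        Uses a single-conformer library over the 19 side-chain-bearing amino
        acids (glycine has no heavy side-chain atom to clash with, so it is
        given zero background probability)."""
        from scpot.sidechain import N_CHI

        rots = {aa: [Rotamer(chis=(-65.0,) * N_CHI[aa], prob=1.0)]
                for aa in AA_ORDER if aa != "G"}
        freqs = np.full(20, 1.0 / 19.0)
        freqs[AA_INDEX["G"]] = 0.0
        lib1 = RotamerLibrary(rotamers=rots, aa_freqs=freqs)
        # facing frames 4.6 A apart: every pair of side chains meets within 3 A
        s = two_residue_structure(4.6)
        cd = contact_degree(s, ("A", 0), ("B", 0), lib1, clash_threshold=0.0)
        assert cd == pytest.approx(1.0)


class TestCdBins:
    def test_bin_edges_and_boundaries(self):
        assert len(CD_BIN_EDGES) == N_CD_BINS + 1
        assert cd_bin(0.0) == 0
        assert cd_bin(2.0**-10) == 1  # half-open: boundary starts the next bin
        assert cd_bin(2.0**-10 - 1e-12) == 0
        assert cd_bin(0.5) == 10
        assert cd_bin(1.0) == 10

    def test_every_value_maps_to_exactly_one_bin(self, rng):
        for cd in rng.uniform(0, 1, 200):
            k = cd_bin(cd)
            assert 0 <= k < N_CD_BINS
            lo, hi = CD_BIN_EDGES[k], CD_BIN_EDGES[k + 1]
            assert lo <= cd < hi or (k == N_CD_BINS - 1 and cd <= 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cd_bin(1.5)


class TestEnumerateContacts:
    @pytest.fixture(scope="class")
    def long_chain(self):
        coords = segment_backbone(20, "strand")
        return structure_from_chains("long", {"A": (coords, "A" * 20)})

    def test_minimum_separation_rule(self, long_chain, lib):
        recs = enumerate_contacts(long_chain, lib, min_seq_sep=5, flank=2)
        pairs = {(r.pos_i, r.pos_j) for r in recs}
        assert all(j - i - 1 >= 5 for i, j in pairs)
        # boundary: 5 residues in between is allowed, 4 is not
        recs1 = enumerate_contacts(long_chain, lib, min_seq_sep=5, flank=0)
        seps = {r.pos_j - r.pos_i - 1 for r in recs1}
        assert 5 in seps and 4 not in seps

    def test_window_completeness_excludes_chain_ends(self, long_chain, lib):
        recs = enumerate_contacts(long_chain, lib, min_seq_sep=5, flank=2)
        positions = {p for r in recs for p in (r.pos_i, r.pos_j)}
        assert positions and min(positions) >= 2 and max(positions) <= 17

    def test_interchain_contacts_flagged(self, lib, tiny_world):
        recs = enumerate_contacts(tiny_world.db[0], lib, flank=1, min_cd=0.1)
        assert recs and all(r.seq_sep == -1 for r in recs)

    def test_tsv_round_trip(self, lib, tiny_world):
        recs = enumerate_contacts(tiny_world.db[0], lib, flank=1, min_cd=0.0)
        back = frame_to_contacts(contacts_to_frame(recs))
        assert [(r.pos_i, r.pos_j, r.aa_i, r.aa_j) for r in back] == \
               [(r.pos_i, r.pos_j, r.aa_i, r.aa_j) for r in recs]
        assert np.allclose([r.cd for r in back], [r.cd for r in recs])


class TestSampleContactDatabase:
    def _records(self, rng, n=400):
        from scpot.contact_geometry import ContactRecord
        cds = rng.uniform(0, 1, n) ** 4  # spread over the log-spaced bins
        return [
            ContactRecord("s", "A", i, "B", i, "A", "V", float(c), -1)
            for i, c in enumerate(cds)
        ]

    def test_per_bin_counts_and_degenerate_bins(self, rng):
        records = self._records(rng)
        db = sample_contact_database(records, per_bin=3, seed=0)
        for k in range(N_CD_BINS):
            available = sum(1 for r in records if cd_bin(r.cd) == k)
            assert db.per_bin_counts[k] == min(3, available)

    def test_deterministic_given_seed(self, rng):
        records = self._records(rng)
        a = sample_contact_database(records, per_bin=5, seed=42)
        b = sample_contact_database(records, per_bin=5, seed=42)
        assert [(r.pos_i, r.cd) for r in a.records] == [(r.pos_i, r.cd) for r in b.records]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sample_contact_database([], per_bin=1, seed=0)


class TestLibraries:
    def test_fixture_probabilities_sum_to_one(self, lib):
        for aa, rots in lib.rotamers.items():
            assert sum(r.prob for r in rots) == pytest.approx(1.0, abs=1e-6)

    def test_aa_freqs_from_database(self, small_db):
        freqs = compute_aa_freqs(small_db)
        assert freqs.sum() == pytest.approx(1.0)
        assert (freqs >= 0).all()

    def test_dunbrack_parser(self, tmp_path):
        text = "\n".join(
            f"SER {phi:5d} {psi:5d} 100 {r} 0 0 0 {p:.6f} {chi:.1f} 0 0 0 10 0 0 0"
            for phi in (-180, -170) for psi in (-60, -50)
            for r, p, chi in ((1, 0.6, -65.0), (2, 0.4, 178.0))
        )
        path = tmp_path / "dunbrack.txt"
        path.write_text(text + "\n")
        dlib = load_dunbrack_library(path)
        assert dlib.backbone_dependent
        rots = dlib.rotamers_for("S", phi=-175.0, psi=-55.0)
        assert len(rots) == 2
        assert sum(r.prob for r in rots) == pytest.approx(1.0)
        assert rots[0].chis[0] == pytest.approx(-65.0)
        # fallback when no backbone context given
        assert dlib.rotamers_for("S")
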