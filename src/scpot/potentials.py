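"""Contact potentials and structure-conditioned energies (SCEs).

The contact potential (CP) is the classic log-odds pair pseudo-energy over a
generic set of contacts,

    E(a,b) = -log[(N_obs(a,b) + eps) / (N_obs(a) N_obs(b) H(a,b) / N + eps)],

with N_obs(a,b) symmetrized over order, N_obs(a) the residue-type counts over
the contact set, N the total residue count, and H(a,b) = 2 - I(a=b) doubling
the heterotypic expectation. Note this reference state is defined up to an
additive constant: summed over unordered pairs it doubles the contact count, so
under pair-independent sampling every energy sits at +log 2 rather than 0; all
downstream uses (rankings, correlations, z-scores) are shift-invariant.

The structure-conditioned energy replaces the generic contact set with a match
ensemble of fragments structurally similar to one interaction motif, and the
marginal-product reference with an expected count under a first-order-only
model: per match, each position's amino-acid probability is a softmax of the
background energy E1 plus a residual correction Delta that pins the expected
marginals to the observed ones.

The per-pair pseudocount is eps = max(N_obs(a,b), N_exp(a,b), 1) / 20, which
bounds |E| for zero-count pairs; fixed-count alternatives are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background_model import BackgroundModel, e1_table
from .constants import AA_ORDER, AA_INDEX, N_AA
from .contact_geometry import ContactDatabase, ContactRecord, N_CD_BINS, cd_bin
from .fragment_search import MatchEnsemble

logger = logging.getLogger(__name__)

MIN_ENSEMBLE_WARN = 1_000
DEFAULT_DELTA = 0.1  # smoothing count for the residual-energy marginal correction

EPSILON_MODES = ("scaled", "fixed", "laplace")


def _pseudocount(n_obs: np.ndarray, n_exp: np.ndarray, mode: str) -> np.ndarray:
    if mode == "scaled":
        return np.maximum(np.maximum(n_obs, n_exp), 1.0) / 20.0
    if mode == "fixed":
        return np.full_like(np.asarray(n_obs, float), 0.05)
    if mode == "laplace":
        return np.ones_like(np.asarray(n_obs, float))
    raise ValueError(f"unknown epsilon mode {mode!r}; expected one of {EPSILON_MODES}")


@dataclass
class PairCounts:
    """Ordered 20x20 pair counts with per-position marginals."""

    n_ordered: np.ndarray  # counts of (aa_i, aa_j) in order
    total: int

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "PairCounts":
        n = np.zeros((N_AA, N_AA))
        for a, b in pairs:
            n[AA_INDEX[a], AA_INDEX[b]] += 1
        return cls(n_ordered=n, total=len(pairs))

    @property
    def symmetrized(self) -> np.ndarray:
        """N_obs(a,b) = N(a,b) + (1 - I(a,b)) N(b,a): order-free counts with
        homotypic contacts counted once."""
        n = self.n_ordered
        return n + n.T - np.diag(np.diag(n))

    @property
    def residue_counts(self) -> np.ndarray:
        """N_obs(a): occurrences of each amino acid over both pair slots."""
        return self.n_ordered.sum(axis=1) + self.n_ordered.sum(axis=0)


@dataclass
class EnergyMatrix:
    values: np.ndarray  # (20, 20)
    symmetric: bool
    provenance: str = ""
    n: int = 0  # contacts or matches behind the statistics

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[AA_INDEX[a], AA_INDEX[b]])

    def lookup(self, a: str, b: str) -> float:
        """Energy of a pair; symmetrized lookup for ordered matrices."""
        if self.symmetric:
            return self[a, b]
        return 0.5 * (self[a, b] + self[b, a])


@dataclass
class ExpectationModel:
    """Per-match first-order amino-acid probabilities and the resulting expected
    pair counts for one ensemble."""

    p_i: np.ndarray  # (M, 20) per-match probabilities at position i
    p_j: np.ndarray  # (M, 20)
    delta_i: np.ndarray  # (20,) residual energies
    delta_j: np.ndarray
    n_exp: np.ndarray  # (20, 20)
    obs_marginal_i: np.ndarray
    obs_marginal_j: np.ndarray

    @property
    def n_matches(self) -> int:
        return self.p_i.shape[0]


def contact_potential(
    records: list[ContactRecord] | list[tuple[str, str]],
    epsilon_mode: str = "scaled",
    provenance: str = "CP",
) -> EnergyMatrix:
    """Eq.-1 contact potential over a set of contacts."""
    pairs = [
        (r.aa_i, r.aa_j) if isinstance(r, ContactRecord) else (r[0], r[1]) for r in records
    ]
    if not pairs:
        raise ValueError("need at least one contact record")
    counts = PairCounts.from_pairs(pairs)
    n_obs = counts.symmetrized
    res = counts.residue_counts
    n_total = 2 * counts.total
    h = 2.0 - np.eye(N_AA)
    n_exp = np.outer(res, res) * h / n_total
    eps = _pseudocount(n_obs, n_exp, epsilon_mode)
    values = -np.log((n_obs + eps) / (n_exp + eps))
    return EnergyMatrix(values=values, symmetric=True, provenance=provenance, n=counts.total)


def cd_binned_potentials(
    dbase: ContactDatabase, epsilon_mode: str = "scaled"
) -> list[EnergyMatrix]:
    """One Eq.-1 contact potential per contact-degree bin (11 matrices).

    Empty bins yield zero matrices flagged with n = 0; ``lookup_cdp`` maps a CD
    value to its bin's matrix.
    """
    out = []
    for k in range(N_CD_BINS):
        recs = dbase.records_in_bin(k)
        if recs:
            em = contact_potential(recs, epsilon_mode, provenance=f"CDP bin {k}")
        else:
            em = EnergyMatrix(
                values=np.zeros((N_AA, N_AA)), symmetric=True,
                provenance=f"CDP bin {k} (empty)", n=0,
            )
        out.append(em)
    return out


def lookup_cdp(cdp: list[EnergyMatrix], cd: float) -> EnergyMatrix:
    return cdp[cd_bin(cd)]


def _match_probability_arrays(ens: MatchEnsemble, bg: BackgroundModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-match softmax probabilities q_m(a) = exp(-E1(a|m)) / sum_a' under the
    background model, at both central positions (aligned order)."""
    e_i = e1_table(bg, [m.desc_i for m in ens.matches])
    e_j = e1_table(bg, [m.desc_j for m in ens.matches])
    q_i = np.exp(-e_i)
    q_j = np.exp(-e_j)
    q_i /= q_i.sum(axis=1, keepdims=True)
    q_j /= q_j.sum(axis=1, keepdims=True)
    return q_i, q_j


def _observed_marginals(ens: MatchEnsemble) -> tuple[np.ndarray, np.ndarray]:
    n_i = np.zeros(N_AA)
    n_j = np.zeros(N_AA)
    for m in ens.matches:
        n_i[AA_INDEX[m.aa_i]] += 1
        n_j[AA_INDEX[m.aa_j]] += 1
    return n_i, n_j


def expected_pair_counts(
    ens: MatchEnsemble, bg: BackgroundModel, delta: float = DEFAULT_DELTA
) -> ExpectationModel:
    """Expected central-pair counts under first-order preferences only.

    For each position, N_e(a) = sum_m q_m(a) with q_m the E1 softmax; the
    residual energy Delta(a) = -ln[(N_o(a) + delta) / (N_e(a) + delta)] pulls the
    expected marginals onto the observed ones, and the corrected per-match
    probabilities p_m(a) (softmax of E1 + Delta) give
    N_exp(a_i, a_j) = sum_m p_m(a_i at i) p_m(a_j at j).

    Matches found with swapped segment assignment were already re-ordered by the
    search, so their counts land transposed here as required.
    """
    if len(ens.matches) == 0:
        raise ValueError("empty match ensemble")
    q_i, q_j = _match_probability_arrays(ens, bg)
    n_o_i, n_o_j = _observed_marginals(ens)

    def corrected(q: np.ndarray, n_o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_e = q.sum(axis=0)
        ratio = (n_o + delta) / (n_e + delta)  # = exp(-Delta)
        with np.errstate(divide="ignore"):
            delta_vec = -np.log(ratio)  # +inf for never-observed aa at delta = 0
        w = q * ratio[None, :]
        return w / w.sum(axis=1, keepdims=True), delta_vec

    p_i, delta_i = corrected(q_i, n_o_i)
    p_j, delta_j = corrected(q_j, n_o_j)
    n_exp = p_i.T @ p_j
    return ExpectationModel(
        p_i=p_i, p_j=p_j, delta_i=delta_i, delta_j=delta_j, n_exp=n_exp,
        obs_marginal_i=n_o_i, obs_marginal_j=n_o_j,
    )


def sce_matrix(
    ens: MatchEnsemble,
    bg: BackgroundModel,
    epsilon_mode: str = "scaled",
    delta: float = DEFAULT_DELTA,
) -> EnergyMatrix:
    """Structure-conditioned energies of an interaction motif (ordered 20x20).

    Row index is the amino acid at the motif's first central position, column
    the second; use :func:`symmetrize` before comparing against a CP.
    """
    if len(ens.matches) == 0:
        raise ValueError("empty match ensemble")
    if len(ens.matches) < MIN_ENSEMBLE_WARN:
        logger.warning(
            "ensemble of %d matches (< %d); SCE statistics may be sparse",
            len(ens.matches), MIN_ENSEMBLE_WARN,
        )
    n_obs = PairCounts.from_pairs([(m.aa_i, m.aa_j) for m in ens.matches]).n_ordered
    model = expected_pair_counts(ens, bg, delta)
    eps = _pseudocount(n_obs, model.n_exp, epsilon_mode)
    values = -np.log((n_obs + eps) / (model.n_exp + eps))
    return EnergyMatrix(
        values=values, symmetric=False,
        provenance=f"SCE {ens.query.structure_id} {ens.query.seg1}x{ens.query.seg2} k={ens.query.flank}",
        n=len(ens.matches),
    )


def symmetrize(e: EnergyMatrix) -> EnergyMatrix:
    """(E + E^T) / 2 with the symmetric flag set."""
    return EnergyMatrix(
        values=0.5 * (e.values + e.values.T), symmetric=True,
        provenance=e.provenance, n=e.n,
    )


def energy_to_frame(e: EnergyMatrix) -> pd.DataFrame:
    return pd.DataFrame(e.values, index=list(AA_ORDER), columns=list(AA_ORDER))


def write_energy_tsv(e: EnergyMatrix, path) -> None:
    energy_to_frame(e).to_csv(path, sep="\t", float_format="%.6f")


def read_energy_tsv(path, symmetric: bool | None = None) -> EnergyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.loc[list(AA_ORDER), list(AA_ORDER)].to_numpy(float)
    if symmetric is None:
        symmetric = bool(np.allclose(values, values.T))
    return EnergyMatrix(values=values, symmetric=symmetric)
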