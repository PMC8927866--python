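"""Evaluation procedures for contact potentials and structure-conditioned energies.

Covers native-pair identification and its enrichment over chance (1/400),
modified z-scores (median/MAD), sweeps of ensemble size against experimental
double-mutant coupling energies, mean-energy scoring of structural models, and
ROC/AUC discrimination of model quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .background_model import BackgroundModel
from .constants import AA_ORDER, AA_INDEX, N_AA
from .contact_geometry import RotamerLibrary, enumerate_contacts
from .fragment_search import FragmentIndex, MatchEnsemble, Motif, extract_motif, search_matches
from .potentials import EnergyMatrix, sce_matrix, symmetrize
from .structure_io import Structure

logger = logging.getLogger(__name__)

CHANCE_RATE = 1.0 / 400.0


@dataclass
class IdentificationResult:
    motif_id: str
    native: tuple[str, str]
    best: tuple[str, str]
    identified: bool
    rank: int  # 1..400, ascending energy, ties broken lexicographically
    zscore: float  # modified z-score of the native pair's energy


@dataclass
class ModelScore:
    model_id: str
    target_id: str
    mean_sce: float
    mean_ce: float
    n_contacts: int
    quality: float | None = None
    quality_metric: str | None = None

    @property
    def empty(self) -> bool:
        return self.n_contacts == 0


@dataclass
class SweepPoint:
    constraint: tuple[str, float]  # ("count", n) or ("rmsd", cap)
    n_matches: int
    r: float  # Pearson r against the experimental couplings (nan when undefined)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def modified_zscore(e: EnergyMatrix, pair: tuple[str, str]) -> float:
    """Z = (E_pair - median(E)) / median(|E - median(E)|) over all 400 entries.

    Returns nan for a degenerate (constant) matrix, where the MAD is zero.
    """
    values = e.values.ravel()
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad == 0.0:
        logger.warning("degenerate energy matrix: MAD is zero")
        return float("nan")
    return (e[pair] - med) / mad


def identify_native(e: EnergyMatrix, native: tuple[str, str], motif_id: str = "") -> IdentificationResult:
    """Does the most favorable (lowest) energy belong to the native pair?

    Rank is the native pair's position in the ascending sort of all 400
    energies; ties break by lexicographic pair order (row-major in the canonical
    amino-acid order), so rank 1 iff identified.
    """
    flat = e.values.ravel()
    best_idx = int(np.argmin(flat))  # argmin takes the lexicographically first tie
    best = (AA_ORDER[best_idx // N_AA], AA_ORDER[best_idx % N_AA])
    nat_idx = AA_INDEX[native[0]] * N_AA + AA_INDEX[native[1]]
    nat_val = flat[nat_idx]
    rank = int(np.sum(flat < nat_val) + np.sum(flat[:nat_idx] == nat_val) + 1)
    return IdentificationResult(
        motif_id=motif_id, native=native, best=best,
        identified=rank == 1, rank=rank, zscore=modified_zscore(e, native),
    )


def enrichment(results: list[IdentificationResult]) -> float:
    """Identified fraction over the 1/400 chance rate."""
    if not results:
        raise ValueError("no identification results")
    frac = sum(r.identified for r in results) / len(results)
    return frac / CHANCE_RATE


def read_coupling_table(path) -> dict[tuple[str, str], float]:
    """TSV with columns aa_i, aa_j, energy (kcal/mol)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {(str(r.aa_i), str(r.aa_j)): float(r.energy) for r in df.itertuples()}


def coupling_correlation(
    e: EnergyMatrix, experimental: dict[tuple[str, str], float]
) -> float:
    """Pearson r between an energy matrix and labeled pair energies.

    Heterotypic pairs use the symmetrized lookup, so tables measured in one
    order only are handled. Returns nan with fewer than 3 overlapping pairs.
    """
    xs, ys = [], []
    for (a, b), val in experimental.items():
        xs.append(e.lookup(a, b))
        ys.append(val)
    if len(xs) < 3:
        logger.warning("only %d overlapping pairs; correlation undefined", len(xs))
        return float("nan")
    return float(stats.pearsonr(xs, ys)[0])


def coupling_sweep(
    ensemble: MatchEnsemble,
    bg: BackgroundModel,
    constraints: list[tuple[str, float]],
    experimental: dict[tuple[str, str], float],
    epsilon_mode: str = "scaled",
    delta: float = 0.1,
) -> list[SweepPoint]:
    """Recompute the SCE on truncations of one ensemble and correlate with
    experimental couplings at each constraint.

    Constraints are ("count", max_matches) or ("rmsd", cap); the ensemble is
    already RMSD-sorted, so both are truncations of the full search.
    """
    points = []
    for kind, value in constraints:
        if kind == "count":
            sub = ensemble.truncated(max_matches=int(value))
        elif kind == "rmsd":
            sub = ensemble.truncated(rmsd_cap=float(value))
        else:
            raise ValueError(f"unknown constraint kind {kind!r}")
        if len(sub) == 0:
            points.append(SweepPoint(constraint=(kind, value), n_matches=0, r=float("nan")))
            continue
        sce = symmetrize(sce_matrix(sub, bg, epsilon_mode, delta))
        points.append(
            SweepPoint(constraint=(kind, value), n_matches=len(sub),
                       r=coupling_correlation(sce, experimental))
        )
    return points


def score_model(
    s: Structure,
    db: list[Structure],
    bg: BackgroundModel,
    lib: RotamerLibrary,
    flank: int = 1,
    cd_min: float = 0.1,
    cp: EnergyMatrix | None = None,
    cutoff: float | None = None,
    max_count: int = 50_000,
    min_matches: int = 1,
    epsilon_mode: str = "scaled",
    delta: float = 0.1,
    target_id: str = "",
    index: FragmentIndex | None = None,
) -> ModelScore:
    """Mean native-pair SCE (and CE) of a structural model over its contacts.

    Every contact with CD >= ``cd_min`` contributes: its flank-k motif is
    searched against ``db``, the SCE matrix computed, and the energy of the
    model's own amino-acid pair taken. Contacts whose ensembles hold fewer than
    ``min_matches`` matches are skipped; with no qualifying contact the score is
    flagged empty (n_contacts = 0, nan means).
    """
    contacts = enumerate_contacts(s, lib, flank=flank, min_cd=cd_min)
    sces, ces = [], []
    for rec in contacts:
        try:
            motif = extract_motif(s, (rec.chain_i, rec.pos_i), (rec.chain_j, rec.pos_j), flank)
        except ValueError:
            continue
        ens = search_matches(motif, db, cutoff=cutoff, max_count=max_count, index=index)
        if len(ens) < min_matches:
            logger.info("contact %s/%s-%s/%s: only %d matches, skipped",
                        rec.chain_i, rec.pos_i, rec.chain_j, rec.pos_j, len(ens))
            continue
        sce = sce_matrix(ens, bg, epsilon_mode, delta)
        sces.append(sce[rec.aa_i, rec.aa_j])
        if cp is not None:
            ces.append(cp.lookup(rec.aa_i, rec.aa_j))
    n = len(sces)
    return ModelScore(
        model_id=s.id, target_id=target_id,
        mean_sce=float(np.mean(sces)) if n else float("nan"),
        mean_ce=float(np.mean(ces)) if ces else float("nan"),
        n_contacts=n,
    )


def roc_auc(
    scores: list[ModelScore],
    quality_threshold: float,
    direction: str = "ge",
    energy: str = "mean_sce",
) -> ROCResult:
    """ROC curve and AUC for separating high- from low-quality models by mean
    energy.

    Positives have quality >= threshold (direction "ge"; use "le" for
    RMSD-like metrics where lower is better). The classifier score is the
    negated mean energy: more favorable energy predicts higher quality. AUC is
    the trapezoid area, which equals the Mann-Whitney U statistic over n+ * n-
    with the midrank convention for ties.
    """
    labeled = [m for m in scores if m.quality is not None and not m.empty]
    y = np.array([
        (m.quality >= quality_threshold) if direction == "ge" else (m.quality <= quality_threshold)
        for m in labeled
    ])
    x = -np.array([getattr(m, energy) for m in labeled])
    return auc_curve(x, y)


def auc_curve(score: np.ndarray, positive: np.ndarray) -> ROCResult:
    """ROC curve from raw classifier scores (higher = predicted positive)."""
    score = np.asarray(score, float)
    positive = np.asarray(positive, bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("one class empty (n+=%d, n-=%d); AUC undefined", n_pos, n_neg)
        return ROCResult(fpr=np.array([]), tpr=np.array([]), auc=float("nan"),
                         n_pos=n_pos, n_neg=n_neg)
    order = np.argsort(-score, kind="stable")
    sorted_pos = positive[order]
    sorted_score = score[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # collapse tied scores so the curve steps once per distinct threshold
    distinct = np.nonzero(np.diff(sorted_score))[0]
    idx = np.concatenate([distinct, [len(sorted_score) - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def alternate_best_worst(models: list[tuple[str, float]], k: int = 20) -> list[tuple[str, float]]:
    """Select up to k models spanning the quality range by alternately taking the
    next-best and next-worst remaining (by the quality value, descending)."""
    pool = sorted(models, key=lambda mq: -mq[1])
    picked = []
    take_best = True
    while pool and len(picked) < k:
        picked.append(pool.pop(0) if take_best else pool.pop())
        take_best = not take_best
    return picked


def read_quality_table(path) -> pd.DataFrame:
    """TSV with columns target, model, metric, value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"target", "model", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"quality table needs columns {sorted(required)}")
    return df
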