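"""Consensus ranking of docking scores and Spearman significance.

Each scoring function ranks the ligands (rank 1 = best, average ranks on
ties, orientation-aware); the consensus rank of a ligand is its mean rank
across functions. Spearman's ρ between any ranking and the ranked
experimental activities measures agreement, and significance is judged
against a permutation null: the distribution of ρ between a fixed
ranking and uniformly random permutations. For 21 ligands the two-sided
critical values are 0.37 (90% confidence) and 0.44 (95%).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreTable",
    "RankResult",
    "rank_scores",
    "consensus_rank",
    "spearman_rho",
    "critical_value",
    "flag_significance",
    "analyze_scores",
]

CONFIDENCE_LEVELS = (0.90, 0.95)


@dataclass(frozen=True)
class ScoreTable:
    """Ligand × scoring-function score matrix with orientations.

    ``higher_better`` must name every scoring function: True if larger
    scores mean better predicted binding (e.g. GoldScore), False for
    energy-like scores where more negative is better.
    """

    scores: pd.DataFrame
    higher_better: dict[str, bool]

    def __post_init__(self):
        if len(self.scores) < 2:
            raise ValueError("score table needs at least 2 ligands")
        if self.scores.isna().any().any():
            raise ValueError("score table has missing cells")
        undeclared = [c for c in self.scores.columns if c not in self.higher_better]
        if undeclared:
            raise ValueError(f"orientation undeclared for: {undeclared}")

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def function_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class RankResult:
    """Ranks, consensus, ρ values and significance flags."""

    per_function_ranks: pd.DataFrame
    consensus: pd.Series
    rho_per_function: dict[str, float]
    rho_consensus: float
    critical_values: dict[float, float]
    flags: dict[str, str]
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ranking": name,
                "spearman_rho": self.rho_per_function[name],
                "significance": self.flags[name],
            }
            for name in self.per_function_ranks.columns
        ]
        rows.append(
            {
                "ranking": "consensus",
                "spearman_rho": self.rho_consensus,
                "significance": self.flags["consensus"],
            }
        )
        return pd.DataFrame(rows).set_index("ranking")


def rank_scores(t: ScoreTable) -> pd.DataFrame:
    """Per-function ligand ranks, 1 = best, average ranks for ties."""
    ranks = {}
    for name in t.function_names:
        s = t.scores[name].to_numpy(dtype=float)
        oriented = -s if t.higher_better[name] else s
        ranks[name] = stats.rankdata(oriented, method="average")
    return pd.DataFrame(ranks, index=t.scores.index)


def consensus_rank(ranks: pd.DataFrame) -> pd.Series:
    """Mean of per-function ranks for each ligand."""
    if ranks.shape[1] < 1:
        raise ValueError("need at least one ranking")
    return ranks.mean(axis=1)


def spearman_rho(a, b) -> float:
    """Spearman's ρ: Pearson correlation of two rank vectors."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.size < 3:
        raise ValueError("rank vectors must have equal length >= 3")
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("zero rank variance; rho undefined")
    return float(np.corrcoef(av, bv)[0, 1])


@functools.lru_cache(maxsize=32)
def _null_rho_sample(n: int, n_perm: int, seed: int) -> np.ndarray:
    """Sorted null sample of ρ between random permutations and identity.

    Permutations are rank vectors without ties, so ρ reduces to
    1 − 6·Σd²/(n(n²−1)); computed in chunks to bound memory.
    """
    rng = np.random.default_rng(seed)
    identity = np.arange(n)
    denom = n * (n**2 - 1)
    out = np.empty(n_perm)
    chunk = 200_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.random((m, n)).argsort(axis=1)
        d2 = ((perms - identity) ** 2).sum(axis=1)
        out[done : done + m] = 1.0 - 6.0 * d2 / denom
        done += m
    out.sort()
    return out


def critical_value(
    n: int, confidence: float, n_perm: int = 100_000, seed: int = 0
) -> float:
    """Two-sided permutation critical value of Spearman's ρ.

    Estimated from the null distribution of ρ between a fixed ranking of
    n items and uniformly random permutations: the smallest attainable ρ
    whose upper-tail probability is at most α/2 (α = 1 − confidence).
    This is the convention of printed significance tables; it equals the
    (1 − α/2) quantile up to the discreteness of the null, which matters
    at small n. By the null's symmetry the two-sided test on |ρ| reduces
    to this one-sided form. Deterministic given ``seed``.
    """
    if n < 5:
        raise ValueError("permutation null too coarse below n = 5")
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must be in (0.5, 1)")
    null = _null_rho_sample(n, n_perm, seed)  # sorted ascending
    alpha = 1.0 - confidence
    m = len(null)
    limit = alpha / 2.0 * m
    # tail count of the first occurrence of each value; nonincreasing in i
    first_occ = np.searchsorted(null, null, side="left")
    tails = m - first_occ
    idx = int(np.argmax(tails <= limit))
    if tails[idx] > limit:
        raise ValueError(f"confidence {confidence} unattainable with {m} permutations")
    return float(null[idx])


def flag_significance(
    rho: float, n: int, n_perm: int = 100_000, seed: int = 0
) -> str:
    """Highest confidence level at which |ρ| is significant.

    Returns "95%", "90%" or "none", using the two-sided permutation
    critical values at the standard confidence levels.
    """
    flag = "none"
    for conf in sorted(CONFIDENCE_LEVELS):
        if abs(rho) > critical_value(n, conf, n_perm=n_perm, seed=seed):
            flag = f"{int(round(conf * 100))}%"
    return flag


def analyze_scores(
    t: ScoreTable,
    activities,
    n_perm: int = 100_000,
    seed: int = 0,
) -> RankResult:
    """Full consensus analysis of a score table against activities.

    Ranks every scoring function, averages ranks into a consensus,
    computes Spearman's ρ of each ranking against the experimental
    activity ranking (rank 1 = most active), and flags significance at
    the permutation critical values.
    """
    act = np.asarray(activities, dtype=float)
    if len(act) != len(t.scores):
        raise ValueError("activity vector length does not match score table")
    ranks = rank_scores(t)
    cons = consensus_rank(ranks)
    act_ranks = stats.rankdata(-act, method="average")  # rank 1 = most active
    n = len(act)
    rho_fn = {name: spearman_rho(ranks[name], act_ranks) for name in ranks.columns}
    rho_cons = spearman_rho(cons, act_ranks)
    crits = {conf: critical_value(n, conf, n_perm=n_perm, seed=seed) for conf in CONFIDENCE_LEVELS}
    flags = {name: flag_significance(rho, n, n_perm=n_perm, seed=seed) for name, rho in rho_fn.items()}
    flags["consensus"] = flag_significance(rho_cons, n, n_perm=n_perm, seed=seed)
    return RankResult(
        per_function_ranks=ranks,
        consensus=cons,
        rho_per_function=rho_fn,
        rho_consensus=rho_cons,
        critical_values=crits,
        flags=flags,
        n_permutations=n_perm,
        seed=seed,
    )
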