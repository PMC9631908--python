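"""Dataset curation and diversity-balanced train/test splitting.

The curation protocol removes structural singletons (mean pairwise
Tanimoto similarity below a threshold), bins the remaining compounds
into one-log-unit activity intervals, and builds a training set that
contains each bin's activity extremes while the most data-set-typical
compound of each bin goes to the test set. The split is then topped up
or trimmed to an ~80/20 ratio. A Shapiro–Wilk check reports whether
activities are normally distributed (advisory only — skewed targets are
analysed anyway, with a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chem_core import Molecule, fingerprint, tanimoto

__all__ = [
    "ActivityDataset",
    "SimilarityMatrix",
    "SplitResult",
    "TRANSPORTERS",
    "similarity_matrix",
    "mean_tanimoto",
    "filter_dissimilar",
    "bin_by_activity",
    "assign_split",
    "shapiro_wilk",
    "split_distribution_report",
]

TRANSPORTERS = ("dat", "net", "sert")


@dataclass(frozen=True)
class ActivityDataset:
    """Compounds with per-transporter pKi values (log units).

    ``table`` is indexed by unique compound id with a ``smiles`` column
    and one ``pki_<target>`` column per transporter; ``molecules`` maps
    id → parsed :class:`Molecule`.
    """

    table: pd.DataFrame
    molecules: dict[str, Molecule]

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def pki(self, target: str) -> pd.Series:
        col = f"pki_{target}"
        if col not in self.table.columns:
            raise KeyError(f"no activity column {col!r}")
        return self.table[col]

    def subset(self, ids: list[str]) -> "ActivityDataset":
        return ActivityDataset(
            table=self.table.loc[ids],
            molecules={i: self.molecules[i] for i in ids},
        )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise Tanimoto matrix over a fixed id order."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    n_bits: int = 1024
    max_path: int = 7

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")

    def value(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[ia, ib])


def similarity_matrix(
    d: ActivityDataset, n_bits: int = 1024, max_path: int = 7
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix from hashed linear-path fingerprints."""
    ids = tuple(d.ids)
    fps = [fingerprint(d.molecules[i], n_bits=n_bits, max_path=max_path) for i in ids]
    n = len(ids)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(ids=ids, matrix=m, n_bits=n_bits, max_path=max_path)


def mean_tanimoto(m: SimilarityMatrix) -> pd.DataFrame:
    """Mean (and SD) of each compound's similarities to all others."""
    n = len(m.ids)
    if n < 2:
        raise ValueError("mean Tanimoto requires at least 2 compounds")
    off = m.matrix[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    return pd.DataFrame(
        {"mean_tc": off.mean(axis=1), "sd_tc": off.std(axis=1, ddof=1) if n > 2 else 0.0},
        index=pd.Index(m.ids, name="compound_id"),
    )


def filter_dissimilar(
    d: ActivityDataset, m: SimilarityMatrix, threshold: float = 0.2
) -> tuple[ActivityDataset, pd.DataFrame]:
    """Remove compounds whose mean Tc is strictly below ``threshold``.

    Returns the retained dataset and a removal report (mean and SD of Tc
    for each removed compound). Compounds at exactly the threshold are
    retained.
    """
    stats_df = mean_tanimoto(m)
    removed_mask = stats_df["mean_tc"] < threshold
    removed = stats_df[removed_mask]
    kept_ids = [i for i in d.ids if i not in set(removed.index)]
    if not kept_ids:
        raise ValueError(f"all compounds fall below mean Tc {threshold}")
    return d.subset(kept_ids), removed


def bin_by_activity(d: ActivityDataset, target: str) -> dict[int, list[str]]:
    """Group compounds into one-log-unit pKi bins [k, k+1)."""
    pki = d.pki(target)
    missing = pki.index[pki.isna()].tolist()
    if missing:
        raise ValueError(f"missing pKi ({target}) for: {missing}")
    bins: dict[int, list[str]] = {}
    for cid, value in pki.items():
        bins.setdefault(int(math.floor(value)), []).append(cid)
    return {k: bins[k] for k in sorted(bins)}


@dataclass(frozen=True)
class SplitResult:
    """Outcome of the diversity-balanced split for one transporter."""

    target: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    removed: pd.DataFrame
    bin_labels: dict[str, int]
    train_fraction: float
    mean_tc: pd.Series | None = None

    def role_of(self, cid: str) -> str:
        if cid in self.train_ids:
            return "train"
        if cid in self.test_ids:
            return "test"
        return "removed"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in [*self.train_ids, *self.test_ids]:
            rows.append(
                {
                    "compound_id": cid,
                    "role": self.role_of(cid),
                    "bin": self.bin_labels[cid],
                    "mean_tc": None if self.mean_tc is None else round(float(self.mean_tc[cid]), 4),
                }
            )
        for cid in self.removed.index:
            rows.append(
                {
                    "compound_id": cid,
                    "role": "removed",
                    "bin": None,
                    "mean_tc": round(float(self.removed.loc[cid, "mean_tc"]), 4),
                }
            )
        return pd.DataFrame(rows).set_index("compound_id")


def assign_split(
    bins: dict[int, list[str]],
    m: SimilarityMatrix,
    d: ActivityDataset,
    target: str,
    train_fraction: float = 0.8,
    removed: pd.DataFrame | None = None,
) -> SplitResult:
    """Build the training/test split from activity bins and similarities.

    Per bin: the compounds with the smallest and greatest pKi go to
    training; of the remainder, the one with the greatest mean Tc (most
    typical of the data set) goes to the test set and the rest to
    training. The test set is then topped up with the next-most-typical
    training compounds (never bin extremes), or trimmed back, until the
    training fraction matches ``train_fraction`` to within one compound.
    All ties break on lexicographic compound id, making the split a pure
    function of its inputs.
    """
    all_ids = [cid for members in bins.values() for cid in members]
    if len(all_ids) < 5:
        raise ValueError(f"only {len(all_ids)} compounds retained; split is meaningless")
    pki = d.pki(target)
    tc = mean_tanimoto(m)["mean_tc"]

    train: list[str] = []
    test: list[str] = []
    extremes: set[str] = set()
    bin_labels: dict[str, int] = {}
    for k, members in sorted(bins.items()):
        for cid in members:
            bin_labels[cid] = k
        lo = min(members, key=lambda c: (pki[c], c))
        hi = sorted(members, key=lambda c: (-pki[c], c))[0]
        extremes.update({lo, hi})
        train.extend(sorted({lo, hi}))
        rest = [c for c in members if c not in {lo, hi}]
        if rest:
            pick = sorted(rest, key=lambda c: (-tc[c], c))[0]
            test.append(pick)
            train.extend(c for c in rest if c != pick)

    n = len(all_ids)
    target_train = round(train_fraction * n)
    # top up the test set with the most typical non-extreme training compounds
    while len(train) > target_train:
        movable = sorted((c for c in train if c not in extremes), key=lambda c: (-tc[c], c))
        if not movable:
            break
        train.remove(movable[0])
        test.append(movable[0])
    # trim the test set back, least typical first
    while len(train) < target_train and test:
        give_back = sorted(test, key=lambda c: (tc[c], c))[0]
        test.remove(give_back)
        train.append(give_back)

    train_sorted = tuple(sorted(train, key=lambda c: (bin_labels[c], pki[c], c)))
    test_sorted = tuple(sorted(test, key=lambda c: (bin_labels[c], pki[c], c)))
    return SplitResult(
        target=target,
        train_ids=train_sorted,
        test_ids=test_sorted,
        removed=removed if removed is not None else pd.DataFrame(columns=["mean_tc", "sd_tc"]),
        bin_labels=bin_labels,
        train_fraction=train_fraction,
        mean_tc=tc,
    )


def shapiro_wilk(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality test: (W, p, H0-accepted-at-alpha)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro–Wilk requires at least 3 observations")
    if arr.size > 5000:
        raise ValueError("Shapiro–Wilk is unreliable above n = 5000")
    w, p = stats.shapiro(arr)
    return float(w), float(p), bool(p > alpha)


def split_distribution_report(
    s: SplitResult, d: ActivityDataset, m: SimilarityMatrix
) -> dict:
    """Summaries showing whether train and test represent the data set.

    Per-bin counts and pKi/mean-Tc summary statistics for the training
    set, the test set and the full retained set, plus a two-sample
    Kolmogorov–Smirnov diagnostic between train and test pKi values and
    advisory Shapiro–Wilk results.
    """
    pki = d.pki(s.target)
    tc = mean_tanimoto(m)["mean_tc"]

    def summary(ids):
        v, t = pki[list(ids)], tc[list(ids)]
        return {
            "n": len(ids),
            "pki_mean": float(v.mean()),
            "pki_sd": float(v.std(ddof=1)) if len(ids) > 1 else 0.0,
            "pki_min": float(v.min()),
            "pki_max": float(v.max()),
            "tc_mean": float(t.mean()),
            "tc_sd": float(t.std(ddof=1)) if len(ids) > 1 else 0.0,
        }

    def bin_counts(ids):
        counts: dict[int, int] = {}
        for cid in ids:
            counts[s.bin_labels[cid]] = counts.get(s.bin_labels[cid], 0) + 1
        return {str(k): counts[k] for k in sorted(counts)}

    all_ids = [*s.train_ids, *s.test_ids]
    ks = stats.ks_2samp(pki[list(s.train_ids)], pki[list(s.test_ids)])
    w, p, normal = shapiro_wilk(pki[all_ids], alpha=0.1)
    if not normal:
        warnings.warn(
            f"{s.target.upper()} activities are not normally distributed "
            f"(Shapiro–Wilk W={w:.3f}, p={p:.3g}); model robustness may suffer",
            stacklevel=2,
        )
    return {
        "target": s.target,
        "bins": {
            "train": bin_counts(s.train_ids),
            "test": bin_counts(s.test_ids),
            "full": bin_counts(all_ids),
        },
        "summary": {
            "train": summary(s.train_ids),
            "test": summary(s.test_ids),
            "full": summary(all_ids),
        },
        "ks_train_vs_test": {"statistic": float(ks.statistic), "p_value": float(ks.pvalue)},
        "shapiro_wilk": {"W": w, "p": p, "normal_at_0.1": normal},
    }
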