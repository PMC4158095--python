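"""Noise-distribution differential-expression calling.

For a two-condition contrast the per-gene signal is the pair
(M, D): M = log2(x̄1/x̄2), the log fold change of condition-mean TPM, and
D = |x̄1 − x̄2|, their absolute difference.  An empirical null — the
"noise" distribution — is built by computing the same (|M*|, |D*|) pair
for every within-condition replicate-vs-replicate comparison of every
gene and pooling across both conditions.  The probability that a gene is
differentially expressed is the fraction of noise pairs its signal
strictly dominates:

    P1(g) = #{ (|M*|,|D*|) : |M*| < |M_g| and |D*| < |D_g| } / #noise

with P0 = 1 − P1 and odds P1/P0.  A gene is called significant when
P1 >= q_threshold (default 0.8, i.e. odds 4:1) and |M| >= m_threshold
(default 1, a two-fold change).  Zero means are replaced by a small
pseudo-expression before the log ratio so M stays finite; D is computed
on the raw means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_PSEUDO = 0.5
DEFAULT_Q_THRESHOLD = 0.8
DEFAULT_M_THRESHOLD = 1.0


@dataclass
class Contrast:
    """Two conditions, each a list of library column names (replicates)."""

    label: str
    condition_1: Sequence[str]
    condition_2: Sequence[str]

    def validate(self, columns: Sequence[str], need_replicates: bool = True) -> None:
        missing = [c for c in [*self.condition_1, *self.condition_2] if c not in columns]
        if missing:
            raise ValueError(f"contrast {self.label!r} references absent libraries: {missing}")
        if need_replicates:
            for name, cond in (("condition_1", self.condition_1), ("condition_2", self.condition_2)):
                if len(cond) < 2:
                    raise ValueError(
                        f"contrast {self.label!r}: {name} has {len(cond)} replicate(s); "
                        "the noise distribution needs at least 2"
                    )


def threshold_odds(q_threshold: float = DEFAULT_Q_THRESHOLD) -> float:
    """Odds P1/P0 implied by a probability threshold (0.8 -> 4.0)."""
    return q_threshold / (1.0 - q_threshold)


def _smoothed_log2_ratio(a: np.ndarray, b: np.ndarray, pseudo: float) -> np.ndarray:
    a = np.where(a > 0, a, pseudo)
    b = np.where(b > 0, b, pseudo)
    return np.log2(a / b)


def signal_statistics(
    tpm: pd.DataFrame, contrast: Contrast, pseudo: float = DEFAULT_PSEUDO
) -> pd.DataFrame:
    """Per-gene condition means, M and D for a contrast."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    contrast.validate(tpm.columns, need_replicates=False)
    x1 = tpm[list(contrast.condition_1)].mean(axis=1).to_numpy()
    x2 = tpm[list(contrast.condition_2)].mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "mean_1": x1,
            "mean_2": x2,
            "M": _smoothed_log2_ratio(x1, x2, pseudo),
            "D": np.abs(x1 - x2),
        },
        index=tpm.index,
    )


def noise_distribution(
    tpm: pd.DataFrame, contrast: Contrast, pseudo: float = DEFAULT_PSEUDO
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (|M*|, |D*|) from all within-condition replicate pairs.

    With r replicates per condition each gene contributes C(r,2) pairs per
    condition; r = 2 in both conditions gives 2 noise pairs per gene.
    """
    contrast.validate(tpm.columns, need_replicates=True)
    abs_m: list[np.ndarray] = []
    abs_d: list[np.ndarray] = []
    for cond in (contrast.condition_1, contrast.condition_2):
        for a_col, b_col in combinations(cond, 2):
            a = tpm[a_col].to_numpy()
            b = tpm[b_col].to_numpy()
            abs_m.append(np.abs(_smoothed_log2_ratio(a, b, pseudo)))
            abs_d.append(np.abs(a - b))
    return np.concatenate(abs_m), np.concatenate(abs_d)


def de_probability(
    signal: pd.DataFrame, noise: tuple[np.ndarray, np.ndarray], chunk: int = 512
) -> pd.Series:
    """P1 per gene: fraction of noise pairs strictly dominated by (|M|,|D|).

    Strict inequalities throughout — ties do not count as exceedance, so a
    gene with M = D = 0 has P1 = 0.
    """
    noise_m, noise_d = noise
    if noise_m.size == 0:
        raise ValueError("empty noise distribution")
    sig_m = np.abs(signal["M"].to_numpy())
    sig_d = np.abs(signal["D"].to_numpy())
    p1 = np.empty(len(sig_m))
    for lo in range(0, len(sig_m), chunk):
        hi = lo + chunk
        dominated = (noise_m[None, :] < sig_m[lo:hi, None]) & (
            noise_d[None, :] < sig_d[lo:hi, None]
        )
        p1[lo:hi] = dominated.sum(axis=1) / noise_m.size
    return pd.Series(p1, index=signal.index, name="P1")


@dataclass
class DEResult:
    """Full per-gene DE table for one contrast plus its call summary."""

    contrast: Contrast
    table: pd.DataFrame  # mean_1, mean_2, M, D, P1, significant, direction
    q_threshold: float = DEFAULT_Q_THRESHOLD
    m_threshold: float = DEFAULT_M_THRESHOLD

    @property
    def significant_genes(self) -> set:
        return set(self.table.index[self.table["significant"]])

    def summary(self) -> dict:
        sig = self.table[self.table["significant"]]
        return {
            "contrast": self.contrast.label,
            "n_genes": len(self.table),
            "n_significant": len(sig),
            "up_in_condition_1": int((sig["direction"] == "up_in_condition_1").sum()),
            "up_in_condition_2": int((sig["direction"] == "up_in_condition_2").sum()),
        }


def call_degs(
    signal: pd.DataFrame,
    p1: pd.Series,
    contrast: Contrast,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    m_threshold: float = DEFAULT_M_THRESHOLD,
) -> DEResult:
    """Apply the probability-and-fold-change calling rule."""
    table = signal.copy()
    table["P1"] = p1
    table["P0"] = 1.0 - p1
    table["significant"] = (table["P1"] >= q_threshold) & (
        table["M"].abs() >= m_threshold
    )
    direction = np.where(table["M"] > 0, "up_in_condition_1", "up_in_condition_2")
    table["direction"] = np.where(table["significant"], direction, "")
    return DEResult(contrast=contrast, table=table, q_threshold=q_threshold, m_threshold=m_threshold)


def run_contrast(
    tpm: pd.DataFrame,
    contrast: Contrast,
    pseudo: float = DEFAULT_PSEUDO,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    m_threshold: float = DEFAULT_M_THRESHOLD,
) -> DEResult:
    """signal_statistics -> noise_distribution -> de_probability -> call_degs."""
    signal = signal_statistics(tpm, contrast, pseudo)
    noise = noise_distribution(tpm, contrast, pseudo)
    p1 = de_probability(signal, noise)
    return call_degs(signal, p1, contrast, q_threshold, m_threshold)


def overlap_counts(deg_sets: dict[str, set]) -> pd.DataFrame:
    """Venn-region membership counts for up to a handful of DEG sets.

    Each row is one non-empty membership pattern; region counts sum to the
    size of the union (inclusion–exclusion holds exactly by construction).
    """
    labels = list(deg_sets)
    universe = set().union(*deg_sets.values()) if deg_sets else set()
    rows = []
    patterns: dict[tuple[bool, ...], int] = {}
    for gene in universe:
        key = tuple(gene in deg_sets[l] for l in labels)
        patterns[key] = patterns.get(key, 0) + 1
    for key, n in sorted(patterns.items(), reverse=True):
        rows.append(
            {**{l: int(k) for l, k in zip(labels, key)}, "n_genes": n}
        )
    df = pd.DataFrame(rows, columns=[*labels, "n_genes"])
    df.attrs["union_size"] = len(universe)
    return df
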