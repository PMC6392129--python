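"""Evaluation statistics for integrity indexes.

Two procedures score how well an integrity index tracks transcript loss
along a degradation series:

* Kendall rank correlation (tau-b, tie-corrected) between each index and
  the Cts of reference transcripts, with an exact permutation p-value at
  small n (degradation series typically have 4-8 points, where the normal
  approximation is poor) and the tie-corrected normal approximation
  otherwise.
* One-way ANOVA across degradation levels followed — only when the ANOVA
  is significant — by Tukey's HSD all-pairs post hoc test, summarized as a
  compact letter display: levels sharing a letter are not significantly
  different at the chosen alpha.

Tau-b is computed by direct pair counting in integer arithmetic (series
are short, so the O(n^2) count is immaterial and exactly reproducible);
the asymptotic p-value and the Tukey pairwise p-values come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError
from .ramp_core import UNDEFINED, _Undefined

__all__ = [
    "KendallResult",
    "CorrelationEntry",
    "CorrelationReport",
    "LetterDisplay",
    "AnovaTukeyResult",
    "kendall_tau_b",
    "correlate_indexes",
    "oneway_anova_tukey",
    "compact_letter_display",
]

EXACT_P_MAX_N = 8


@dataclass(frozen=True)
class KendallResult:
    """Tau-b and its p-value; ``method`` is ``exact`` or ``asymptotic``."""

    tau: float | _Undefined
    p_value: float | _Undefined
    n: int
    method: str

    @property
    def defined(self) -> bool:
        return not isinstance(self.tau, _Undefined)


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    """Concordant/discordant pairs and per-vector tie counts, all integers."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif (dx > 0) == (dy > 0):
                concordant += 1
            else:
                discordant += 1
    return concordant, discordant, ties_x, ties_y


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by enumerating all n! orderings of y.

    Under the permutation null the tau-b denominator is fixed by the two
    tie structures, so only the numerator C - D varies; the comparison is
    made on integer numerators and is exact.
    """
    n = len(x)
    sx = np.sign(x[:, None] - x[None, :]).astype(np.int64)
    sy = np.sign(y[:, None] - y[None, :]).astype(np.int64)
    num_obs = int(np.sum(np.triu(sx * sy, k=1)))
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    yp = np.asarray(y)[perms]  # (n!, n)
    nums = np.zeros(len(perms), dtype=np.int64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if sx[i, j]:
                nums += sx[i, j] * np.sign(yp[:, i] - yp[:, j]).astype(np.int64)
    return float(np.mean(np.abs(nums) >= abs(num_obs)))


def kendall_tau_b(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> KendallResult:
    """Tie-corrected Kendall rank correlation.

    ``tau_b = (C - D) / sqrt((n0 - Tx) * (n0 - Ty))`` with C/D the
    concordant/discordant pair counts, n0 = n(n-1)/2 and Tx/Ty the tied
    pair counts.  ``method``: ``exact`` (full permutation enumeration,
    n <= 8), ``asymptotic`` (normal approximation with tie correction), or
    ``auto`` (exact when n <= 8).  A constant vector has no rank
    information: tau and p are :data:`~ratioamp.ramp_core.UNDEFINED`.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise DomainError("x and y must be 1-D sequences of equal length")
    n = len(xa)
    if n < 3:
        raise DomainError("kendall_tau_b requires n >= 3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise DomainError("x and y must be finite")
    if method not in ("auto", "exact", "asymptotic"):
        raise DomainError("method must be 'auto', 'exact' or 'asymptotic'")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return KendallResult(UNDEFINED, UNDEFINED, n, "undefined")

    concordant, discordant, ties_x, ties_y = _pair_counts(xa, ya)
    n0 = n * (n - 1) // 2
    tau = (concordant - discordant) / math.sqrt((n0 - ties_x) * (n0 - ties_y))

    if method == "exact" and n > EXACT_P_MAX_N:
        raise DomainError(f"exact p-value limited to n <= {EXACT_P_MAX_N}")
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_P_MAX_N)
    if use_exact:
        p = _exact_permutation_p(xa, ya)
        return KendallResult(tau, p, n, "exact")
    p = float(sps.kendalltau(xa, ya, method="asymptotic").pvalue)
    return KendallResult(tau, p, n, "asymptotic")


@dataclass(frozen=True)
class CorrelationEntry:
    index_name: str
    target_name: str
    tau: float | _Undefined
    p_value: float | _Undefined
    n: int
    significant: bool


@dataclass(frozen=True)
class CorrelationReport:
    """Kendall correlation grid: integrity indexes x reference transcripts."""

    entries: tuple[CorrelationEntry, ...]
    alpha: float = 0.05

    def get(self, index_name: str, target_name: str) -> CorrelationEntry:
        for e in self.entries:
            if e.index_name == index_name and e.target_name == target_name:
                return e
        raise KeyError((index_name, target_name))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "index": e.index_name,
                    "target": e.target_name,
                    "tau": math.nan if isinstance(e.tau, _Undefined) else float(e.tau),
                    "p_value": float(e.p_value) if not isinstance(e.p_value, _Undefined) else math.nan,
                    "n": e.n,
                    "significant": e.significant,
                }
            )
        return pd.DataFrame(rows, columns=["index", "target", "tau", "p_value", "n", "significant"])


def correlate_indexes(
    table: pd.DataFrame,
    index_cols: Sequence[str],
    target_cols: Sequence[str],
    subset: Sequence[str] | None = None,
    experiment_col: str = "experiment",
    alpha: float = 0.05,
) -> CorrelationReport:
    """Kendall-correlate every integrity index against every target Ct.

    *table* holds one row per sample with index values (ratio-amplicon
    pairs, an electrophoretic score) and reference-transcript Cts.
    *subset* restricts to the named experiments — e.g. dropping a
    UV-style treatment to ask whether an electrophoresis-blind mechanism
    drove a poor correlation.  Rows with missing values are dropped per
    (index, target) combination; fewer than 3 complete rows is an error.
    """
    data = table
    if subset is not None:
        if experiment_col not in table.columns:
            raise DomainError(f"no column {experiment_col!r} to subset on")
        data = table[table[experiment_col].isin(list(subset))]
    entries: list[CorrelationEntry] = []
    for icol in index_cols:
        for tcol in target_cols:
            sub = data[[icol, tcol]].dropna()
            if len(sub) < 3:
                raise InsufficientDataError(
                    f"fewer than 3 complete rows for ({icol}, {tcol})"
                )
            res = kendall_tau_b(sub[icol].to_numpy(), sub[tcol].to_numpy())
            significant = res.defined and float(res.p_value) <= alpha
            entries.append(
                CorrelationEntry(icol, tcol, res.tau, res.p_value, res.n, significant)
            )
    return CorrelationReport(entries=tuple(entries), alpha=alpha)


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: levels sharing a letter are indistinguishable.

    ``letters`` maps level -> sorted letter string (e.g. ``"ab"``);
    ``pairwise_p`` maps each level pair to its Tukey-adjusted p-value and
    is empty when the post hoc step was skipped.
    """

    letters: Mapping[str, str]
    pairwise_p: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    display: LetterDisplay
    alpha: float
    posthoc_run: bool


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def compact_letter_display(
    levels: Sequence[str],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Starts from one group holding every level; each significant pair
    splits every group containing both; groups that become subsets of
    others are absorbed.  The result satisfies: two levels share a letter
    iff their adjusted p exceeds *alpha*.
    """
    sig_pairs = [
        pair for pair, p in pairwise_p.items() if p <= alpha
    ]
    groups: list[set[str]] = [set(levels)]
    for a, b in sig_pairs:
        next_groups: list[set[str]] = []
        for grp in groups:
            if a in grp and b in grp:
                next_groups.append(grp - {a})
                next_groups.append(grp - {b})
            else:
                next_groups.append(grp)
        # absorb: drop any group contained in another
        groups = [
            g
            for i, g in enumerate(next_groups)
            if g
            and not any(
                g < other or (g == other and i > j)
                for j, other in enumerate(next_groups)
            )
        ]
    letters: dict[str, list[str]] = {lv: [] for lv in levels}
    for letter, grp in zip(_LETTERS, groups):
        for lv in grp:
            letters[lv].append(letter)
    if len(groups) > len(_LETTERS):  # pragma: no cover - >26 groups
        raise DomainError("more homogeneous groups than available letters")
    return {lv: "".join(sorted(ls)) for lv, ls in letters.items()}


def oneway_anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA across degradation levels, with conditional Tukey HSD.

    The post hoc step runs only when the ANOVA p-value is at or below
    *alpha* (mirroring the conditional testing procedure); otherwise every
    level receives the same single letter.  Unequal group sizes use the
    Tukey-Kramer adjustment via the studentized-range distribution.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 levels")
    arrays: dict[str, np.ndarray] = {}
    for level, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise DomainError(f"level {level!r} has fewer than 2 replicates")
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"level {level!r} has non-finite values")
        arrays[level] = arr
    levels = list(arrays)

    f_stat, p_value = sps.f_oneway(*arrays.values())
    f_stat = float(f_stat)
    p_value = float(p_value)
    if math.isnan(f_stat):  # all groups identical constants
        f_stat, p_value = 0.0, 1.0

    if p_value > alpha:
        display = LetterDisplay(
            letters={lv: "a" for lv in levels}, pairwise_p={}
        )
        return AnovaTukeyResult(f_stat, p_value, display, alpha, posthoc_run=False)

    tukey = sps.tukey_hsd(*arrays.values())
    pairwise: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(levels)), 2):
        pairwise[(levels[i], levels[j])] = float(tukey.pvalue[i, j])
    letters = compact_letter_display(levels, pairwise, alpha)
    return AnovaTukeyResult(
        f_stat, p_value, LetterDisplay(letters=letters, pairwise_p=pairwise),
        alpha, posthoc_run=True,
    )
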