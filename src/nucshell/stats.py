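"""Region-of-interest aggregation, fold changes and two-group comparisons.

The statistical unit is the nucleus: layer profiles are first collapsed to
one value per nucleus per unit (layer or RO), and group statistics are then
taken across nuclei. Pooling voxels across nuclei is available only as a
diagnostic (`pooled_ro_means`) and never feeds a test.

With K = 24 layers and ro_size = 4 the regions of interest are RO-1
(layers 1-4, nuclear centre) through RO-6 (layers 21-24, outermost shell
next to the nuclear envelope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientReplicatesError, ValidationError
from .shells import RadialProfile

__all__ = [
    "ROSummary",
    "GroupComparison",
    "nucleus_ro_values",
    "aggregate_ro",
    "fold_change",
    "compare_groups",
    "pooled_ro_means",
]


@dataclass(frozen=True)
class ROSummary:
    """Cross-nucleus summary of one region of interest for one group."""

    ro_index: int
    layer_range: tuple[int, int]
    condition: str
    per_nucleus: np.ndarray  # one RO mean per nucleus (NaN-free)
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test result for one layer or one RO."""

    unit: str  # "layer" | "RO"
    index: int
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(self.p <= self.alpha)


def _sem(values: np.ndarray) -> float:
    n = values.size
    if n <= 1:
        return 0.0  # n = 1 convention: sd defined as 0
    return float(np.std(values, ddof=1) / np.sqrt(n))


def nucleus_ro_values(profile: RadialProfile, ro_size: int) -> np.ndarray:
    """Per-nucleus RO means: voxel-count-weighted mean of the layer means.

    Weighting by voxel count makes the RO value equal to the plain mean of
    the raw intensities over all voxels in the RO's layers; empty layers
    carry zero weight. An RO that is empty altogether yields NaN.
    """
    K = profile.K
    if K % ro_size != 0:
        raise ValidationError(f"K={K} is not divisible by ro_size={ro_size}")
    n_ro = K // ro_size
    out = np.empty(n_ro)
    for r in range(n_ro):
        sl = slice(r * ro_size, (r + 1) * ro_size)
        counts = profile.voxel_count[sl].astype(np.float64)
        means = profile.mean_intensity[sl]
        total = counts.sum()
        if total == 0:
            out[r] = np.nan
        else:
            filled = np.where(counts > 0, means, 0.0)
            out[r] = float(np.dot(filled, counts) / total)
    return out


def aggregate_ro(profiles: Iterable[RadialProfile], ro_size: int = 4) -> list[ROSummary]:
    """Collapse layer profiles into RO summaries for one group of nuclei.

    RO r covers layers ``(r-1)*ro_size + 1 .. r*ro_size``. Nuclei whose RO
    is entirely empty are excluded from that RO's statistics.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles to aggregate")
    ks = {p.K for p in profiles}
    if len(ks) > 1:
        raise ValidationError(f"profiles mix layer counts: {sorted(ks)}")
    K = ks.pop()
    if K % ro_size != 0:
        raise ValidationError(f"K={K} is not divisible by ro_size={ro_size}")
    conditions = {p.condition for p in profiles}
    condition = conditions.pop() if len(conditions) == 1 else "mixed"
    values = np.vstack([nucleus_ro_values(p, ro_size) for p in profiles])
    summaries = []
    for r in range(K // ro_size):
        col = values[:, r]
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise DegenerateDataError(f"RO-{r + 1} is empty in every nucleus")
        summaries.append(
            ROSummary(
                ro_index=r + 1,
                layer_range=(r * ro_size + 1, (r + 1) * ro_size),
                condition=condition,
                per_nucleus=col,
                mean=float(col.mean()),
                sem=_sem(col),
                n=int(col.size),
            )
        )
    return summaries


def fold_change(summary_a: ROSummary, summary_b: ROSummary) -> float:
    """Ratio of group means, b over a (e.g. RO-6 mean / RO-1 mean)."""
    if summary_a.mean == 0:
        raise DegenerateDataError("fold change undefined: reference RO mean is 0")
    return summary_b.mean / summary_a.mean


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        # both samples constant: scipy yields 0/0
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    return t, p


def compare_groups(
    profiles_a: Sequence[RadialProfile],
    profiles_b: Sequence[RadialProfile],
    unit: str = "RO",
    alpha: float = 0.05,
    ro_size: int = 4,
    equal_var: bool = True,
    holm: bool = False,
) -> list[GroupComparison]:
    """Per-layer or per-RO two-sample t-tests between two conditions.

    Equal-variance (Student's) two-sided test by default; ``equal_var=False``
    switches to Welch. ``holm=True`` applies a Holm step-down correction
    across the units before flagging significance (off by default: each
    unit is reported at face value).
    """
    if unit not in ("layer", "RO"):
        raise ValidationError(f"unit must be 'layer' or 'RO', got {unit!r}")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 nuclei per group, got {len(profiles_a)} and {len(profiles_b)}"
        )
    label_a = profiles_a[0].condition or "A"
    label_b = profiles_b[0].condition or "B"

    def per_nucleus_matrix(profiles: Sequence[RadialProfile]) -> np.ndarray:
        if unit == "layer":
            return np.vstack([p.mean_intensity for p in profiles])
        return np.vstack([nucleus_ro_values(p, ro_size) for p in profiles])

    mat_a = per_nucleus_matrix(profiles_a)
    mat_b = per_nucleus_matrix(profiles_b)
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValidationError("groups have different numbers of units")
    results = []
    for idx in range(mat_a.shape[1]):
        a = mat_a[:, idx]
        b = mat_b[:, idx]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            # a unit empty/missing in nearly all nuclei (e.g. layer K on
            # nuclei thinner than one voxel step per bin): report NaN
            # rather than abort the whole comparison
            t, p = np.nan, np.nan
        else:
            t, p = _ttest(a, b, equal_var)
        results.append(
            GroupComparison(
                unit=unit,
                index=idx + 1,
                group_a=label_a,
                group_b=label_b,
                mean_a=float(a.mean()) if a.size else np.nan,
                mean_b=float(b.mean()) if b.size else np.nan,
                sem_a=_sem(a),
                sem_b=_sem(b),
                n_a=int(a.size),
                n_b=int(b.size),
                t=t,
                p=p,
                alpha=alpha,
            )
        )
    if holm:
        order = np.argsort([r.p for r in results])
        m = len(results)
        adjusted = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * results[i].p)
            adjusted[i] = min(1.0, running)
        results = [
            GroupComparison(**{**r.__dict__, "p": float(adjusted[i])})
            for i, r in enumerate(results)
        ]
    return results


def pooled_ro_means(profiles: Sequence[RadialProfile], ro_size: int = 4) -> np.ndarray:
    """Diagnostic only: RO means pooling voxels across all nuclei."""
    ks = {p.K for p in profiles}
    if len(ks) != 1:
        raise ValidationError("profiles mix layer counts")
    K = ks.pop()
    n_ro = K // ro_size
    sums = np.zeros(n_ro)
    counts = np.zeros(n_ro)
    for p in profiles:
        for r in range(n_ro):
            sl = slice(r * ro_size, (r + 1) * ro_size)
            c = p.voxel_count[sl].astype(float)
            m = np.where(c > 0, p.mean_intensity[sl], 0.0)
            sums[r] += np.dot(m, c)
            counts[r] += c.sum()
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
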