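"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: the distance
oracle is an O(n^2) nearest-background scan, the Otsu oracle walks every
histogram split with plain two-class arithmetic, and the t oracle is the
closed-form pooled-variance statistic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_edt(fg: np.ndarray, sampling=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Exhaustive nearest-background Euclidean distance (tiny volumes only)."""
    fg = np.asarray(fg, dtype=bool)
    sampling = np.asarray(sampling, dtype=float)
    out = np.zeros(fg.shape, dtype=float)
    bg_coords = np.argwhere(~fg) * sampling
    fg_coords = np.argwhere(fg)
    if fg_coords.size == 0:
        return out
    assert bg_coords.size > 0, "oracle needs at least one background voxel"
    for idx in fg_coords:
        delta = bg_coords - idx * sampling
        out[tuple(idx)] = np.sqrt((delta**2).sum(axis=1).min())
    return out


def exhaustive_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Scan every histogram split, maximizing between-class variance.

    Returns the midpoint between the largest background and smallest
    foreground value of the best split (first maximum on ties), mirroring
    the production convention with independent per-split arithmetic.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_k, best_var = None, -np.inf
    total = counts.sum()
    for k in range(n_bins - 1):
        c0, c1 = counts[: k + 1], counts[k + 1 :]
        w0, w1 = c0.sum(), c1.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float(np.dot(c0, centers[: k + 1])) / w0
        mu1 = float(np.dot(c1, centers[k + 1 :])) / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    assert best_k is not None
    cut = edges[best_k + 1]
    return float((values[values < cut].max() + values[values >= cut].min()) / 2.0)


def pooled_t_and_p(a, b) -> tuple[float, float]:
    """Closed-form pooled-variance two-sided t-test."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def mcf10a_phantom():
    """One MCF10A-like phantom with default noise, reused across tests."""
    from nucshell import mcf10a_like

    return mcf10a_like(seed=11)


@pytest.fixture(scope="session")
def mcf10a_analysis(mcf10a_phantom):
    """Segmentation + profiling of the shared phantom (expensive, run once)."""
    from nucshell import analyse_volume

    img, truth = mcf10a_phantom
    labels, profiles, dmax = analyse_volume(img)
    return img, truth, labels, profiles, dmax


@pytest.fixture()
def small_sphere_volume():
    """Solid sphere radius 12 voxels in a 32^3 grid, unit spacing."""
    from nucshell.segment import LabelMask

    zz, yy, xx = np.mgrid[0:32, 0:32, 0:32]
    fg = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 12**2
    return LabelMask(fg.astype(np.int32), (1.0, 1.0, 1.0))
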