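"""Shared fixtures and independent oracles used across the test suite.

The oracles here deliberately recompute quantities by a different route than
the library (longhand ANOVA, brute-force threshold search, exhaustive
sign-flip enumeration) so that agreement between the two is informative.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from cmrquant.phantom import PhantomSpec


# ---------------------------------------------------------------------------
# independent oracles


def icc_anova_oracle(matrix, absolute_agreement=True) -> float:
    """Longhand two-way ANOVA ICC: explicit sums over cells, no vectorised
    shortcuts shared with the implementation."""
    x = np.asarray(matrix, float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if absolute_agreement:
        denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    else:
        denom = ms_rows + (k - 1) * ms_err
    return (ms_rows - ms_err) / denom


def otsu_brute_oracle(values, n_bins=256):
    """Exhaustive minimisation of the within-class variance sum over the
    interior histogram edges; ties to the lowest threshold."""
    values = np.asarray(values, float)
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return None
    edges = np.linspace(vmin, vmax, n_bins + 1)
    best_edge, best_wcv = None, np.inf
    for edge in edges[1:-1]:
        lo = values[values <= edge]
        hi = values[values > edge]
        if lo.size == 0 or hi.size == 0:
            continue
        wcv = lo.size * lo.var() + hi.size * hi.var()
        if wcv < best_wcv:
            best_wcv, best_edge = wcv, edge
    return best_edge


def wilcoxon_enum_oracle(x) -> float:
    """Exact signed-rank two-sided p by enumeration over all sign flips."""
    x = np.asarray(x, float)
    n = x.size
    ranks = rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ],
        float,
    )
    p_le = float(np.mean(ws <= w_obs))
    p_ge = float(np.mean(ws >= w_obs))
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# phantom helpers


def random_phantom_spec(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """A random but valid phantom over a realistic condition range."""
    base = dict(
        matrix_size=96,
        endo_radius=15.0,
        epi_radius=25.0,
        n_slices=6,
        infarct_slice_span=(1, 5),
        infarct_angular_extent=float(rng.uniform(40, 140)),
        infarct_transmurality=float(rng.uniform(0.3, 1.0)),
        infarct_angle_deg=float(rng.uniform(0, 360)),
        mvo_fraction=float(rng.choice([0.0, 0.15])),
        noise_sd=float(rng.uniform(5, 15)),
        blur_sigma_mm=float(rng.uniform(0.0, 1.0)),
        speckle_count=int(rng.integers(0, 3)),
        seed=int(rng.integers(0, 2**31)),
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noise-free, blur-free, fully separable phantom."""
    return PhantomSpec(
        noise_sd=0.0,
        blur_sigma_mm=0.0,
        infarct_transmurality=1.0,
        infarct_angular_extent=90.0,
        infarct_slice_span=(0, 8),
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    from cmrquant.phantom import generate_phantom

    return generate_phantom(clean_spec)
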