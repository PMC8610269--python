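"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from cavquant import ImageSimConfig, SegmentationParams, generate_core_image

# fixed thresholds at half the rendered marker signal (base * exposure/ref)
FIXED_PARAMS = SegmentationParams(
    threshold_method={"dapi": "fixed", "vimentin": "fixed", "panck": "fixed"},
    fixed_thresholds={"dapi": 0.09, "vimentin": 0.2, "panck": 0.2},
    nucleus_association_radius=10,
)


def noise_free_config(**overrides) -> ImageSimConfig:
    base = dict(image_size=128, n_nuclei=100, noise_sd=0.0, bleedthrough=0.0, seed=11)
    base.update(overrides)
    return ImageSimConfig(**base)


@pytest.fixture
def noise_free_core():
    return generate_core_image(noise_free_config())


def exact_ranksum_p(x, y) -> float:
    """Brute-force two-sided exact rank-sum p by enumerating all rank splits.

    Valid for tie-free pooled samples.  Enumerates every way the x-ranks
    could fall among the pooled ranks, computes the Mann-Whitney U for each,
    and doubles the smaller tail (capped at 1) — the standard two-sided
    exact convention.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == n + m, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(n + m), n):
        r = sum(c + 1 for c in combo)
        us.append(r - n * (n + 1) / 2)
    us = np.asarray(us, float)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def km_product_limit(times, events):
    """Hand-rolled product-limit estimator: returns [(t, S(t))] at event times
    and the median (smallest t with S <= 0.5, or None)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    s = 1.0
    curve = []
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= (at_risk - d) / at_risk
        curve.append((float(t), s))
    median = next((t for t, surv in curve if surv <= 0.5 + 1e-12), None)
    return curve, median


def one_sample_t_p(deltas) -> float:
    """Closed-form one-sample t-test p-value via the t survival function."""
    from scipy.stats import t as tdist

    d = np.asarray(deltas, float)
    n = d.size
    tstat = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return 2.0 * tdist.sf(abs(tstat), n - 1)
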