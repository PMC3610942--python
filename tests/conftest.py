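"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from epicoex.partitions import JOINT_GENOTYPES

_LN_2PI = float(np.log(2.0 * np.pi))


def draw_module(rng, rho_by_genotype, n_per_class=30, sd=0.97,
                mean_by_genotype=None, sd_by_genotype=None):
    """Draw (x, y, g1, g2) with per-joint-genotype bivariate parameters.

    ``n_per_class`` may be an int (balanced) or a dict per genotype.
    """
    xs, ys, g1s, g2s = [], [], [], []
    for gt in JOINT_GENOTYPES:
        n = n_per_class[gt] if isinstance(n_per_class, dict) else n_per_class
        r = rho_by_genotype[gt]
        s = sd_by_genotype[gt] if sd_by_genotype else sd
        mx, my = mean_by_genotype[gt] if mean_by_genotype else (0.0, 0.0)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        xs.append(mx + s * z1)
        ys.append(my + s * (r * z1 + np.sqrt(1 - r * r) * z2))
        g1s.append(np.full(n, gt[0]))
        g2s.append(np.full(n, gt[1]))
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(g1s), np.concatenate(g2s))


def bvn_logpdf_oracle(x, y, rho, sd):
    """Independent per-sample bivariate normal log-density (means 0)."""
    det = sd**4 * (1 - rho**2)
    quad = (x * x - 2 * rho * x * y + y * y) / (sd * sd * (1 - rho * rho))
    return -_LN_2PI - 0.5 * np.log(det) - 0.5 * quad


def grid_search_rho_oracle(x, y, g1, g2, partition, sd, step=1e-4):
    """Brute-force per-class correlation MLE over a rho grid.

    Returns (rho_hat dict, total loglik).  Independent of the package's
    fitting path: plain grid evaluation of the summed log-density.
    """
    labels = np.asarray([partition.class_of[(a, b)] for a, b in zip(g1, g2)])
    grid = np.arange(-1.0 + step, 1.0, step)
    rho_hat, total = {}, 0.0
    for c in range(1, partition.k + 1):
        m = labels == c
        n = float(m.sum())
        s = float(np.sum(x[m] ** 2 + y[m] ** 2))
        p = float(np.sum(x[m] * y[m]))
        ll = (
            -n * (_LN_2PI + 2 * np.log(sd))
            - 0.5 * n * np.log1p(-grid * grid)
            - (s - 2 * grid * p) / (2 * sd * sd * (1 - grid * grid))
        )
        best = int(np.argmax(ll))
        rho_hat[c] = float(grid[best])
        total += float(ll[best])
    return rho_hat, total


@pytest.fixture(scope="session")
def demo_panel():
    """The bundled demo panel (NQT-transformed), built once per session."""
    from epicoex import demo_spec, make_benchmark_dataset
    from epicoex.preprocess import normal_quantile_transform

    expr, geno, truth = make_benchmark_dataset(demo_spec(rng_seed=0))
    return normal_quantile_transform(expr), geno, truth
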