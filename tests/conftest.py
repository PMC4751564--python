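"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from ribiscreen.synthetic_data import GeneratorConfig, generate_screen


def grid_best_loglik(x, mu_lo, mu_hi, step=0.05, sd_values=None, w_values=None) -> float:
    """Brute-force grid optimum of the 2-component mixture log-likelihood.

    Independent of the EM path: exhaustively scores every (mu1, mu2, sd1,
    sd2, w) combination on a regular grid and returns the best value found.
    """
    x = np.asarray(x, dtype=float)
    mus = np.arange(mu_lo, mu_hi + step / 2, step)
    sds = np.asarray(sd_values if sd_values is not None else np.arange(0.05, 0.55, 0.05))
    ws = np.asarray(w_values if w_values is not None else np.arange(0.05, 0.96, 0.05))
    # per-component log pdf for every (mu, sd) pair: shape (n_mu, n_sd, n_pts)
    comp = (
        -0.5 * math.log(2 * math.pi)
        - np.log(sds)[None, :, None]
        - 0.5 * ((x[None, None, :] - mus[:, None, None]) / sds[None, :, None]) ** 2
    )
    best = -np.inf
    for w in ws:
        # mixture log density for every (mu1,sd1) x (mu2,sd2) combination
        a = comp[:, :, None, None, :] + math.log(w)
        b = comp[None, None, :, :, :] + math.log(1 - w)
        ll = np.logaddexp(a, b).sum(axis=-1)
        best = max(best, float(ll.max()))
    return best


def brute_force_induced_edges(edges, gene_set) -> int:
    """Double loop over all unordered pairs of the gene set."""
    genes = sorted(set(gene_set))
    present = set()
    for a, b, *_ in edges:
        if a != b:
            present.add((a, b) if a < b else (b, a))
    count = 0
    for g1, g2 in itertools.combinations(genes, 2):
        pair = (g1, g2) if g1 < g2 else (g2, g1)
        if pair in present:
            count += 1
    return count


def hypergeom_upper_tail_enumeration(n_universe, n_annot, n_hits, overlap) -> float:
    """P(X >= overlap) by direct combinatorial enumeration."""
    total = math.comb(n_universe, n_hits)
    acc = 0
    for k in range(overlap, min(n_annot, n_hits) + 1):
        acc += math.comb(n_annot, k) * math.comb(n_universe - n_annot, n_hits - k)
    return acc / total


@pytest.fixture(scope="session")
def small_screen():
    """One default-parameter synthetic screen at 960 strains (KCl only)."""
    config = GeneratorConfig(n_strains=960, seed=42)
    wells, truth = generate_screen(config, conditions=("KCl",))
    return config, wells["KCl"], truth


@pytest.fixture(scope="session")
def full_default_config():
    return GeneratorConfig(seed=7)
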