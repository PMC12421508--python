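"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's neighbour-search and
geometry helpers: minimum-image distances are found by enumerating all
27 periodic images, pair lists by O(N²) scans, and run lengths by a
per-frame state walk, so tests compare two independent routes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def brute_min_image(a, b, box):
    """Minimum displacement b-a over all 27 periodic images (oracle)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    box = np.asarray(box, float)
    best, best_norm = None, np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = b + np.array(shift) * box - a
        n = np.linalg.norm(d)
        if n < best_norm:
            best, best_norm = d, n
    return best


def brute_pairs(idx_a, idx_b, coords, box, cutoff):
    """O(N^2) minimum-image pair set (unordered frozensets) within cutoff."""
    out = set()
    for ia in idx_a:
        for ib in idx_b:
            if ia == ib:
                continue
            d = np.linalg.norm(brute_min_image(coords[ia], coords[ib], box))
            if d <= cutoff:
                out.add(frozenset((int(ia), int(ib))))
    return out


def brute_contact_score(idx_a, idx_b, coords, box):
    """Untruncated switching-function sum over all cross pairs (oracle)."""
    total = 0.0
    for ia in idx_a:
        for ib in idx_b:
            if ia == ib:
                continue
            d = np.linalg.norm(brute_min_image(coords[ia], coords[ib], box))
            total += 1.0 / (1.0 + np.exp(5.0 * (d - 5.0)))
    return total


def brute_bulk_flags(water_pos, polymer_pos, box, threshold):
    """All-pairs bulk/bound classification (oracle)."""
    flags = []
    for w in water_pos:
        dmin = min(np.linalg.norm(brute_min_image(w, p, box)) for p in polymer_pos)
        flags.append(dmin > threshold)
    return np.array(flags)


def brute_runs(mask):
    """Run lengths of consecutive True frames; censored if touching an end."""
    mask = list(mask)
    out = []
    length, start = 0, None
    for i, v in enumerate(mask + [False]):
        if v:
            if length == 0:
                start = i
            length += 1
        elif length:
            out.append((length, start == 0 or start + length == len(mask)))
            length = 0
    return out


@pytest.fixture(scope="session")
def toy_wall():
    from acetwall import ToyCellWallSpec, gen_toy_cellwall

    return gen_toy_cellwall(ToyCellWallSpec(seed=3))


@pytest.fixture(scope="session")
def boltzmann_118():
    """Boltzmann fixture with a 1.18 kcal/mol planted acetyl offset."""
    from acetwall import BoltzmannSiteSpec, gen_boltzmann_sites

    spec = BoltzmannSiteSpec(
        site_counts={"carboxyl": 100, "acetyl": 400},
        site_energies={"carboxyl": 0.0, "acetyl": 1.18},
        n_ions=100, n_frames=120, seed=5)
    return gen_boltzmann_sites(spec)
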