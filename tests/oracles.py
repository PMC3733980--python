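"""Independent reference implementations used only to check the fast paths.

These deliberately avoid the package's convolution machinery: the
isotopologue oracle enumerates integer compositions of each element's atoms
over its isotopes and aggregates probability mass by nominal offset, and the
labeled-subset oracle enumerates every subset of residues that could have
been drawn from the labeled pool.
"""

from __future__ import annotations

import itertools
from math import comb, prod

import numpy as np

from msilac.constants import ISOTOPE_ABUNDANCE, RESIDUE_FORMULA, WATER


def _compositions(n: int, k: int):
    """All ways to place n identical atoms into k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _multinomial(counts: tuple[int, ...]) -> int:
    total, out = 0, 1
    for c in counts:
        total += c
        out *= comb(total, c)
    return out


def enumerate_pattern(formula_counts: dict[str, int], n15_fraction=None) -> np.ndarray:
    """Exhaustive aggregated isotopomer distribution of a small formula.

    Returns the full (untruncated) abundance vector over nominal offsets,
    summing to 1.  Feasible for formulas up to a dozen atoms or so.
    """
    per_element = []
    for element, n_atoms in formula_counts.items():
        if n_atoms == 0:
            continue
        if element == "N" and n15_fraction is not None:
            abund = (1.0 - n15_fraction, n15_fraction)
        else:
            abund = ISOTOPE_ABUNDANCE[element]
        dist: dict[int, float] = {}
        for combo in _compositions(n_atoms, len(abund)):
            p = _multinomial(combo) * prod(a**c for a, c in zip(abund, combo))
            offset = sum(j * c for j, c in enumerate(combo))
            dist[offset] = dist.get(offset, 0.0) + p
        per_element.append(dist)

    total: dict[int, float] = {0: 1.0}
    for dist in per_element:
        merged: dict[int, float] = {}
        for o1, p1 in total.items():
            for o2, p2 in dist.items():
                merged[o1 + o2] = merged.get(o1 + o2, 0.0) + p1 * p2
        total = merged
    out = np.zeros(max(total) + 1)
    for offset, p in total.items():
        out[offset] = p
    return out


def add_formulas(*formulas: dict[str, int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for f in formulas:
        for e, n in f.items():
            out[e] = out.get(e, 0) + n
    return out


def labeled_subset_pattern(sequence: str, q: float, p: float, n_bins: int) -> np.ndarray:
    """New-protein envelope by enumeration over labeled-residue subsets.

    Each subset S of residues is drawn from the labeled pool with probability
    q^|S| (1-q)^(R-|S|); its envelope is the exhaustive pattern of the whole
    peptide with the N atoms of residues in S at enrichment p and everything
    else natural.  Feasible for R <= 6.
    """
    residues = [RESIDUE_FORMULA[r] for r in sequence]
    n = len(residues)
    acc = np.zeros(n_bins)
    for mask in itertools.product([0, 1], repeat=n):
        weight = prod(q if m else (1.0 - q) for m in mask)
        labeled = add_formulas(*(r for r, m in zip(residues, mask) if m)) or {}
        unlabeled = add_formulas(
            WATER, *(r for r, m in zip(residues, mask) if not m)
        )
        pat_l = enumerate_pattern(labeled, n15_fraction=p) if labeled else np.array([1.0])
        pat_u = enumerate_pattern(unlabeled)
        pat = np.convolve(pat_l, pat_u)[:n_bins]
        padded = np.zeros(n_bins)
        padded[: pat.size] += pat
        acc += weight * padded
    return acc / acc.sum()
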