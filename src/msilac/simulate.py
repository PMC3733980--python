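"""Synthetic data with known ground truth for every pipeline stage.

Two generators emulate the study design (four replicate gels, three time
points, four doses, half-labeled 98%-enriched medium):

* :func:`simulate_spectrum` forward-models a MALDI peptide envelope as a
  mixture of pre-existing (natural) and newly synthesized (partially
  15N-labeled) material with multiplicative Gaussian bin noise;
* :func:`simulate_spot_tables` draws per-protein temporal archetypes
  (monotone down, dip-then-recover, rise-then-fall, null) and emits raw
  replicate gel intensities with log-normal noise plus the truth table.

Both are bit-reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .chem import PeptideSequence, as_peptide, composition
from .errors import InvalidInputError
from .isotopes import default_n_bins, natural_pattern
from .turnover import (
    LabelingDesign,
    SpectrumObservation,
    mixture_pattern,
    new_protein_pattern,
    theoretical_grid,
)

ARCHETYPES = ("down", "V_up", "V_down", "null")

#: Archetype ratio shapes at (0, mid, late) time points — the medians of the
#: corresponding printed time-course clusters, so defaults "look like" the
#: study's data.  down: monotone decrease; V_up: dip then partial recovery;
#: V_down: overshoot then fall; null: flat.
ARCHETYPE_SHAPES: dict[str, tuple[float, float, float]] = {
    "down": (1.0, 0.61, 0.28),
    "V_up": (1.0, 0.37, 0.795),
    "V_down": (1.0, 2.13, 0.77),
    "null": (1.0, 1.0, 1.0),
}

#: Maximal fold of the monotone-down archetype medians; the reference point
#: for rescaling effect sizes.
_REFERENCE_FOLD = 1.0 / ARCHETYPE_SHAPES["down"][2]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic world, defaulting to the study's design."""

    seed: int = 0
    n_proteins: int = 200
    n_replicates: int = 4
    #: Mixing proportions over (down, V_up, V_down, null).  Differential
    #: spots are a minority of all spots detected on a gel — normalizing to
    #: the entire gel intensity presumes exactly that — so 80% of simulated
    #: spots are null; the non-null 20% splits by the printed cluster shares
    #: (37 / 47.8 / 15.2).
    archetype_mix: tuple[float, float, float, float] = (0.074, 0.0956, 0.0304, 0.80)
    #: Largest true fold change of a non-null protein; default reproduces the
    #: printed cluster-median magnitudes exactly.
    fold_effect: float = _REFERENCE_FOLD
    #: Log-normal replicate noise on spot intensities (2-DE densitometry).
    replicate_cv: float = 0.10
    #: Multiplicative Gaussian noise on spectral bins.
    spectrum_noise_cv: float = 0.05
    design: LabelingDesign = field(default_factory=LabelingDesign)
    #: Nominal summed intensity of a simulated spectrum (arbitrary units).
    spectrum_total_intensity: float = 1.0e4

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9 or any(
            p < 0 for p in self.archetype_mix
        ):
            raise InvalidInputError("archetype_mix must be proportions summing to 1")
        if self.fold_effect <= 1:
            raise InvalidInputError("fold_effect must exceed 1")
        if self.replicate_cv < 0 or self.spectrum_noise_cv < 0:
            raise InvalidInputError("coefficients of variation must be >= 0")
        if self.n_proteins < 1 or self.n_replicates < 2:
            raise InvalidInputError("need >= 1 protein and >= 2 replicates")


def archetype_ratios(archetype: str, fold_effect: float) -> tuple[float, float, float]:
    """Expected ratio triplet of an archetype at a given effect size.

    The printed-median shapes are rescaled in log space by
    ``log(fold_effect) / log(reference fold)``, which changes magnitude but
    never the shape class.
    """
    if archetype not in ARCHETYPES:
        raise InvalidInputError(f"unknown archetype {archetype!r}")
    exponent = np.log(fold_effect) / np.log(_REFERENCE_FOLD)
    base = np.asarray(ARCHETYPE_SHAPES[archetype])
    return tuple(float(x) for x in base**exponent)


def simulate_spectrum(
    peptide: Union[str, PeptideSequence],
    f_true: float,
    config: SimulationConfig = SimulationConfig(),
    n_bins: int | None = None,
    seed: int | None = None,
) -> SpectrumObservation:
    """Forward-simulate the observed envelope of a peptide with true new
    fraction ``f_true`` under the config's labeling design.

    Bin intensities are the mixture envelope scaled to the nominal total and
    perturbed by multiplicative Gaussian noise (clipped at zero); peaks sit
    exactly on the theoretical unit-mass m/z grid.  ``seed`` overrides the
    config seed so sweeps can decorrelate replicates.
    """
    if not 0.0 <= f_true <= 1.0:
        raise InvalidInputError("f_true must lie in [0, 1]")
    pep = as_peptide(peptide)
    formula = composition(pep)
    if n_bins is None:
        n_bins = default_n_bins(formula)
    old = natural_pattern(formula, n_bins)
    new = new_protein_pattern(pep, config.design, n_bins)
    mix = mixture_pattern(f_true, old, new)

    rng = np.random.default_rng(config.seed if seed is None else seed)
    noise = 1.0 + config.spectrum_noise_cv * rng.standard_normal(n_bins)
    intensities = np.clip(
        mix.abundances * config.spectrum_total_intensity * noise, 0.0, None
    )
    grid = theoretical_grid(mix.monoisotopic_mass, n_bins)
    return SpectrumObservation(
        tuple(zip(grid.tolist(), intensities.tolist())),
        label=f"sim:{pep.sequence}:f={f_true:.3f}",
    )


def simulate_spot_tables(
    config: SimulationConfig = SimulationConfig(),
    conditions: tuple[str, ...] = ("t0", "t12", "t48"),
) -> tuple[dict[str, list[pd.Series]], pd.DataFrame]:
    """Replicated raw-intensity spot tables with known archetype structure.

    Returns ``(tables, truth)``: ``tables`` maps each condition label to one
    raw-intensity Series per replicate gel (spot_id index), exercising the
    intensity-mode path end to end; ``truth`` has one row per protein with
    its archetype and expected ratio at each condition.

    Baseline abundances are drawn log-uniform over two decades; replicate
    noise is log-normal with the configured CV (densitometry is positive and
    right-skewed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    archetypes = rng.choice(ARCHETYPES, size=n, p=config.archetype_mix)
    baseline = 10.0 ** rng.uniform(3.0, 5.0, size=n)

    ratio_matrix = np.vstack(
        [archetype_ratios(a, config.fold_effect) for a in archetypes]
    )
    if ratio_matrix.shape[1] != len(conditions):
        raise InvalidInputError(
            f"archetype shapes have 3 points but {len(conditions)} conditions given"
        )

    sigma = np.sqrt(np.log1p(config.replicate_cv**2))
    spot_ids = [f"spot{i + 1}" for i in range(n)]
    tables: dict[str, list[pd.Series]] = {c: [] for c in conditions}
    for j, cond in enumerate(conditions):
        mean = baseline * ratio_matrix[:, j]
        for _ in range(config.n_replicates):
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
            tables[cond].append(pd.Series(mean * noise, index=spot_ids, name=cond))

    truth = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "archetype": archetypes,
            **{f"ratio_{c}": ratio_matrix[:, j] for j, c in enumerate(conditions)},
        }
    )
    return tables, truth
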