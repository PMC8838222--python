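"""Synthetic karyotypes, flow histograms and species tables with ground truth.

Every generator is a pure function of its spec (which embeds the seed):
rerunning with the same spec yields byte-identical output.  The defaults
mirror the study system the package targets — a perennial legume group
with base number x = 8, a monoploid genome size near 1.14 pg, maize
(5.43 pg/2C) as internal standard, standard-peak CVs around 3.4% and
sample CVs around 7.8% on silica-dried material, and even ploidy levels
2x/4x/6x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, KaryoploidError
from .flowcyto import MAIZE_2C_PG, DEFAULT_NBINS, FlowHistogram
from .karyotype import (
    DEFAULT_MEDIAN_TOLERANCE,
    ArmPair,
    LEVAN_TYPES,
    MetaphaseKaryotype,
    parse_karyotype_formula,
)


def _levan_interval(label: str, median_tolerance: float) -> tuple[float, float]:
    bounds = {
        "M": (1.0, 1.0 + median_tolerance),
        "m": (1.0 + median_tolerance, 1.7),
        "sm": (1.7, 3.0),
        "st": (3.0, 7.0),
        "t": (7.0, 10.0),  # open-ended class, capped for simulation
    }
    return bounds[label]


@dataclass(frozen=True)
class SimKaryotypeSpec:
    """Target composition and noise model for one simulated karyotype.

    ``formula`` is a karyotype formula (e.g. ``"1M + 6m + 1sm"``); arm
    ratios are drawn uniformly inside each requested Levan class, keeping a
    ``boundary_margin`` fraction of the class width away from both class
    boundaries so the noise-free karyotype always classifies back to the
    requested formula.  ``noise_sd`` is multiplicative measurement noise
    per arm, as a fraction of arm length.
    """

    formula: str = "1M + 6m + 1sm"
    mean_cl: float = 2.2
    cl_spread: float = 0.15
    noise_sd: float = 0.02
    median_tolerance: float = DEFAULT_MEDIAN_TOLERANCE
    boundary_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_sd < 0.2:
            raise InvalidMeasurementError(f"noise_sd must lie in [0, 0.2), got {self.noise_sd}")
        if not 0.0 <= self.boundary_margin < 0.5:
            raise KaryoploidError(f"infeasible boundary margin {self.boundary_margin}")
        if self.mean_cl <= 0 or not 0.0 <= self.cl_spread < 1.0:
            raise InvalidMeasurementError("mean_cl must be positive, cl_spread in [0, 1)")


def gen_karyotype(spec: SimKaryotypeSpec) -> tuple[MetaphaseKaryotype, tuple[str, ...]]:
    """Simulate one metaphase karyotype with known Levan types.

    Returns the karyotype (chromosomes in canonical longest-first order)
    and the true type labels aligned with that order.  With ``noise_sd=0``
    re-classification at the spec's tolerance recovers the labels exactly.
    """
    rng = np.random.default_rng(spec.seed)
    labels = parse_karyotype_formula(spec.formula)
    pairs: list[tuple[ArmPair, str]] = []
    for label in labels:
        lo, hi = _levan_interval(label, spec.median_tolerance)
        margin = spec.boundary_margin * (hi - lo)
        r = rng.uniform(lo + margin, hi - margin)
        total = spec.mean_cl * (1.0 + rng.uniform(-spec.cl_spread, spec.cl_spread))
        q = total / (1.0 + r)
        p = total - q
        if spec.noise_sd > 0:
            q *= max(1.0 + rng.normal(0.0, spec.noise_sd), 0.05)
            p *= max(1.0 + rng.normal(0.0, spec.noise_sd), 0.05)
        pairs.append((ArmPair(q, p), label))
    pairs.sort(key=lambda t: t[0].total, reverse=True)
    karyotype = MetaphaseKaryotype(
        species_id=f"sim[{spec.formula}]",
        chromosomes=tuple(pair for pair, _ in pairs),
        two_n=2 * len(pairs),
    )
    return karyotype, tuple(label for _, label in pairs)


@dataclass(frozen=True)
class SimFlowSpec:
    """Mixture model for a two-peak PI fluorescence histogram.

    Events are multinomially split between exponential low-channel debris,
    the standard G1 peak, the sample G1 peak, and optional G2 doublets at
    twice each G1 position; each peak is Gaussian with sd = cv/100 · mean.
    The sample peak lands at ``standard_channel · true_two_c /
    standard_two_c`` and must stay inside the histogram.
    """

    true_two_c: float = 2.17
    standard_two_c: float = MAIZE_2C_PG
    standard_channel: float = 500.0
    cv_standard: float = 3.37
    cv_sample: float = 7.79
    n_events: int = 10_000
    debris_fraction: float = 0.05
    g2_fraction: float = 0.05
    standard_fraction: float = 0.5
    nbins: int = DEFAULT_NBINS
    seed: int = 0

    @property
    def sample_channel(self) -> float:
        return self.standard_channel * self.true_two_c / self.standard_two_c

    def __post_init__(self) -> None:
        if not 1.0 <= self.sample_channel <= self.nbins - 1:
            raise InvalidMeasurementError(
                f"sample peak at channel {self.sample_channel:.1f} lies outside "
                f"[1, {self.nbins - 1}]"
            )
        if not 0.0 <= self.debris_fraction < 1.0 or not 0.0 <= self.g2_fraction < 0.3:
            raise InvalidMeasurementError("debris_fraction in [0,1), g2_fraction in [0,0.3)")
        if self.n_events <= 0 or self.cv_standard < 0 or self.cv_sample < 0:
            raise InvalidMeasurementError("need positive event count and non-negative CVs")
        if not 0.0 < self.standard_fraction < 1.0:
            raise InvalidMeasurementError("standard_fraction must lie in (0, 1)")


def gen_flow_histogram(spec: SimFlowSpec) -> tuple[FlowHistogram, dict]:
    """Simulate a binned fluorescence histogram plus its ground truth.

    The truth dict records the component means, CVs, the expected 2C and
    the exact event count drawn for each mixture component.
    """
    rng = np.random.default_rng(spec.seed)
    peaks = 1.0 - spec.debris_fraction
    w_std = peaks * spec.standard_fraction
    w_smp = peaks - w_std
    weights = np.array(
        [
            spec.debris_fraction,
            w_std * (1.0 - spec.g2_fraction),
            w_std * spec.g2_fraction,
            w_smp * (1.0 - spec.g2_fraction),
            w_smp * spec.g2_fraction,
        ]
    )
    counts = rng.multinomial(spec.n_events, weights)
    std_sd = spec.cv_standard / 100.0 * spec.standard_channel
    smp_sd = spec.cv_sample / 100.0 * spec.sample_channel
    events = np.concatenate(
        [
            1.0 + rng.exponential(scale=spec.nbins / 8.0, size=counts[0]),
            rng.normal(spec.standard_channel, std_sd, size=counts[1]),
            rng.normal(2.0 * spec.standard_channel, 2.0 * std_sd, size=counts[2]),
            rng.normal(spec.sample_channel, smp_sd, size=counts[3]),
            rng.normal(2.0 * spec.sample_channel, 2.0 * smp_sd, size=counts[4]),
        ]
    )
    hist = FlowHistogram.from_events(
        events, nbins=spec.nbins, meta={"sample_id": f"sim[2C={spec.true_two_c}]"}
    )
    truth = {
        "standard_channel": spec.standard_channel,
        "sample_channel": spec.sample_channel,
        "cv_standard": spec.cv_standard,
        "cv_sample": spec.cv_sample,
        "two_c": spec.true_two_c,
        "component_counts": {
            "debris": int(counts[0]),
            "standard_g1": int(counts[1]),
            "standard_g2": int(counts[2]),
            "sample_g1": int(counts[3]),
            "sample_g2": int(counts[4]),
        },
    }
    return hist, truth


@dataclass(frozen=True)
class SimSpeciesTableSpec:
    """Structure of a simulated species table with known ploidy levels.

    ``levels`` maps ploidy level to number of species (the default roughly
    mirrors a section dominated by diploids with fewer tetra- and
    hexaploids); each species gets between ``individuals_per_species[0]``
    and ``[1]`` individuals whose 2C values scatter around level · Cx with
    relative sd ``within_species_sd``.
    """

    cx: float = 1.14
    levels: Mapping[int, int] = field(default_factory=lambda: {2: 24, 4: 8, 6: 3})
    individuals_per_species: tuple[int, int] = (1, 4)
    within_species_sd: float = 0.05
    base_x: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cx <= 0:
            raise InvalidMeasurementError(f"cx must be positive, got {self.cx}")
        if any(c < 0 for c in self.levels.values()) or sum(self.levels.values()) < 1:
            raise InvalidMeasurementError("need at least one species across levels")
        if not 0.0 <= self.within_species_sd < 0.2:
            raise InvalidMeasurementError("within_species_sd must lie in [0, 0.2)")
        lo, hi = self.individuals_per_species
        if not 1 <= lo <= hi:
            raise InvalidMeasurementError("individuals_per_species must be an increasing pair >= 1")


def gen_species_table(spec: SimSpeciesTableSpec) -> pd.DataFrame:
    """Simulate a per-individual genome-size table with true ploidy levels.

    Columns: ``sample_id, species, individual, two_c_pg, two_n,
    count_source, true_level`` — the schema consumed by the ploidy stage
    plus the hidden truth.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.individuals_per_species
    rows = []
    sp_no = 0
    for level in sorted(spec.levels):
        for _ in range(spec.levels[level]):
            sp_no += 1
            species = f"sp{sp_no:03d}_{level}x"
            n_ind = int(rng.integers(lo, hi + 1))
            true_2c = level * spec.cx
            for ind in range(1, n_ind + 1):
                two_c = true_2c * (1.0 + rng.normal(0.0, spec.within_species_sd))
                rows.append(
                    {
                        "sample_id": f"{species}_{ind}",
                        "species": species,
                        "individual": ind,
                        "two_c_pg": round(float(max(two_c, 1e-6)), 4),
                        "two_n": level * spec.base_x,
                        "count_source": "own",
                        "true_level": level,
                    }
                )
    return pd.DataFrame(rows)
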