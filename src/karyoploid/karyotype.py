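"""Karyotype morphometrics from per-chromosome arm measurements.

A mitotic metaphase karyotype is represented as the haploid complement of
chromosomes, each with a short arm (q) and a long arm (p), measured in µm.
From these the classical cytogenetic descriptors are computed:

* Levan centromere-position classes M / m / sm / st / t from the arm ratio
  r = p/q,
* the karyotype formula (e.g. ``"1M + 6m + 1sm"``),
* the symmetry/asymmetry indices TF%, AsK%, Syi%, S%,
* the mean arm ratio R and mean centromeric index Ci,
* the two-way Stebbins symmetry class (``"1A"`` … ``"4C"``).

All index functions operate on :class:`MetaphaseKaryotype` and are invariant
to chromosome ordering and (except for the raw lengths CL, q, p) to uniform
scaling of all measurements.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyKaryotypeError, InvalidMeasurementError

#: Levan centromere-type labels in canonical rendering order.
LEVAN_TYPES: tuple[str, ...] = ("M", "m", "sm", "st", "t")

#: Upper arm-ratio bound (inclusive) of each non-median Levan class.
#: The median class M is bounded by ``1 + median_tolerance`` (see
#: :func:`classify_levan`); ratios above 7.0 are acro-/telocentric (t).
LEVAN_UPPER_BOUNDS: tuple[tuple[float, str], ...] = (
    (1.7, "m"),
    (3.0, "sm"),
    (7.0, "st"),
)

#: Default half-width of the "median" (M) band around r = 1.  A strict
#: r == 1 is never observed in real measurements, so chromosomes with
#: r ≤ 1.05 are called M by default.
DEFAULT_MEDIAN_TOLERANCE = 0.05


@dataclass(frozen=True)
class ArmPair:
    """One chromosome's arm lengths in µm, normalised so that ``q <= p``.

    Parameters given in the wrong order (short arm longer than long arm)
    are swapped silently on construction; non-positive or non-finite
    lengths raise :class:`InvalidMeasurementError`.
    """

    q: float
    p: float

    def __post_init__(self) -> None:
        q, p = float(self.q), float(self.p)
        if not (math.isfinite(q) and math.isfinite(p)) or q <= 0 or p <= 0:
            raise InvalidMeasurementError(
                f"arm lengths must be finite and positive, got q={self.q!r}, p={self.p!r}"
            )
        if q > p:
            q, p = p, q
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "p", p)

    @property
    def total(self) -> float:
        """Total chromosome length q + p (µm)."""
        return self.q + self.p

    @property
    def ratio(self) -> float:
        """Arm ratio r = p/q (≥ 1 by normalisation)."""
        return self.p / self.q

    @property
    def centromeric_index(self) -> float:
        """Ci = q / (q + p), as a fraction in (0, 0.5]."""
        return self.q / (self.q + self.p)


@dataclass(frozen=True)
class MetaphaseKaryotype:
    """The haploid chromosome complement of one metaphase plate.

    ``chromosomes`` holds one :class:`ArmPair` per chromosome of the haploid
    set (length n); ``two_n`` is the somatic chromosome number and ``base_x``
    the base chromosome number of the group, so that ``two_n / base_x`` is
    the ploidy level when the division is exact.  Chromosomes are stored
    sorted by total length, longest first.
    """

    species_id: str
    chromosomes: tuple[ArmPair, ...]
    two_n: int
    base_x: int = 8

    def __post_init__(self) -> None:
        chroms = tuple(self.chromosomes)
        if len(chroms) == 0:
            raise EmptyKaryotypeError(f"karyotype {self.species_id!r} has no chromosomes")
        if self.two_n <= 0 or self.two_n % 2:
            raise InvalidMeasurementError(
                f"2n must be a positive even integer, got {self.two_n!r}"
            )
        if self.base_x <= 0:
            raise InvalidMeasurementError(f"base number x must be positive, got {self.base_x!r}")
        chroms = tuple(sorted(chroms, key=lambda c: c.total, reverse=True))
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def n(self) -> int:
        """Number of chromosomes in the stored (haploid) complement."""
        return len(self.chromosomes)

    @property
    def ploidy(self) -> int | None:
        """Integer ploidy level 2n/x, or None when 2n is not a multiple of x."""
        return self.two_n // self.base_x if self.two_n % self.base_x == 0 else None

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        q = np.array([c.q for c in self.chromosomes])
        p = np.array([c.p for c in self.chromosomes])
        return q, p


@dataclass(frozen=True)
class KaryotypeSummary:
    """All per-karyotype descriptors, unrounded.

    ``cl``, ``q_mean`` and ``p_mean`` are in µm; ``tf``, ``ask``, ``syi`` and
    ``s`` are percentages; ``r`` is the mean arm ratio and ``ci`` the mean
    centromeric index as a fraction.  Use :meth:`report_row` for the
    conventional report rounding: lengths and ratios to two decimals,
    integer indices to the nearest integer — except AsK%, which published
    karyotype tables conventionally truncate (so that a printed TF 45 can
    sit next to AsK 54).
    """

    species_id: str
    two_n: int
    n: int
    cl: float
    q_mean: float
    p_mean: float
    tf: float
    ask: float
    syi: float
    s: float
    r: float
    ci: float
    kf: str
    stebbins: str

    def report_row(self) -> dict[str, object]:
        return {
            "species_id": self.species_id,
            "two_n": self.two_n,
            "n": self.n,
            "cl_um": round(self.cl, 2),
            "q_um": round(self.q_mean, 2),
            "p_um": round(self.p_mean, 2),
            "tf_pct": int(round(self.tf)),
            "s_pct": int(round(self.s)),
            "ask_pct": int(math.floor(self.ask + 1e-9)),
            "syi_pct": int(round(self.syi)),
            "r": round(self.r, 2),
            "ci": round(self.ci, 2),
            "kf": self.kf,
            "stebbins": self.stebbins,
        }


def classify_levan(pair: ArmPair, median_tolerance: float = DEFAULT_MEDIAN_TOLERANCE) -> str:
    """Classify one chromosome's centromere position from its arm ratio.

    Thresholds (inclusive on the lower, more symmetric class):

    ====== =======================
    class  arm ratio r = p/q
    ====== =======================
    M      r ≤ 1 + median_tolerance
    m      r ≤ 1.7
    sm     r ≤ 3.0
    st     r ≤ 7.0
    t      r > 7.0
    ====== =======================
    """
    if median_tolerance < 0:
        raise ValueError(f"median_tolerance must be >= 0, got {median_tolerance}")
    return classify_levan_ratio(pair.ratio, median_tolerance)


def classify_levan_ratio(r: float, median_tolerance: float = DEFAULT_MEDIAN_TOLERANCE) -> str:
    """Levan class for a raw arm ratio (see :func:`classify_levan`)."""
    if not math.isfinite(r) or r < 1.0:
        raise InvalidMeasurementError(f"arm ratio must be finite and >= 1, got {r!r}")
    if r <= 1.0 + median_tolerance:
        return "M"
    for upper, label in LEVAN_UPPER_BOUNDS:
        if r <= upper:
            return label
    return "t"


def karyotype_formula(types: Iterable[str]) -> str:
    """Render Levan type labels as a karyotype formula.

    Counts are listed in the fixed order M, m, sm, st, t, with zero counts
    omitted and no space between count and label, e.g. ``"1M + 6m + 1sm"``
    or ``"8m"``.
    """
    counts = Counter(types)
    if not counts:
        raise EmptyKaryotypeError("cannot render a formula for an empty karyotype")
    unknown = set(counts) - set(LEVAN_TYPES)
    if unknown:
        raise ValueError(f"unknown chromosome type label(s): {sorted(unknown)}")
    return " + ".join(f"{counts[t]}{t}" for t in LEVAN_TYPES if counts[t])


_FORMULA_TERM = re.compile(r"^(\d+)(M|m|sm|st|t)$")


def parse_karyotype_formula(formula: str) -> list[str]:
    """Inverse of :func:`karyotype_formula`: expand a formula to a label list."""
    labels: list[str] = []
    for term in formula.split("+"):
        m = _FORMULA_TERM.match(term.strip())
        if m is None:
            raise ValueError(f"malformed karyotype formula term: {term.strip()!r}")
        labels.extend([m.group(2)] * int(m.group(1)))
    if not labels:
        raise EmptyKaryotypeError(f"empty karyotype formula: {formula!r}")
    return labels


def tf_percent(k: MetaphaseKaryotype) -> float:
    """Total form percentage: 100 · Σq / Σ(q + p), in (0, 50]."""
    q, p = k._arrays()
    return 100.0 * q.sum() / (q.sum() + p.sum())


def ask_percent(k: MetaphaseKaryotype) -> float:
    """Arano–Saito asymmetry index: 100 · Σp / Σ(q + p); complement of TF%."""
    return 100.0 - tf_percent(k)


def syi_percent(k: MetaphaseKaryotype) -> float:
    """Symmetry index of Greilhuber & Speta: 100 · mean(q) / mean(p)."""
    q, p = k._arrays()
    return 100.0 * q.mean() / p.mean()


def s_percent(k: MetaphaseKaryotype) -> float:
    """Shortest/longest chromosome ratio: 100 · min(total) / max(total).

    Defined as 100 for a single-chromosome complement.
    """
    totals = np.array([c.total for c in k.chromosomes])
    if totals.size == 1:
        return 100.0
    return 100.0 * totals.min() / totals.max()


def arm_ratio_mean(k: MetaphaseKaryotype) -> float:
    """Mean of the per-chromosome arm ratios p_i/q_i (not the ratio of means)."""
    return float(np.mean([c.ratio for c in k.chromosomes]))


def centromeric_index_mean(k: MetaphaseKaryotype) -> float:
    """Mean per-chromosome centromeric index q_i/(q_i + p_i), as a fraction."""
    return float(np.mean([c.centromeric_index for c in k.chromosomes]))


def stebbins_class(k: MetaphaseKaryotype, ratio_threshold: float = 2.0) -> str:
    """Two-way Stebbins symmetry category, e.g. ``"1A"``.

    The letter comes from the largest/smallest total-length ratio L/S
    (A: < 2, B: 2–4 inclusive, C: > 4); the digit from the proportion π of
    chromosomes with arm ratio ≥ ``ratio_threshold``
    (1: π = 0, 2: 0 < π ≤ 0.5, 3: 0.5 < π < 1, 4: π = 1).
    """
    totals = np.array([c.total for c in k.chromosomes])
    ls = totals.max() / totals.min()
    letter = "A" if ls < 2.0 else ("B" if ls <= 4.0 else "C")
    pi = float(np.mean([c.ratio >= ratio_threshold for c in k.chromosomes]))
    if pi == 0.0:
        digit = "1"
    elif pi <= 0.5:
        digit = "2"
    elif pi < 1.0:
        digit = "3"
    else:
        digit = "4"
    return digit + letter


def summarize_karyotype(
    k: MetaphaseKaryotype,
    median_tolerance: float = DEFAULT_MEDIAN_TOLERANCE,
) -> KaryotypeSummary:
    """Compute the full descriptor set for one karyotype.

    CL is the mean total chromosome length, i.e. mean(q) + mean(p).
    """
    q, p = k._arrays()
    labels = [classify_levan(c, median_tolerance) for c in k.chromosomes]
    return KaryotypeSummary(
        species_id=k.species_id,
        two_n=k.two_n,
        n=k.n,
        cl=float(q.mean() + p.mean()),
        q_mean=float(q.mean()),
        p_mean=float(p.mean()),
        tf=tf_percent(k),
        ask=ask_percent(k),
        syi=syi_percent(k),
        s=s_percent(k),
        r=arm_ratio_mean(k),
        ci=centromeric_index_mean(k),
        kf=karyotype_formula(labels),
        stebbins=stebbins_class(k),
    )


# ---------------------------------------------------------------------------
# measurement-file I/O
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = (
    "individual_id",
    "plate_id",
    "chromosome_index",
    "short_arm_um",
    "long_arm_um",
)


def read_measurements_csv(
    path_or_buffer,
    base_x: int = 8,
) -> tuple[dict[tuple[str, str], MetaphaseKaryotype], list[str]]:
    """Read a per-chromosome arm-length table into karyotypes.

    Expected columns: ``individual_id, plate_id, chromosome_index,
    short_arm_um, long_arm_um`` (one row per chromosome of the haploid
    complement; an optional ``two_n`` column overrides the default
    ``2 × n`` somatic count).

    Returns ``(karyotypes, errors)`` keyed by ``(individual_id, plate_id)``;
    malformed rows are reported with their 1-based line number and skipped,
    the rest of the file is still processed.
    """
    df = pd.read_csv(path_or_buffer, dtype={"individual_id": str, "plate_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidMeasurementError(f"measurement file lacks column(s): {missing}")
    errors: list[str] = []
    pairs: dict[tuple[str, str], list[ArmPair]] = {}
    two_n_hint: dict[tuple[str, str], int] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        key = (str(row["individual_id"]), str(row["plate_id"]))
        try:
            pair = ArmPair(float(row["short_arm_um"]), float(row["long_arm_um"]))
        except (InvalidMeasurementError, TypeError, ValueError) as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        pairs.setdefault(key, []).append(pair)
        if "two_n" in df.columns and pd.notna(row["two_n"]):
            two_n_hint[key] = int(row["two_n"])
    karyotypes: dict[tuple[str, str], MetaphaseKaryotype] = {}
    for key, chroms in pairs.items():
        two_n = two_n_hint.get(key, 2 * len(chroms))
        try:
            karyotypes[key] = MetaphaseKaryotype(
                species_id=key[0], chromosomes=tuple(chroms), two_n=two_n, base_x=base_x
            )
        except (InvalidMeasurementError, EmptyKaryotypeError) as exc:
            errors.append(f"individual {key[0]!r} plate {key[1]!r}: {exc}")
    return karyotypes, errors


def mean_karyotype(
    plates: Sequence[MetaphaseKaryotype], species_id: str | None = None
) -> MetaphaseKaryotype:
    """Average several metaphase plates of one individual, chromosome-wise.

    This is an extension beyond the usual best-plate convention: plates must
    have equal chromosome numbers; arms are averaged position-wise after the
    canonical longest-first ordering.
    """
    if not plates:
        raise EmptyKaryotypeError("no plates to average")
    ns = {k.n for k in plates}
    if len(ns) != 1:
        raise InvalidMeasurementError(f"plates have differing chromosome numbers: {sorted(ns)}")
    q = np.mean([[c.q for c in k.chromosomes] for k in plates], axis=0)
    p = np.mean([[c.p for c in k.chromosomes] for k in plates], axis=0)
    return MetaphaseKaryotype(
        species_id=species_id or plates[0].species_id,
        chromosomes=tuple(ArmPair(qi, pi) for qi, pi in zip(q, p)),
        two_n=plates[0].two_n,
        base_x=plates[0].base_x,
    )


def plot_idiogram(k: MetaphaseKaryotype, ax=None):
    """Draw a minimal rectangle idiogram (one bar per chromosome, centromere
    at the arm boundary).  Requires matplotlib; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * k.n), 3))
    for i, c in enumerate(k.chromosomes):
        ax.bar(i, c.p, width=0.6, bottom=0.0, color="#4477aa", edgecolor="black")
        ax.bar(i, -c.q, width=0.6, bottom=0.0, color="#66ccee", edgecolor="black")
    ax.axhline(0.0, color="black", lw=1)
    ax.set_xticks(range(k.n))
    ax.set_xticklabels([str(i + 1) for i in range(k.n)])
    ax.set_ylabel("arm length (µm)")
    ax.set_title(k.species_id)
    return ax
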