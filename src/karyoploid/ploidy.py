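"""Ploidy inference from 2C genome sizes and chromosome counts.

Within a group sharing a base chromosome number x, 2C DNA content scales
nearly linearly with ploidy level: a 2x individual carries ~2·Cx pg, a 4x
individual ~4·Cx, where Cx is the monoploid (1Cx) genome size.  Given a
calibration Cx — typically the mean 2C of chromosome-counted diploids
divided by two — each 2C measurement is assigned the allowed ploidy level
with the smallest relative deviation, or left indeterminate when even the
nearest level deviates by more than a tolerance.  Assignments can then be
reconciled against observed chromosome counts to surface possible
cytotype variation (individuals of one species differing in ploidy).

:class:`PloidyClassifier` exposes the same calibrate/assign procedure as a
scikit-learn estimator (``fit`` on known-diploid 2C values, ``predict``
ploidy levels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import InvalidMeasurementError, KaryoploidError

DEFAULT_ALLOWED_LEVELS: tuple[int, ...] = (2, 4, 6, 8)
DEFAULT_REL_TOLERANCE = 0.15
DEFAULT_BASE_X = 8

#: Sentinel used in reports for measurements matching no allowed level.
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PloidyCalibration:
    """Monoploid genome size Cx (pg) plus assignment policy."""

    cx: float
    allowed_levels: tuple[int, ...] = DEFAULT_ALLOWED_LEVELS
    rel_tolerance: float = DEFAULT_REL_TOLERANCE

    def __post_init__(self) -> None:
        if self.cx <= 0:
            raise InvalidMeasurementError(f"Cx must be positive, got {self.cx}")
        if not self.allowed_levels or any(l <= 0 for l in self.allowed_levels):
            raise InvalidMeasurementError(f"invalid ploidy levels: {self.allowed_levels}")
        if not 0.0 < self.rel_tolerance < 0.5:
            raise InvalidMeasurementError(
                f"rel_tolerance must lie in (0, 0.5), got {self.rel_tolerance}"
            )
        object.__setattr__(self, "allowed_levels", tuple(sorted(self.allowed_levels)))


@dataclass(frozen=True)
class PloidyAssignment:
    """One 2C value mapped onto the ploidy ladder.

    ``level`` is None for indeterminate assignments; ``deviation`` is the
    relative distance |2C − level·Cx| / (level·Cx) to the nearest allowed
    level regardless of whether it was accepted.
    """

    two_c: float
    level: int | None
    deviation: float
    base_x: int = DEFAULT_BASE_X
    flags: frozenset[str] = frozenset()

    @property
    def expected_2n(self) -> int | None:
        return None if self.level is None else self.level * self.base_x

    @property
    def label(self) -> str:
        return INDETERMINATE if self.level is None else f"{self.level}x"


@dataclass(frozen=True)
class ChromosomeCount:
    """An observed somatic chromosome number and where it came from."""

    two_n: int
    source: str = "own"

    def __post_init__(self) -> None:
        if self.two_n <= 0 or int(self.two_n) != self.two_n:
            raise InvalidMeasurementError(f"2n must be a positive integer, got {self.two_n!r}")
        if self.source not in ("own", "literature"):
            raise ValueError(f"count source must be 'own' or 'literature', got {self.source!r}")


def calibrate_cx(
    diploid_two_c_values: Iterable[float],
    allowed_levels: tuple[int, ...] = DEFAULT_ALLOWED_LEVELS,
    rel_tolerance: float = DEFAULT_REL_TOLERANCE,
) -> PloidyCalibration:
    """Monoploid value Cx = mean(known-diploid 2C values) / 2."""
    values = np.asarray(list(diploid_two_c_values), dtype=float)
    if values.size == 0:
        raise KaryoploidError("cannot calibrate Cx from an empty diploid set")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise InvalidMeasurementError("diploid 2C values must be finite and positive")
    return PloidyCalibration(
        cx=float(values.mean()) / 2.0,
        allowed_levels=allowed_levels,
        rel_tolerance=rel_tolerance,
    )


def assign_ploidy(
    two_c: float, cal: PloidyCalibration, base_x: int = DEFAULT_BASE_X
) -> PloidyAssignment:
    """Assign the allowed ploidy level with minimal relative deviation.

    Exceeding ``cal.rel_tolerance`` at every allowed level yields an
    indeterminate assignment flagged ``outlier_genome_size``.
    """
    if two_c <= 0:
        raise InvalidMeasurementError(f"2C must be positive, got {two_c}")
    levels = np.asarray(cal.allowed_levels, dtype=float)
    deviations = np.abs(two_c - levels * cal.cx) / (levels * cal.cx)
    i = int(np.argmin(deviations))
    dev = float(deviations[i])
    if dev <= cal.rel_tolerance:
        return PloidyAssignment(two_c=two_c, level=int(levels[i]), deviation=dev, base_x=base_x)
    return PloidyAssignment(
        two_c=two_c,
        level=None,
        deviation=dev,
        base_x=base_x,
        flags=frozenset({"outlier_genome_size"}),
    )


def concordance(
    assignment: PloidyAssignment, count: ChromosomeCount, base_x: int = DEFAULT_BASE_X
) -> tuple[str, frozenset[str]]:
    """Reconcile a genome-size ploidy call with a chromosome count.

    Discordant whenever the count disagrees with ``level × x`` or the
    assignment is indeterminate; discordant pairs carry the flag
    ``possible_cytotype_variation``.
    """
    if assignment.level is not None and count.two_n == assignment.level * base_x:
        return "concordant", frozenset()
    return "discordant", frozenset({"possible_cytotype_variation"})


def aggregate_by_ploidy(assignments: Sequence[PloidyAssignment]) -> pd.DataFrame:
    """Per-level 2C summary: n, mean, sd, min, max (pg).

    The spread is the population standard deviation (n denominator).
    Indeterminate assignments are excluded; empty levels are omitted.
    """
    rows = [(a.level, a.two_c) for a in assignments if a.level is not None]
    if not rows:
        return pd.DataFrame(
            columns=["n", "mean_pg", "sd_pg", "min_pg", "max_pg"],
            index=pd.Index([], name="level"),
        )
    df = pd.DataFrame(rows, columns=["level", "two_c"])
    out = df.groupby("level")["two_c"].agg(
        n="size",
        mean_pg="mean",
        sd_pg=lambda v: float(np.std(v, ddof=0)),
        min_pg="min",
        max_pg="max",
    )
    return out


class PloidyClassifier(BaseEstimator):
    """scikit-learn estimator wrapper around calibrate/assign.

    ``fit(X)`` takes the 2C values (pg) of individuals independently known
    to be diploid — e.g. from chromosome counts — and stores the monoploid
    calibration ``cx_``.  ``predict(X)`` maps arbitrary 2C values to ploidy
    levels (float array, NaN for indeterminate); :meth:`assign` returns the
    full per-value :class:`PloidyAssignment` objects.
    """

    def __init__(
        self,
        allowed_levels: tuple[int, ...] = DEFAULT_ALLOWED_LEVELS,
        rel_tolerance: float = DEFAULT_REL_TOLERANCE,
        base_x: int = DEFAULT_BASE_X,
    ):
        self.allowed_levels = allowed_levels
        self.rel_tolerance = rel_tolerance
        self.base_x = base_x

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        cal = calibrate_cx(values, tuple(self.allowed_levels), self.rel_tolerance)
        self.cx_ = cal.cx
        self.calibration_ = cal
        self.n_features_in_ = 1
        return self

    def assign(self, X) -> list[PloidyAssignment]:
        check_is_fitted(self, "calibration_")
        values = np.asarray(X, dtype=float).ravel()
        return [assign_ploidy(v, self.calibration_, self.base_x) for v in values]

    def predict(self, X) -> np.ndarray:
        return np.array(
            [np.nan if a.level is None else float(a.level) for a in self.assign(X)]
        )


# ---------------------------------------------------------------------------
# phylogeny annotation
# ---------------------------------------------------------------------------

_ANNOTATION = re.compile(r"\|2C=[^|'\",():;\[\]]*\|2n=[^|'\",():;\[\]]*")


def _tip_label_spans(text: str) -> list[tuple[int, int, bool]]:
    """(start, end, quoted) spans of tip labels in a newick string.

    A tip label is a (possibly quoted) token immediately following ``(`` or
    ``,``; internal-node labels (after ``)``) are left untouched.
    """
    spans: list[tuple[int, int, bool]] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i] in "(,":
            j = i + 1
            while j < n and text[j].isspace():
                j += 1
            if j < n and text[j] not in "(),:;":
                if text[j] == "'":
                    k = j + 1
                    while k < n:
                        if text[k] == "'" and k + 1 < n and text[k + 1] == "'":
                            k += 2
                            continue
                        if text[k] == "'":
                            break
                        k += 1
                    spans.append((j, k + 1, True))
                    i = k + 1
                    continue
                k = j
                while k < n and text[k] not in ",():;[" and not text[k].isspace():
                    k += 1
                spans.append((j, k, False))
                i = k
                continue
        i += 1
    return spans


def _label_variants(label: str) -> list[str]:
    variants = [label, label.replace("_", " "), label.replace(" ", "_")]
    return variants


def _resolve(label: str, records: Mapping[str, object]) -> str | None:
    """Record key matching a tip label: exact first, then case-insensitive,
    with underscore/space variants tried in both passes."""
    for cand in _label_variants(label):
        if cand in records:
            return cand
    lowered = {k.lower(): k for k in records}
    for cand in _label_variants(label):
        if cand.lower() in lowered:
            return lowered[cand.lower()]
    return None


def annotate_tree(
    newick_text: str,
    records: Mapping[str, tuple[object, object]],
    decimals: int = 2,
) -> tuple[str, list[str]]:
    """Suffix every tip label with mean 2C and chromosome number.

    ``records`` maps tip labels to ``(two_c, two_n)`` where ``two_c`` is a
    scalar or an iterable of per-individual values (averaged) and either
    entry may be None.  Every tip receives a ``|2C=<value>|2n=<value>``
    suffix, with ``#`` standing in for missing values, so a tree where no
    record matches still renders ``|2C=#|2n=#`` everywhere.  Topology and
    all other bytes are untouched: :func:`strip_annotations` restores the
    input exactly.  Returns ``(annotated_text, warnings)``.
    """
    import dendropy

    # parse once to reject malformed input before editing text
    dendropy.Tree.get(data=newick_text, schema="newick", preserve_underscores=True)

    spans = _tip_label_spans(newick_text)
    matched_keys: set[str] = set()
    warnings: list[str] = []
    pieces: list[str] = []
    last = 0
    for start, end, quoted in spans:
        raw = newick_text[start:end]
        label = raw[1:-1].replace("''", "'") if quoted else raw
        key = _resolve(label, records)
        if key is None:
            two_c_txt = two_n_txt = "#"
            warnings.append(f"tip {label!r} has no record")
        else:
            matched_keys.add(key)
            two_c, two_n = records[key]
            if two_c is None:
                two_c_txt = "#"
            else:
                vals = np.atleast_1d(np.asarray(two_c, dtype=float))
                two_c_txt = f"{vals.mean():.{decimals}f}"
            two_n_txt = "#" if two_n is None else str(int(two_n))
        suffix = f"|2C={two_c_txt}|2n={two_n_txt}"
        if quoted:
            annotated = raw[:-1] + suffix + "'"
        else:
            annotated = raw + suffix
        pieces.append(newick_text[last:start])
        pieces.append(annotated)
        last = end
    pieces.append(newick_text[last:])
    unmatched_records = [k for k in records if k not in matched_keys]
    warnings.extend(f"record {k!r} matched no tip" for k in unmatched_records)
    return "".join(pieces), warnings


def strip_annotations(newick_text: str) -> str:
    """Remove ``|2C=...|2n=...`` suffixes added by :func:`annotate_tree`."""
    return _ANNOTATION.sub("", newick_text)
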