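"""Packaged reference tables for a well-characterised legume study group.

Two small published-style tables ship with the package and drive the
worked examples, the regression tests and the reproduction script:

* a per-species karyotype table (mean arm lengths, asymmetry indices and
  karyotype formulae for 17 chromosome-counted species), and
* a per-individual genome-size table (internal-standard and sample peak
  means, CVs and 2C values for 64 measured individuals, plus two counted
  individuals without flow data).

``counted`` marks individuals that were also used for chromosome counts;
for those ``two_n`` carries the observed somatic number.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .flowcyto import MAIZE_2C_PG

#: 2C value (pg) of the internal standard used throughout the tables.
STANDARD_2C_PG = MAIZE_2C_PG


def _read(name: str) -> pd.DataFrame:
    with resources.files("karyoploid.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_karyotype_table() -> pd.DataFrame:
    """Per-species karyotype descriptors (17 species).

    Columns: species, individuals, plates, two_n, cl_um, q_um, p_um,
    tf_pct, s_pct, ask_pct, syi_pct, r, ci, kf.
    """
    return _read("karyotype_table.csv")


def load_genome_size_table(measured_only: bool = True) -> pd.DataFrame:
    """Per-individual flow-cytometry records.

    With ``measured_only`` (default) the two chromosome-counted individuals
    lacking flow measurements are dropped, leaving 64 measured rows (62
    individuals of the focal genus plus two outgroup individuals).
    """
    df = _read("genome_size_table.csv")
    df["counted"] = df["counted"].astype(bool)
    if measured_only:
        df = df.dropna(subset=["two_c_pg"]).reset_index(drop=True)
    return df


def counted_diploid_two_c(df: pd.DataFrame | None = None) -> pd.Series:
    """2C values of individuals with an own diploid (2n = 16) count.

    These are the calibration set for the monoploid genome size Cx.
    """
    if df is None:
        df = load_genome_size_table()
    sel = df[df["counted"] & (df["two_n"] == 16) & df["two_c_pg"].notna()]
    return sel["two_c_pg"].astype(float)
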