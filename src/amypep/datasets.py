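"""Access to the packaged reference tables.

The package bundles, as plain CSV, the published summary tables for a panel
of 20 food-derived alpha-amylase inhibitory peptides docked against porcine
pancreatic alpha-amylase (PDB 1PIF): the peptide panel itself, per-residue
interaction numbers (IN) and hydrogen-bond values (HBV) on the enzyme,
per-residue HBV entries on the peptide side, and per-peptide positional
statistics (R_N, F).  Transcription is verbatim, including internal
inconsistencies of the printed tables (see :func:`amypep.pipeline.report_flags`).

Also bundled: a compact amino-acid property table (17 standard scales over
the 20 amino acids, each labeled with one of four property classes) used as
the default input for descriptor reduction.  Values are taken from widely
used published scales (Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity,
Grantham polarity, Zamyatnin volumes, Zimmerman bulkiness, ...) plus counts
derivable from side-chain chemistry.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .peptides import Peptide, load_peptide_table


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("amypep.data") / name)


def load_peptides() -> list[Peptide]:
    """The 20-peptide panel with normalized IC50 activities (mmol/U)."""
    return load_peptide_table(fixture_path("table1_peptides.csv"))


def load_enzyme_in() -> pd.DataFrame:
    """Per-residue interaction numbers on the enzyme (69 residues)."""
    return pd.read_csv(fixture_path("table2_in.csv"), keep_default_na=False)


def load_enzyme_hbv() -> pd.DataFrame:
    """Per-residue hydrogen-bond values on the enzyme (34 residues)."""
    return pd.read_csv(fixture_path("table3_hbv.csv"), keep_default_na=False)


def load_peptide_hbv_entries() -> pd.DataFrame:
    """Peptide-side per-residue HBV entries.

    One row per hydrogen-bonding residue occurrence, keyed by
    (peptide id, N-terminal position).  Duplicated printed rows are retained
    verbatim.
    """
    return pd.read_csv(fixture_path("table5_peptide_hbv.csv"))


def load_positional() -> pd.DataFrame:
    """Per-peptide R_N and F values (19 peptides; one peptide formed no bonds)."""
    return pd.read_csv(fixture_path("table7_rn_f.csv"))


def load_printed_enzyme_class_summary() -> pd.DataFrame:
    """Published per-class IN/HBV aggregates on the enzyme, as printed."""
    return pd.read_csv(fixture_path("table4_printed.csv"), keep_default_na=False)


def load_printed_peptide_class_summary() -> pd.DataFrame:
    """Published per-class HBV aggregates on the peptide side, as printed."""
    return pd.read_csv(fixture_path("table6_printed.csv"), keep_default_na=False)


def load_printed_peptide_aa_summary() -> pd.DataFrame:
    """Published per-amino-acid HBV summary on the peptide side, as printed."""
    return pd.read_csv(
        fixture_path("table5_printed_summary.csv"), keep_default_na=False
    )


def load_aa_properties() -> tuple[pd.DataFrame, pd.Series]:
    """The bundled amino-acid property table.

    Returns ``(values, classes)`` where ``values`` is a 20 x P numeric frame
    indexed by one-letter code (missing entries are NaN, imputed downstream)
    and ``classes`` maps each parameter to its property class label
    (HYDROPHOBIC, ELECTRICAL, HYDROGEN_BOND or STERIC).
    """
    return read_property_table(fixture_path("aa_properties.csv"))


def read_property_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read an amino-acid property CSV with a second header row of class labels."""
    raw = pd.read_csv(path, header=None)
    names = raw.iloc[0, 1:].tolist()
    classes = pd.Series(raw.iloc[1, 1:].tolist(), index=names, name="class")
    values = raw.iloc[2:].copy()
    values.index = values.iloc[:, 0].astype(str)
    values.index.name = "code"
    values = values.iloc[:, 1:]
    values.columns = names
    values = values.apply(pd.to_numeric, errors="coerce")
    return values, classes
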