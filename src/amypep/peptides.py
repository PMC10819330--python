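"""Peptides, activities, and amino-acid side-chain classification.

The study set is a panel of food-derived alpha-amylase inhibitory peptides,
each with an IC50 normalized to the amount of enzyme activity used in the
assay (mmol per activity unit, mmol/U).  Activities enter downstream
regression as the negative base-10 logarithm of that normalized IC50
(a pIC50-style transform).

Side chains are grouped into the four conventional charge/polarity classes.
Cysteine is treated as polar uncharged; non-standard residues such as
pyroglutamate ("Pca") fall into an explicit UNCLASSIFIED bucket rather than
being silently dropped.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k.capitalize() for k, v in THREE_TO_ONE.items()}


class SideChainClass(enum.Enum):
    """Four-way side-chain grouping plus a bucket for non-standard residues."""

    NONPOLAR = "Nonpolar"
    POLAR_UNCHARGED = "Uncharged"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    UNCLASSIFIED = "Unclassified"

    @classmethod
    def from_label(cls, label: str) -> "SideChainClass":
        """Map a report-table label (e.g. ``"Uncharged"``) to the enum."""
        label = (label or "").strip()
        if not label or label in {"-", "—"}:
            return cls.UNCLASSIFIED
        for member in cls:
            if member.value.lower() == label.lower():
                return member
        raise ValueError(f"unknown side-chain class label: {label!r}")


_CLASS_OF_AA: dict[str, SideChainClass] = {}
for _aa in "AVLIPFMW":
    _CLASS_OF_AA[_aa] = SideChainClass.NONPOLAR
for _aa in "GSTCYNQ":
    _CLASS_OF_AA[_aa] = SideChainClass.POLAR_UNCHARGED
for _aa in "KRH":
    _CLASS_OF_AA[_aa] = SideChainClass.POSITIVE
for _aa in "DE":
    _CLASS_OF_AA[_aa] = SideChainClass.NEGATIVE


@dataclass(frozen=True)
class Peptide:
    """One inhibitory peptide with its normalized activity.

    ``ic50_mmol_per_U`` is the half-inhibitory amount per enzyme activity
    unit; smaller means more potent.
    """

    peptide_id: int
    sequence: str
    ic50_mmol_per_U: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.peptide_id}: empty sequence")
        bad = sorted(set(self.sequence) - set(STANDARD_AA))
        if bad:
            raise ValueError(
                f"peptide {self.peptide_id}: invalid amino-acid letter(s) "
                f"{''.join(bad)!r} in sequence {self.sequence!r}"
            )
        if not self.ic50_mmol_per_U > 0:
            raise ValueError(
                f"peptide {self.peptide_id}: IC50 must be positive, "
                f"got {self.ic50_mmol_per_U}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def neg_log_activity(self) -> float:
        return neg_log_activity(self.ic50_mmol_per_U)


def classify_residue(code: str) -> SideChainClass:
    """Classify a one- or three-letter amino-acid code by side-chain type.

    Unknown or non-standard codes (e.g. pyroglutamate ``"Pca"``) return
    :attr:`SideChainClass.UNCLASSIFIED` with a logged warning.
    """
    raw = code
    code = code.strip()
    if len(code) == 3:
        one = THREE_TO_ONE.get(code.upper())
    elif len(code) == 1:
        one = code.upper() if code.upper() in STANDARD_AA else None
    else:
        one = None
    if one is None:
        logger.warning("unrecognized residue code %r classified as UNCLASSIFIED", raw)
        return SideChainClass.UNCLASSIFIED
    return _CLASS_OF_AA[one]


def normalize_ic50(
    ic50_mmol_per_L: float, volume_L: float, activity_U: float
) -> float:
    """Convert a concentration IC50 (mmol/L) to an activity-normalized one.

    IC50[mmol/U] = IC50[mmol/L] x assay volume [L] / enzyme activity [U].
    """
    for name, value in (
        ("ic50_mmol_per_L", ic50_mmol_per_L),
        ("volume_L", volume_L),
        ("activity_U", activity_U),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")
    return ic50_mmol_per_L * volume_L / activity_U


def neg_log_activity(ic50_mmol_per_U: float) -> float:
    """Negative base-10 logarithm of the normalized IC50."""
    if not ic50_mmol_per_U > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_mmol_per_U}")
    return -math.log10(ic50_mmol_per_U)


def load_peptide_table(path: str | Path) -> list[Peptide]:
    """Load a peptide panel from a delimited text file.

    The file must carry columns ``id``, ``sequence``, ``ic50`` (mmol/U) and
    ``source``.  Lengths are recomputed from the sequences; a stated
    ``length`` column, if present, is checked against them.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"peptide table {path} is empty") from exc
    if df.empty:
        raise ValueError(f"peptide table {path} has no data rows")
    required = {"id", "sequence", "ic50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"peptide table {path} missing column(s): {', '.join(sorted(missing))}"
        )
    peptides: list[Peptide] = []
    for idx, row in df.iterrows():
        try:
            pep = Peptide(
                peptide_id=int(row["id"]),
                sequence=str(row["sequence"]).strip(),
                ic50_mmol_per_U=float(row["ic50"]),
                source_label=str(row.get("source", "") or ""),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {idx + 2} of {path.name}: {exc}") from exc
        if "length" in df.columns and not pd.isna(row["length"]):
            stated = int(row["length"])
            if stated != pep.length:
                raise ValueError(
                    f"row {idx + 2} of {path.name}: stated length {stated} "
                    f"!= sequence length {pep.length}"
                )
        peptides.append(pep)
    return peptides


def residue_counts(
    peptides: Iterable[Peptide], exclusions: Iterable[str] = ()
) -> Counter:
    """Occurrences of each amino acid across all sequences, minus exclusions."""
    excl = {e.upper() for e in exclusions}
    counts: Counter = Counter()
    for pep in peptides:
        counts.update(pep.sequence)
    for aa in excl:
        counts.pop(aa, None)
    return counts


def count_residues_by_class(
    peptides: Iterable[Peptide], exclusions: Iterable[str] = ()
) -> dict[SideChainClass, int]:
    """Residue occurrences summed by side-chain class.

    ``exclusions`` drops the named amino acids entirely (used to mirror
    report tables that leave out residues never observed to hydrogen-bond).
    Classes with zero count are omitted.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("peptide list is empty")
    by_class: dict[SideChainClass, int] = {}
    for aa, n in residue_counts(peptides, exclusions).items():
        cls = classify_residue(aa)
        by_class[cls] = by_class.get(cls, 0) + n
    return by_class
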