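"""Length-weighted positional statistics of hydrogen bonds on a peptide.

Two per-peptide statistics locate where along the chain the hydrogen bonds
sit, each a weighted mean over the peptide's m bonds with the bond lengths
d_i as weights:

* R_N = sum_i [ (n_i - 1)/(L - 1) * d_i ] / sum_i d_i — the N-terminal
  position value.  0 when every bond sits on the first residue, 1 on the
  last.
* F = sum_i [ (1 - (min(n_i, c_i) - 1)/h) * d_i ] / sum_i d_i — the
  near-median (terminal-proximity) value, with c_i = L - n_i + 1 the
  position counted from the C-terminus and half-span h = (L-1)/2 for odd L,
  (L-2)/2 for even L.  1 when every bond is at a terminus, 0 at the center.

Both lie in [0, 1] and are invariant to a common rescaling of the d_i.
Peptides that form no bonds have no defined value and are omitted from
panel summaries rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .contacts import HydrogenBond
from .peptides import Peptide


class NoBondsError(ValueError):
    """A positional statistic was requested for a peptide without bonds."""


def _positions_lengths(
    bonds: Iterable[HydrogenBond | tuple[int, float]],
) -> tuple[np.ndarray, np.ndarray]:
    positions, lengths = [], []
    for bond in bonds:
        if isinstance(bond, HydrogenBond):
            positions.append(bond.position)
            lengths.append(bond.length)
        else:
            n_i, d_i = bond
            positions.append(int(n_i))
            lengths.append(float(d_i))
    return np.asarray(positions, dtype=int), np.asarray(lengths, dtype=float)


def _validate(positions: np.ndarray, lengths: np.ndarray, length: int) -> None:
    if positions.size == 0:
        raise NoBondsError("no hydrogen bonds: statistic undefined")
    if np.any((positions < 1) | (positions > length)):
        raise ValueError(
            f"bond positions {positions.tolist()} outside 1..{length}"
        )
    if np.any(lengths <= 0):
        raise ValueError("bond lengths must be positive")


@dataclass(frozen=True)
class PositionalResult:
    peptide_id: int
    sequence: str
    m: int
    r_n: float
    f_value: float


def r_n(
    bonds: Iterable[HydrogenBond | tuple[int, float]],
    length: int,
    weighting: str = "length",
) -> float:
    """N-terminal position value of a peptide's hydrogen bonds.

    ``weighting="length"`` uses the bond lengths d_i as weights (the
    reference definition); ``"inverse"`` uses 1/d_i instead (a non-standard
    alternative provided for sensitivity checks).
    """
    if length < 2:
        raise ValueError(f"peptide length must be >= 2, got {length}")
    positions, lengths = _positions_lengths(bonds)
    _validate(positions, lengths, length)
    weights = _weights(lengths, weighting)
    factors = (positions - 1) / (length - 1)
    return float(np.sum(factors * weights) / np.sum(weights))


def near_median_f(
    bonds: Iterable[HydrogenBond | tuple[int, float]],
    length: int,
    weighting: str = "length",
) -> float:
    """Near-median (terminal-proximity) value of a peptide's hydrogen bonds."""
    if length < 3:
        raise ValueError(f"peptide length must be >= 3, got {length}")
    positions, lengths = _positions_lengths(bonds)
    _validate(positions, lengths, length)
    weights = _weights(lengths, weighting)
    factors = np.array([_terminal_proximity(n, length) for n in positions])
    return float(np.sum(factors * weights) / np.sum(weights))


def _terminal_proximity(n_i: int, length: int) -> float:
    """Positional factor of F: 1 at either terminus, 0 at the center."""
    c_i = length - n_i + 1
    half = (length - 1) / 2.0 if length % 2 else (length - 2) / 2.0
    return 1.0 - (min(n_i, c_i) - 1) / half


def _weights(lengths: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "length":
        return lengths
    if weighting == "inverse":
        return 1.0 / lengths
    raise ValueError(f"weighting must be 'length' or 'inverse', got {weighting!r}")


def batch_positional(
    peptides: Sequence[Peptide],
    bonds: Iterable[HydrogenBond],
    weighting: str = "length",
) -> tuple[list[PositionalResult], dict[str, float] | None]:
    """Per-peptide R_N and F plus their panel means.

    Peptides with zero bonds are omitted from the results and the means.
    Returns ``(results, means)`` with ``means`` None when no peptide bonded.
    """
    by_peptide: dict[int, list[HydrogenBond]] = {}
    for bond in bonds:
        by_peptide.setdefault(bond.peptide_id, []).append(bond)
    results: list[PositionalResult] = []
    for pep in peptides:
        pep_bonds = by_peptide.get(pep.peptide_id, [])
        if not pep_bonds:
            continue
        results.append(
            PositionalResult(
                peptide_id=pep.peptide_id,
                sequence=pep.sequence,
                m=len(pep_bonds),
                r_n=r_n(pep_bonds, pep.length, weighting),
                f_value=near_median_f(pep_bonds, pep.length, weighting),
            )
        )
    if not results:
        return results, None
    means = {
        "r_n": float(np.mean([r.r_n for r in results])),
        "f": float(np.mean([r.f_value for r in results])),
        "n_peptides": len(results),
    }
    return results, means


def one_sample_t_test(
    values: Sequence[float], mu0: float = 0.5
) -> dict[str, float]:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    Used to test whether the panel mean of R_N or F differs from the
    no-preference value 0.5.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two observations")
    if np.allclose(values, values[0]):
        raise ValueError("sample variance is zero; t-test undefined")
    t, p = stats.ttest_1samp(values, popmean=mu0)
    return {"t": float(t), "df": int(values.size - 1), "p": float(p)}
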