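"""Peptide QSAR: descriptor reduction, TTPN encoding, PLS1 regression, VIP.

Pipeline
--------
1.  An amino-acid property table (20 rows x P numeric scales, each scale
    labeled HYDROPHOBIC, ELECTRICAL, HYDROGEN_BOND or STERIC) is reduced
    per class by principal component analysis; the top components of each
    class, at a per-class quota (default 2/4/2/5 = 13), become the amino
    acid descriptors.
2.  Each peptide is encoded by two-terminal position numbering (TTPN): the
    five N-terminal and five C-terminal residues are concatenated into a
    decapeptide (windows overlap verbatim for lengths 5-9), and each of
    the 10 positions is expanded into the 13 descriptors, giving variables
    V-1..V-130 with V-k = descriptor d of position p, k = 13 (p - 1) + d.
3.  A single-response partial least squares regression (PLS1, NIPALS with
    X-only deflation) links the autoscaled 130-variable matrix to the
    negative log activity.
4.  Variable importance in projection:
    VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a ),
    where SS_a is the y-variance explained by component a and w_a its
    weight vector; the mean squared VIP over variables is exactly 1, so
    VIP > 1 marks above-average importance ("significant" variables).
5.  The count of significant variables (NSIV) is summarized per decapeptide
    position (N1..N5, C1..C5) and per descriptor property class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import Peptide, STANDARD_AA

PROPERTY_CLASSES = ("HYDROPHOBIC", "ELECTRICAL", "HYDROGEN_BOND", "STERIC")
#: Per-class descriptor quotas (13 descriptors in total).
DEFAULT_QUOTAS: dict[str, int] = {
    "HYDROPHOBIC": 2,
    "ELECTRICAL": 4,
    "HYDROGEN_BOND": 2,
    "STERIC": 5,
}
TTPN_POSITIONS = 10

_VARIABLE_RE = re.compile(r"^V-(\d+)$")


@dataclass(frozen=True)
class DescriptorSet:
    """Amino-acid descriptors: a 20 x D numeric table plus class labels."""

    values: pd.DataFrame  # index: one-letter codes; columns: descriptor names
    classes: dict[str, str]  # descriptor name -> property class

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def quotas(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cls in self.classes.values():
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def reduce_descriptors(
    table: pd.DataFrame,
    classes: pd.Series | Mapping[str, str],
    quotas: Mapping[str, int] | None = None,
) -> DescriptorSet:
    """Reduce a property table to descriptors by per-class PCA.

    Within each property class the parameters are mean-imputed,
    standardized across the 20 amino acids, and decomposed; the top
    ``quota`` principal-component scores become that class's descriptors.
    Each component is oriented so its loading on the class's first
    parameter is non-negative, making signs deterministic.
    """
    quotas = dict(quotas or DEFAULT_QUOTAS)
    classes = pd.Series(dict(classes))
    missing_rows = sorted(set(STANDARD_AA) - set(table.index))
    if missing_rows:
        raise ValueError(f"property table missing amino acid(s): {missing_rows}")
    table = table.loc[list(STANDARD_AA)]
    cols_by_class: dict[str, list[str]] = {c: [] for c in quotas}
    for col in table.columns:
        cls = classes.get(col)
        if cls not in cols_by_class:
            raise ValueError(f"parameter {col!r} has unknown class {cls!r}")
        cols_by_class[cls].append(col)
    desc_values: dict[str, np.ndarray] = {}
    desc_classes: dict[str, str] = {}
    serial = 0
    for cls in PROPERTY_CLASSES:
        if cls not in quotas:
            continue
        quota = quotas[cls]
        cols = cols_by_class.get(cls, [])
        if not cols:
            raise ValueError(f"no parameters labeled {cls}")
        block = table[cols].astype(float).copy()
        block = block.fillna(block.mean())  # per-parameter mean imputation
        centered = block.to_numpy() - block.to_numpy().mean(axis=0)
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            flat = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"zero-variance parameter(s) in class {cls}: {flat}")
        z = centered / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
        if quota > rank:
            raise ValueError(
                f"class {cls}: quota {quota} exceeds rank {rank} of its block"
            )
        scores = u[:, :quota] * s[:quota]
        # orient: loading of each component on the block's first parameter >= 0
        signs = np.where(vt[:quota, 0] < 0, -1.0, 1.0)
        scores = scores * signs
        for j in range(quota):
            serial += 1
            name = f"D{serial}_{cls.lower()}"
            desc_values[name] = scores[:, j]
            desc_classes[name] = cls
    values = pd.DataFrame(desc_values, index=list(STANDARD_AA))
    return DescriptorSet(values=values, classes=desc_classes)


def ttpn_decapeptide(sequence: str) -> str:
    """Concatenate the first five and last five residues of a peptide.

    For lengths 5-9 the two windows overlap and the shared residues appear
    in both halves verbatim.
    """
    if len(sequence) < 5:
        raise ValueError(
            f"TTPN needs peptide length >= 5, got {len(sequence)} ({sequence!r})"
        )
    return sequence[:5] + sequence[-5:]


def variable_name(position: int, descriptor: int, n_descriptors: int = 13) -> str:
    """Name of the variable for (decapeptide position, descriptor index)."""
    if not 1 <= position <= TTPN_POSITIONS:
        raise ValueError(f"position must be in 1..{TTPN_POSITIONS}")
    if not 1 <= descriptor <= n_descriptors:
        raise ValueError(f"descriptor must be in 1..{n_descriptors}")
    return f"V-{n_descriptors * (position - 1) + descriptor}"


def decode_variable(name: str, n_descriptors: int = 13) -> tuple[int, int]:
    """Inverse of :func:`variable_name`: ``"V-k"`` -> (position, descriptor)."""
    match = _VARIABLE_RE.match(name.strip())
    if not match:
        raise ValueError(f"malformed variable name {name!r}; expected 'V-<k>'")
    k = int(match.group(1))
    if not 1 <= k <= TTPN_POSITIONS * n_descriptors:
        raise ValueError(f"variable index {k} outside 1..{TTPN_POSITIONS * n_descriptors}")
    position = (k - 1) // n_descriptors + 1
    descriptor = k - n_descriptors * (position - 1)
    return position, descriptor


def ttpn_encode(
    peptide: Peptide | str, descriptors: DescriptorSet
) -> np.ndarray:
    """Encode one peptide into the TTPN descriptor vector (10 x D values)."""
    sequence = peptide.sequence if isinstance(peptide, Peptide) else peptide
    deca = ttpn_decapeptide(sequence)
    rows = descriptors.values.loc[list(deca)].to_numpy()
    return rows.reshape(-1)


def encode_matrix(
    peptides: Sequence[Peptide | str], descriptors: DescriptorSet
) -> pd.DataFrame:
    """Encode a panel into an N x (10 D) matrix with columns V-1..V-10D."""
    d = descriptors.n_descriptors
    names = [
        variable_name(p, j, d)
        for p in range(1, TTPN_POSITIONS + 1)
        for j in range(1, d + 1)
    ]
    data = np.vstack([ttpn_encode(pep, descriptors) for pep in peptides])
    index = [
        pep.peptide_id if isinstance(pep, Peptide) else i
        for i, pep in enumerate(peptides, start=1)
    ]
    return pd.DataFrame(data, columns=names, index=index)


@dataclass
class PLSRModel:
    """Fitted single-response PLS model on autoscaled data."""

    n_components: int
    weights: np.ndarray  # p x A, unit-norm columns
    x_loadings: np.ndarray  # p x A
    scores: np.ndarray  # n x A
    y_loadings: np.ndarray  # A,
    coef: np.ndarray  # p, on the autoscaled scale
    ss_y: np.ndarray  # A, y-variance explained per component
    r2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    variable_names: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = (X - self.x_mean) / self.x_std
        return self.y_mean + self.y_std * (z @ self.coef)


def fit_plsr(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    n_components: int = 2,
) -> PLSRModel:
    """Fit PLS1 by NIPALS with deflation of X only.

    Columns of X and y are autoscaled internally (mean 0, variance 1,
    ddof = 1).  Each component's weight vector maximizes covariance between
    the X-score and the response; the fit is deterministic given the input.
    """
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    flat = np.nonzero(x_std == 0)[0]
    if flat.size:
        which = names[flat[0]] if names else f"column {flat[0]}"
        raise ValueError(f"zero-variance predictor: {which}")
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=1))
    if y_std == 0:
        raise ValueError("response has zero variance")
    Xa = (X - x_mean) / x_std
    ya = (y - y_mean) / y_std

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xdef = Xa.copy()
    for a in range(n_components):
        w = Xdef.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(
                f"component {a + 1}: residual covariance is zero; "
                f"reduce n_components"
            )
        w /= norm
        t = Xdef @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        P[:, a] = Xdef.T @ t / tt
        q[a] = float(ya @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xdef = Xdef - np.outer(t, P[:, a])
    # regression coefficients on the autoscaled scale
    coef = W @ np.linalg.solve(P.T @ W, q)
    y_hat = T @ q
    ss_tot = float(ya @ ya)
    ss_y = q**2 * np.einsum("ij,ij->j", T, T)
    r2 = 1.0 - float((ya - y_hat) @ (ya - y_hat)) / ss_tot
    return PLSRModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        scores=T,
        y_loadings=q,
        coef=coef,
        ss_y=ss_y,
        r2=r2,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        variable_names=names,
    )


def vip(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection for every predictor.

    Satisfies mean(VIP^2) = 1 exactly, so the VIP > 1 rule selects
    variables of above-average importance.
    """
    W, ss = model.weights, model.ss_y
    p = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def select_significant(
    vip_values: Sequence[float],
    names: Sequence[str] | None = None,
    threshold: float = 1.0,
) -> list[str]:
    """Variables with VIP above the threshold, ordered by VIP descending.

    Ties keep the original variable order (stable sort).
    """
    vip_values = np.asarray(list(vip_values), dtype=float)
    if names is None:
        names = [f"V-{j + 1}" for j in range(len(vip_values))]
    order = sorted(
        (j for j in range(len(vip_values)) if vip_values[j] > threshold),
        key=lambda j: (-vip_values[j], j),
    )
    return [names[j] for j in order]


def nsiv_summaries(
    selected: Iterable[str],
    descriptors: DescriptorSet,
) -> dict[str, dict]:
    """Counts of significant variables by decapeptide slot and property class.

    Positions 1-5 are the N-terminal slots N1..N5, positions 6-10 the
    C-terminal slots C1..C5.  Class means divide the class total by its
    descriptor quota.
    """
    d = descriptors.n_descriptors
    desc_names = list(descriptors.values.columns)
    quotas = descriptors.quotas
    by_position = {f"N{i}": 0 for i in range(1, 6)}
    by_position.update({f"C{i}": 0 for i in range(1, 6)})
    class_totals = {cls: 0 for cls in quotas}
    for name in selected:
        position, descriptor = decode_variable(name, n_descriptors=d)
        slot = f"N{position}" if position <= 5 else f"C{position - 5}"
        by_position[slot] += 1
        cls = descriptors.classes[desc_names[descriptor - 1]]
        class_totals[cls] += 1
    by_class = {
        cls: {
            "n_descriptors": quotas[cls],
            "total": class_totals[cls],
            "mean": class_totals[cls] / quotas[cls],
        }
        for cls in quotas
    }
    return {"by_position": by_position, "by_class": by_class}
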