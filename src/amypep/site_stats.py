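"""Per-residue interaction and hydrogen-bond statistics with class aggregation.

Two per-residue metrics summarize a panel of docked enzyme-peptide poses:

* IN (interaction number): for each enzyme residue, the number of peptides
  in the panel that contact it — one count per peptide-residue interaction.
* HBV (hydrogen-bond value): for each residue (enzyme- or peptide-side),
  ``sum_i D / d_i`` over its hydrogen bonds, with D = 3.5 A the maximum bond
  length and d_i the individual bond lengths.  Many short bonds score high;
  each term is >= 1, so HBV is bounded below by the bond count.

Residues are then pooled by side-chain class and compared with a
Kruskal-Wallis rank test; pairwise Dunn tests with Bonferroni correction
yield compact letter displays (classes sharing a letter are not
significantly different).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import MAX_HBOND_LENGTH, HydrogenBond, InteractionRecord
from .peptides import Peptide, SideChainClass, classify_residue, residue_counts

CLASS_ORDER = [
    SideChainClass.NONPOLAR,
    SideChainClass.POLAR_UNCHARGED,
    SideChainClass.POSITIVE,
    SideChainClass.NEGATIVE,
]


@dataclass(frozen=True)
class ResidueStat:
    """Per-residue value of one metric (IN count or HBV)."""

    residue_label: str
    side_chain_class: SideChainClass
    in_count: int = 0
    hbv: float = 0.0


@dataclass(frozen=True)
class ClassSummary:
    """Per-class aggregate: residue count, metric total, and mean."""

    side_chain_class: SideChainClass
    n_residues: int
    total: float
    mean: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used in the report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_in(records: Iterable[InteractionRecord]) -> dict[str, int]:
    """Interaction number per enzyme residue label, pooled over peptides."""
    counts: Counter = Counter(r.enzyme_residue_label for r in records)
    return dict(counts)


def compute_hbv(
    bonds: Iterable[HydrogenBond],
    group_key: Callable[[HydrogenBond], Hashable] | None = None,
) -> dict[Hashable, float]:
    """HBV = sum of D/d_i per group of hydrogen bonds.

    By default bonds are grouped by enzyme residue label; pass ``group_key``
    to group peptide-side (e.g. by ``(peptide_id, position)``).  Groups with
    no bonds are simply absent.
    """
    if group_key is None:
        group_key = lambda b: b.enzyme_residue_label  # noqa: E731
    out: dict[Hashable, float] = defaultdict(float)
    for bond in bonds:
        if not 0 < bond.length <= MAX_HBOND_LENGTH:
            raise ValueError(
                f"bond length {bond.length} outside (0, {MAX_HBOND_LENGTH}]"
            )
        out[group_key(bond)] += MAX_HBOND_LENGTH / bond.length
    return dict(out)


def residue_stats_from_table(
    table: pd.DataFrame, metric: str
) -> list[ResidueStat]:
    """Build :class:`ResidueStat` rows from a per-residue report table.

    ``table`` needs columns ``residue``, ``residue_type`` and either
    ``in_count`` or ``hbv``.
    """
    stats_out = []
    for _, row in table.iterrows():
        cls = SideChainClass.from_label(str(row["residue_type"]))
        stats_out.append(
            ResidueStat(
                residue_label=str(row["residue"]),
                side_chain_class=cls,
                in_count=int(row["in_count"]) if metric == "IN" else 0,
                hbv=float(row["hbv"]) if metric == "HBV" else 0.0,
            )
        )
    return stats_out


def summarize_by_class(
    stats_in: Sequence[ResidueStat],
    metric: str,
    include_unclassified: bool = False,
) -> list[ClassSummary]:
    """Aggregate a per-residue metric by side-chain class.

    ``metric`` is ``"IN"`` or ``"HBV"``.  Residues outside the four standard
    classes (e.g. pyroglutamate) are excluded unless requested.
    """
    if metric not in {"IN", "HBV"}:
        raise ValueError(f"metric must be 'IN' or 'HBV', got {metric!r}")
    if not stats_in:
        raise ValueError("no residue statistics to summarize")
    grouped: dict[SideChainClass, list[float]] = defaultdict(list)
    for st in stats_in:
        if (
            st.side_chain_class is SideChainClass.UNCLASSIFIED
            and not include_unclassified
        ):
            continue
        value = float(st.in_count if metric == "IN" else st.hbv)
        grouped[st.side_chain_class].append(value)
    order = CLASS_ORDER + [SideChainClass.UNCLASSIFIED]
    summaries = []
    for cls in order:
        if cls not in grouped:
            continue
        values = grouped[cls]
        total = float(np.sum(values))
        summaries.append(
            ClassSummary(
                side_chain_class=cls,
                n_residues=len(values),
                total=total,
                mean=total / len(values),
            )
        )
    return summaries


def _per_residue_hbv_entries(
    bonds_or_entries: Iterable[HydrogenBond] | pd.DataFrame,
) -> list[tuple[str, int, int, float]]:
    """Normalize input to (amino_acid, peptide_id, position, hbv) tuples."""
    if isinstance(bonds_or_entries, pd.DataFrame):
        return [
            (str(r["amino_acid"]), int(r["peptide_id"]), int(r["position"]),
             float(r["hbv"]))
            for _, r in bonds_or_entries.iterrows()
        ]
    grouped = compute_hbv(
        bonds_or_entries,
        group_key=lambda b: (b.peptide_id, b.position, b.peptide_residue),
    )
    return [
        (aa, pid, pos, hbv) for (pid, pos, aa), hbv in sorted(grouped.items())
    ]


def aggregate_peptide_amino_acids(
    bonds_or_entries: Iterable[HydrogenBond] | pd.DataFrame,
    peptides: Sequence[Peptide],
    exclusions: Iterable[str] = (),
) -> pd.DataFrame:
    """Peptide-side HBV aggregation per amino acid.

    Accepts either raw :class:`HydrogenBond` records (HBVs are computed per
    peptide residue first) or a pre-computed entry table with columns
    ``amino_acid``, ``peptide_id``, ``position``, ``hbv``.

    The occurrence count per amino acid comes from the peptide sequences, so
    residues that never form a bond still enter the denominator of the mean.
    Excluded amino acids are omitted entirely.  Returns a frame indexed by
    one-letter code with columns ``residue_type``, ``n_entries``, ``total``,
    ``n_occurrences``, ``mean``.
    """
    entries = _per_residue_hbv_entries(bonds_or_entries)
    known = {p.peptide_id for p in peptides}
    for aa, pid, pos, _ in entries:
        if pid not in known:
            raise ValueError(f"entry {aa} {pid}-{pos} references unknown peptide {pid}")
    excl = {e.upper() for e in exclusions}
    occurrences = residue_counts(peptides, excl)
    totals: dict[str, float] = defaultdict(float)
    n_entries: Counter = Counter()
    for aa, _, _, hbv in entries:
        if aa in excl:
            continue
        totals[aa] += hbv
        n_entries[aa] += 1
    rows = []
    for aa in sorted(occurrences):
        count = occurrences[aa]
        total = totals.get(aa, 0.0)
        rows.append(
            {
                "amino_acid": aa,
                "residue_type": classify_residue(aa).value,
                "n_entries": n_entries.get(aa, 0),
                "total": total,
                "n_occurrences": count,
                "mean": total / count if count else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("amino_acid")


def peptide_class_hbv_groups(
    bonds_or_entries: Iterable[HydrogenBond] | pd.DataFrame,
    peptides: Sequence[Peptide],
    exclusions: Iterable[str] = (),
) -> dict[SideChainClass, list[float]]:
    """Per-residue-occurrence HBV samples pooled by side-chain class.

    Every amino-acid occurrence across the panel contributes one value:
    its HBV if it formed hydrogen bonds, else 0 — the sampling unit used
    for the peptide-side group comparison.
    """
    entries = _per_residue_hbv_entries(bonds_or_entries)
    excl = {e.upper() for e in exclusions}
    occurrences = residue_counts(peptides, excl)
    groups: dict[SideChainClass, list[float]] = defaultdict(list)
    per_aa_values: dict[str, list[float]] = defaultdict(list)
    for aa, _, _, hbv in entries:
        if aa not in excl:
            per_aa_values[aa].append(hbv)
    for aa, count in sorted(occurrences.items()):
        values = per_aa_values.get(aa, [])
        padded = values + [0.0] * (count - len(values))
        groups[classify_residue(aa)].extend(padded)
    return dict(groups)


def kruskal_wallis(groups: Mapping[Hashable, Sequence[float]]) -> dict[str, float]:
    """Kruskal-Wallis H test across >= 2 non-empty groups.

    Midrank tie correction; p from chi-squared with k-1 degrees of freedom.
    Identical constants across all groups give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = []
    for key, values in groups.items():
        values = list(values)
        if not values:
            raise ValueError(f"group {key!r} is empty")
        samples.append(np.asarray(values, dtype=float))
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "p": 1.0, "df": len(groups) - 1}
    h, p = stats.kruskal(*samples)
    return {"H": float(h), "p": float(p), "df": len(groups) - 1}


def dunn_posthoc(
    groups: Mapping[Hashable, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise Dunn z-tests on pooled midranks, Bonferroni-corrected.

    Returns a symmetric frame of adjusted two-sided p-values.  The tie
    correction term sum(t^3 - t) / (12 (N - 1)) is subtracted from the
    rank-variance factor N (N + 1) / 12.
    """
    keys = list(groups)
    samples = {k: np.asarray(list(groups[k]), dtype=float) for k in keys}
    pooled = np.concatenate([samples[k] for k in keys])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[Hashable, float] = {}
    start = 0
    for k in keys:
        n_k = len(samples[k])
        mean_rank[k] = float(np.mean(ranks[start : start + n_k]))
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_factor = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(keys) * (len(keys) - 1) // 2
    pmat = pd.DataFrame(np.ones((len(keys), len(keys))), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            se = np.sqrt(
                variance_factor * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
            )
            if se == 0:
                p_adj = 1.0
            else:
                z = (mean_rank[a] - mean_rank[b]) / se
                p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
            pmat.loc[a, b] = pmat.loc[b, a] = p_adj
    return pmat


def significance_letters(
    groups: Mapping[Hashable, Sequence[float]], alpha: float = 0.05
) -> dict[Hashable, str]:
    """Compact letter display from Kruskal-Wallis + Dunn post hoc.

    Groups sharing a letter are not significantly different at ``alpha``.
    If the omnibus test is not significant, every group shares one letter.
    Letters are assigned greedily in order of decreasing group mean.
    """
    keys = sorted(groups, key=lambda k: -float(np.mean(list(groups[k]))))
    omnibus = kruskal_wallis(groups)
    if omnibus["p"] >= alpha:
        return {k: "a" for k in keys}
    pmat = dunn_posthoc(groups)
    differs = {
        (a, b): pmat.loc[a, b] < alpha for a in keys for b in keys if a != b
    }
    letter_groups: list[list] = []  # each letter = a clique of non-different groups
    for k in keys:
        placed = False
        for clique in letter_groups:
            if all(not differs[(k, other)] for other in clique):
                clique.append(k)
                placed = True
        if not placed:
            letter_groups.append([k])
    # absorb redundant letters (cliques fully contained in another)
    pruned: list[list] = []
    for clique in letter_groups:
        if not any(set(clique) < set(other) for other in letter_groups):
            if set(clique) not in [set(c) for c in pruned]:
                pruned.append(clique)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[Hashable, str] = {k: "" for k in keys}
    for letter, clique in zip(alphabet, pruned):
        for k in clique:
            out[k] += letter
    return {k: "".join(sorted(v)) for k, v in out.items()}
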