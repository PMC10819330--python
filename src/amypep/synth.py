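"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the study data — a panel of ~20
peptides of length 5-16, a few heavy-atom hydrogen bonds per peptide with
lengths in (2.4, 3.5] A, residue-level enzyme contacts, and a TTPN-encoded
descriptor matrix with a sparse linear activity model — without claiming
physical realism of the geometry.  Every generator is a pure function of
its configuration (including the seed).

Bond positions can be biased toward the peptide termini through ``beta``:
a position n is drawn with probability proportional to exp(beta * g(n))
where g is the same terminal-proximity transform used by the F statistic,
so beta directly shifts the expected F (beta = 0 gives uniform positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .contacts import HydrogenBond
from .peptides import Peptide, STANDARD_AA
from .positional import _terminal_proximity
from .qsar import DescriptorSet, encode_matrix


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults mirror the study conditions: 20 peptides, lengths 5-16,

    roughly three hydrogen bonds per peptide, bond lengths near 3.0 A, and
    a 20-sample sparse linear QSAR with 5 active variables and noise at 10%
    of the signal spread.
    """

    seed: int = 0
    n_peptides: int = 20
    length_range: tuple[int, int] = (5, 16)
    composition: dict[str, float] | None = None  # per-AA weights; None = uniform
    mean_bonds_per_peptide: float = 3.3
    beta: float = 1.0  # terminal bias of bond positions; 0 = uniform
    bond_length_mean: float = 3.0
    bond_length_sd: float = 0.2
    bond_length_range: tuple[float, float] = (2.4, 3.5)
    qsar_support_size: int = 5
    qsar_effect_size: float = 1.0
    qsar_noise_sd_ratio: float = 0.1  # noise SD as a fraction of signal SD


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent streams per generator so stages can be re-run in isolation
    return np.random.default_rng([config.seed, stream])


def simulate_peptides(config: SimulationConfig) -> list[Peptide]:
    """Random peptide panel: lengths uniform in range, residues i.i.d.

    Activities are drawn log-uniform over the observed IC50 range
    (about 10-500 mmol/U) and are independent of sequence; use
    :func:`simulate_qsar` when a sequence-activity link is needed.
    """
    rng = _rng(config, 1)
    weights = config.composition or {aa: 1.0 for aa in STANDARD_AA}
    alphabet = sorted(weights)
    probs = np.array([weights[aa] for aa in alphabet], dtype=float)
    if probs.sum() <= 0 or np.any(probs < 0):
        raise ValueError("composition weights must be non-negative and sum > 0")
    probs = probs / probs.sum()
    lo, hi = config.length_range
    peptides = []
    for pid in range(1, config.n_peptides + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(alphabet), size=length, p=probs))
        ic50 = float(10 ** rng.uniform(1.0, 2.7))
        peptides.append(Peptide(peptide_id=pid, sequence=seq, ic50_mmol_per_U=ic50))
    return peptides


def sample_bond_lengths(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Bond lengths from a normal truncated to the allowed range."""
    lo, hi = config.bond_length_range
    a = (lo - config.bond_length_mean) / config.bond_length_sd
    b = (hi - config.bond_length_mean) / config.bond_length_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.bond_length_mean, scale=config.bond_length_sd,
        size=n, random_state=rng,
    )


def simulate_hbonds(
    peptides: Sequence[Peptide], config: SimulationConfig
) -> list[HydrogenBond]:
    """Hydrogen-bond records for a panel, with terminal position bias ``beta``.

    Bond counts are Poisson; a peptide may draw zero bonds, exercising the
    omission path of the positional statistics.
    """
    rng = _rng(config, 2)
    bonds: list[HydrogenBond] = []
    for pep in peptides:
        m = int(rng.poisson(config.mean_bonds_per_peptide))
        if m == 0:
            continue
        proximity = np.array(
            [_terminal_proximity(n, pep.length) for n in range(1, pep.length + 1)]
        )
        logits = config.beta * proximity
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        positions = rng.choice(np.arange(1, pep.length + 1), size=m, p=probs)
        lengths = sample_bond_lengths(m, config, rng)
        for n_i, d_i in zip(positions, lengths):
            bonds.append(
                HydrogenBond(
                    peptide_id=pep.peptide_id,
                    position=int(n_i),
                    peptide_residue=pep.sequence[int(n_i) - 1],
                    length=float(d_i),
                )
            )
    return bonds


def expected_f_uniform(length: int) -> float:
    """Exact E[F] for uniformly placed bonds on a peptide of given length.

    Because bond lengths are independent of positions, the expectation of
    the d-weighted mean equals the unweighted positional mean.
    """
    return float(
        np.mean([_terminal_proximity(n, length) for n in range(1, length + 1)])
    )


def simulate_qsar(
    config: SimulationConfig, descriptors: DescriptorSet
) -> dict:
    """Sparse linear activity model on a TTPN-encoded random panel.

    y = X beta + eps, with beta nonzero on a random support of
    ``qsar_support_size`` variables (autoscaled X) and eps Gaussian with SD
    equal to ``qsar_noise_sd_ratio`` times the signal SD.  Returns X, y,
    the support names, and the coefficient vector.
    """
    rng = _rng(config, 3)
    p = 10 * descriptors.n_descriptors
    if config.qsar_support_size > p:
        raise ValueError("support size exceeds number of variables")
    peptides = simulate_peptides(config)
    X = encode_matrix(peptides, descriptors)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    support_idx = rng.choice(p, size=config.qsar_support_size, replace=False)
    beta = np.zeros(p)
    beta[support_idx] = config.qsar_effect_size * rng.choice(
        [-1.0, 1.0], size=config.qsar_support_size
    )
    signal = Xs.to_numpy(dtype=float) @ beta
    noise_sd = config.qsar_noise_sd_ratio * (signal.std(ddof=1) or 1.0)
    y = signal + rng.normal(0.0, noise_sd, size=len(peptides))
    return {
        "peptides": peptides,
        "X": X,
        "y": y,
        "support": [X.columns[j] for j in sorted(support_idx)],
        "beta": beta,
        "noise_sd": noise_sd,
    }


def _pdb_atom_line(
    serial: int, name: str, res_name: str, chain: str, res_seq: int,
    xyz: tuple[float, float, float], element: str, hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    x, y, z = xyz
    return (
        f"{record}{serial:5d} {name:<4s} {res_name:>3s} {chain}{res_seq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def simulate_complex_pdb(
    n_hbonds: int, n_contacts: int, seed: int = 0
) -> tuple[str, dict]:
    """Two-chain PDB text with planted interface pairs and its truth table.

    Chain A is the "enzyme", chain B the "peptide".  Each planted hydrogen
    bond is an enzyme carbonyl O facing a peptide backbone N at a distance
    drawn from U(2.6, 3.5); each extra contact is a pure carbon-carbon pair
    at U(3.6, 3.95) — inside a 4.0 A interaction cutoff but not a polar
    pair.  Residue pairs are spaced far apart so no unplanned pair falls
    within 5 A.  A water molecule and explicit hydrogens are included to
    exercise the parser's filters.

    Returns ``(pdb_text, truth)`` with truth listing the planted bonds
    (peptide position, enzyme residue label, distance) and the full
    expected contact residue set at cutoff 4.0 A.
    """
    if n_hbonds < 0 or n_contacts < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    serial = 0
    truth_bonds: list[dict] = []
    contact_labels: list[str] = []
    spacing = 25.0

    def add(name, res_name, chain, res_seq, xyz, element, hetatm=False):
        nonlocal serial
        serial += 1
        lines.append(
            _pdb_atom_line(serial, name, res_name, chain, res_seq, xyz, element,
                           hetatm)
        )

    n_pairs = n_hbonds + n_contacts
    for k in range(n_pairs):
        base = (spacing * k, 0.0, 0.0)
        res_seq = k + 1
        is_hbond = k < n_hbonds
        if is_hbond:
            d = float(rng.uniform(2.6, 3.5))
            # enzyme residue: backbone carbons plus the bonding O
            add(" O  ", "SER", "A", res_seq, base, "O")
            add(" C  ", "SER", "A", res_seq, (base[0], base[1] - 1.3, 0.0), "C")
            add(" CA ", "SER", "A", res_seq, (base[0], base[1] - 2.6, 0.0), "C")
            # peptide residue: bonding N plus carbons
            add(" N  ", "GLY", "B", res_seq, (base[0] + d, 0.0, 0.0), "N")
            add(" CA ", "GLY", "B", res_seq, (base[0] + d, 1.5, 0.0), "C")
            add(" C  ", "GLY", "B", res_seq, (base[0] + d, 3.0, 0.0), "C")
            add(" H  ", "GLY", "B", res_seq, (base[0] + d, -1.0, 0.0), "H")
            label = f"Ser{res_seq}"
            truth_bonds.append(
                {"position": res_seq, "enzyme_residue": label, "length": d}
            )
            contact_labels.append(label)
        else:
            d = float(rng.uniform(3.6, 3.95))
            add(" CA ", "ALA", "A", res_seq, base, "C")
            add(" CB ", "ALA", "A", res_seq, (base[0], -1.5, 0.0), "C")
            add(" CA ", "ALA", "B", res_seq, (base[0] + d, 0.0, 0.0), "C")
            add(" CB ", "ALA", "B", res_seq, (base[0] + d, 1.5, 0.0), "C")
            contact_labels.append(f"Ala{res_seq}")
    # a stray water near the interface must not contribute atoms
    add(" O  ", "HOH", "A", 900, (0.0, 2.0, 0.0), "O", hetatm=True)
    lines.append("END")
    truth = {
        "hbonds": truth_bonds,
        "contact_residues": contact_labels,
        "n_hbonds": n_hbonds,
        "n_contacts": n_contacts,
    }
    return "\n".join(lines) + "\n", truth
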