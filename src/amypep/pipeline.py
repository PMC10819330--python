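"""End-to-end orchestration: fixtures or extracted records -> report tables.

``run_pipeline`` drives every stage over one set of inputs and writes
CSV mirrors of the report tables plus a JSON summary and a run manifest
with per-output digests.  Two modes are exposed:

* ``mode: paper`` — replicates the published aggregation choices: cysteine
  and glutamine are excluded from the peptide-side denominators (neither
  ever formed a hydrogen bond in the panel), the non-standard N-terminal
  pyroglutamate is dropped from enzyme-side class aggregation, and the
  positional statistics weight by the bond lengths d_i.
* ``mode: default`` — includes all 20 amino acids on the peptide side;
  otherwise identical.

``report_flags`` re-derives every per-class aggregate from the per-residue
tables and flags printed summary cells that the underlying tables cannot
reproduce (the bundled reference tables contain several such cells).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import datasets, qsar, site_stats
from .peptides import SideChainClass, count_residues_by_class, load_peptide_table
from .positional import one_sample_t_test
from .site_stats import round_half_up

logger = logging.getLogger(__name__)

#: Amino acids excluded from peptide-side aggregation in paper mode.
PAPER_EXCLUSIONS = frozenset({"C", "Q"})

TABLE_FILES = (
    "in_by_residue.csv",
    "hbv_by_residue.csv",
    "class_summary.csv",
    "peptide_aa_hbv.csv",
    "positional.csv",
    "qsar_nsiv.csv",
)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path | None) -> dict:
    config: dict = {"mode": "paper", "qsar": {}}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config.update(user)
    if config["mode"] not in {"paper", "default"}:
        raise ValueError(f"mode must be 'paper' or 'default', got {config['mode']!r}")
    return config


def _read_input(config: dict, key: str, default_loader) -> pd.DataFrame:
    path = config.get("inputs", {}).get(key)
    if path is None:
        return default_loader()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file for {key!r} not found: {path}")
    return pd.read_csv(path, keep_default_na=False)


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "amypep_out",
) -> Path:
    """Run all stages and write report tables, summary and manifest.

    ``config`` may be a YAML path, a dict, or None (packaged fixtures,
    paper mode).  Returns the output directory.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    mode = config.get("mode", "paper")
    exclusions = PAPER_EXCLUSIONS if mode == "paper" else frozenset()
    weighting = config.get("positional_weighting", "length")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    peptides_path = config.get("inputs", {}).get("peptides")
    if peptides_path is not None and not Path(peptides_path).exists():
        raise FileNotFoundError(f"peptide table not found: {peptides_path}")
    peptides = (
        datasets.load_peptides()
        if peptides_path is None
        else load_peptide_table(peptides_path)
    )

    summary: dict[str, Any] = {"mode": mode, "n_peptides": len(peptides)}

    # --- enzyme side: IN and HBV per residue, class aggregation ----------
    in_table = _read_input(config, "enzyme_in", datasets.load_enzyme_in)
    hbv_table = _read_input(config, "enzyme_hbv", datasets.load_enzyme_hbv)
    in_table.to_csv(out / "in_by_residue.csv", index=False)
    hbv_table.to_csv(out / "hbv_by_residue.csv", index=False)

    class_rows = []
    summary["enzyme"] = {}
    for metric, table in (("IN", in_table), ("HBV", hbv_table)):
        stats_in = site_stats.residue_stats_from_table(table, metric)
        summaries = site_stats.summarize_by_class(stats_in, metric)
        value_col = "in_count" if metric == "IN" else "hbv"
        groups = {
            s.side_chain_class: [
                float(r[value_col])
                for _, r in table.iterrows()
                if SideChainClass.from_label(str(r["residue_type"]))
                is s.side_chain_class
            ]
            for s in summaries
        }
        letters = site_stats.significance_letters(groups)
        kw = site_stats.kruskal_wallis(groups)
        summary["enzyme"][metric] = {
            "kruskal_H": kw["H"],
            "kruskal_p": kw["p"],
            "classes": {},
        }
        for s in summaries:
            class_rows.append(
                {
                    "side": "enzyme",
                    "metric": metric,
                    "side_chain_type": s.side_chain_class.value,
                    "n_residues": s.n_residues,
                    "total": round_half_up(s.total, 2),
                    "mean": round_half_up(s.mean, 2),
                    "letters": letters[s.side_chain_class],
                }
            )
            summary["enzyme"][metric]["classes"][s.side_chain_class.value] = {
                "n": s.n_residues,
                "total": s.total,
                "mean": s.mean,
                "letters": letters[s.side_chain_class],
            }

    # --- peptide side: per-AA HBV and class aggregation ------------------
    entries = _read_input(config, "peptide_hbv", datasets.load_peptide_hbv_entries)
    aa_table = site_stats.aggregate_peptide_amino_acids(entries, peptides, exclusions)
    aa_out = aa_table.reset_index()
    for col in ("total", "mean"):
        aa_out[col] = aa_out[col].map(lambda v: round_half_up(v, 2))
    aa_out.to_csv(out / "peptide_aa_hbv.csv", index=False)

    pep_groups = site_stats.peptide_class_hbv_groups(entries, peptides, exclusions)
    pep_letters = site_stats.significance_letters(pep_groups)
    kw = site_stats.kruskal_wallis(pep_groups)
    class_counts = count_residues_by_class(peptides, exclusions)
    summary["peptide"] = {
        "exclusions": sorted(exclusions),
        "kruskal_H": kw["H"],
        "kruskal_p": kw["p"],
        "classes": {},
    }
    for cls in site_stats.CLASS_ORDER:
        if cls not in pep_groups:
            continue
        values = pep_groups[cls]
        total = float(np.sum(values))
        class_rows.append(
            {
                "side": "peptide",
                "metric": "HBV",
                "side_chain_type": cls.value,
                "n_residues": class_counts[cls],
                "total": round_half_up(total, 2),
                "mean": round_half_up(total / class_counts[cls], 2),
                "letters": pep_letters[cls],
            }
        )
        summary["peptide"]["classes"][cls.value] = {
            "n": class_counts[cls],
            "total": total,
            "mean": total / class_counts[cls],
            "letters": pep_letters[cls],
        }
    pd.DataFrame(class_rows).to_csv(out / "class_summary.csv", index=False)

    # --- positional statistics -------------------------------------------
    positional = _read_input(config, "positional", datasets.load_positional)
    positional.to_csv(out / "positional.csv", index=False)
    summary["positional"] = {
        "n_peptides": int(len(positional)),
        "mean_r_n": float(positional["r_n"].mean()),
        "mean_f": float(positional["f"].mean()),
        "weighting": weighting,
        "t_test_r_n": one_sample_t_test(positional["r_n"], mu0=0.5),
        "t_test_f": one_sample_t_test(positional["f"], mu0=0.5),
    }

    # --- QSAR: descriptors, TTPN encoding, PLSR, VIP, NSIV ----------------
    qsar_cfg = config.get("qsar", {})
    n_components = int(qsar_cfg.get("n_components", 2))
    props_path = qsar_cfg.get("property_table")
    if props_path is None:
        props, prop_classes = datasets.load_aa_properties()
    else:
        props, prop_classes = datasets.read_property_table(props_path)
    descriptors = qsar.reduce_descriptors(props, prop_classes)
    X = qsar.encode_matrix(peptides, descriptors)
    y = [p.neg_log_activity for p in peptides]
    model = qsar.fit_plsr(X, y, n_components=n_components)
    vip_values = qsar.vip(model)
    selected = qsar.select_significant(vip_values, names=list(X.columns))
    nsiv = qsar.nsiv_summaries(selected, descriptors)
    nsiv_rows = [
        {"kind": "position", "key": slot, "nsiv": count, "mean": ""}
        for slot, count in nsiv["by_position"].items()
    ] + [
        {
            "kind": "class",
            "key": cls,
            "nsiv": info["total"],
            "mean": round_half_up(info["mean"], 2),
        }
        for cls, info in nsiv["by_class"].items()
    ]
    pd.DataFrame(nsiv_rows).to_csv(out / "qsar_nsiv.csv", index=False)
    summary["qsar"] = {
        "n_components": n_components,
        "r2": model.r2,
        "n_significant": len(selected),
        "top_variables": selected[:5],
        "vip_mean_square": float(np.mean(vip_values**2)),
        "nsiv": nsiv,
    }

    summary["flags"] = report_flags(config)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    manifest = {
        "config": {k: v for k, v in config.items()},
        "row_counts": {
            "peptides": len(peptides),
            "enzyme_in": int(len(in_table)),
            "enzyme_hbv": int(len(hbv_table)),
            "peptide_hbv_entries": int(len(entries)),
            "positional": int(len(positional)),
            "qsar_variables": int(X.shape[1]),
        },
        "outputs": {
            name: _digest(out / name)
            for name in (*TABLE_FILES, "summary.json")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def report_flags(config: dict | None = None) -> list[str]:
    """Consistency warnings: printed class aggregates vs per-residue tables.

    Each flag names a summary cell that cannot be reproduced by summing the
    corresponding per-residue table.
    """
    config = config or {}
    flags: list[str] = []
    printed = datasets.load_printed_enzyme_class_summary()
    for metric, loader in (
        ("IN", datasets.load_enzyme_in),
        ("HBV", datasets.load_enzyme_hbv),
    ):
        table = _read_input(config, f"enzyme_{metric.lower()}", loader)
        stats_in = site_stats.residue_stats_from_table(table, metric)
        recomputed = {
            s.side_chain_class.value: s
            for s in site_stats.summarize_by_class(stats_in, metric)
        }
        for _, row in printed[printed["metric"] == metric].iterrows():
            cls = str(row["side_chain_type"])
            rec = recomputed.get(cls)
            if rec is None:
                flags.append(f"enzyme {metric}: class {cls} absent from table")
                continue
            for field_name, printed_val, actual in (
                ("n_residues", float(row["n_residues"]), float(rec.n_residues)),
                ("total", float(row["total"]), round_half_up(rec.total, 2)),
                ("mean", float(row["mean"]), round_half_up(rec.mean, 2)),
            ):
                if abs(printed_val - actual) > 1e-9:
                    flags.append(
                        f"enzyme {metric} {cls} {field_name}: printed "
                        f"{printed_val:g} but per-residue table gives {actual:g}"
                    )
    # peptide side: printed per-AA totals vs entry sums
    entries = _read_input(config, "peptide_hbv", datasets.load_peptide_hbv_entries)
    peptides = datasets.load_peptides()
    recomputed_aa = site_stats.aggregate_peptide_amino_acids(
        entries, peptides, PAPER_EXCLUSIONS
    )
    printed_aa = datasets.load_printed_peptide_aa_summary()
    for _, row in printed_aa.iterrows():
        aa = str(row["amino_acid"])
        if aa not in recomputed_aa.index:
            flags.append(f"peptide HBV: amino acid {aa} absent from entries")
            continue
        rec = recomputed_aa.loc[aa]
        for field_name, printed_val, actual in (
            ("count", float(row["n_occurrences"]), float(rec["n_occurrences"])),
            ("total", float(row["total"]), round_half_up(rec["total"], 2)),
            ("mean", float(row["mean"]), round_half_up(rec["mean"], 2)),
        ):
            if abs(printed_val - actual) > 1e-9:
                flags.append(
                    f"peptide HBV {aa} {field_name}: printed {printed_val:g} "
                    f"but entry sums give {actual:g}"
                )
    return flags
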