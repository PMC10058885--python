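"""Run summaries and report views (TSV tables, JSON, figures).

The JSON summary is the canonical machine-readable output of a pipeline
run: it records tool version, seed and input checksums, and every
percentage both unrounded (full float) and rounded for presentation
(2 decimals, half-up).  TSV tables and figures are views derived from it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .genotoxicity import genotox_dataframe, genotox_table
from .methylation import methylation_table
from .profiles_io import BandMatrix

__all__ = ["round_half_up", "build_summary", "write_summary", "render_figures"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.005 -> 2.01), as report tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _both(x: float) -> dict[str, float]:
    return {"value": x, "rounded": round_half_up(x)}


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_summary(
    rapd_matrix: BandMatrix,
    credra_matrix: BandMatrix | None,
    genotox_mode: str = "pooled",
    methylation_mode: str = "average",
    seed: int | None = None,
    input_paths: dict[str, str | Path] | None = None,
) -> dict:
    """Assemble the canonical JSON-ready summary of one pipeline run."""
    summary: dict = {
        "tool": "credra",
        "version": __version__,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (input_paths or {}).items()
        },
        "genotox": {"mode": genotox_mode, "rows": []},
        "methylation": {"mode": methylation_mode, "samples": {}},
    }
    results = genotox_table(rapd_matrix, aggregate=genotox_mode)
    for r in results:
        s = r.summary
        summary["genotox"]["rows"].append(
            {
                "sample_id": s.sample_id,
                "dose_mg_per_L": rapd_matrix.sample(s.sample_id).dose_mg_per_L,
                "primer": s.primer_name,
                "appeared": s.appeared,
                "disappeared": s.disappeared,
                "a": s.a,
                "n": s.n,
                "polymorphism_percent": _both(r.polymorphism_percent),
                "gts_percent": _both(r.gts_percent),
            }
        )
    if credra_matrix is not None:
        table = methylation_table(credra_matrix, mode=methylation_mode)
        for sid in table.columns:
            dose = credra_matrix.sample(sid).dose_mg_per_L
            col = {"dose_mg_per_L": dose}
            col.update({row: _both(float(v)) for row, v in table[sid].items()})
            summary["methylation"]["samples"][sid] = col
    return summary


def write_summary(summary: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write summary.json plus the gts.tsv / methylation.tsv views."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")

    rows = [
        {
            "sample_id": r["sample_id"],
            "dose_mg_per_L": r["dose_mg_per_L"],
            "primer": r["primer"],
            "a": r["a"],
            "n": r["n"],
            "polymorphism_percent": r["polymorphism_percent"]["rounded"],
            "gts_percent": r["gts_percent"]["rounded"],
        }
        for r in summary["genotox"]["rows"]
    ]
    paths["gts"] = out_dir / "gts.tsv"
    pd.DataFrame(rows).to_csv(paths["gts"], sep="\t", index=False)

    samples = summary["methylation"]["samples"]
    if samples:
        meth = pd.DataFrame(
            {
                sid: {
                    k: v["rounded"]
                    for k, v in col.items()
                    if isinstance(v, dict)
                }
                for sid, col in samples.items()
            }
        )
        paths["methylation"] = out_dir / "methylation.tsv"
        meth.to_csv(paths["methylation"], sep="\t")
    return paths


_TYPE_ROWS = [
    ("type_I_percent", "Type I (non)"),
    ("type_II_percent", "Type II (semi)"),
    ("type_III_percent", "Type III (full)"),
    ("type_IV_percent", "Type IV (full)"),
]
_RATIO_ROWS = [
    ("total_methylation_percent", "total"),
    ("full_methylation_percent", "full"),
    ("semi_methylation_percent", "semi"),
]


def render_figures(summary: dict, out_dir: str | Path) -> list[Path]:
    """Grouped bars of type percentages and a pattern-ratio chart by dose.

    Plot failures warn and continue; an empty summary produces no files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    samples = summary.get("methylation", {}).get("samples", {})
    if not samples:
        warnings.warn("summary has no methylation samples; no figures rendered")
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(samples.items(), key=lambda kv: kv[1]["dose_mg_per_L"])
    labels = [sid for sid, _ in ordered]
    written: list[Path] = []
    try:
        fig, ax = plt.subplots(figsize=(9, 4.5))
        x = np.arange(len(ordered))
        width = 0.8 / len(_TYPE_ROWS)
        for i, (key, label) in enumerate(_TYPE_ROWS):
            vals = [col[key]["value"] for _, col in ordered]
            ax.bar(x + (i - 1.5) * width, vals, width, label=label)
        ax.set_xticks(x, labels, rotation=45, ha="right")
        ax.set_ylabel("share of classifiable bands (%)")
        ax.set_title("Methylation types by Cu dose")
        ax.legend()
        fig.tight_layout()
        p = out_dir / "methylation_types.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(9, 4.5))
        for key, label in _RATIO_ROWS:
            vals = [col[key]["value"] for _, col in ordered]
            ax.plot(x, vals, marker="o", label=label)
        ax.set_xticks(x, labels, rotation=45, ha="right")
        ax.set_ylabel("pattern ratio (%)")
        ax.set_title("Methylation patterns by Cu dose")
        ax.legend()
        fig.tight_layout()
        p = out_dir / "methylation_patterns.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    except Exception as exc:  # plotting is best-effort by contract
        warnings.warn(f"figure rendering failed: {exc}")
    return written
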