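"""Combined markdown report over the pipeline's stage outputs.

Every number in the report is read back from a stage artifact (TSV/JSON);
stages that have not run yet appear as explicit placeholders.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

SECTIONS = [
    ("Peak classification", ["class_summary.json"]),
    ("GRE motif content", ["gre_report.tsv"]),
    ("Signal profiles", ["meta_profiles.tsv", "window_tests.tsv"]),
    ("TSS proximity", ["proximity_report.tsv"]),
    ("Differential expression", ["deg_summary.tsv"]),
    ("DEG-peak linkage", ["deg_linkage_summary.json"]),
]


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _table_md(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(_fmt(v) for v in row) + " |")
    return "\n".join(lines)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def build_report(outdir) -> tuple[str, list[str]]:
    """Assemble the report text; returns (markdown, missing-stage names)."""
    outdir = Path(outdir)
    parts = ["# GR peak class analysis report\n"]
    missing = []
    for title, files in SECTIONS:
        parts.append(f"\n## {title}\n")
        absent = [f for f in files if not (outdir / f).exists()]
        if absent:
            missing.append(title)
            parts.append(f"_stage missing: expected {', '.join(absent)};"
                         " run the corresponding subcommand_\n")
            continue
        for f in files:
            path = outdir / f
            if f.endswith(".json"):
                payload = json.loads(
                    "\n".join(l for l in path.read_text().splitlines()
                              if not l.startswith("#"))
                )
                parts.append("```json\n" + json.dumps(payload, indent=2) + "\n```\n")
            elif f == "meta_profiles.tsv":
                df = _read_tsv(path)
                peak = (
                    df.groupby(["factor", "condition", "gr_class"], sort=True)["mean_signal"]
                    .max().reset_index().rename(columns={"mean_signal": "profile_peak_height"})
                )
                parts.append(_table_md(peak) + "\n")
            else:
                df = _read_tsv(path)
                parts.append(_table_md(df) + "\n")
        if title == "Signal profiles" and (outdir / "meta_profiles.png").exists():
            parts.append("\n![meta-profiles](meta_profiles.png)\n")
    return "".join(parts), missing


def write_report(outdir) -> list[str]:
    outdir = Path(outdir)
    text, missing = build_report(outdir)
    (outdir / "report.md").write_text(text)
    for title in missing:
        warnings.warn(f"report: stage missing for section {title!r}", stacklevel=2)
    return missing
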