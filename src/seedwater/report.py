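"""Markdown analysis report assembled from pipeline artifacts.

Reads the CSV artifacts written by the pipeline stages (water-efficiency
table, Gpf estimates, optional growth-response fits) and renders one
human-readable document. Rendering is pure: unchanged artifacts give
byte-identical reports (no timestamps).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import ReportError
from .deficit import classify_sensitivity

__all__ = ["render_report"]

_WE_FILE = "we.csv"
_GPF_FILE = "gpf.csv"
_FITS_FILE = "fits.csv"


def render_report(artifact_dir: str | Path) -> str:
    """Render the analysis summary for a directory of pipeline artifacts.

    Requires ``we.csv`` (efficiency table) and ``gpf.csv`` (deficit fits);
    ``fits.csv`` (growth-response coefficients) is included when present.
    Missing required artifacts raise :class:`ReportError` naming them.
    """
    d = Path(artifact_dir)
    missing = [f for f in (_WE_FILE, _GPF_FILE) if not (d / f).exists()]
    if missing:
        raise ReportError(f"missing artifact(s) in {d}: {', '.join(missing)}")

    we = pd.read_csv(d / _WE_FILE)
    gpf = pd.read_csv(d / _GPF_FILE)

    lines: list[str] = []
    lines.append("# Seedling water-requirement analysis")
    lines.append("")

    lines.append("## Deficit sensitivity (growth plant factor)")
    lines.append("")
    lines.append("| species | response | Gpf | Vm | sensitivity |")
    lines.append("|---|---|---|---|---|")
    for _, r in gpf.iterrows():
        label = classify_sensitivity(float(r["gpf"]))
        lines.append(
            f"| {r['species']} | {r['response']} | {r['gpf']:.4f} "
            f"| {r['vm']:.3f} | {label} |"
        )
    lines.append("")
    gmax = float(gpf["gpf"].max())
    if gmax < 0.5:
        lines.append(
            f"All growth plant factors are below 0.5 (max {gmax:.3f}): growth "
            "loss is proportionally small relative to the water deficit applied."
        )
    else:
        lines.append(f"Maximum growth plant factor: {gmax:.3f}.")
    lines.append("")

    lines.append("## Water efficiency (growth per litre applied)")
    lines.append("")
    has_letters = "letter_h" in we.columns and we["letter_h"].notna().any()
    if has_letters:
        lines.append("| species | phase | treatment | HWE (cm/L) |  | DWE (mm/L) |  |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in we.iterrows():
            lines.append(
                f"| {r['species']} | {r['phase']} | {r['treatment']} "
                f"| {r['hwe']:.3f} | {r.get('letter_h', '')} "
                f"| {r['dwe']:.3f} | {r.get('letter_d', '')} |"
            )
    else:
        lines.append("| species | phase | treatment | HWE (cm/L) | DWE (mm/L) |")
        lines.append("|---|---|---|---|---|")
        for _, r in we.iterrows():
            lines.append(
                f"| {r['species']} | {r['phase']} | {r['treatment']} "
                f"| {r['hwe']:.3f} | {r['dwe']:.3f} |"
            )
    lines.append("")

    if (d / _FITS_FILE).exists():
        fits = pd.read_csv(d / _FITS_FILE)
        lines.append("## Growth response to applied volume")
        lines.append("")
        lines.append("| species | phase | response | kind | intercept | slope | quad | r2 |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for _, r in fits.iterrows():
            quad = "" if pd.isna(r.get("quad")) else f"{r['quad']:.4f}"
            lines.append(
                f"| {r.get('species', '')} | {r.get('phase', '')} | {r['response']} "
                f"| {r['kind']} | {r['intercept']:.3f} | {r['slope']:.4f} "
                f"| {quad} | {r['r2']:.4f} |"
            )
        lines.append("")

    return "\n".join(lines)
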