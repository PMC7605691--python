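"""Water-efficiency indicators (HWE, DWE) and multiple-comparison letters.

Water efficiency is growth per litre applied, WE = Vg / Tva, where Vg is the
final observed value of the growth variable in a phase (height, cm, giving
HWE in cm/L; or diameter, mm, giving DWE in mm/L) and Tva the cumulative
volume applied to the plant over that phase. Vg is the final value, not
final-minus-initial: back-computing published WE x volume reproduces the
published final sizes, which identifies the convention used.

For replicate-level data the module attaches compact-letter-display group
letters from Tukey's HSD at a chosen significance level, after a Bartlett
homogeneity check on the groups (a rejection warns but does not stop the
analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import AggregationError, DomainError, FitError, PhaseDataset

__all__ = [
    "EfficiencyRecord",
    "GroupComparison",
    "compute_we",
    "volume_fraction",
    "efficiency_table",
    "tukey_letters",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class EfficiencyRecord:
    """HWE/DWE for one species x phase x treatment cell."""

    species: str
    phase: str
    treatment: str
    hwe: float                   # cm per L
    dwe: float                   # mm per L
    letter_h: str | None = None  # Tukey group letters (replicate data only)
    letter_d: str | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Bartlett statistic plus Tukey-HSD compact letter display for labelled groups."""

    groups: dict[str, tuple[float, ...]]
    statistic: float
    p_bartlett: float
    letters: dict[str, str]
    alpha: float


def compute_we(vg: float, tva: float) -> float:
    """Water efficiency WE = Vg / Tva (growth units per litre)."""
    if tva <= 0:
        raise DomainError(f"total applied volume must be > 0, got {tva}")
    if vg < 0:
        raise DomainError(f"growth value must be >= 0, got {vg}")
    return vg / tva


def volume_fraction(partial_volume: float, total_volume: float) -> float:
    """Percent of a phase's total applied volume delivered in a sub-period."""
    if total_volume <= 0:
        raise DomainError(f"total volume must be > 0, got {total_volume}")
    if partial_volume < 0:
        raise DomainError(f"partial volume must be >= 0, got {partial_volume}")
    return 100.0 * partial_volume / total_volume


def efficiency_table(
    ds: PhaseDataset,
    phase: str | None = None,
    letters: bool = False,
    alpha: float = 0.05,
) -> list[EfficiencyRecord]:
    """One :class:`EfficiencyRecord` per species x phase x treatment cell.

    Vg is the replicate-mean final size of the cell; Tva the cell's total
    applied volume. Records are ordered species then treatment within each
    phase. With ``letters=True`` and >= 2 replicates per treatment, Tukey
    group letters (per species x phase, across treatments) are attached to
    both indicators; with treatment means only, letters stay ``None``.
    """
    phases = [phase] if phase is not None else ["tube", "pot"]
    records: list[EfficiencyRecord] = []
    for ph in phases:
        final = ds.final_sizes(ph)
        letter_maps = _phase_letters(ds, final, ph, alpha) if letters else {}
        for sp, g in final.groupby("species", sort=True):
            lh, ld = letter_maps.get(str(sp), ({}, {}))
            for _, row in g.sort_values("treatment").iterrows():
                trt = str(row["treatment"])
                records.append(EfficiencyRecord(
                    species=str(sp), phase=ph, treatment=trt,
                    hwe=compute_we(row["height_cm"], row["total_volume_l"]),
                    dwe=compute_we(row["diameter_mm"], row["total_volume_l"]),
                    letter_h=lh.get(trt), letter_d=ld.get(trt),
                ))
    return records


def _phase_letters(ds: PhaseDataset, final: pd.DataFrame, phase: str, alpha: float):
    """Per-species Tukey letters on replicate-level WE, when replicates exist."""
    df = ds.to_frame()
    df = df[df["phase"] == phase]
    out: dict[str, tuple[dict[str, str], dict[str, str]]] = {}
    for sp, g in df.groupby("species", sort=True):
        if final[final["species"] == sp]["n_replicates"].min() < 2:
            continue
        groups_h: dict[str, list[float]] = {}
        groups_d: dict[str, list[float]] = {}
        for trt, gg in g.groupby("treatment"):
            last = gg[gg["day"] == gg["day"].max()]
            spec = ds.treatments.get((str(sp), phase, str(trt)))
            if spec is None:
                raise AggregationError(
                    f"no treatment specification for cell ({sp}, {phase}, {trt})"
                )
            groups_h[str(trt)] = [compute_we(v, spec.total_volume)
                                  for v in last["height_cm"]]
            groups_d[str(trt)] = [compute_we(v, spec.total_volume)
                                  for v in last["diameter_mm"]]
        out[str(sp)] = (
            tukey_letters(groups_h, alpha=alpha).letters,
            tukey_letters(groups_d, alpha=alpha).letters,
        )
    return out


def tukey_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Tukey HSD over all group pairs plus a compact letter display.

    Letters are built by insert-and-absorb: all groups start in one class,
    every significantly different pair splits the classes containing both,
    and subset classes are absorbed. Classes are lettered 'a', 'b', ... in
    descending order of their largest group mean, so groups sharing any
    letter are pairwise non-significant at ``alpha`` and the display is
    invariant to group input order.

    A Bartlett variance-homogeneity check runs first; a rejection at
    ``alpha`` emits a warning but the letters are still computed.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    if len(groups) < 2:
        raise FitError("at least 2 groups are required")
    clean = {str(k): np.asarray(v, dtype=float) for k, v in sorted(groups.items())}
    for label, arr in clean.items():
        if arr.size < 2:
            raise FitError(f"group {label!r} needs >= 2 replicates, got {arr.size}")

    labels = list(clean)
    means = {lb: float(arr.mean()) for lb, arr in clean.items()}
    pooled_var = float(np.mean([arr.var(ddof=1) for arr in clean.values()]))

    if pooled_var == 0.0:
        # no within-group noise: equal means are trivially one class,
        # unequal means leave the studentized range undefined
        if len(set(means.values())) > 1:
            raise FitError(
                "zero within-group variance with unequal means: "
                "Tukey comparison is degenerate"
            )
        stat, p_bart = 0.0, 1.0
        significant: set[frozenset[str]] = set()
    else:
        stat, p_bart = stats.bartlett(*clean.values())
        if p_bart < alpha:
            warnings.warn(
                f"Bartlett homogeneity test rejects at alpha={alpha} "
                f"(p={p_bart:.3g}); Tukey letters computed anyway",
                UserWarning, stacklevel=2,
            )
        endog = np.concatenate(list(clean.values()))
        lab = np.concatenate([[lb] * clean[lb].size for lb in labels])
        res = pairwise_tukeyhsd(endog, lab, alpha=alpha)
        # statsmodels enumerates pairs (i, j), i < j, over sorted unique
        # labels — the same order `labels` was built in
        pairs = [(labels[i], labels[j])
                 for i in range(len(labels)) for j in range(i + 1, len(labels))]
        significant = {
            frozenset(pair) for pair, rej in zip(pairs, res.reject) if bool(rej)
        }

    letters = _compact_letter_display(labels, means, significant)
    return GroupComparison(
        groups={lb: tuple(arr) for lb, arr in clean.items()},
        statistic=float(stat), p_bartlett=float(p_bart),
        letters=letters, alpha=alpha,
    )


def _compact_letter_display(
    labels: Sequence[str],
    means: Mapping[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Guarantees: a significant pair never shares a letter; a non-significant
    pair always shares at least one; every group gets >= 1 letter.
    """
    classes: list[set[str]] = [set(labels)]
    for pair in significant:
        g1, g2 = tuple(pair)
        new_classes: list[set[str]] = []
        for cls in classes:
            if g1 in cls and g2 in cls:
                new_classes.append(cls - {g1})
                new_classes.append(cls - {g2})
            else:
                new_classes.append(cls)
        # absorb: drop empty classes, duplicates, and subsets of another class
        kept: list[set[str]] = []
        for cls in new_classes:
            if not cls or any(cls <= other for other in kept):
                continue
            kept = [other for other in kept if not other < cls]
            kept.append(cls)
        classes = kept
    # letter classes in descending order of their best (largest-mean) member
    classes.sort(key=lambda c: -max(means[g] for g in c))
    out: dict[str, str] = {lb: "" for lb in labels}
    for letter, cls in zip(_LETTERS, classes):
        for g in cls:
            out[g] += letter
    return {lb: "".join(sorted(s)) for lb, s in out.items()}
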