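"""Domain types, dataset validation, CSV I/O and the reconstructed reference dataset.

The package analyses two-phase seedling irrigation experiments: phase 1
("tube", 280 cm^3 plastic tubes) applies four water-replacement levels
V1..V4 (~40%..100% of the species water requirement) via drip emitters of
different flow rates; phase 2 ("pot", 18 dm^3 pots) applies a uniform full
water replacement. Growth is tracked as plant height (cm) and collar
diameter (mm), water as cumulative applied volume (L per plant).

The reference dataset shipped here (:func:`build_inpaper_fixture`) is the
published treatment-mean experiment for *Schizolobium parahyba*,
*Cytharexylum myrianthum* and *Ceiba speciosa*, reconstructed by inverting
the water-efficiency definition WE = Vg / Tva: final size = WE x total
applied volume, using the published per-cell WE values and per-treatment
volumes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "LEVELS",
    "PHASES",
    "SPECIES",
    "PRINTED_FINAL_TUBE_V4",
    "SeedwaterError",
    "SchemaError",
    "DomainError",
    "FitError",
    "ConvergenceError",
    "AggregationError",
    "ReportError",
    "Finding",
    "SpeciesInfo",
    "TreatmentSpec",
    "GrowthObservation",
    "PhaseDataset",
    "read_observations",
    "read_treatments",
    "write_observations",
    "write_treatments",
    "build_inpaper_fixture",
    "validate_dataset",
]

LEVELS = ("V1", "V2", "V3", "V4")
PHASES = ("tube", "pot")

OBS_COLUMNS = ("species", "phase", "treatment", "replicate", "day",
               "height_cm", "diameter_mm")
TRT_COLUMNS = ("species", "phase", "level", "emitter_flow_lph", "total_volume_l")


class SeedwaterError(Exception):
    """Base class for package errors."""


class SchemaError(SeedwaterError):
    """An input table is missing or misnames a required column."""


class DomainError(SeedwaterError, ValueError):
    """An argument is outside the physically meaningful domain."""


class FitError(SeedwaterError):
    """A regression or estimation problem is degenerate or under-determined."""


class ConvergenceError(FitError):
    """An iterative estimator failed to bracket or reach its solution."""


class AggregationError(SeedwaterError):
    """A dataset cell required for aggregation is missing."""


class ReportError(SeedwaterError):
    """A report input artifact is missing or unreadable."""


@dataclass(frozen=True)
class Finding:
    """One validation finding: what rule failed and where."""

    kind: str
    message: str
    location: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.kind}: {self.message}{loc}"


@dataclass(frozen=True)
class SpeciesInfo:
    """A studied species with its per-phase total applied volumes.

    ``phase1_total_volumes`` holds the four cumulative volumes (L per plant)
    delivered to treatments V1..V4 over the tube phase; ``phase2_total_volume``
    is the single uniform pot-phase volume.
    """

    code: str
    name: str
    phase1_total_volumes: tuple[float, float, float, float]
    phase2_total_volume: float

    def __post_init__(self) -> None:
        if len(self.phase1_total_volumes) != 4:
            raise DomainError("exactly 4 phase-1 volumes (V1..V4) required")
        vols = self.phase1_total_volumes
        if any(v <= 0 for v in vols) or self.phase2_total_volume <= 0:
            raise DomainError(f"{self.code}: volumes must be > 0")
        if not all(a < b for a, b in zip(vols, vols[1:])):
            raise DomainError(
                f"{self.code}: phase-1 volumes must be strictly increasing V1<V2<V3<V4"
            )


@dataclass(frozen=True)
class TreatmentSpec:
    """One irrigation level: emitter flow rate (L/h) and cumulative volume (L/plant)."""

    level: str
    emitter_flow: float
    total_volume: float

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DomainError(f"treatment level must be one of {LEVELS}, got {self.level!r}")
        if self.emitter_flow <= 0:
            raise DomainError(f"{self.level}: emitter_flow must be > 0")
        if self.total_volume <= 0:
            raise DomainError(f"{self.level}: total_volume must be > 0")


@dataclass(frozen=True)
class GrowthObservation:
    """One measurement of one plant at one date.

    ``day`` counts days after emergence; ``height`` is collar-to-apical-bud
    distance in cm, ``diameter`` the collar diameter in mm.
    """

    species: str
    phase: str
    treatment: str
    replicate: int
    day: int
    height: float
    diameter: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise DomainError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.treatment not in LEVELS:
            raise DomainError(f"treatment must be one of {LEVELS}, got {self.treatment!r}")
        if self.height < 0:
            raise DomainError(f"height must be >= 0, got {self.height}")
        if self.diameter < 0:
            raise DomainError(f"diameter must be >= 0, got {self.diameter}")
        if self.day < 0:
            raise DomainError(f"day must be >= 0, got {self.day}")

    @property
    def key(self) -> tuple[str, str, str, int, int]:
        return (self.species, self.phase, self.treatment, self.replicate, self.day)


@dataclass
class PhaseDataset:
    """A collection of growth observations plus the treatment specifications.

    ``treatments`` maps ``(species, phase, level)`` to a :class:`TreatmentSpec`
    so one dataset can carry both experimental phases. ``provenance`` records
    where the data came from: ``"fixture"`` (reconstructed published means),
    ``"simulated"`` (irrigation simulator) or ``"user"``.
    """

    observations: list[GrowthObservation]
    treatments: dict[tuple[str, str, str], TreatmentSpec] = field(default_factory=dict)
    provenance: str = "user"

    def __post_init__(self) -> None:
        if not self.observations:
            raise DomainError("dataset must contain at least one observation")

    # -- convenience accessors -------------------------------------------------

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for o in self.observations:
            seen.setdefault(o.species, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": o.species, "phase": o.phase, "treatment": o.treatment,
                    "replicate": o.replicate, "day": o.day,
                    "height_cm": o.height, "diameter_mm": o.diameter,
                }
                for o in self.observations
            ],
            columns=list(OBS_COLUMNS),
        )

    def treatments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": sp, "phase": ph, "level": t.level,
                    "emitter_flow_lph": t.emitter_flow, "total_volume_l": t.total_volume,
                }
                for (sp, ph, _lv), t in sorted(self.treatments.items())
            ],
            columns=list(TRT_COLUMNS),
        )

    def final_sizes(self, phase: str) -> pd.DataFrame:
        """Treatment-level final sizes for one phase.

        For each (species, treatment) cell, takes the observations at the
        latest measured day and averages over replicates, attaching the
        cell's total applied volume. Raises :class:`AggregationError` if a
        cell has no treatment specification.
        """
        df = self.to_frame()
        df = df[df["phase"] == phase]
        if df.empty:
            raise AggregationError(f"no observations in phase {phase!r}")
        rows = []
        for (sp, trt), g in df.groupby(["species", "treatment"], sort=True):
            last = g[g["day"] == g["day"].max()]
            spec = self.treatments.get((sp, phase, trt))
            if spec is None:
                raise AggregationError(
                    f"no treatment specification for cell ({sp}, {phase}, {trt})"
                )
            rows.append({
                "species": sp, "treatment": trt,
                "height_cm": float(last["height_cm"].mean()),
                "diameter_mm": float(last["diameter_mm"].mean()),
                "total_volume_l": spec.total_volume,
                "n_replicates": int(last.shape[0]),
            })
        return pd.DataFrame(rows)

    def digest(self) -> str:
        """SHA-256 over the canonical CSV rendering (order-sensitive)."""
        h = hashlib.sha256()
        h.update(self.to_frame().to_csv(index=False).encode())
        h.update(self.treatments_frame().to_csv(index=False).encode())
        return h.hexdigest()


# -----------------------------------------------------------------------------
# CSV input / output
# -----------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_observations(
    path: str | Path,
    treatments: str | Path | Mapping[tuple[str, str, str], TreatmentSpec] | None = None,
    schema: Mapping[str, str] | None = None,
) -> PhaseDataset:
    """Read a growth-observation CSV into a validated :class:`PhaseDataset`.

    Parameters
    ----------
    path
        Comma-separated file with header row; required columns are
        ``species,phase,treatment,replicate,day,height_cm,diameter_mm``
        (rename via ``schema``, a mapping from file column to canonical name).
    treatments
        Either a treatments CSV (``species,phase,level,emitter_flow_lph,
        total_volume_l``), a ready mapping, or None (a sibling
        ``treatments.csv`` is picked up when present).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    _require_columns(df, OBS_COLUMNS, path)

    obs: list[GrowthObservation] = []
    for idx, row in df.iterrows():
        try:
            obs.append(GrowthObservation(
                species=str(row["species"]), phase=str(row["phase"]),
                treatment=str(row["treatment"]), replicate=int(row["replicate"]),
                day=int(row["day"]), height=float(row["height_cm"]),
                diameter=float(row["diameter_mm"]),
            ))
        except (DomainError, ValueError) as exc:
            raise DomainError(f"{path} row {idx}: {exc}") from exc

    trt_map: dict[tuple[str, str, str], TreatmentSpec] = {}
    if treatments is None:
        sibling = path.with_name("treatments.csv")
        if sibling.exists():
            trt_map = read_treatments(sibling)
    elif isinstance(treatments, (str, Path)):
        trt_map = read_treatments(treatments)
    else:
        trt_map = dict(treatments)
    return PhaseDataset(observations=obs, treatments=trt_map, provenance="user")


def read_treatments(path: str | Path) -> dict[tuple[str, str, str], TreatmentSpec]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"treatments file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRT_COLUMNS, path)
    out: dict[tuple[str, str, str], TreatmentSpec] = {}
    for idx, row in df.iterrows():
        try:
            spec = TreatmentSpec(
                level=str(row["level"]),
                emitter_flow=float(row["emitter_flow_lph"]),
                total_volume=float(row["total_volume_l"]),
            )
        except DomainError as exc:
            raise DomainError(f"{path} row {idx}: {exc}") from exc
        out[(str(row["species"]), str(row["phase"]), spec.level)] = spec
    return out


def write_observations(ds: PhaseDataset, path: str | Path) -> None:
    # %.17g keeps write-then-read the exact identity on float64 values
    ds.to_frame().to_csv(Path(path), index=False, float_format="%.17g")


def write_treatments(ds: PhaseDataset, path: str | Path) -> None:
    ds.treatments_frame().to_csv(Path(path), index=False, float_format="%.17g")


# -----------------------------------------------------------------------------
# Reconstructed published experiment
# -----------------------------------------------------------------------------

# Cumulative applied volumes (L per plant), tube phase, V1..V4.
_TUBE_VOLUMES = {
    "S_parahyba": (0.91, 1.49, 1.74, 2.40),
    "C_myrianthum": (0.46, 0.62, 0.95, 1.08),
    "C_speciosa": (0.33, 0.52, 0.66, 0.85),
}
# Uniform pot-phase volume (L per plant) applied to every treatment-legacy group.
_POT_VOLUMES = {"S_parahyba": 70.0, "C_myrianthum": 50.3, "C_speciosa": 52.7}

# Mean emitter flow rates (L/h), tube phase, V1..V4.
_EMITTER_FLOWS = {
    "S_parahyba": (1.2, 1.8, 2.1, 2.9),
    "C_myrianthum": (1.1, 1.5, 2.3, 2.6),
    "C_speciosa": (0.7, 1.1, 1.4, 1.8),
}
_POT_EMITTER_FLOW = 2.0  # one pressure-compensated dripper per pot, L/h

# Published water-efficiency indicators per species, V1..V4:
# (HWE tube, HWE pot) in cm/L, (DWE tube, DWE pot) in mm/L.
# The C. speciosa tube-DWE V1 cell is printed with a decimal-comma typo
# ("17,002"); it is read as 17.002, continuing the monotone column.
_WE_TABLE = {
    "S_parahyba": {
        ("height", "tube"): (35.018, 22.013, 21.475, 17.694),
        ("height", "pot"): (1.072, 0.986, 0.993, 1.267),
        ("diameter", "tube"): (7.582, 5.196, 4.676, 3.510),
        ("diameter", "pot"): (0.296, 0.297, 0.283, 0.298),
    },
    "C_myrianthum": {
        ("height", "tube"): (52.676, 39.343, 26.877, 25.401),
        ("height", "pot"): (1.760, 2.010, 1.909, 1.841),
        ("diameter", "tube"): (8.074, 6.431, 4.808, 4.345),
        ("diameter", "pot"): (0.257, 0.300, 0.318, 0.277),
    },
    "C_speciosa": {
        ("height", "tube"): (80.653, 60.513, 52.930, 44.039),
        ("height", "pot"): (2.055, 2.052, 2.098, 2.305),
        ("diameter", "tube"): (17.002, 11.809, 9.433, 8.138),
        ("diameter", "pot"): (0.469, 0.477, 0.482, 0.510),
    },
}

#: Published final tube-phase sizes at full replacement (V4): (height cm, diameter mm).
PRINTED_FINAL_TUBE_V4 = {
    "S_parahyba": (42.5, 8.4),
    "C_speciosa": (37.4, 6.9),
    "C_myrianthum": (27.4, 4.7),
}

_TUBE_FINAL_DAY = 80   # tube phase ends 80 days after emergence
_POT_FINAL_DAY = 230   # pot phase ends 230 days after emergence

SPECIES = (
    SpeciesInfo("S_parahyba", "S. parahyba", _TUBE_VOLUMES["S_parahyba"], 70.0),
    SpeciesInfo("C_myrianthum", "C. myrianthum", _TUBE_VOLUMES["C_myrianthum"], 50.3),
    SpeciesInfo("C_speciosa", "C. speciosa", _TUBE_VOLUMES["C_speciosa"], 52.7),
)


def build_inpaper_fixture() -> PhaseDataset:
    """Reconstruct the published treatment-mean dataset.

    Returns one observation per species x phase x treatment cell
    (3 x 2 x 4 = 24 records), with final height and diameter recovered as
    WE x total applied volume, i.e. by inverting WE = Vg / Tva. The values
    are treatment means (replicate index 1): the per-replicate raw data was
    never published, so replicate-level analyses (Tukey letters) are
    exercised on simulated data instead.
    """
    obs: list[GrowthObservation] = []
    treatments: dict[tuple[str, str, str], TreatmentSpec] = {}
    for info in SPECIES:
        sp = info.code
        for phase in PHASES:
            day = _TUBE_FINAL_DAY if phase == "tube" else _POT_FINAL_DAY
            for i, level in enumerate(LEVELS):
                if phase == "tube":
                    tva = _TUBE_VOLUMES[sp][i]
                    flow = _EMITTER_FLOWS[sp][i]
                else:
                    tva = _POT_VOLUMES[sp]
                    flow = _POT_EMITTER_FLOW
                hwe = _WE_TABLE[sp][("height", phase)][i]
                dwe = _WE_TABLE[sp][("diameter", phase)][i]
                obs.append(GrowthObservation(
                    species=sp, phase=phase, treatment=level, replicate=1,
                    day=day, height=hwe * tva, diameter=dwe * tva,
                ))
                treatments[(sp, phase, level)] = TreatmentSpec(
                    level=level, emitter_flow=flow, total_volume=tva,
                )
    return PhaseDataset(observations=obs, treatments=treatments, provenance="fixture")


# -----------------------------------------------------------------------------
# Validation
# -----------------------------------------------------------------------------

def validate_dataset(ds: PhaseDataset) -> list[Finding]:
    """Check dataset-level invariants, returning one finding per violation.

    Checks: non-negative sizes, key uniqueness, presence of a treatment
    specification for every observation, and strictly increasing V1<..<V4
    cumulative volumes within each species x phase. Returns an empty list
    iff all invariants hold; findings are reports, not exceptions.
    """
    findings: list[Finding] = []
    seen: set[tuple[str, str, str, int, int]] = set()
    for i, o in enumerate(ds.observations):
        loc = f"observation {i} {o.key}"
        if o.height < 0:
            findings.append(Finding("negative_size", f"height {o.height} < 0", loc))
        if o.diameter < 0:
            findings.append(Finding("negative_size", f"diameter {o.diameter} < 0", loc))
        if o.key in seen:
            findings.append(Finding(
                "duplicate_key",
                "duplicated (species, phase, treatment, replicate, day)", loc,
            ))
        seen.add(o.key)
        if ds.treatments and (o.species, o.phase, o.treatment) not in ds.treatments:
            findings.append(Finding(
                "missing_treatment",
                f"no TreatmentSpec for ({o.species}, {o.phase}, {o.treatment})", loc,
            ))

    by_cell: dict[tuple[str, str], dict[str, float]] = {}
    for (sp, ph, lv), spec in ds.treatments.items():
        by_cell.setdefault((sp, ph), {})[lv] = spec.total_volume
    for (sp, ph), vols in sorted(by_cell.items()):
        if ph != "tube":
            continue  # pot volumes are uniform across treatment-legacy groups
        ordered = [vols[lv] for lv in LEVELS if lv in vols]
        if any(a >= b for a, b in zip(ordered, ordered[1:])):
            findings.append(Finding(
                "volume_monotonicity",
                "tube-phase volumes are not strictly increasing V1<V2<V3<V4",
                f"({sp}, {ph})",
            ))
    return findings
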