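"""Domain types and file IO for titration-based kinetic runs.

A kinetic run is a time series of thiosulfate titres (or oxidant
concentrations) sampled from a reaction mixture whose composition is recorded
in :class:`ReactionConditions`. Runs travel on disk as a long-format CSV
(one sample per row) plus a YAML manifest that supplies per-run conditions;
analysis results travel as a JSON report with a plain-text summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ReportError, SchemaError, UnitError, ValidationError
from .units import celsius_to_kelvin, titre_to_concentration

__all__ = [
    "VALUE_UNITS",
    "DESIGN_LABELS",
    "ReactionConditions",
    "TitrationTimeSeries",
    "KineticDataset",
    "AnalysisReport",
    "load_runs",
    "write_runs",
    "write_report",
    "read_report",
]

#: accepted tags for the ``value`` column of the long-format CSV
VALUE_UNITS = ("cm3_titre", "mol_per_dm3")

DESIGN_LABELS = (
    "cat_grid",
    "pcm_grid",
    "os_grid",
    "oh_grid",
    "temp_grid",
    "stoichiometry",
    "custom",
)

#: ratio [PCM]0/[CAT]0 above which a run counts as pseudo-first-order
PSEUDO_FIRST_ORDER_EXCESS = 10.0

CSV_COLUMNS = ("run_id", "replicate_id", "time_s", "value", "value_unit")

_CONDITION_FIELDS = ("cat0", "pcm0", "os_total", "oh", "ionic_strength", "temperature")


@dataclass(frozen=True)
class ReactionConditions:
    """Composition and temperature of one kinetic run.

    All concentrations are mol dm^-3; ``temperature`` is kelvin.

    cat0
        initial chloramine-T (oxidant) concentration
    pcm0
        initial paracetamol (substrate) concentration
    os_total
        gross osmium(VIII) catalyst concentration
    oh
        hydroxide concentration (treated as buffered during a run)
    ionic_strength
        ionic strength set with NaNO3; the rate law does not depend on it
    """

    cat0: float
    pcm0: float
    os_total: float
    oh: float
    ionic_strength: float = 0.0
    temperature: float = 308.15

    def __post_init__(self) -> None:
        for name in ("cat0", "pcm0", "os_total", "oh", "ionic_strength"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature!r}")

    @property
    def is_pseudo_first_order(self) -> bool:
        """True when the substrate is in at least ten-fold excess over the oxidant."""
        return self.pcm0 >= PSEUDO_FIRST_ORDER_EXCESS * self.cat0

    @classmethod
    def from_celsius(cls, *, temperature_c: float, **kwargs: float) -> "ReactionConditions":
        return cls(temperature=celsius_to_kelvin(temperature_c), **kwargs)

    def replace(self, **changes: float) -> "ReactionConditions":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _CONDITION_FIELDS}


@dataclass
class TitrationTimeSeries:
    """One kinetic run: sampling times and titres (or concentrations).

    ``values`` carries either thiosulfate titres in cm^3 (``value_unit ==
    "cm3_titre"``) or oxidant concentrations in mol dm^-3
    (``"mol_per_dm3"``). ``concentrations()`` resolves the unit tag.
    """

    run_id: str
    replicate_id: int
    times: np.ndarray
    values: np.ndarray
    value_unit: str
    conditions: ReactionConditions
    aliquot_volume: float = 10.0
    thio_normality: float = 0.01

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError(f"run {self.run_id!r}: times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValidationError(
                f"run {self.run_id!r}: {self.times.size} times but {self.values.size} values"
            )
        if self.times.size == 0:
            raise ValidationError(f"run {self.run_id!r}: empty time series")
        if self.times[0] < 0:
            raise ValidationError(f"run {self.run_id!r}: times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"run {self.run_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError(f"run {self.run_id!r}: values must be finite and non-negative")
        if self.value_unit not in VALUE_UNITS:
            raise UnitError(
                f"run {self.run_id!r}: unknown unit tag {self.value_unit!r}; "
                f"expected one of {VALUE_UNITS}"
            )
        if self.aliquot_volume <= 0:
            raise ValidationError(f"run {self.run_id!r}: aliquot_volume must be positive")
        if self.values.size > 1 and self.values[-1] > self.values[0]:
            # decaying oxidant should trend downward; only warn, noise may wiggle
            warnings.warn(
                f"run {self.run_id!r}: values increase from first to last sample; "
                "expected a decaying oxidant",
                stacklevel=2,
            )

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def concentrations(self) -> np.ndarray:
        """Oxidant concentration (mol dm^-3) at every sampling time."""
        if self.value_unit == "mol_per_dm3":
            return self.values.copy()
        return titre_to_concentration(self.values, self.thio_normality, self.aliquot_volume)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": self.run_id,
                "replicate_id": self.replicate_id,
                "time_s": self.times,
                "value": self.values,
                "value_unit": self.value_unit,
            }
        )


@dataclass
class KineticDataset:
    """A collection of runs sharing an experimental-design label."""

    runs: list[TitrationTimeSeries]
    design_label: str = "custom"

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValidationError("a KineticDataset must contain at least one run")
        if self.design_label not in DESIGN_LABELS:
            raise ValidationError(
                f"unknown design_label {self.design_label!r}; expected one of {DESIGN_LABELS}"
            )

    def __iter__(self) -> Iterator[TitrationTimeSeries]:
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)

    def replicate_groups(self) -> dict[str, list[TitrationTimeSeries]]:
        """Runs grouped by run_id (replicates share a run_id)."""
        groups: dict[str, list[TitrationTimeSeries]] = {}
        for run in self.runs:
            groups.setdefault(run.run_id, []).append(run)
        return groups


# ---------------------------------------------------------------------------
# CSV + manifest round trip
# ---------------------------------------------------------------------------

def write_runs(dataset: KineticDataset, csv_path: str | Path, manifest_path: str | Path) -> None:
    """Write a dataset as long-format CSV plus a YAML conditions manifest."""
    csv_path, manifest_path = Path(csv_path), Path(manifest_path)
    frame = pd.concat([run.to_frame() for run in dataset.runs], ignore_index=True)
    # %.17g round-trips doubles exactly through the text format
    frame.to_csv(csv_path, index=False, float_format="%.17g")

    manifest: dict[str, Any] = {"design_label": dataset.design_label, "runs": {}}
    for run in dataset.runs:
        entry = manifest["runs"].setdefault(
            run.run_id,
            {
                "conditions": run.conditions.to_dict(),
                "aliquot_volume": float(run.aliquot_volume),
                "thio_normality": float(run.thio_normality),
            },
        )
        if entry["conditions"] != run.conditions.to_dict():
            raise ValidationError(
                f"replicates of run {run.run_id!r} carry different conditions"
            )
    with open(manifest_path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)


def load_runs(csv_path: str | Path, manifest_path: str | Path) -> KineticDataset:
    """Read a long-format CSV and its YAML manifest into a validated dataset.

    Rows are sorted by time within each (run_id, replicate_id); schema
    violations raise :class:`SchemaError` naming the offending column or run.
    """
    csv_path, manifest_path = Path(csv_path), Path(manifest_path)
    if not csv_path.exists():
        raise SchemaError(f"data file not found: {csv_path}")
    if not manifest_path.exists():
        raise SchemaError(f"manifest file not found: {manifest_path}")

    frame = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [column for column in CSV_COLUMNS if column not in frame.columns]
    if missing:
        raise SchemaError(f"data file {csv_path} is missing column(s): {', '.join(missing)}")

    with open(manifest_path, encoding="utf-8") as handle:
        manifest = yaml.safe_load(handle)
    if not isinstance(manifest, dict) or "runs" not in manifest:
        raise SchemaError(f"manifest {manifest_path} must map run_id -> conditions under 'runs'")
    design_label = manifest.get("design_label", "custom")

    runs: list[TitrationTimeSeries] = []
    for (run_id, replicate_id), group in frame.groupby(["run_id", "replicate_id"], sort=True):
        run_id = str(run_id)
        entry = manifest["runs"].get(run_id)
        if entry is None:
            raise SchemaError(f"manifest does not supply conditions for run {run_id!r}")
        units = group["value_unit"].unique()
        if len(units) != 1:
            raise UnitError(f"run {run_id!r} mixes unit tags {sorted(units)}")
        unit = str(units[0])
        if unit not in VALUE_UNITS:
            raise UnitError(f"run {run_id!r}: unknown unit tag {unit!r}")
        group = group.sort_values("time_s")
        times = group["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"run {run_id!r}: non-monotone or duplicated times")
        runs.append(
            TitrationTimeSeries(
                run_id=run_id,
                replicate_id=int(replicate_id),
                times=times,
                values=group["value"].to_numpy(dtype=float),
                value_unit=unit,
                conditions=ReactionConditions(**entry["conditions"]),
                aliquot_volume=float(entry.get("aliquot_volume", 10.0)),
                thio_normality=float(entry.get("thio_normality", 0.01)),
            )
        )
    return KineticDataset(runs=runs, design_label=design_label)


# ---------------------------------------------------------------------------
# Analysis report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Container for everything the pipeline derives from a dataset.

    Every constant is stored in a dict that carries its value, units and the
    conditions it was derived under; ``provenance`` records the seed, package
    version and input digests so a report is reproducible.
    """

    rate_fits: list[dict[str, Any]] = field(default_factory=list)
    derived_constants: dict[str, Any] = field(default_factory=dict)
    mechanism: dict[str, Any] = field(default_factory=dict)
    activation: dict[str, Any] = field(default_factory=dict)
    stoichiometry: dict[str, Any] = field(default_factory=dict)
    reproducibility: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not any(
            (
                self.rate_fits,
                self.derived_constants,
                self.mechanism,
                self.activation,
                self.stoichiometry,
                self.reproducibility,
            )
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "rate_fits": self.rate_fits,
            "derived_constants": self.derived_constants,
            "mechanism": self.mechanism,
            "activation": self.activation,
            "stoichiometry": self.stoichiometry,
            "reproducibility": self.reproducibility,
            "provenance": self.provenance,
        }


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def _summary_lines(report: dict[str, Any]) -> Iterable[str]:
    yield "pcmkin analysis summary"
    yield "======================="
    if report.get("rate_fits"):
        yield f"rate fits: {len(report['rate_fits'])} runs"
    for section in ("derived_constants", "mechanism", "activation", "stoichiometry",
                    "reproducibility"):
        body = report.get(section)
        if body:
            yield f"[{section}]"
            for key, value in body.items():
                yield f"  {key}: {value}"
    prov = report.get("provenance") or {}
    if prov:
        yield "[provenance]"
        for key, value in prov.items():
            yield f"  {key}: {value}"


def write_report(report: AnalysisReport, outdir: str | Path) -> Path:
    """Write ``report.json`` (machine readable, lossless floats) and
    ``summary.txt`` into ``outdir``; returns the JSON path."""
    if report.is_empty:
        raise ReportError("refusing to write an empty report (nothing to report)")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        payload = report.to_dict()
        json_path = outdir / "report.json"
        with open(json_path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, default=_json_default)
        with open(outdir / "summary.txt", "w", encoding="utf-8") as handle:
            handle.write("\n".join(_summary_lines(payload)) + "\n")
    except OSError as exc:  # unwritable path
        raise ReportError(f"cannot write report under {outdir}: {exc}") from exc
    return json_path


def read_report(path: str | Path) -> dict[str, Any]:
    """Reload a machine-readable report; numeric fields round-trip exactly
    (JSON floats are written with full repr precision)."""
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    with open(path, encoding="utf-8") as handle:
        return json.load(handle)


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of an input file, for report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def conditions_vary(runs: Sequence[TitrationTimeSeries], *, ignore: Sequence[str] = ()) -> list[str]:
    """Names of condition fields that are not constant across ``runs``."""
    varying = []
    for name in _CONDITION_FIELDS:
        if name in ignore:
            continue
        values = np.array([getattr(run.conditions, name) for run in runs])
        if not np.allclose(values, values[0], rtol=1e-12, atol=0.0):
            varying.append(name)
    return varying
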