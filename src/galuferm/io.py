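"""Delimited-text readers, JSON report writer and packaged fixtures.

Dialect: UTF-8; comma-separated by default with tabs auto-selected for
``.tsv`` files; decimal points only; ``#`` starts a comment line. Readers
validate and reject malformed input instead of coercing it. Reports are
JSON with a metadata block (tool version, config hash, input checksums) and
no timestamps, so re-running with identical inputs yields byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .biochem import parse_formula
from .chemostat import DEFAULT_BIOMASS_FORMULA, BatchTimeCourse, ChemostatRecord
from .kinetics import KineticsDataset
from .proteome import ProteomeTable

__all__ = [
    "read_rate_table",
    "read_chemostat_config",
    "read_proteome_table",
    "read_kinetics_table",
    "read_batch_table",
    "write_report",
    "write_rate_table",
    "write_proteome_table",
    "write_kinetics_table",
    "write_batch_table",
    "fixture_path",
    "list_fixtures",
]

_RATE_UNITS = {
    "mmol/g/h": 1.0,
    "mmol g-1 h-1": 1.0,
    "mmol/gdw/h": 1.0,
    "mol/g/h": 1e3,
    "umol/g/h": 1e-3,
}


def _rows(path: str | Path) -> list[list[str]]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append([c.strip() for c in line.split(sep)])
    return rows


def read_rate_table(
    path: str | Path,
    dilution_rate: float,
    substrate_id: str = "galua",
    biomass_formula: str = DEFAULT_BIOMASS_FORMULA,
) -> ChemostatRecord:
    """Read a (compound_id, rate, unit) table into a chemostat record.

    A header row is required; units are converted to mmol g^-1 h^-1;
    duplicated compounds, unknown units and unknown compounds are errors.
    """
    rows = _rows(path)
    if not rows:
        raise ValueError(f"{path}: empty rate table")
    header = [h.lower() for h in rows[0]]
    if header[:3] != ["compound_id", "rate", "unit"]:
        raise ValueError(
            f"{path}: header must be compound_id,rate,unit (got {rows[0]})")
    rates: dict[str, float] = {}
    for row in rows[1:]:
        if len(row) != 3:
            raise ValueError(f"{path}: malformed row {row}")
        cid, rate, unit = row
        if cid in rates:
            raise ValueError(f"{path}: duplicated compound row {cid!r}")
        if unit not in _RATE_UNITS:
            raise ValueError(f"{path}: unknown unit {unit!r} "
                             f"(accepted: {sorted(_RATE_UNITS)})")
        rates[cid] = float(rate) * _RATE_UNITS[unit]
    return ChemostatRecord(
        dilution_rate=dilution_rate, rates=rates, substrate_id=substrate_id,
        biomass_formula=parse_formula(biomass_formula))


def read_chemostat_config(path: str | Path) -> dict:
    """Sidecar YAML for a rate table: dilution_rate, substrate_id, biomass_formula."""
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    allowed = {"dilution_rate", "substrate_id", "biomass_formula"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "dilution_rate" not in cfg:
        raise ValueError(f"{path}: dilution_rate is required")
    cfg.setdefault("substrate_id", "galua")
    cfg.setdefault("biomass_formula", DEFAULT_BIOMASS_FORMULA)
    return cfg


def read_proteome_table(path: str | Path) -> ProteomeTable:
    """Read (protein_id[, count]) rows; detection-only tables omit the count."""
    rows = _rows(path)
    if not rows:
        raise ValueError(f"{path}: empty proteome table")
    header = [h.lower() for h in rows[0]]
    if header[0] != "protein_id":
        raise ValueError(f"{path}: first column must be protein_id")
    with_counts = len(header) > 1 and header[1] in {"count", "normalized_spectral_count"}
    counts: dict[str, float] = {}
    detected: set[str] = set()
    for row in rows[1:]:
        pid = row[0]
        if pid in detected or pid in counts:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        if with_counts:
            counts[pid] = float(row[1])
        detected.add(pid)
    return ProteomeTable(detected=detected, counts=counts)


def read_kinetics_table(path: str | Path, enzyme: str = "",
                        apparent: bool = False) -> KineticsDataset:
    """Read (substrate_mm, rate) rows into a kinetics dataset."""
    rows = _rows(path)
    if not rows:
        raise ValueError(f"{path}: empty kinetics table")
    header = [h.lower() for h in rows[0]]
    if header[:2] != ["substrate_mm", "rate"]:
        raise ValueError(f"{path}: header must be substrate_mm,rate")
    data = np.array([[float(r[0]), float(r[1])] for r in rows[1:]])
    return KineticsDataset(substrate_mm=data[:, 0], rate=data[:, 1],
                           enzyme=enzyme, apparent=apparent)


def read_batch_table(path: str | Path) -> BatchTimeCourse:
    """Read (time_h, biomass, <compound>...) rows into a batch time course."""
    rows = _rows(path)
    if not rows:
        raise ValueError(f"{path}: empty batch table")
    header = rows[0]
    if [h.lower() for h in header[:2]] != ["time_h", "biomass"]:
        raise ValueError(f"{path}: header must start with time_h,biomass")
    data = np.array([[float(c) for c in r] for r in rows[1:]])
    conc = {name: data[:, 2 + i] for i, name in enumerate(header[2:])}
    return BatchTimeCourse(time=data[:, 0], biomass=data[:, 1],
                           concentrations=conc)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(payload: dict, path: str | Path,
                 inputs: list[str | Path] = (), config: dict | None = None) -> None:
    """Write a JSON report with a deterministic metadata block."""
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True).encode()).hexdigest()[:16]
    doc = {
        "tool": "galuferm",
        "version": __version__,
        "config_hash": cfg_hash,
        "input_checksums": {str(p): _checksum(p) for p in inputs},
        "result": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def _header_comment(seed: int | None) -> str:
    return f"# generated by galuferm {__version__}" + (
        f" (seed {seed})\n" if seed is not None else "\n")


def write_rate_table(rec: ChemostatRecord, path: str | Path,
                     seed: int | None = None) -> None:
    lines = [_header_comment(seed).rstrip("\n"), "compound_id,rate,unit"]
    for cid in sorted(rec.rates):
        lines.append(f"{cid},{float(rec.rates[cid])!r},mmol/g/h")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_proteome_table(pt: ProteomeTable, path: str | Path,
                         seed: int | None = None) -> None:
    lines = [_header_comment(seed).rstrip("\n")]
    if pt.counts:
        lines.append("protein_id\tcount")
        lines += [f"{pid}\t{float(pt.counts[pid])!r}" for pid in sorted(pt.counts)]
    else:
        lines.append("protein_id")
        lines += sorted(pt.detected)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_kinetics_table(d: KineticsDataset, path: str | Path,
                         seed: int | None = None) -> None:
    lines = [_header_comment(seed).rstrip("\n"), "substrate_mm,rate"]
    lines += [f"{float(s)!r},{float(v)!r}" for s, v in zip(d.substrate_mm, d.rate)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_batch_table(tc: BatchTimeCourse, path: str | Path,
                      seed: int | None = None) -> None:
    names = sorted(tc.concentrations)
    lines = [_header_comment(seed).rstrip("\n"),
             ",".join(["time_h", "biomass"] + names)]
    for i in range(len(tc.time)):
        vals = [tc.time[i], tc.biomass[i]] + [tc.concentrations[n][i] for n in names]
        lines.append(",".join(repr(float(v)) for v in vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_FIXTURES = {
    "chemostat_rates": "chemostat_rates.csv",
    "chemostat_config": "chemostat_config.yml",
    "lcv1_proteome": "lcv1_proteome.tsv",
    "lcv1_evidence": "lcv1_evidence.map",
    "enzyme_activities": "enzyme_activities.csv",
}


def list_fixtures() -> dict[str, str]:
    """Names and file names of the packaged fixture tables."""
    return dict(_FIXTURES)


def fixture_path(name: str):
    """Importlib-resources path of a packaged fixture (context-manager safe)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return resources.as_file(
        resources.files("galuferm.data.fixtures").joinpath(_FIXTURES[name]))
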