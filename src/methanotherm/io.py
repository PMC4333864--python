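"""Tabular and sequence I/O plus the full-analysis orchestrator.

All tables are UTF-8 CSV/TSV with headers, decimal points and no thousands
separators. Temperatures are degC everywhere on disk; the Kelvin conversion
happens only inside the Arrhenius fitting. Not-detected qPCR cells are the
literal token "ND".
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import community as comm
from . import isotope as iso
from . import kinetics, thermo
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)

ND_TOKEN = "ND"


class IOFormatError(ValueError):
    pass


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# gas tables

def read_gas_csv(path) -> list[kinetics.GasTimeSeries]:
    """Read a long-format gas table (temperature_C, replicate, day, ch4, co2[, h2])."""
    df = pd.read_csv(path)
    if df.empty:
        raise IOFormatError(f"{path}: empty gas table")
    required = {"temperature_C", "replicate", "day", "ch4", "co2"}
    missing = required - set(df.columns)
    if missing:
        raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (temp, rep), g in df.groupby(["temperature_C", "replicate"], sort=True):
        g = g.sort_values("day")
        if g["day"].duplicated().any():
            raise IOFormatError(
                f"{path}: duplicate day in bottle temperature={temp} replicate={rep}"
            )
        out.append(
            kinetics.GasTimeSeries(
                temperature_C=float(temp),
                replicate=str(rep),
                times=g["day"].to_numpy(float),
                ch4=g["ch4"].to_numpy(float),
                co2=g["co2"].to_numpy(float),
                h2=g["h2"].to_numpy(float) if "h2" in g.columns else None,
            )
        )
    return out


def write_gas_csv(series: Iterable[kinetics.GasTimeSeries], path) -> None:
    rows = []
    for s in series:
        for i, day in enumerate(s.times):
            row = {
                "temperature_C": s.temperature_C,
                "replicate": s.replicate,
                "day": day,
                "ch4": s.ch4[i],
                "co2": s.co2[i],
            }
            if s.h2 is not None:
                row["h2"] = s.h2[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# qPCR table (wide layout: first column day, remaining columns temperatures)

_CELL_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(?:(?:±|\+/-)\s*([0-9.eE+-]+))?\s*$")


def read_qpcr_csv(path) -> thermo.QpcrTable:
    """Parse the wide mcrA table: cells "m", "m±s" (or "m+/-s"), or "ND"."""
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise IOFormatError(f"{path}: empty qPCR table")
    day_col = df.columns[0]
    try:
        temps = [float(c) for c in df.columns[1:]]
    except ValueError as e:
        raise IOFormatError(f"{path}: non-numeric temperature header: {e}") from e
    days = [float(d) for d in df[day_col]]
    means = pd.DataFrame(index=pd.Index(days, name="day"), columns=temps, dtype=float)
    ses = means.copy()
    for i, day in enumerate(days):
        for col, temp in zip(df.columns[1:], temps):
            cell = str(df.iloc[i][col]).strip()
            if cell == ND_TOKEN or cell.lower() in ("nan", ""):
                means.loc[day, temp] = math.nan
                ses.loc[day, temp] = math.nan
                continue
            m = _CELL_RE.match(cell)
            if not m or ("±" in cell or "+/-" in cell) and m.group(2) is None:
                raise IOFormatError(f"{path}: malformed qPCR cell {cell!r} at day {day}, {temp} degC")
            try:
                mean = float(m.group(1))
                se = float(m.group(2)) if m.group(2) is not None else 0.0
            except ValueError as e:
                raise IOFormatError(f"{path}: malformed qPCR cell {cell!r}") from e
            means.loc[day, temp] = mean
            ses.loc[day, temp] = se
    return thermo.QpcrTable(means=means, ses=ses)


def write_qpcr_csv(table: thermo.QpcrTable, path) -> None:
    rows = []
    for day in table.means.index:
        row = {"day": day}
        for col in table.means.columns:
            m = float(table.means.loc[day, col])
            s = float(table.ses.loc[day, col])
            if math.isnan(m):
                row[f"{float(col):g}"] = ND_TOKEN
            elif not math.isnan(s) and s > 0:
                row[f"{float(col):g}"] = f"{m!r}±{s!r}"
            else:
                row[f"{float(col):g}"] = repr(m)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# isotope tables

def read_isotope_csv(path) -> list[iso.IsotopeRecord]:
    df = pd.read_csv(path)
    required = {"temperature_C", "day", "d13c_ch4", "d13c_co2"}
    missing = required - set(df.columns)
    if missing:
        raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        iso.IsotopeRecord(
            temperature_C=float(r.temperature_C), day=float(r.day),
            d13c_ch4=float(r.d13c_ch4), d13c_co2=float(r.d13c_co2),
            alpha_app=float(r.alpha_app) if "alpha_app" in df.columns and not pd.isna(r.alpha_app) else None,
        )
        for r in df.itertuples()
    ]


def write_isotope_csv(records: Iterable[iso.IsotopeRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "temperature_C": r.temperature_C, "day": r.day,
                "d13c_ch4": r.d13c_ch4, "d13c_co2": r.d13c_co2,
                "alpha_app": r.alpha_app,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# community tables and sequences

def read_trflp_tsv(path) -> list[comm.TrflpProfile]:
    """Peak table: sample-identifying columns plus (trf_bp, height)."""
    df = pd.read_csv(path, sep="\t")
    required = {"temperature_C", "day", "replicate", "trf_bp", "height"}
    missing = required - set(df.columns)
    if missing:
        raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (temp, day, rep), g in df.groupby(["temperature_C", "day", "replicate"], sort=True):
        out.append(
            comm.TrflpProfile(
                temperature_C=float(temp), day=float(day), replicate=str(rep),
                trf_bp=[int(b) for b in g["trf_bp"]],
                heights=[float(h) for h in g["height"]],
            )
        )
    return out


def write_trflp_tsv(profiles: Iterable[comm.TrflpProfile], path) -> None:
    rows = []
    for p in profiles:
        for bp, h in zip(p.trf_bp, p.heights):
            rows.append(
                {
                    "temperature_C": p.temperature_C, "day": p.day,
                    "replicate": p.replicate, "trf_bp": bp, "height": h,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_refmap_tsv(path) -> comm.TrfReferenceMap:
    df = pd.read_csv(path, sep="\t")
    if not {"trf_bp", "taxon"} <= set(df.columns):
        raise IOFormatError(f"{path}: expected columns (trf_bp, taxon)")
    return comm.build_reference_map(
        (str(r.taxon), int(r.trf_bp)) for r in df.itertuples()
    )


def write_refmap_tsv(refmap: comm.TrfReferenceMap, path) -> None:
    rows = [
        {"trf_bp": bp, "taxon": taxon}
        for bp, taxa in sorted(refmap.entries.items())
        for taxon in taxa
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_libraries_tsv(path) -> list[comm.CloneLibrary]:
    df = pd.read_csv(path, sep="\t")
    if not {"library", "otu", "count"} <= set(df.columns):
        raise IOFormatError(f"{path}: expected columns (library, otu, count)")
    return [
        comm.CloneLibrary(label=str(lbl), otu_counts=[int(c) for c in g["count"]])
        for lbl, g in df.groupby("library", sort=True)
    ]


def write_libraries_tsv(libraries: Iterable[comm.CloneLibrary], path) -> None:
    rows = []
    for lib in libraries:
        for i, c in enumerate(lib.otu_counts):
            rows.append({"library": lib.label, "otu": f"otu{i + 1:03d}", "count": c})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()],
        str(path), "fasta",
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every layer of a synthetic experiment to its on-disk dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gas": outdir / "gas.csv",
        "qpcr": outdir / "qpcr.csv",
        "isotopes": outdir / "isotopes.csv",
        "trflp": outdir / "trflp.tsv",
        "libraries": outdir / "libraries.tsv",
        "truth": outdir / "truth.json",
    }
    write_gas_csv(dataset.gas, paths["gas"])
    write_qpcr_csv(dataset.qpcr, paths["qpcr"])
    write_isotope_csv(dataset.isotopes, paths["isotopes"])
    write_trflp_tsv(dataset.profiles, paths["trflp"])
    write_libraries_tsv(dataset.libraries, paths["libraries"])
    paths["truth"].write_text(dataset.truth_json())
    return paths


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class RunConfig:
    """Paths and parameters for a full analysis run; None paths skip a stage."""

    gas_path: str | None = None
    qpcr_path: str | None = None
    isotope_path: str | None = None
    trflp_path: str | None = None
    refmap_path: str | None = None
    libraries_path: str | None = None
    output_dir: str = "."
    window_points: int = 3
    boltzmann_eV_per_K: float = thermo.BOLTZMANN_EV_PER_K
    min_points: int = 2
    alpha: float = 0.05
    active_from_day: float = 20.0
    lower_threshold: float = 1.03
    mixed_threshold: float = 1.04
    trf_tolerance_bp: int = 1
    minor_threshold_percent: float = 1.0
    rarefaction_step: int = 10
    seed: int = 0
    stages: tuple[str, ...] = ("rates", "arrhenius", "isotope", "trflp", "clones")


def _fit_report(points, min_points, alpha) -> dict:
    single = thermo.fit_single(points)
    report = {
        "single": {
            "E": single.E, "M": single.M, "se_E": single.se_E,
            "r2": single.r2, "n": single.n, "rss": single.rss,
        }
    }
    try:
        seg = thermo.fit_segmented(points, min_points)
        choice = thermo.select_model(single, seg, alpha)
        report["segmented"] = {
            "break_after_temperature_C": seg.break_after_temperature_C,
            "E_low": seg.low.E, "E_high": seg.high.E,
            "M_low": seg.low.M, "M_high": seg.high.M,
            "se_E_low": seg.low.se_E, "se_E_high": seg.high.se_E,
            "pooled_rss": seg.pooled_rss,
            "f_stat": seg.f_stat, "p_value": seg.p_value,
        }
        report["selected"] = choice
    except (thermo.ThermoError, thermo.FTestUndefinedError) as e:
        logger.warning("segmented fit unavailable (%s); reporting single fit", e)
        report["selected"] = "single"
        report["segmented_error"] = str(e)
    return report


def run_full_analysis(config: RunConfig) -> dict:
    """Chain every requested stage; per-stage errors are labelled and collected.

    Returns the machine-readable summary that is also written to
    ``summary.json`` in the output directory. Stages that fail leave the other
    stages' results untouched; the summary's "errors" list carries the stage
    labels, and callers (the CLI) map a non-empty list to a non-zero exit.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "errors": []}

    def fail(stage: str, e: Exception) -> None:
        logger.error("[%s] %s", stage, e)
        report["errors"].append({"stage": stage, "error": str(e)})

    rates: dict[str, list[kinetics.RateEstimate]] = {}
    if "rates" in config.stages:
        try:
            if config.gas_path is None:
                raise IOFormatError("rates stage requested but no gas table given")
            gas = read_gas_csv(config.gas_path)
            rows = []
            for label in ("ch4", "co2"):
                rates[label] = kinetics.rates_by_temperature(gas, label, config.window_points)
                rows += [
                    {
                        "temperature_C": r.temperature_C, "gas": r.gas,
                        "p_max": r.p_max, "se": r.se, "lag_days": r.lag_days,
                        "window_r2": r.window_r2,
                    }
                    for r in rates[label]
                ]
            pd.DataFrame(rows).to_csv(out / "rates.csv", index=False)
            report["rates"] = rows
        except Exception as e:
            fail("rates", e)

    if "arrhenius" in config.stages and rates:
        try:
            fits: dict = {}
            for label, rr in rates.items():
                pts = thermo.transform_rates(rr, config.boltzmann_eV_per_K)
                fits[label] = _fit_report(pts, config.min_points, config.alpha)
            if config.qpcr_path is not None:
                qpcr = read_qpcr_csv(config.qpcr_path)
                normed = thermo.normalize_rates(rates["ch4"], qpcr)
                pts = thermo.transform_rates(normed, config.boltzmann_eV_per_K)
                fits["ch4_normalized"] = _fit_report(pts, config.min_points, config.alpha)
            report["arrhenius"] = fits
            (out / "arrhenius.json").write_text(json.dumps(fits, indent=2))
        except Exception as e:
            fail("arrhenius", e)

    if "isotope" in config.stages:
        try:
            if config.isotope_path is None:
                raise IOFormatError("isotope stage requested but no isotope table given")
            records = iso.annotate_alpha(read_isotope_csv(config.isotope_path))
            write_isotope_csv(records, out / "isotopes_alpha.csv")
            labels = iso.classify_pathway(
                records, config.active_from_day,
                config.lower_threshold, config.mixed_threshold,
            )
            report["pathway"] = {f"{t:g}": lbl for t, lbl in labels.items()}
            pd.DataFrame(
                [{"temperature_C": t, "pathway": lbl} for t, lbl in labels.items()]
            ).to_csv(out / "pathway.csv", index=False)
        except Exception as e:
            fail("isotope", e)

    if "trflp" in config.stages:
        try:
            if config.trflp_path is None:
                raise IOFormatError("trflp stage requested but no peak table given")
            profiles = [
                comm.filter_minor(comm.relative_abundance(p), config.minor_threshold_percent)
                for p in read_trflp_tsv(config.trflp_path)
            ]
            refmap = read_refmap_tsv(config.refmap_path) if config.refmap_path else None
            rows = []
            for p in profiles:
                for bp, pct in zip(p.trf_bp, p.percent):
                    rows.append(
                        {
                            "temperature_C": p.temperature_C, "day": p.day,
                            "replicate": p.replicate, "trf_bp": bp, "percent": pct,
                            "taxa": ";".join(
                                comm.assign_taxa(bp, refmap, config.trf_tolerance_bp)
                            ) if refmap else "",
                        }
                    )
                rows.append(
                    {
                        "temperature_C": p.temperature_C, "day": p.day,
                        "replicate": p.replicate, "trf_bp": -1,
                        "percent": p.diverse_percent, "taxa": "Diverse",
                    }
                )
            pd.DataFrame(rows).to_csv(out / "trflp_percent.csv", index=False)
            report["trflp_profiles"] = len(profiles)
        except Exception as e:
            fail("trflp", e)

    if "clones" in config.stages:
        try:
            if config.libraries_path is None:
                raise IOFormatError("clones stage requested but no library table given")
            libraries = read_libraries_tsv(config.libraries_path)
            rows, raref = [], []
            for lib in libraries:
                rows.append(
                    {
                        "library": lib.label, "N": lib.N, "n_otus": len(lib.otu_counts),
                        "n1": lib.n1, "coverage_percent": lib.coverage_percent,
                    }
                )
                depths = list(range(1, lib.N + 1, config.rarefaction_step))
                if depths[-1] != lib.N:
                    depths.append(lib.N)
                for d, s in zip(depths, comm.rarefaction_curve(lib.otu_counts, depths)):
                    raref.append({"library": lib.label, "depth": d, "expected_otus": s})
            pd.DataFrame(rows).to_csv(out / "coverage.csv", index=False)
            pd.DataFrame(raref).to_csv(out / "rarefaction.csv", index=False)
            report["coverage"] = rows
        except Exception as e:
            fail("clones", e)

    (out / "summary.json").write_text(json.dumps(report, indent=2))
    return report
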