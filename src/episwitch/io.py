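"""Readers and writers for the pipeline's plain-text dialects.

Formats handled (all UTF-8; comment lines start with ``#`` and carry
provenance such as the generating config hash and seed):

- relaxation time-course TSV: ``genotype replicate initial_state
  time_hr n_cells n_gfp_pos``;
- flow events CSV: ``cell_id,rfp,gfp`` (raw intensities) or
  ``cell_id,rfp_pos,gfp_pos`` (boolean dialect), auto-detected from the
  header;
- pedigree TSV: ``genotype direction n_divisions n_events``;
- BED3 fragment intervals (0-based half-open) and bedGraph profiles;
- JSON fit results.

Malformed rows are reported with their 1-based line number.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from episwitch.assays import FlowPopulation, PedigreeCounts
from episwitch.kinetics import FitResult, RelaxationTimeCourse, to_per_generation
from episwitch.mnase import FragmentSet, OccupancyProfile

__all__ = [
    "ParseError",
    "read_timecourses",
    "write_timecourses",
    "read_flow_events",
    "write_flow_events",
    "read_pedigree",
    "write_pedigree",
    "read_bed3",
    "write_bed3",
    "write_bedgraph",
    "read_bedgraph",
    "fit_result_to_dict",
    "write_fit_results",
    "read_fit_results",
]


class ParseError(ValueError):
    """A malformed row, reported with its 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}: {v}" for k, v in provenance.items()]


def _data_lines(path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# Relaxation time courses

_TC_COLUMNS = ["genotype", "replicate", "initial_state", "time_hr", "n_cells", "n_gfp_pos"]


def write_timecourses(courses: list[RelaxationTimeCourse], path, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("\t".join(_TC_COLUMNS))
    for tc in courses:
        for t, n, k in tc.points:
            lines.append(f"{tc.genotype}\t{tc.replicate_id}\t{tc.initial_state}\t{t!r}\t{n}\t{k}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_timecourses(path) -> list[RelaxationTimeCourse]:
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(path, 1, "empty time-course file")
    header_no, header = rows[0]
    if header.split("\t") != _TC_COLUMNS:
        raise ParseError(path, header_no, f"expected header {_TC_COLUMNS}, got {header.split(chr(9))}")
    grouped: dict[tuple[str, str, str], list[tuple[float, int, int]]] = defaultdict(list)
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(path, lineno, f"expected 6 tab-separated fields, got {len(parts)}")
        geno, rep, state, t_s, n_s, k_s = parts
        try:
            t, n, k = float(t_s), int(n_s), int(k_s)
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad numeric field: {exc}") from None
        if n < 1 or not (0 <= k <= n):
            raise ParseError(path, lineno, f"need 1 <= n_cells and 0 <= n_gfp_pos <= n_cells, got {k}/{n}")
        grouped[(geno, rep, state)].append((t, n, k))
    return [
        RelaxationTimeCourse(genotype=g, replicate_id=r, initial_state=s, points=tuple(sorted(pts)))
        for (g, r, s), pts in grouped.items()
    ]


# ---------------------------------------------------------------------------
# Flow events

def write_flow_events(pop: FlowPopulation, path, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    if pop.dialect == "boolean":
        lines.append("cell_id,rfp_pos,gfp_pos")
        for i, row in enumerate(pop.events.itertuples(index=False)):
            lines.append(f"{i},{int(row.rfp_pos)},{int(row.gfp_pos)}")
    else:
        lines.append("cell_id,rfp,gfp")
        for i, row in enumerate(pop.events.itertuples(index=False)):
            lines.append(f"{i},{row.rfp:g},{row.gfp:g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_flow_events(path, genotype: str = "", replicate_id: str = "") -> FlowPopulation:
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(path, 1, "empty flow events file")
    header_no, header = rows[0]
    cols = header.split(",")
    if cols == ["cell_id", "rfp_pos", "gfp_pos"]:
        boolean = True
    elif cols == ["cell_id", "rfp", "gfp"]:
        boolean = False
    else:
        raise ParseError(path, header_no, f"unrecognized flow header {cols}")
    rec = []
    for lineno, line in rows[1:]:
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(path, lineno, f"expected 3 comma-separated fields, got {len(parts)}")
        try:
            if boolean:
                rec.append((bool(int(parts[1])), bool(int(parts[2]))))
            else:
                r, g = float(parts[1]), float(parts[2])
                if r < 0 or g < 0:
                    raise ValueError("negative intensity")
                rec.append((r, g))
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad field: {exc}") from None
    columns = ["rfp_pos", "gfp_pos"] if boolean else ["rfp", "gfp"]
    events = pd.DataFrame(rec, columns=columns)
    return FlowPopulation(events=events, genotype=genotype, replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# Pedigrees

_PED_COLUMNS = ["genotype", "direction", "n_divisions", "n_events"]


def write_pedigree(counts: list[PedigreeCounts], path, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("\t".join(_PED_COLUMNS))
    for c in counts:
        lines.append(f"{c.genotype}\t{c.direction}\t{c.n_divisions}\t{c.n_events}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pedigree(path) -> list[PedigreeCounts]:
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(path, 1, "empty pedigree file")
    header_no, header = rows[0]
    if header.split("\t") != _PED_COLUMNS:
        raise ParseError(path, header_no, f"expected header {_PED_COLUMNS}")
    out = []
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(path, lineno, f"expected 4 tab-separated fields, got {len(parts)}")
        try:
            out.append(
                PedigreeCounts(
                    genotype=parts[0],
                    direction=parts[1],
                    n_divisions=int(parts[2]),
                    n_events=int(parts[3]),
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


# ---------------------------------------------------------------------------
# BED3 / bedGraph

def write_bed3(frags: FragmentSet, path, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    for row in frags.fragments.itertuples(index=False):
        lines.append(f"{row.chrom}\t{row.start}\t{row.end}")
    Path(path).write_text("\n".join(lines) + "\n" if lines else "", encoding="utf-8")


def read_bed3(path, region: tuple[str, int, int]) -> FragmentSet:
    rec = []
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(path, lineno, f"BED3 needs >= 3 fields, got {len(parts)}")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad coordinate: {exc}") from None
        if start >= end:
            raise ParseError(path, lineno, f"start must be < end, got {start} >= {end}")
        if start < 0:
            raise ParseError(path, lineno, f"negative start {start}")
        rec.append((chrom, start, end))
    frags = pd.DataFrame(rec, columns=["chrom", "start", "end"])
    return FragmentSet(fragments=frags, region=region)


def write_bedgraph(profile: OccupancyProfile, path, which: str = "smoothed", provenance: dict | None = None) -> None:
    """Emit a profile as bedGraph (0-based half-open), merging equal-value runs."""
    values = profile.smoothed if which == "smoothed" else profile.raw
    if values is None:
        raise ValueError(f"profile has no {which!r} values")
    lines = _provenance_lines(provenance)
    pos = profile.positions
    run_start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[run_start]:
            v = values[run_start]
            if v != 0:
                lines.append(f"{profile.chrom}\t{pos[run_start]}\t{pos[i - 1] + 1}\t{v:g}")
            run_start = i
    Path(path).write_text("\n".join(lines) + "\n" if lines else "", encoding="utf-8")


def read_bedgraph(path) -> pd.DataFrame:
    rec = []
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(path, lineno, f"bedGraph needs 4 fields, got {len(parts)}")
        try:
            rec.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad field: {exc}") from None
    return pd.DataFrame(rec, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Fit results

def fit_result_to_dict(fit: FitResult) -> dict:
    """JSON-ready summary of a fit, in per-hour and per-generation units."""
    per_gen = to_per_generation(fit.rates)
    g = fit.rates.generation_time_hr
    d = {
        "genotype": fit.genotype,
        "k_on_per_hr": fit.rates.k_on,
        "k_off_per_hr": fit.rates.k_off,
        "k_on_per_gen": per_gen.k_on,
        "k_off_per_gen": per_gen.k_off,
        "ci_k_on_per_hr": list(fit.ci_k_on),
        "ci_k_off_per_hr": list(fit.ci_k_off),
        "ci_k_on_per_gen": [b * g for b in fit.ci_k_on],
        "ci_k_off_per_gen": [b * g for b in fit.ci_k_off],
        "generation_time_hr": g,
        "method": fit.fit_method,
        "rss": fit.rss,
        "n_points": fit.n_points,
    }
    if fit.sd_k_on is not None:
        d["sd_k_on_per_hr"] = fit.sd_k_on
        d["sd_k_off_per_hr"] = fit.sd_k_off
    return d


def write_fit_results(fits: list[FitResult], path, provenance: dict | None = None) -> None:
    payload = {"fits": [fit_result_to_dict(f) for f in fits]}
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_fit_results(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
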