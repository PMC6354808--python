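"""Long-format dataset I/O, published-table reproduction, transit arithmetic.

Datasets are long-format CSVs with one row per event:

    subject_id, weight_g, event_type{dose|obs}, time_h, amount_mg,
    infusion_h, output{plasma|csf}, conc_ug_ml, excluded{0|1}

Missing fields are empty; unknown columns survive a read/write
round-trip. ``reproduce_table3_summaries`` recomputes every derived
cell of the published exposure table (penetration integers and both
median/IQR summary rows) from the per-animal inputs and reports
pass/fail per cell against the transcribed printed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference
from .exposure import round_half_up, summarize_cohort
from .models import CSF, PLASMA, DoseEvent, Observation, PKParams, SubjectRecord

__all__ = [
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "flag_gross_outliers",
    "Table3Report",
    "reproduce_table3_summaries",
    "transit_arithmetic",
]

REQUIRED_COLUMNS = [
    "subject_id",
    "weight_g",
    "event_type",
    "time_h",
    "amount_mg",
    "infusion_h",
    "output",
    "conc_ug_ml",
    "excluded",
]


class DatasetFormatError(ValueError):
    """Malformed dataset; the message names the offending CSV rows."""


def _fmt(x: float) -> str:
    """Shortest round-trip decimal representation."""
    return repr(float(x))


def _parse_float(raw: str, what: str, line: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise DatasetFormatError(f"line {line}: non-numeric {what} {raw!r}") from None


def read_dataset(path) -> list[SubjectRecord]:
    """Parse a long-format dataset CSV into SubjectRecord objects.

    Rows are validated individually; all problems are reported together
    with their 1-based CSV line numbers (header is line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    problems: list[str] = []
    subjects: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        sid = row["subject_id"]
        if not sid:
            problems.append(f"line {line}: empty subject_id")
            continue
        try:
            entry = subjects.setdefault(sid, {"weight": None, "doses": [], "obs": []})
            if row["weight_g"]:
                w = _parse_float(row["weight_g"], "weight_g", line)
                if entry["weight"] is None:
                    entry["weight"] = w
                elif entry["weight"] != w:
                    raise DatasetFormatError(
                        f"line {line}: conflicting weight_g for subject {sid!r}"
                    )
            etype = row["event_type"]
            t = _parse_float(row["time_h"], "time_h", line)
            if etype == "dose":
                amount = _parse_float(row["amount_mg"], "amount_mg", line)
                if amount <= 0:
                    raise DatasetFormatError(f"line {line}: dose row with zero amount")
                inf = _parse_float(row["infusion_h"] or "0", "infusion_h", line)
                entry["doses"].append(
                    DoseEvent(start_time=t, amount=amount, infusion_duration=inf)
                )
            elif etype == "obs":
                conc = _parse_float(row["conc_ug_ml"], "conc_ug_ml", line)
                output = row["output"]
                if output not in (PLASMA, CSF):
                    raise DatasetFormatError(
                        f"line {line}: unknown output channel {output!r}"
                    )
                excluded = row["excluded"] in ("1", "true", "True")
                extra = {c: row[c] for c in extra_cols if row[c] != ""}
                entry["obs"].append(
                    Observation(
                        time=t,
                        value=conc,
                        output=output,
                        excluded=excluded,
                        extra=extra,
                    )
                )
            else:
                raise DatasetFormatError(
                    f"line {line}: event_type must be 'dose' or 'obs', got {etype!r}"
                )
        except DatasetFormatError as e:
            problems.append(str(e))
        except ValueError as e:
            problems.append(f"line {line}: {e}")
    if problems:
        raise DatasetFormatError("; ".join(problems))
    out = []
    for sid, entry in subjects.items():
        if entry["weight"] is None:
            raise DatasetFormatError(f"subject {sid!r} has no weight_g")
        out.append(
            SubjectRecord(
                id=sid,
                weight=entry["weight"],
                doses=sorted(entry["doses"], key=lambda d: d.start_time),
                observations=sorted(entry["obs"], key=lambda o: (o.time, o.output)),
            )
        )
    return out


def write_dataset(dataset: Sequence[SubjectRecord], path) -> None:
    """Write SubjectRecords as a long-format CSV (read/write round-trips)."""
    extra_cols: list[str] = []
    for sub in dataset:
        for o in sub.observations:
            for k in o.extra:
                if k not in extra_cols:
                    extra_cols.append(k)
    rows = []
    for sub in dataset:
        for d in sub.doses:
            rows.append(
                {
                    "subject_id": sub.id,
                    "weight_g": _fmt(sub.weight),
                    "event_type": "dose",
                    "time_h": _fmt(d.start_time),
                    "amount_mg": _fmt(d.amount),
                    "infusion_h": _fmt(d.infusion_duration),
                    "output": "",
                    "conc_ug_ml": "",
                    "excluded": "",
                }
            )
        for o in sub.observations:
            row = {
                "subject_id": sub.id,
                "weight_g": _fmt(sub.weight),
                "event_type": "obs",
                "time_h": _fmt(o.time),
                "amount_mg": "",
                "infusion_h": "",
                "output": o.output,
                "conc_ug_ml": _fmt(o.value),
                "excluded": "1" if o.excluded else "0",
            }
            row.update({k: o.extra.get(k, "") for k in extra_cols})
            rows.append(row)
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS + extra_cols).to_csv(path, index=False)


def flag_gross_outliers(
    dataset: Sequence[SubjectRecord], factor: float = 50.0
) -> list[SubjectRecord]:
    """Mark plasma observations more than ``factor`` times the subject's
    plasma median as excluded - the manual quality-control rule used for
    the 100-fold outlier in the original analysis."""
    out = []
    for sub in dataset:
        plasma_vals = [o.value for o in sub.observations if o.output == PLASMA]
        med = float(np.median(plasma_vals)) if plasma_vals else 0.0
        obs = [
            Observation(o.time, o.value, o.output, True, dict(o.extra))
            if (o.output == PLASMA and med > 0 and o.value > factor * med)
            else o
            for o in sub.observations
        ]
        out.append(SubjectRecord(sub.id, sub.weight, list(sub.doses), obs))
    return out


# -- published-table reproduction -------------------------------------------

_METRICS = [
    "cmax_plasma",
    "auc_plasma",
    "cmax_csf",
    "tmax_csf",
    "auc_csf",
    "t_half",
    "pen_cmax_pct",
    "pen_auc_pct",
]


@dataclass
class Table3Report:
    """Cell-by-cell comparison of recomputed versus printed values."""

    cells: dict[str, tuple[float, float, bool]] = field(default_factory=dict)

    def add(self, name: str, recomputed: float, printed: float, atol: float = 0.05):
        ok = abs(recomputed - printed) <= atol
        self.cells[name] = (recomputed, printed, ok)

    @property
    def all_pass(self) -> bool:
        return all(ok for _, _, ok in self.cells.values())

    @property
    def failures(self) -> list[str]:
        return [k for k, (_, _, ok) in self.cells.items() if not ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cell": k, "recomputed": r, "printed": p, "pass": ok}
                for k, (r, p, ok) in self.cells.items()
            ]
        )


def reproduce_table3_summaries(
    fixture: pd.DataFrame | None = None,
    printed_summary: pd.DataFrame | None = None,
    median_on_rounded: bool = True,
) -> Table3Report:
    """Recompute every derived cell of the published exposure table.

    Per-animal penetration integers come from the printed AUC/Cmax
    inputs (half-up rounding); the two summary rows (all animals, and
    animals with sampled CSF only) use the (n+1)p quantile convention.
    Penetration summaries are computed on the rounded integers by
    default; the raw-ratio alternative is available via
    ``median_on_rounded=False``.
    """
    fixture = fixture if fixture is not None else reference.load_table3()
    if len(fixture) == 0:
        raise ValueError("empty exposure fixture")
    printed_summary = (
        printed_summary if printed_summary is not None else reference.load_table3_summary()
    )
    report = Table3Report()
    pen_auc_raw = 100.0 * fixture["auc_csf"] / fixture["auc_plasma"]
    pen_cmax_raw = 100.0 * fixture["cmax_csf"] / fixture["cmax_plasma"]
    pen_auc = pen_auc_raw.map(round_half_up)
    pen_cmax = pen_cmax_raw.map(round_half_up)
    for animal, rec, printed in zip(fixture["animal"], pen_auc, fixture["pen_auc_pct"]):
        report.add(f"animal{animal}.pen_auc_pct", float(rec), float(printed), atol=0.0)
    for animal, rec, printed in zip(
        fixture["animal"], pen_cmax, fixture["pen_cmax_pct"]
    ):
        report.add(f"animal{animal}.pen_cmax_pct", float(rec), float(printed), atol=0.0)

    recomputed = fixture.copy()
    recomputed["pen_auc_pct"] = pen_auc if median_on_rounded else pen_auc_raw
    recomputed["pen_cmax_pct"] = pen_cmax if median_on_rounded else pen_cmax_raw
    groups = {
        "all": np.ones(len(fixture), dtype=bool),
        "csf_sampled": fixture["csf_sampled"].to_numpy(dtype=bool),
    }
    for gname, mask in groups.items():
        sub = recomputed.loc[mask]
        printed_rows = printed_summary[printed_summary["group"] == gname].set_index(
            "metric"
        )
        for metric in _METRICS:
            if metric not in printed_rows.index:
                continue
            s = summarize_cohort(sub[metric].to_numpy(dtype=float))
            row = printed_rows.loc[metric]
            # printed precision: 1 decimal for exposures, integers for percents
            report.add(f"{gname}.{metric}.median", s.median, float(row["median"]))
            report.add(f"{gname}.{metric}.q1", s.iqr[0], float(row["q1"]))
            report.add(f"{gname}.{metric}.q3", s.iqr[1], float(row["q3"]))
    return report


def transit_arithmetic(params: PKParams | None = None) -> dict[str, float]:
    """Mass-transit arithmetic from the population medians.

    combined_transit_rate = K13 + K34 (1/h): the serial rates moving
    drug from the central compartment into the CSF. The approach to
    steady state takes about three half-times of that combined rate,
    3*ln(2)/(K13+K34). The central elimination half-life is ln(2)/kel.
    All values rounded to 2 decimals for reporting.
    """
    params = params or reference.REFERENCE_MEDIANS
    for name in ("K13", "K34", "kel"):
        v = params.get(name)
        if v is None or v <= 0:
            raise ValueError(f"positive {name!r} required")
    combined = params.K13 + params.K34
    return {
        "combined_transit_rate": round(combined, 2),
        "time_to_steady_state": round(3.0 * math.log(2.0) / combined, 2),
        "kel_half_life": round(math.log(2.0) / params.kel, 2),
    }
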