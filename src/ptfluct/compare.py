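"""Condition summaries and ΔT/ΔP comparison tables.

A :class:`ConditionSummary` is one row of the per-condition property table:
protein-averaged MSF (Å²), apparent volume per heavy atom V_app/N_HA (Å³),
interior-water count N_w,in, hydrogen-bond population N_HB and pair-averaged
lifetime τ_HB (ps), each with a block-averaging error.

:func:`delta_table` compares the two endpoint states along one axis
(temperature at constant pressure, or pressure at constant temperature).
Percent changes are 100·(high − low)/low with respect to the low state and
printed as integers rounded half-away-from-zero; N_w,in changes are signed
differences to 2 decimals and N_HB changes signed integers.  Errors are
propagated in quadrature but kept out of the printed table view.

The package ships reference summaries for E. coli and M. profunda DHFR at
the four (T, P) states of their organisms' growth conditions
(``ptfluct/data/dhfr_condition_summaries.tsv``), loadable with
:func:`packaged_dhfr_summaries`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .core import ConditionLabel
from .errors import PairingError, ParseError

_VALUE_ERR_RE = re.compile(
    r"^\s*(?P<value>[-+−]?[\d.]+(?:[eE][-+]?\d+)?)"
    r"(?:\s*(?:±|\+/-|\+-)\s*(?P<err>[\d.]+(?:[eE][-+]?\d+)?))?\s*$"
)

_COLUMNS = [
    "protein",
    "temperature_K",
    "pressure_bar",
    "MSF_A2",
    "Vapp_per_NHA_A3",
    "N_w_in",
    "N_HB",
    "tau_HB_ps",
]


@dataclass(frozen=True)
class Measurement:
    value: float
    error: float = 0.0

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("errors must be non-negative")

    def __str__(self) -> str:
        return f"{self.value} ± {self.error}"


@dataclass(frozen=True)
class ConditionSummary:
    label: ConditionLabel
    msf: Measurement  # Å²
    v_app_per_heavy_atom: Measurement  # Å³
    n_w_in: Measurement
    n_hb: Measurement
    tau_hb: Measurement  # ps


@dataclass(frozen=True)
class DeltaRow:
    """One comparison row: changes from the low to the high endpoint state."""

    protein_id: str
    held_fixed: str  # "pressure" or "temperature"
    held_value: float  # bar or K
    pct_msf: int
    pct_vapp: int
    delta_n_w_in: float  # 2 decimals
    delta_n_hb: int
    pct_tau_hb: int
    # unrounded values and quadrature-propagated errors, for programmatic use
    raw: dict = None
    errors: dict = None


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention behind the printed tables)."""
    scale = 10**ndigits
    y = x * scale
    r = math.floor(abs(y) + 0.5) * (1 if y >= 0 else -1)
    return r / scale


def _parse_measurement(cell: str, line_no: int, column: str) -> Measurement:
    cell = cell.replace("−", "-")  # unicode minus
    m = _VALUE_ERR_RE.match(cell)
    if not m:
        raise ParseError(f"line {line_no}: cannot parse {column!r} cell {cell!r}")
    err = m.group("err")
    return Measurement(float(m.group("value")), float(err) if err else 0.0)


def load_condition_summaries(path) -> list[ConditionSummary]:
    """Read a TSV of condition summaries (one row per protein × T × P).

    Cells may be bare numbers or ``value ± error``; a unicode minus sign is
    accepted.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    lines = [
        (i + 1, ln)
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path}: no data rows")
    header_no, header = lines[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols != _COLUMNS:
        raise ParseError(
            f"{path} line {header_no}: header {cols} does not match the "
            f"condition-summary schema {_COLUMNS}"
        )
    out = []
    for line_no, ln in lines[1:]:
        cells = [c.strip() for c in ln.split("\t")]
        if len(cells) != len(_COLUMNS):
            raise ParseError(
                f"{path} line {line_no}: expected {len(_COLUMNS)} columns, "
                f"got {len(cells)}"
            )
        try:
            label = ConditionLabel(
                protein_id=cells[0],
                temperature=float(cells[1]),
                pressure=float(cells[2]),
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {line_no}: {exc}") from exc
        out.append(
            ConditionSummary(
                label=label,
                msf=_parse_measurement(cells[3], line_no, "MSF_A2"),
                v_app_per_heavy_atom=_parse_measurement(
                    cells[4], line_no, "Vapp_per_NHA_A3"
                ),
                n_w_in=_parse_measurement(cells[5], line_no, "N_w_in"),
                n_hb=_parse_measurement(cells[6], line_no, "N_HB"),
                tau_hb=_parse_measurement(cells[7], line_no, "tau_HB_ps"),
            )
        )
    if not out:
        raise ParseError(f"{path}: header only, no data rows")
    return out


def write_condition_summaries(summaries: Sequence[ConditionSummary], path) -> None:
    lines = ["\t".join(_COLUMNS)]
    for s in summaries:
        cells = [
            s.label.protein_id,
            f"{s.label.temperature:g}",
            f"{s.label.pressure:g}",
            str(s.msf),
            str(s.v_app_per_heavy_atom),
            str(s.n_w_in),
            str(s.n_hb),
            str(s.tau_hb),
        ]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def packaged_dhfr_summaries() -> list[ConditionSummary]:
    """The shipped EcDHFR/MpDHFR condition summaries (four states each)."""
    ref = resources.files("ptfluct").joinpath("data/dhfr_condition_summaries.tsv")
    with resources.as_file(ref) as p:
        return load_condition_summaries(p)


def _pct(low: Measurement, high: Measurement) -> tuple[float, float]:
    """Percent change w.r.t. the low state, with quadrature error."""
    p = 100.0 * (high.value - low.value) / low.value
    # d p / d high = 100/low ; d p / d low = -100*high/low^2
    err = math.hypot(
        100.0 * high.error / low.value,
        100.0 * high.value * low.error / low.value**2,
    )
    return p, err


def _diff(low: Measurement, high: Measurement) -> tuple[float, float]:
    return high.value - low.value, math.hypot(low.error, high.error)


def delta_table(
    summaries: Sequence[ConditionSummary],
    axis: str,
) -> list[DeltaRow]:
    """Endpoint comparison rows along one axis.

    ``axis="temperature"``: for each (protein, pressure) the change from the
    low-T to the high-T state, percentages w.r.t. the low-T value.
    ``axis="pressure"``: likewise at constant temperature, w.r.t. low P.
    """
    if axis not in {"temperature", "pressure"}:
        raise ValueError("axis must be 'temperature' or 'pressure'")
    held = "pressure" if axis == "temperature" else "temperature"

    def held_value(s: ConditionSummary) -> float:
        return s.label.pressure if held == "pressure" else s.label.temperature

    def vary_value(s: ConditionSummary) -> float:
        return s.label.temperature if axis == "temperature" else s.label.pressure

    groups: dict[tuple[str, float], list[ConditionSummary]] = {}
    for s in summaries:
        groups.setdefault((s.label.protein_id, held_value(s)), []).append(s)

    rows = []
    for (protein, hv), members in groups.items():
        if len(members) != 2:
            raise PairingError(
                f"{protein} at {held} {hv}: need exactly the two endpoint "
                f"conditions along {axis}, found {len(members)}"
            )
        low, high = sorted(members, key=vary_value)
        if vary_value(low) == vary_value(high):
            raise PairingError(
                f"{protein} at {held} {hv}: duplicate {axis} endpoints"
            )
        pct_msf, e_msf = _pct(low.msf, high.msf)
        pct_vapp, e_vapp = _pct(low.v_app_per_heavy_atom, high.v_app_per_heavy_atom)
        d_nwin, e_nwin = _diff(low.n_w_in, high.n_w_in)
        d_nhb, e_nhb = _diff(low.n_hb, high.n_hb)
        pct_tau, e_tau = _pct(low.tau_hb, high.tau_hb)
        rows.append(
            DeltaRow(
                protein_id=protein,
                held_fixed=held,
                held_value=hv,
                pct_msf=int(round_half_away(pct_msf)),
                pct_vapp=int(round_half_away(pct_vapp)),
                delta_n_w_in=round_half_away(d_nwin, 2),
                delta_n_hb=int(round_half_away(d_nhb)),
                pct_tau_hb=int(round_half_away(pct_tau)),
                raw={
                    "pct_msf": pct_msf,
                    "pct_vapp": pct_vapp,
                    "delta_n_w_in": d_nwin,
                    "delta_n_hb": d_nhb,
                    "pct_tau_hb": pct_tau,
                },
                errors={
                    "pct_msf": e_msf,
                    "pct_vapp": e_vapp,
                    "delta_n_w_in": e_nwin,
                    "delta_n_hb": e_nhb,
                    "pct_tau_hb": e_tau,
                },
            )
        )
    rows.sort(key=lambda r: (r.protein_id, r.held_value))
    return rows


def format_delta_table(rows: Sequence[DeltaRow]) -> str:
    """Tab-separated view mirroring the printed comparison tables."""
    if not rows:
        return ""
    axis_tag = "T" if rows[0].held_fixed == "pressure" else "P"
    header = "\t".join(
        [
            f"protein ({'P, bar' if axis_tag == 'T' else 'T, K'})",
            f"d{axis_tag}_pct_MSF",
            f"d{axis_tag}_pct_Vapp_per_NHA",
            f"d{axis_tag}_N_w_in",
            f"d{axis_tag}_N_HB",
            f"d{axis_tag}_pct_tau_HB",
        ]
    )
    lines = [header]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    f"{r.protein_id} ({r.held_value:g})",
                    str(r.pct_msf),
                    str(r.pct_vapp),
                    f"{r.delta_n_w_in:.2f}",
                    str(r.delta_n_hb),
                    str(r.pct_tau_hb),
                ]
            )
        )
    return "\n".join(lines) + "\n"
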