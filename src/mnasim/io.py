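"""CSV/JSON/YAML input-output and run configuration.

Breakthrough-curve CSVs follow the schema
``time_d, pore_volumes, conc_mg_per_L, analyte, column_id`` (header row
mandatory, UTF-8, '.' decimal separator, '#' comment lines allowed).
Round-trips are lossless to 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .column import BreakthroughCurve, ColumnSpec
from .exceptions import ValidationError

__all__ = [
    "read_btc",
    "write_btc",
    "write_wells_csv",
    "write_plume_csv",
    "write_json",
    "RunConfig",
    "CONFIG_DEFAULTS",
]

BTC_SCHEMA = "mnasim-btc-v1"
_REQUIRED = ("time_d", "conc_mg_per_L")


def read_btc(
    path,
    *,
    spec: ColumnSpec | None = None,
    flow_rate: float | None = None,
    pore_volume: float | None = None,
) -> BreakthroughCurve:
    """Read a breakthrough curve CSV, validating the schema row by row.

    If the ``pore_volumes`` column is absent it is derived from
    ``flow_rate``/``pore_volume`` (or a :class:`ColumnSpec`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"breakthrough-curve file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    times = df["time_d"].to_numpy(dtype=float)
    conc = df["conc_mg_per_L"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(times) | ~np.isfinite(conc))
    if bad.size:
        raise ValidationError(f"{path}: non-numeric value at data row {bad[0] + 1}")
    dec = np.flatnonzero(np.diff(times) <= 0)
    if dec.size:
        raise ValidationError(
            f"{path}: time_d not strictly increasing at data row {dec[0] + 2}"
        )
    neg = np.flatnonzero(conc < 0)
    if neg.size:
        raise ValidationError(f"{path}: negative concentration at data row {neg[0] + 1}")

    if "pore_volumes" in df.columns:
        pv = df["pore_volumes"].to_numpy(dtype=float)
    else:
        if spec is not None:
            flow_rate, pore_volume = spec.flow_rate, spec.pore_volume
        if flow_rate is None or pore_volume is None:
            raise ValidationError(
                f"{path}: no pore_volumes column; supply spec or flow_rate and pore_volume"
            )
        pv = times * flow_rate / pore_volume

    analyte = str(df["analyte"].iloc[0]) if "analyte" in df.columns else "TCA"
    column_id = str(df["column_id"].iloc[0]) if "column_id" in df.columns else ""
    return BreakthroughCurve(times, pv, conc, analyte=analyte, column_id=column_id)


def write_btc(curve: BreakthroughCurve, path, *, seed=None, comments=()) -> None:
    """Write a breakthrough curve CSV with schema/seed comment headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# schema = {BTC_SCHEMA}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    lines.extend(f"# {c}" for c in comments)
    df = pd.DataFrame(
        {
            "time_d": curve.times,
            "pore_volumes": curve.pore_volumes,
            "conc_mg_per_L": curve.concentrations,
            "analyte": curve.analyte,
            "column_id": curve.column_id,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_wells_csv(records, path, *, seed=None) -> None:
    """Write well series as ``well_id, time_d, conc_mg_per_L``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"well_id": r.well_id, "time_d": r.times, "conc_mg_per_L": r.concentrations}
        )
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        pd.concat(frames).to_csv(fh, index=False, float_format="%.12g")


def write_plume_csv(states, path, *, min_conc: float = 1e-6, seed=None) -> None:
    """Long-format gridded output ``time_d, layer, row, col, conc_mg_per_L``.

    Cells below ``min_conc`` are omitted to keep files reviewable.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in states:
        ll, rr, cc = np.nonzero(st.concentration >= min_conc)
        rows.append(
            pd.DataFrame(
                {
                    "time_d": st.time,
                    "layer": ll,
                    "row": rr,
                    "col": cc,
                    "conc_mg_per_L": st.concentration[ll, rr, cc],
                }
            )
        )
    out = pd.concat(rows) if rows else pd.DataFrame(
        columns=["time_d", "layer", "row", "col", "conc_mg_per_L"]
    )
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        out.to_csv(fh, index=False, float_format="%.8g")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialise {type(x)}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Flat configuration keys, their defaults, and meaning.  CLI flags override
#: file values; every run writes the fully resolved config next to outputs.
CONFIG_DEFAULTS = {
    "seed": 0,                              # master random seed
    # column geometry & packing
    "length_m": 0.30,
    "inner_diameter_m": 0.10,
    "porosity_biotic": 0.296,
    "porosity_control": 0.289,
    "bulk_density_biotic_kg_m3": 1850.0,
    "bulk_density_control_kg_m3": 1880.0,
    "flow_rate_ml_min": 0.1,
    # transport / reaction
    "dispersivity_m": 0.005,
    "sorption_coeff_m3_kg": 6.8e-5,
    "sorption_rate_per_d": 0.1,             # 'equilibrium' for the instant limit
    "decay_per_d": 0.0045,
    # experiment / generator
    "inlet_mean_mg_L": 31.36,
    "inlet_sd_mg_L": 1.87,
    "duration_d": 25.0,
    "sampling_interval_d": 2.0,
    "noise_fraction": 0.05,
    "tracer_conc_g_L": 3.0,
    "tracer_duration_pv": 3.0,
    "tracer_noise_fraction": 0.02,
    # column numerics
    "nx": 200,
    "courant": 0.5,
    "scheme": "hybrid",
    # site grid & flow
    "site_nx": 100,
    "site_ny": 100,
    "site_nlayers": 4,
    "layer_thickness_m": 2.0,
    "conductivity_m_d": 0.1944,             # horizontal K (10x measured vertical)
    "vertical_anisotropy": 10.0,
    "site_porosity": 0.296,
    "head_west_m": 10.0,
    "head_east_m": 9.8,
    # site transport
    "longitudinal_dispersivity_m": 1.0,
    "transverse_dispersivity_m": 0.1,
    "kernel_scale_m": 8.0,
    "output_times_d": [1.0, 183.0, 365.0, 730.0, 1825.0],
}


class RunConfig:
    """Flat, validated run configuration with attribute access.

    Unknown keys are rejected so typos fail loudly.
    """

    def __init__(self, **overrides) -> None:
        unknown = set(overrides) - set(CONFIG_DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        self._values = dict(CONFIG_DEFAULTS)
        self._values.update({k: v for k, v in overrides.items() if v is not None})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls(**data)

    def to_yaml(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self._values, fh, sort_keys=True)

    def __getattr__(self, name):
        try:
            return self._values[name]
        except KeyError as exc:  # pragma: no cover - defensive
            raise AttributeError(name) from exc

    def asdict(self) -> dict:
        return dict(self._values)

    # convenience builders ---------------------------------------------------

    def column_spec(self, which: str) -> ColumnSpec:
        from .column import ML_PER_MIN_TO_M3_PER_DAY

        if which not in ("biotic", "control"):
            raise ValidationError("which must be 'biotic' or 'control'")
        return ColumnSpec(
            length=self.length_m,
            inner_diameter=self.inner_diameter_m,
            porosity=getattr(self, f"porosity_{which}"),
            bulk_density=getattr(self, f"bulk_density_{which}_kg_m3"),
            flow_rate=self.flow_rate_ml_min * ML_PER_MIN_TO_M3_PER_DAY,
            column_id="1" if which == "biotic" else "2",
        )

    @property
    def sorption_rate(self) -> float:
        value = self.sorption_rate_per_d
        if value == "equilibrium":
            from .column import EQUILIBRIUM

            return EQUILIBRIUM
        return float(value)
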