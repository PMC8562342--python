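"""Fermentation time-course data model and derived quantities.

The central container is :class:`FermentationDataset`: a tidy long-format
table of concentration measurements (strain x replicate x time x analyte),
from which the two downstream stages derive their inputs —

* nitrogen *utilization* (concentration consumed since inoculation), the
  predictor block of the chemometric stage, and
* specific exchange fluxes over an exponential-phase window
  (mmol / gDW / h, uptake negative), the constraints of the modelling stage.

Utilization is the difference between the concentration at inoculation and
at a sampled time point; no interpolation is performed there, mirroring how
fermentation samples are actually taken.  Depletion times, by contrast, are
threshold crossings and *are* linearly interpolated between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_UNITS",
    "NITROGEN_VARIABLES",
    "SchemaError",
    "ValidationError",
    "MediumSpec",
    "FermentationDataset",
    "UtilizationMatrix",
    "FluxMeasurements",
    "read_fermentation_csv",
    "write_fermentation_csv",
    "compute_utilization",
    "depletion_time",
    "nitrogen_group",
    "od_to_dcw",
    "estimate_exchange_fluxes",
    "build_utilization_matrix",
]

ALLOWED_UNITS = {"g/L", "mg/L", "µg/L", "Brix", "OD600", "gDW/L"}
_UNIT_ALIASES = {"ug/L": "µg/L", "od600": "OD600", "brix": "Brix"}

REQUIRED_COLUMNS = ["strain", "replicate", "time_h", "analyte", "value", "unit"]

#: The 18 nitrogen predictor variables used in the regression stage:
#: ammonia plus 17 amino-acid variables with arginine and glutamine merged
#: (they co-elute chromatographically and are treated as one pool).
#: Proline is excluded because wine yeast do not assimilate it anaerobically,
#: and cysteine is excluded from the predictor set.
NITROGEN_VARIABLES = [
    "NH3", "Ala", "Arg/Gln", "Asn", "Asp", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Ser", "Thr", "Trp", "Tyr", "Val",
]


class SchemaError(ValueError):
    """A required column or key is missing or mistyped."""


class ValidationError(ValueError):
    """Rows violate the dataset invariants (with offending rows listed)."""


@dataclass
class MediumSpec:
    """Composition of the fermentation medium.

    yan_mg_per_L is yeast assimilable nitrogen: ammonium-N plus free
    amino-acid N excluding proline.  A mismatch between the declared YAN and
    the sum over components is reported as a warning, not an error, because
    YAN assays and amino-acid panels rarely agree exactly.
    """

    sugars: dict[str, float] = field(default_factory=dict)  # g/L
    yan_mg_per_L: float = 0.0
    ammonium_mg_per_L: float = 0.0
    amino_acids: dict[str, float] = field(default_factory=dict)  # mg/L
    pH: float = 3.25

    #: mg N per mg compound, ammonium; amino-acid N content varies and the
    #: consistency check uses a coarse 1 N per residue accounting.
    _N_FRACTION_NH4 = 14.0 / 18.0

    def __post_init__(self) -> None:
        for name, conc in {**self.sugars, **self.amino_acids}.items():
            if conc < 0:
                raise ValidationError(f"negative concentration for {name!r}: {conc}")
        if self.yan_mg_per_L < 0 or self.ammonium_mg_per_L < 0:
            raise ValidationError("YAN and ammonium concentrations must be >= 0")

    def check_yan_consistency(self, rel_tol: float = 0.25) -> bool:
        """Warn (never raise) if declared YAN is far from the component sum."""
        if not self.amino_acids or self.yan_mg_per_L <= 0:
            return True
        # coarse N accounting: NH4-N plus ~10% of amino-acid mass as alpha-N
        approx = self.ammonium_mg_per_L * self._N_FRACTION_NH4 + 0.10 * sum(
            c for a, c in self.amino_acids.items() if a != "Pro"
        )
        ok = abs(approx - self.yan_mg_per_L) <= rel_tol * self.yan_mg_per_L
        if not ok:
            warnings.warn(
                f"declared YAN {self.yan_mg_per_L:.0f} mg N/L vs ~{approx:.0f} "
                "mg N/L from components",
                stacklevel=2,
            )
        return ok


class FermentationDataset:
    """Long-format concentration time series with validation.

    Parameters
    ----------
    records
        DataFrame with columns strain, replicate, time_h, analyte, value,
        unit.  Within each (strain, replicate, analyte) series, times must
        be unique, include 0, and concentrations must be non-negative; the
        unit must be constant per analyte.
    medium
        Optional :class:`MediumSpec` metadata.
    assay_corrected
        Analytes whose series were reconciled across two assays (in this
        study ammonia, measured both by UPLC and an enzymatic kit).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        medium: MediumSpec | None = None,
        assay_corrected: set[str] | None = None,
    ) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = records.loc[:, REQUIRED_COLUMNS].copy()
        df["unit"] = df["unit"].replace(_UNIT_ALIASES)
        self._validate(df)
        df = df.sort_values(["strain", "replicate", "analyte", "time_h"], kind="stable")
        self.records = df.reset_index(drop=True)
        self.medium = medium
        self.assay_corrected = set(assay_corrected or ())

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_unit = df.index[~df["unit"].isin(ALLOWED_UNITS)].tolist()
        if bad_unit:
            raise ValidationError(f"unknown unit in rows {bad_unit[:10]}")
        neg = df.index[(df["value"] < 0) & ~df["unit"].isin({"Brix"})].tolist()
        if neg:
            raise ValidationError(f"negative concentration in rows {neg[:10]}")
        if (df["time_h"] < 0).any():
            rows = df.index[df["time_h"] < 0].tolist()
            raise ValidationError(f"negative time in rows {rows[:10]}")
        if (df["replicate"] < 1).any():
            rows = df.index[df["replicate"] < 1].tolist()
            raise ValidationError(f"replicate < 1 in rows {rows[:10]}")
        for (strain, rep, analyte), grp in df.groupby(
            ["strain", "replicate", "analyte"], sort=False
        ):
            if grp["time_h"].duplicated().any():
                raise ValidationError(
                    f"duplicate times for ({strain}, {rep}, {analyte})"
                )
            if 0.0 not in set(grp["time_h"]):
                raise ValidationError(
                    f"series ({strain}, {rep}, {analyte}) lacks time 0"
                )
            if grp["unit"].nunique() != 1:
                raise ValidationError(
                    f"inconsistent units for ({strain}, {rep}, {analyte})"
                )

    # -- access -----------------------------------------------------------
    @property
    def strains(self) -> list[str]:
        return sorted(self.records["strain"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.records["analyte"].unique())

    def replicates(self, strain: str) -> list[int]:
        sel = self.records[self.records["strain"] == strain]
        return sorted(sel["replicate"].unique())

    def series(
        self, strain: str, replicate: int, analyte: str
    ) -> tuple[np.ndarray, np.ndarray, str]:
        """Return (times_h, values, unit) for one series, times ascending."""
        sel = self.records[
            (self.records["strain"] == strain)
            & (self.records["replicate"] == replicate)
            & (self.records["analyte"] == analyte)
        ]
        if sel.empty:
            raise KeyError(f"no series for ({strain!r}, {replicate}, {analyte!r})")
        sel = sel.sort_values("time_h")
        return (
            sel["time_h"].to_numpy(float),
            sel["value"].to_numpy(float),
            sel["unit"].iloc[0],
        )

    def _single_series_key(self, analyte: str) -> tuple[str, int]:
        sel = self.records[self.records["analyte"] == analyte]
        if sel.empty:
            raise KeyError(f"analyte {analyte!r} not in dataset")
        keys = sel[["strain", "replicate"]].drop_duplicates()
        if len(keys) != 1:
            raise ValueError(
                f"analyte {analyte!r} has {len(keys)} series; pass strain and "
                "replicate explicitly"
            )
        return keys.iloc[0]["strain"], int(keys.iloc[0]["replicate"])


@dataclass
class UtilizationMatrix:
    """Paired predictor/response blocks for the regression stage.

    X holds nitrogen utilization (mg/L consumed since inoculation) and Y the
    matched response concentrations (biomass in gDW/L or VOCs in µg/L) at
    the same (strain, replicate, time) rows.
    """

    row_ids: list[tuple[str, int, float]]
    columns: list[str]
    X: np.ndarray
    Y: np.ndarray
    y_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValidationError("X contains non-finite entries")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError("X and Y row counts differ")
        if self.X.shape[1] != len(self.columns):
            raise ValidationError("X column count does not match column names")
        for i, (_, _, t) in enumerate(self.row_ids):
            if t == 0 and not np.allclose(self.X[i], 0.0):
                raise ValidationError(f"utilization row at t=0 not all zero (row {i})")


@dataclass
class FluxMeasurements:
    """Specific exchange rates over a time window (mmol/gDW/h).

    Sign convention: uptake negative, secretion positive (COBRA convention).
    """

    window: tuple[float, float]
    values: dict[str, float]
    biomass_mean_gDW_per_L: float
    molar_masses: dict[str, float]

    def __post_init__(self) -> None:
        t1, t2 = self.window
        if not t2 > t1:
            raise ValidationError(f"window end {t2} must exceed start {t1}")
        for analyte, q in self.values.items():
            if not np.isfinite(q):
                raise ValidationError(f"non-finite rate for {analyte!r}")


# -- I/O -------------------------------------------------------------------

def read_fermentation_csv(
    path: str | Path,
    schema: dict[str, str] | None = None,
    medium: MediumSpec | None = None,
) -> FermentationDataset:
    """Read a tidy fermentation CSV into a validated dataset.

    ``schema`` maps the file's column names onto the canonical ones, e.g.
    ``{"sample_time": "time_h"}``; identity by default.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    return FermentationDataset(df, medium=medium)


def write_fermentation_csv(ds: FermentationDataset, path: str | Path) -> None:
    ds.records.to_csv(path, index=False)


# -- derived quantities ----------------------------------------------------

def _resolve(ds: FermentationDataset, analyte, strain, replicate):
    if strain is None or replicate is None:
        strain, replicate = ds._single_series_key(analyte)
    return ds.series(strain, replicate, analyte)


def compute_utilization(
    ds: FermentationDataset,
    analyte: str,
    t: float,
    strain: str | None = None,
    replicate: int | None = None,
) -> float:
    """Concentration consumed since inoculation: ``C(0) - C(t)``.

    ``t`` must be an exactly sampled time (no interpolation).  The result
    may be negative: net excretion back into the medium is retained, as is
    seen for some amino acids in stationary phase.
    """
    times, values, _ = _resolve(ds, analyte, strain, replicate)
    hits = np.flatnonzero(np.isclose(times, t))
    if hits.size == 0:
        below = times[times < t]
        above = times[times > t]
        near = []
        if below.size:
            near.append(f"{below.max():g} h")
        if above.size:
            near.append(f"{above.min():g} h")
        raise ValueError(
            f"t={t:g} h is not a sampled time for {analyte!r}; nearest sampled "
            f"time(s): {', '.join(near)}"
        )
    c0 = values[np.flatnonzero(np.isclose(times, 0.0))[0]]
    return float(c0 - values[hits[0]])


def depletion_time(
    ds: FermentationDataset,
    analyte: str,
    fraction: float = 0.95,
    strain: str | None = None,
    replicate: int | None = None,
) -> float | None:
    """Earliest time at which ``fraction`` of the initial concentration has
    been consumed, linearly interpolated between samples; None if never.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    times, values, _ = _resolve(ds, analyte, strain, replicate)
    if times.size < 2:
        raise ValueError(f"series for {analyte!r} has fewer than 2 points")
    c0 = values[0]
    if c0 == 0:
        warnings.warn(
            f"{analyte!r} starts at 0; depletion time undefined", stacklevel=2
        )
        return None
    util = c0 - values
    target = fraction * c0
    for i in range(times.size):
        if util[i] >= target:
            if i == 0:
                return float(times[0])
            du = util[i] - util[i - 1]
            if du <= 0:  # jumped over the target at a flat segment
                return float(times[i])
            frac = (target - util[i - 1]) / du
            return float(times[i - 1] + frac * (times[i] - times[i - 1]))
    return None


def nitrogen_group(t95: float | None) -> str | None:
    """Assign the consumption-timing group from a 95%-utilization time.

    I: depleted by 28 h; II: by 44 h; III: by 72 h; IV: only after 96 h.
    Times in (72, 96] h fall between the named groups and return None, as
    does a compound never reaching 95% utilization.
    """
    if t95 is None:
        return None
    if t95 <= 28:
        return "I"
    if t95 <= 44:
        return "II"
    if t95 <= 72:
        return "III"
    if t95 > 96:
        return "IV"
    return None


def od_to_dcw(
    od: np.ndarray | float, slope: float, intercept: float = 0.0
) -> np.ndarray | float:
    """Optical density (600 nm) to dry cell weight via a strain calibration
    line; negative outputs are clipped to 0 with a warning.
    """
    if slope <= 0:
        raise ValueError("calibration slope must be > 0")
    dcw = np.asarray(od, dtype=float) * slope + intercept
    if np.any(dcw < 0):
        warnings.warn("calibration yields negative biomass; clipping to 0",
                      stacklevel=2)
        dcw = np.clip(dcw, 0.0, None)
    return float(dcw) if np.isscalar(od) else dcw


_TO_G_PER_L = {"g/L": 1.0, "mg/L": 1e-3, "µg/L": 1e-6, "gDW/L": 1.0}


def estimate_exchange_fluxes(
    ds: FermentationDataset,
    window: tuple[float, float],
    molar_masses: dict[str, float],
    analytes: list[str],
    biomass_analyte: str = "biomass",
    strain: str | None = None,
    replicate: int | None = None,
) -> FluxMeasurements:
    """Finite-difference specific exchange rates over a sampling window.

    q_i = ΔC_i / (M_i * X̄ * Δt) with X̄ the trapezoidal-mean biomass over
    the window; concentrations are converted to g/L, so q is in mmol/gDW/h
    and consumption gives q < 0.
    """
    t1, t2 = window
    if not t2 > t1:
        raise ValidationError("window end must exceed start")
    bt, bx, bunit = _resolve(ds, biomass_analyte, strain, replicate)
    if bunit != "gDW/L":
        raise ValidationError(f"biomass series must be gDW/L, got {bunit}")
    inwin = (bt >= t1) & (bt <= t2)
    if not (np.any(np.isclose(bt, t1)) and np.any(np.isclose(bt, t2))):
        raise ValueError("both window endpoints must be sampled times")
    xbar = float(np.trapezoid(bx[inwin], bt[inwin]) / (t2 - t1))
    if xbar == 0:
        raise ValueError("mean biomass over the window is zero")

    rates: dict[str, float] = {}
    for analyte in analytes:
        if analyte not in molar_masses:
            raise ValueError(f"no molar mass given for {analyte!r}")
        times, values, unit = _resolve(ds, analyte, strain, replicate)
        if unit not in _TO_G_PER_L:
            raise ValidationError(f"cannot convert unit {unit!r} to g/L")
        i1 = np.flatnonzero(np.isclose(times, t1))
        i2 = np.flatnonzero(np.isclose(times, t2))
        if i1.size == 0 or i2.size == 0:
            raise ValueError(f"{analyte!r} not sampled at both window endpoints")
        dc = (values[i2[0]] - values[i1[0]]) * _TO_G_PER_L[unit]  # g/L
        q = dc * 1000.0 / (molar_masses[analyte] * xbar * (t2 - t1))
        rates[analyte] = float(q)
    return FluxMeasurements(
        window=(t1, t2),
        values=rates,
        biomass_mean_gDW_per_L=xbar,
        molar_masses=dict(molar_masses),
    )


def build_utilization_matrix(
    ds: FermentationDataset,
    times: list[float],
    responses: list[str],
    nitrogen_analytes: list[str] | None = None,
    merge_arg_gln: bool = True,
) -> UtilizationMatrix:
    """Assemble the pooled predictor/response blocks.

    Rows are ordered strain-major, then replicate, then time — a fixed,
    documented ordering, because interleaved (Venetian-blinds) CV folds
    depend on row order.  Arg and Gln utilizations are summed into one
    merged ``Arg/Gln`` column by default.
    """
    if nitrogen_analytes is None:
        nitrogen_analytes = [v for v in NITROGEN_VARIABLES if v != "Arg/Gln"]
        if merge_arg_gln:
            nitrogen_analytes += ["Arg", "Gln"]
    columns = list(NITROGEN_VARIABLES) if merge_arg_gln else list(nitrogen_analytes)

    row_ids: list[tuple[str, int, float]] = []
    xrows: list[list[float]] = []
    yrows: list[list[float]] = []
    for strain in ds.strains:
        for rep in ds.replicates(strain):
            for t in times:
                util = {
                    a: compute_utilization(ds, a, t, strain=strain, replicate=rep)
                    for a in nitrogen_analytes
                }
                if merge_arg_gln:
                    util["Arg/Gln"] = util.pop("Arg", 0.0) + util.pop("Gln", 0.0)
                xrows.append([util[c] for c in columns])
                yvals = []
                for resp in responses:
                    times_r, values_r, _ = ds.series(strain, rep, resp)
                    hit = np.flatnonzero(np.isclose(times_r, t))
                    if hit.size == 0:
                        raise ValueError(f"{resp!r} not sampled at t={t:g} h")
                    yvals.append(float(values_r[hit[0]]))
                yrows.append(yvals)
                row_ids.append((strain, rep, float(t)))
    return UtilizationMatrix(
        row_ids=row_ids,
        columns=columns,
        X=np.asarray(xrows),
        Y=np.asarray(yrows),
        y_names=list(responses),
    )
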