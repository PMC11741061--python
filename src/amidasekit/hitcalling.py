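"""Control-referenced hit calling for enzyme substrate screens.

Raw readouts come from two assay routes:

* **HPLC**: substrate peak areas measured at the start (t0) and end (t24)
  of the incubation.  The statistic is the *relative removal*, the percent
  decrease of the peak area.
* **Colorimetric plate reader**: optical-density (OD) time series tracking
  chromophore release, read against a complete-turnover reference solution
  and expressed as a percent *yield*.

Both routes are anchored on a catalytically inactivated enzyme variant
(triad serine to alanine) carried through every assay as the negative
control.  A candidate/substrate pair is a hit only if it clears the
control-derived statistic for its route:

* HPLC: median removal strictly greater than ``median + m x IQR`` of the
  control removals (outlier-filtered with Tukey fences), *and* median
  removal above an absolute floor (default 50 %).
* Plate: mean yield at a substrate-specific evaluation time at least
  ``k`` control standard deviations above the control mean (default k=2);
  4-nitrophenyl esters additionally require a mean yield above 30 % to
  guard against their appreciable self-hydrolysis.

The long-format measurement table is a :class:`pandas.DataFrame` with
columns ``enzyme_id, substrate_id, replicate, route, time, value,
is_control, is_reference``.  HPLC rows use ``time`` in hours (0 and 24);
plate rows use minutes.  Reference rows (``is_reference``) carry the
complete-turnover OD for a substrate and are not attributed to an enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

HPLC = "hplc"
COLORIMETRIC = "colorimetric"

MEASUREMENT_COLUMNS = [
    "enzyme_id",
    "substrate_id",
    "replicate",
    "route",
    "time",
    "value",
    "is_control",
    "is_reference",
]


class HitCallingError(ValueError):
    """Raised when inputs violate the hit-calling contracts."""


class HitCallingConfig(BaseModel):
    """Thresholds and per-substrate settings for hit calling.

    ``control_fence_multiplier`` governs Tukey outlier removal on control
    replicates; ``hit_iqr_multiplier`` is the multiplier in the
    ``median + m x IQR`` hit condition.  Both default to 1.5 but are
    distinct rules.  ``evaluation_times`` maps each colorimetric substrate
    to the minute at which its yield is judged, chosen per substrate to
    account for self-hydrolysis and differing reaction rates.
    """

    model_config = {"extra": "forbid"}

    hplc_removal_threshold: float = 50.0
    control_fence_multiplier: float = 1.5
    hit_iqr_multiplier: float = 1.5
    plate_sd_multiplier: float = 2.0
    ester_yield_threshold: float = 30.0
    evaluation_times: dict[str, float] = Field(default_factory=dict)
    ester_substrates: list[str] = Field(default_factory=list)
    control_enzyme_id: str = "CTRL-S146A"

    @field_validator(
        "hplc_removal_threshold",
        "control_fence_multiplier",
        "hit_iqr_multiplier",
        "plate_sd_multiplier",
        "ester_yield_threshold",
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("hit-calling thresholds must be positive")
        return v


@dataclass
class ActivityMatrix:
    """Binary enzymes x substrates hit matrix with per-cell provenance.

    ``values`` is a 0/1 integer DataFrame indexed by enzyme id with one
    column per substrate.  ``provenance`` maps ``(enzyme_id,
    substrate_id)`` to the route, statistics and thresholds that decided
    the cell.  ``dropped_enzymes`` lists rows removed by the
    active-with-at-least-one-substrate inclusion rule.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    dropped_enzymes: list = field(default_factory=list)

    @property
    def enzyme_ids(self) -> list:
        return list(self.values.index)

    @property
    def substrate_ids(self) -> list:
        return list(self.values.columns)

    def n_cells(self) -> int:
        return int(self.values.size)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="enzyme_id")

    @classmethod
    def from_csv(cls, path) -> "ActivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.astype(int))


# ---------------------------------------------------------------------------
# Per-sample statistics
# ---------------------------------------------------------------------------

def relative_removal(area_t0, area_t24):
    """Percent decrease of a substrate peak area between t0 and t24.

    ``100 * (A_t0 - A_t24) / A_t0``.  Negative values (area increase) are
    preserved; nothing is clamped.  Accepts scalars or arrays.
    """
    a0 = np.asarray(area_t0, dtype=float)
    a24 = np.asarray(area_t24, dtype=float)
    if np.any(a0 <= 0):
        bad = np.argwhere(np.atleast_1d(a0) <= 0).ravel()
        raise HitCallingError(
            f"relative removal undefined for non-positive t0 area at sample index {bad[0]}"
        )
    out = 100.0 * (a0 - a24) / a0
    if np.isscalar(area_t0):
        return float(out)
    return out


def compute_yield(od_sample, od_reference):
    """Product yield as percent of the complete-turnover reference OD."""
    ref = np.asarray(od_reference, dtype=float)
    if np.any(ref <= 0):
        raise HitCallingError("yield undefined for non-positive reference OD")
    out = 100.0 * np.asarray(od_sample, dtype=float) / ref
    if np.isscalar(od_sample):
        return float(out)
    return out


def filter_control_outliers(control_removals, multiplier: float = 1.5):
    """Drop control replicates outside the Tukey fences.

    Fences are ``[Q1 - m*IQR, Q3 + m*IQR]`` with linearly interpolated
    (type-7) quartiles.  Returns ``(kept, removed)`` as float arrays.
    Requires at least three replicates for the fences to be meaningful.
    """
    values = np.asarray(control_removals, dtype=float)
    if values.size < 3:
        raise HitCallingError(
            f"need >=3 control replicates to compute Tukey fences, got {values.size}"
        )
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


# ---------------------------------------------------------------------------
# HPLC route
# ---------------------------------------------------------------------------

def removal_records(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate relative removals from long-format HPLC rows.

    Pairs the t0 and t24 areas of each (enzyme, substrate, replicate) and
    returns columns ``enzyme_id, substrate_id, replicate, is_control,
    relative_removal``.
    """
    hplc = measurements[measurements["route"] == HPLC]
    if hplc.empty:
        return pd.DataFrame(
            columns=["enzyme_id", "substrate_id", "replicate", "is_control", "relative_removal"]
        )
    keys = ["enzyme_id", "substrate_id", "replicate", "is_control"]
    wide = hplc.pivot_table(index=keys, columns="time", values="value").reset_index()
    t0, t24 = sorted(c for c in wide.columns if c not in keys)
    wide["relative_removal"] = relative_removal(wide[t0].to_numpy(), wide[t24].to_numpy())
    return wide[keys + ["relative_removal"]]


def call_hplc_hits(removals: pd.DataFrame, cfg: HitCallingConfig) -> pd.DataFrame:
    """Apply the two HPLC hit conditions per (enzyme, substrate) pair.

    hit <=> median(sample removals) > median(control) + m*IQR(control)
    and median(sample removals) > the absolute removal threshold.
    Control statistics are computed per substrate after Tukey outlier
    filtering.  Returns one row per pair with the decision and the
    statistics that produced it.
    """
    decisions = []
    for substrate_id, sub in removals.groupby("substrate_id", sort=True):
        ctrl = sub[sub["is_control"]]["relative_removal"].to_numpy()
        if ctrl.size == 0:
            raise HitCallingError(f"no control removals for substrate {substrate_id!r}")
        kept, removed = filter_control_outliers(ctrl, cfg.control_fence_multiplier)
        q1, q3 = np.percentile(kept, [25, 75])
        control_stat = float(np.median(kept)) + cfg.hit_iqr_multiplier * (q3 - q1)
        samples = sub[~sub["is_control"]]
        medians = samples.groupby("enzyme_id", sort=True)["relative_removal"].median()
        for enzyme_id, med in medians.items():
            decisions.append(
                {
                    "enzyme_id": enzyme_id,
                    "substrate_id": substrate_id,
                    "route": HPLC,
                    "hit": int(med > control_stat and med > cfg.hplc_removal_threshold),
                    "sample_statistic": float(med),
                    "control_statistic": control_stat,
                    "absolute_threshold": cfg.hplc_removal_threshold,
                    "n_control_outliers_removed": int(removed.size),
                }
            )
    return pd.DataFrame(decisions)


# ---------------------------------------------------------------------------
# Colorimetric route
# ---------------------------------------------------------------------------

def call_plate_hits(measurements: pd.DataFrame, cfg: HitCallingConfig) -> pd.DataFrame:
    """Call hits on colorimetric substrates at their evaluation times.

    Per-replicate yields are ODs at the substrate's configured evaluation
    time divided by the mean complete-turnover reference OD at that time.
    hit <=> mean(sample yields) >= mean(control yields) +
    k*SD(control yields) and mean(sample) > mean(control); 4-nitrophenyl
    esters additionally require mean yield above the ester floor.  The
    strict mean comparison only matters for the degenerate zero-variance
    control ("at least k SD *higher*" read as a positive margin).

    The evaluation time must be present on the measured time grid; no
    interpolation is performed.
    """
    plate = measurements[measurements["route"] == COLORIMETRIC]
    decisions = []
    for substrate_id, sub in plate.groupby("substrate_id", sort=True):
        if substrate_id not in cfg.evaluation_times:
            raise HitCallingError(f"no evaluation time configured for substrate {substrate_id!r}")
        t_eval = cfg.evaluation_times[substrate_id]
        at_t = sub[sub["time"] == t_eval]
        if at_t.empty:
            grid = sorted(sub["time"].unique())
            raise HitCallingError(
                f"evaluation time {t_eval} min for substrate {substrate_id!r} is not on the "
                f"measured time grid {grid}; no interpolation is performed"
            )
        ref = at_t[at_t["is_reference"]]["value"].to_numpy()
        if ref.size == 0:
            raise HitCallingError(
                f"no complete-turnover reference series for substrate {substrate_id!r}"
            )
        ref_od = float(np.mean(ref))
        ctrl = at_t[at_t["is_control"] & ~at_t["is_reference"]]
        if ctrl.empty:
            raise HitCallingError(f"no control replicates for substrate {substrate_id!r}")
        ctrl_yields = compute_yield(ctrl["value"].to_numpy(), ref_od)
        ctrl_mean = float(np.mean(ctrl_yields))
        ctrl_sd = float(np.std(ctrl_yields, ddof=1)) if ctrl_yields.size > 1 else 0.0
        threshold = ctrl_mean + cfg.plate_sd_multiplier * ctrl_sd
        is_ester = substrate_id in cfg.ester_substrates
        samples = at_t[~at_t["is_control"] & ~at_t["is_reference"]]
        means = samples.groupby("enzyme_id", sort=True)["value"].apply(
            lambda od: float(np.mean(compute_yield(od.to_numpy(), ref_od)))
        )
        for enzyme_id, mean_yield in means.items():
            hit = mean_yield >= threshold and mean_yield > ctrl_mean
            if is_ester:
                hit = hit and mean_yield > cfg.ester_yield_threshold
            decisions.append(
                {
                    "enzyme_id": enzyme_id,
                    "substrate_id": substrate_id,
                    "route": COLORIMETRIC,
                    "hit": int(hit),
                    "sample_statistic": mean_yield,
                    "control_statistic": threshold,
                    "absolute_threshold": cfg.ester_yield_threshold if is_ester else float("nan"),
                    "evaluation_time": t_eval,
                }
            )
    return pd.DataFrame(decisions)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_activity_matrix(
    hplc_decisions: pd.DataFrame,
    plate_decisions: pd.DataFrame,
    drop_inactive_enzymes: bool = False,
) -> ActivityMatrix:
    """Merge both routes into one binary matrix over the full grid.

    Raises on conflicting duplicate decisions for a pair.  When
    ``drop_inactive_enzymes`` is set, enzymes active on no substrate are
    removed (the modelling inclusion rule) and recorded in
    ``dropped_enzymes``.
    """
    frames = [d for d in (hplc_decisions, plate_decisions) if d is not None and len(d)]
    if not frames:
        raise HitCallingError("no hit decisions to assemble")
    decisions = pd.concat(frames, ignore_index=True)
    dup = decisions.groupby(["enzyme_id", "substrate_id"])["hit"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        pair = conflicts.index[0]
        raise HitCallingError(f"conflicting duplicate decisions for pair {pair}")
    decisions = decisions.drop_duplicates(["enzyme_id", "substrate_id"])
    matrix = (
        decisions.pivot(index="enzyme_id", columns="substrate_id", values="hit")
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    if matrix.isna().any().any():
        missing = matrix.stack(dropna=False)
        pair = missing[missing.isna()].index[0]
        raise HitCallingError(f"decision grid incomplete: no decision for pair {pair}")
    matrix = matrix.astype(int)
    provenance = {
        (r.enzyme_id, r.substrate_id): {
            k: getattr(r, k)
            for k in ("route", "sample_statistic", "control_statistic", "absolute_threshold")
            if hasattr(r, k)
        }
        for r in decisions.itertuples()
    }
    dropped: list = []
    if drop_inactive_enzymes:
        inactive = matrix.sum(axis=1) == 0
        dropped = list(matrix.index[inactive])
        matrix = matrix.loc[~inactive]
        if matrix.empty:
            import warnings

            warnings.warn(
                "all enzymes inactive; activity matrix is empty "
                f"(dropped: {', '.join(map(str, dropped))})",
                stacklevel=2,
            )
    return ActivityMatrix(values=matrix, provenance=provenance, dropped_enzymes=dropped)


def call_hits(
    measurements: pd.DataFrame,
    cfg: HitCallingConfig,
    drop_inactive_enzymes: bool = False,
) -> ActivityMatrix:
    """End-to-end hit calling: removals, both routes, assembly."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise HitCallingError(f"measurement table lacks columns: {missing}")
    removals = removal_records(measurements)
    hplc = call_hplc_hits(removals, cfg) if len(removals) else pd.DataFrame()
    plate = (
        call_plate_hits(measurements, cfg)
        if (measurements["route"] == COLORIMETRIC).any()
        else pd.DataFrame()
    )
    return assemble_activity_matrix(hplc, plate, drop_inactive_enzymes=drop_inactive_enzymes)
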