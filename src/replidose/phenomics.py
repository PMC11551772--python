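"""Biolog Phenotype Microarray analysis.

PM plates (PM1–PM20) read out respiration of a strain in 96 conditions
per plate as reduction of a tetrazolium dye (OD590) over time.  The
summary statistic per well is the area under the kinetic curve (AUC).
Two strains are compared by plotting the replicate-mean AUC of one
against the other: wells on the bisector ``y = x`` behave identically,
and a well is *flagged* as a candidate phenotype when (i) one strain's
mean AUC is at least double the other's and (ii) the error bars do not
cross the bisector, i.e. the axis-aligned error cross centred on the
point does not touch ``y = x`` — equivalently
``|mean_wt - mean_mut| > e_wt + e_mut``.

Whether the error bar is the standard deviation or the standard error
is selectable (``error_bar``); both conventions appear in practice and
the flag rule is sensitive to the choice, so it is never silently
resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticSeries

__all__ = [
    "PMWell",
    "PMComparison",
    "well_auc",
    "compare_pm",
    "flag_differences",
    "bisector_clearance",
    "read_kinetics_csv",
    "read_platemap_csv",
    "long_from_wide",
    "compare_all",
]

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


@dataclass(frozen=True)
class PMWell:
    """One well's kinetic trace for one strain replicate."""

    plate: str
    well: str
    compound: str
    strain: str
    replicate: int
    series: KineticSeries

    def __post_init__(self) -> None:
        if not _WELL_RE.match(self.well):
            raise ValueError(f"invalid 96-well id {self.well!r}")


@dataclass(frozen=True)
class PMComparison:
    """WT-vs-mutant AUC comparison for one well."""

    plate: str
    well: str
    compound: str
    mean_auc_wt: float
    mean_auc_mut: float
    sd_wt: float
    sd_mut: float
    se_wt: float
    se_mut: float
    n_wt: int
    n_mut: int
    ratio: float
    direction: str  # "mutant_higher" | "wt_higher" | "none"
    flagged: bool = False


def well_auc(series: KineticSeries, baseline: str = "first_reading") -> float:
    """Trapezoidal AUC of a kinetic trace, in OD·min.

    ``baseline="first_reading"`` subtracts the first OD value before
    integrating (plate-reader convention); ``"none"`` integrates the raw
    signal.  The integral is taken as-is — a trace dipping below its
    baseline can yield a negative contribution, which callers see.
    """
    if baseline not in ("first_reading", "none"):
        raise ValueError("baseline must be 'first_reading' or 'none'")
    v = series.values
    if baseline == "first_reading":
        v = v - v[0]
    return float(np.trapezoid(v, series.time_min))


def compare_pm(
    wt: list[PMWell], mut: list[PMWell], baseline: str = "first_reading"
) -> PMComparison:
    """Aggregate replicate AUCs of two strains for one well.

    Requires >= 2 replicates per strain (assays are run at least in
    duplicate) on the same plate/well/compound.  ``ratio`` is
    max(mean)/min(mean); when the smaller mean is <= 0 the ratio is
    reported as ``inf`` (the two-fold criterion is then trivially met,
    and the error-bar condition does the discriminating).
    """
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need at least two replicates per strain")
    keys = {(w.plate, w.well, w.compound) for w in wt + mut}
    if len(keys) != 1:
        raise ValueError(f"mismatched plate/well/compound between strains: {keys}")
    plate, well, compound = keys.pop()
    auc_wt = np.array([well_auc(w.series, baseline) for w in wt])
    auc_mut = np.array([well_auc(w.series, baseline) for w in mut])
    m_wt, m_mut = float(auc_wt.mean()), float(auc_mut.mean())
    sd_wt = float(auc_wt.std(ddof=1))
    sd_mut = float(auc_mut.std(ddof=1))
    lo, hi = sorted([m_wt, m_mut])
    ratio = float("inf") if lo <= 0 else hi / lo
    if m_wt == m_mut:
        direction = "none"
    else:
        direction = "mutant_higher" if m_mut > m_wt else "wt_higher"
    return PMComparison(
        plate=plate,
        well=well,
        compound=compound,
        mean_auc_wt=m_wt,
        mean_auc_mut=m_mut,
        sd_wt=sd_wt,
        sd_mut=sd_mut,
        se_wt=sd_wt / np.sqrt(len(auc_wt)),
        se_mut=sd_mut / np.sqrt(len(auc_mut)),
        n_wt=len(auc_wt),
        n_mut=len(auc_mut),
        ratio=ratio,
        direction=direction,
    )


def bisector_clearance(
    mean_wt: float, mean_mut: float, e_wt: float, e_mut: float
) -> bool:
    """True when the error cross at ``(mean_wt, mean_mut)`` with
    half-widths ``(e_wt, e_mut)`` stays clear of the bisector ``y = x``;
    closed form: ``|mean_wt - mean_mut| > e_wt + e_mut``."""
    if e_wt < 0 or e_mut < 0:
        raise ValueError("error half-widths must be >= 0")
    return abs(mean_wt - mean_mut) > e_wt + e_mut


def flag_differences(
    comparisons: list[PMComparison], error_bar: str = "sd"
) -> list[PMComparison]:
    """Apply the two-part difference flag and return all comparisons
    with ``flagged`` set (the flagged subset is
    ``[c for c in out if c.flagged]``).

    A well is flagged iff the larger mean AUC is at least double the
    smaller one AND the error bars (``sd`` or ``se`` per ``error_bar``)
    do not cross the bisector.
    """
    if error_bar not in ("sd", "se"):
        raise ValueError("error_bar must be 'sd' or 'se'")
    out = []
    for c in comparisons:
        e_wt = c.sd_wt if error_bar == "sd" else c.se_wt
        e_mut = c.sd_mut if error_bar == "sd" else c.se_mut
        flag = c.ratio >= 2.0 and bisector_clearance(
            c.mean_auc_wt, c.mean_auc_mut, e_wt, e_mut
        )
        out.append(
            PMComparison(
                **{**c.__dict__, "flagged": bool(flag)}
            )
        )
    return out


# ---------------------------------------------------------------------------
# tabular I/O

_KINETICS_COLS = ["plate", "well", "compound", "strain", "replicate", "time_min", "od"]


def read_kinetics_csv(path) -> pd.DataFrame:
    """Long-format kinetics table: one row per reading, columns
    ``plate, well, compound, strain, replicate, time_min, od``."""
    df = pd.read_csv(path)
    missing = [c for c in _KINETICS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"kinetics CSV missing columns {missing}")
    return df


def read_platemap_csv(path) -> pd.DataFrame:
    """Plate map: columns ``plate, well, compound``."""
    df = pd.read_csv(path)
    missing = [c for c in ("plate", "well", "compound") if c not in df.columns]
    if missing:
        raise ValueError(f"plate map CSV missing columns {missing}")
    return df


def long_from_wide(
    wide: pd.DataFrame, plate: str, strain: str, replicate: int, platemap: pd.DataFrame
) -> pd.DataFrame:
    """Reshape a wide plate-reader export (a ``time_min`` column plus one
    column per well) into the long kinetics format."""
    if "time_min" not in wide.columns:
        raise ValueError("wide export needs a 'time_min' column")
    compound = platemap.set_index(["plate", "well"])["compound"]
    rows = wide.melt(id_vars="time_min", var_name="well", value_name="od")
    rows["plate"] = plate
    rows["strain"] = strain
    rows["replicate"] = replicate
    rows["compound"] = [
        compound.get((plate, w), "") for w in rows["well"]
    ]
    return rows[_KINETICS_COLS]


def wells_from_table(df: pd.DataFrame) -> list[PMWell]:
    """Group a long kinetics table into :class:`PMWell` objects."""
    wells = []
    keys = ["plate", "well", "compound", "strain", "replicate"]
    for (plate, well, compound, strain, rep), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("time_min")
        wells.append(
            PMWell(
                str(plate),
                str(well),
                str(compound),
                str(strain),
                int(rep),
                KineticSeries(sub["time_min"].to_numpy(), sub["od"].to_numpy()),
            )
        )
    return wells


def compare_all(
    df: pd.DataFrame,
    wt_strain: str,
    mut_strain: str,
    baseline: str = "first_reading",
    error_bar: str = "sd",
) -> list[PMComparison]:
    """Full screen: build wells, compare every (plate, well) present for
    both strains, and apply the difference flag."""
    wells = wells_from_table(df)
    by_key: dict[tuple[str, str, str], dict[str, list[PMWell]]] = {}
    for w in wells:
        by_key.setdefault((w.plate, w.well, w.compound), {}).setdefault(
            w.strain, []
        ).append(w)
    comparisons = []
    for key in sorted(by_key):
        strains = by_key[key]
        if wt_strain in strains and mut_strain in strains:
            comparisons.append(
                compare_pm(strains[wt_strain], strains[mut_strain], baseline)
            )
    return flag_differences(comparisons, error_bar)


def comparisons_to_frame(comparisons: list[PMComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
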